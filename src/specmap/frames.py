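"""Snapshot container for MD frames with force-field metadata.

A :class:`SnapshotFrame` carries, for one MD snapshot, the atom coordinates
(angstrom), OPLS-style partial charges (e), per-atom Lennard-Jones
parameters (sigma in angstrom, epsilon in kJ/mol) and a role label per
atom.  The roles identify the terminal-alkyne probe atoms (the terminal
hydrogen and the two triple-bond carbons), the solvent, solvent atoms
excluded from the repulsive Lennard-Jones sums (the electron-donor
nitrogens), and any remaining solute atoms.

The box is orthorhombic (edge lengths in angstrom); minimum-image
displacements assume it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ROLE_H",
    "ROLE_CH",
    "ROLE_CR",
    "ROLE_SOLVENT",
    "ROLE_DONOR",
    "ROLE_OTHER_SOLUTE",
    "ROLES",
    "SnapshotFrame",
    "minimum_image",
]

ROLE_H = "H_terminal"
ROLE_CH = "C_H"  # triple-bond carbon bonded to the terminal hydrogen
ROLE_CR = "C_R"  # triple-bond carbon bonded to the R group
ROLE_SOLVENT = "solvent"
ROLE_DONOR = "donor_excluded"  # e.g. the TEA nitrogen
ROLE_OTHER_SOLUTE = "other_solute"

ROLES = (ROLE_H, ROLE_CH, ROLE_CR, ROLE_SOLVENT, ROLE_DONOR, ROLE_OTHER_SOLUTE)


def minimum_image(displacements: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap Cartesian displacement vectors into the central image."""
    return displacements - box * np.round(displacements / box)


@dataclass
class SnapshotFrame:
    """One MD snapshot with charges, LJ parameters and role labels."""

    coordinates: np.ndarray  # (N, 3) angstrom
    charges: np.ndarray  # (N,) elementary charges
    lj_sigma: np.ndarray  # (N,) angstrom
    lj_epsilon: np.ndarray  # (N,) kJ/mol
    roles: np.ndarray  # (N,) strings from ROLES
    box: np.ndarray  # (3,) orthorhombic edge lengths, angstrom

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.lj_sigma = np.asarray(self.lj_sigma, dtype=float)
        self.lj_epsilon = np.asarray(self.lj_epsilon, dtype=float)
        self.roles = np.asarray(self.roles, dtype=object)
        self.box = np.asarray(self.box, dtype=float)
        n = self.coordinates.shape[0]
        if self.coordinates.shape != (n, 3):
            raise ValueError("coordinates must have shape (N, 3)")
        for name in ("charges", "lj_sigma", "lj_epsilon", "roles"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},), got {arr.shape}")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive orthorhombic edge lengths")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        if not np.all(np.isfinite(self.charges)):
            raise ValueError("charges must be finite")
        unknown = set(self.roles) - set(ROLES)
        if unknown:
            raise ValueError(f"unknown role label(s): {sorted(unknown)}")
        for role in (ROLE_H, ROLE_CH, ROLE_CR):
            count = int(np.sum(self.roles == role))
            if count != 1:
                raise ValueError(
                    f"expected exactly one atom with role {role!r}, found {count}"
                )

    @property
    def n_atoms(self) -> int:
        return int(self.coordinates.shape[0])

    def index_of(self, role: str) -> int:
        """Index of the unique atom carrying one of the three probe roles."""
        idx = np.nonzero(self.roles == role)[0]
        if idx.size != 1:
            raise ValueError(f"role {role!r} is not unique in this frame")
        return int(idx[0])

    def position_of(self, role: str) -> np.ndarray:
        return self.coordinates[self.index_of(role)]

    def mask(self, *roles: str) -> np.ndarray:
        """Boolean mask selecting atoms whose role is in ``roles``."""
        return np.isin(self.roles, list(roles))
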
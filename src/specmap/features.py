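"""Spectroscopic-map variables extracted from MD snapshots.

Six variables are computed per frame at the terminal-alkyne probe:

* ``f0, f1, f2`` -- the solvent electric field at the terminal hydrogen
  projected on the C-H bond direction, and its first and second derivatives
  with respect to the C-H bond length (three-point centered finite
  differences, 0.1 angstrom spacing by default).  Electrostatics use the
  damped shifted force (DSF) kernel, so the pair field goes smoothly to
  zero at the cutoff without Ewald sums.
* ``u_H, u_CH, u_CR`` -- the repulsive (r^-12) part of the Lennard-Jones
  interaction summed over solvent atoms at each of the three probe atoms,
  using each solvent atom's own sigma and epsilon (no combining rules).
  Donor-flagged atoms (the solvent nitrogens) are excluded from these sums;
  their influence is already carried by the field variables.

Sign convention: the projection axis points from the terminal hydrogen
toward its carbon.  An electron-rich (negatively charged) site facing the
hydrogen therefore gives a *negative* projected field, and with the fitted
map coefficients lowers the frequency -- matching the red shift of
nitrogen-associated alkynes.

All features are returned in atomic units (fields in E_h/(e a0) with
derivatives per a0; LJ sums in E_h), ready to be contracted with the map
coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erfc

from .frames import (
    ROLE_CH,
    ROLE_CR,
    ROLE_DONOR,
    ROLE_H,
    ROLE_SOLVENT,
    SnapshotFrame,
    minimum_image,
)
from .units import ANGSTROM_TO_BOHR, KJMOL_TO_HARTREE

__all__ = [
    "FeatureVector",
    "dsf_field",
    "projected_field_derivatives",
    "repulsive_lj",
    "compute_features",
    "DEFAULT_CUTOFF",
    "DEFAULT_DAMPING",
    "DEFAULT_SPACING",
]

#: electrostatic / LJ cutoff, angstrom (1.4 nm, the simulation cutoff)
DEFAULT_CUTOFF = 14.0
#: DSF damping parameter, 1/angstrom
DEFAULT_DAMPING = 0.2
#: finite-difference spacing for the field derivatives, angstrom
DEFAULT_SPACING = 0.1


@dataclass(frozen=True)
class FeatureVector:
    """The six map variables for one frame, in atomic units."""

    f0: float  # projected field, E_h/(e a0)
    f1: float  # first derivative along the bond, E_h/(e a0^2)
    f2: float  # second derivative, E_h/(e a0^3)
    u_H: float  # repulsive LJ sum at the terminal hydrogen, E_h
    u_CH: float  # ... at the carbon bonded to H
    u_CR: float  # ... at the carbon bonded to R

    def __post_init__(self) -> None:
        values = self.as_array()
        if not np.all(np.isfinite(values)):
            raise ValueError("map features must be finite")
        if min(self.u_H, self.u_CH, self.u_CR) < 0:
            raise ValueError("repulsive LJ sums must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.f0, self.f1, self.f2, self.u_H, self.u_CH, self.u_CR])


def _check_cutoff(frame: SnapshotFrame, cutoff: float) -> None:
    half_min_edge = float(np.min(frame.box)) / 2.0
    if cutoff >= half_min_edge:
        raise ValueError(
            f"cutoff {cutoff} A must be smaller than half the minimum box edge "
            f"({half_min_edge} A) for minimum-image validity"
        )


def _dsf_kernel(r: np.ndarray, alpha: float, cutoff: float, variant: str) -> np.ndarray:
    """Radial field kernel f(r) such that E = q f(r) r_hat, in 1/length^2."""
    f = erfc(alpha * r) / r**2 + 2.0 * alpha * np.exp(-(alpha * r) ** 2) / (
        np.sqrt(np.pi) * r
    )
    if variant == "dsf":
        rc = cutoff
        f_rc = erfc(alpha * rc) / rc**2 + 2.0 * alpha * np.exp(-(alpha * rc) ** 2) / (
            np.sqrt(np.pi) * rc
        )
        f = f - f_rc
    elif variant != "dsp":
        raise ValueError(f"unknown electrostatics variant {variant!r}; use 'dsf' or 'dsp'")
    return f


def dsf_field(
    frame: SnapshotFrame,
    eval_point: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
    damping: float = DEFAULT_DAMPING,
    variant: str = "dsf",
) -> np.ndarray:
    """Damped-shifted-force electric field of the solvent at a point.

    Sums over all solvent atoms (donor-flagged nitrogens included; solute
    atoms excluded) within the minimum-image cutoff.  For the default
    ``variant="dsf"`` the radial kernel is force-shifted so the pair field
    vanishes continuously at the cutoff; ``variant="dsp"`` differentiates
    the damped shifted *potential* instead (no kernel shift).

    Returns the field vector in atomic units, E_h/(e a0).
    """
    _check_cutoff(frame, cutoff)
    eval_point = np.asarray(eval_point, dtype=float)
    sel = frame.mask(ROLE_SOLVENT, ROLE_DONOR)
    if not np.any(sel):
        return np.zeros(3)
    disp = minimum_image(eval_point[None, :] - frame.coordinates[sel], frame.box)
    dist = np.linalg.norm(disp, axis=1)
    zero = np.nonzero(dist < 1e-12)[0]
    if zero.size:
        atom = int(np.nonzero(sel)[0][zero[0]])
        raise ValueError(f"evaluation point coincides with atom index {atom}")
    within = dist < cutoff
    if not np.any(within):
        return np.zeros(3)
    disp, dist = disp[within], dist[within]
    q = frame.charges[sel][within]
    # work in bohr so q [e] and r [a0] give the field directly in E_h/(e a0)
    dist_b = dist * ANGSTROM_TO_BOHR
    alpha_b = damping / ANGSTROM_TO_BOHR
    cutoff_b = cutoff * ANGSTROM_TO_BOHR
    kernel = _dsf_kernel(dist_b, alpha_b, cutoff_b, variant)
    unit_vec = disp / dist[:, None]
    return (q * kernel) @ unit_vec


def projected_field_derivatives(
    frame: SnapshotFrame,
    spacing: float = DEFAULT_SPACING,
    cutoff: float = DEFAULT_CUTOFF,
    damping: float = DEFAULT_DAMPING,
    variant: str = "dsf",
) -> tuple[float, float, float]:
    """Projected field at the terminal H and its bond-length derivatives.

    The field is fully re-summed at the hydrogen site and at the two points
    displaced by +/- ``spacing`` along the bond-extension direction; the
    displaced point at larger C-H separation is the forward point of the
    finite differences

        f1 = (p(+) - p(-)) / (2 d),   f2 = (p(+) - 2 p(0) + p(-)) / d^2,

    where p is the field projected on the H->C unit vector (see the module
    docstring for the sign convention).  Results are in atomic units with
    derivatives taken per bohr.
    """
    if spacing <= 0:
        raise ValueError(f"finite-difference spacing must be positive, got {spacing}")
    h_pos = frame.position_of(ROLE_H)
    c_pos = frame.position_of(ROLE_CH)
    bond = minimum_image(h_pos - c_pos, frame.box)  # C -> H
    bond_len = float(np.linalg.norm(bond))
    if bond_len < 0.05:
        raise ValueError(f"degenerate C-H bond vector (length {bond_len:.4g} A)")
    extend = bond / bond_len  # direction of increasing bond length
    project = -extend  # H -> C projection axis
    p = np.empty(3)
    for k, shift in enumerate((-spacing, 0.0, spacing)):
        field = dsf_field(frame, h_pos + shift * extend, cutoff, damping, variant)
        p[k] = field @ project
    d_bohr = spacing * ANGSTROM_TO_BOHR
    f0 = p[1]
    f1 = (p[2] - p[0]) / (2.0 * d_bohr)
    f2 = (p[2] - 2.0 * p[1] + p[0]) / d_bohr**2
    return float(f0), float(f1), float(f2)


def repulsive_lj(
    frame: SnapshotFrame,
    site_role: str,
    cutoff: float = DEFAULT_CUTOFF,
) -> float:
    """Repulsive Lennard-Jones sum at one probe atom, in hartree.

    ``sum_m 4 eps_m (sigma_m / r_m)^12`` over solvent atoms within the
    minimum-image cutoff, using the solvent atom's own parameters (no
    mixing rules).  Donor-flagged atoms are skipped: the sums run over the
    non-nitrogen solvent atoms only.
    """
    if site_role not in (ROLE_H, ROLE_CH, ROLE_CR):
        raise ValueError(f"site_role must be a probe-atom role, got {site_role!r}")
    _check_cutoff(frame, cutoff)
    site = frame.position_of(site_role)
    sel = frame.mask(ROLE_SOLVENT)
    if not np.any(sel):
        return 0.0
    eps = frame.lj_epsilon[sel]
    sig = frame.lj_sigma[sel]
    if np.any(eps < 0) or np.any(sig < 0):
        raise ValueError("Lennard-Jones sigma and epsilon must be non-negative")
    disp = minimum_image(site[None, :] - frame.coordinates[sel], frame.box)
    dist = np.linalg.norm(disp, axis=1)
    within = dist < cutoff
    energy_kjmol = np.sum(4.0 * eps[within] * (sig[within] / dist[within]) ** 12)
    return float(energy_kjmol * KJMOL_TO_HARTREE)


def compute_features(
    frame: SnapshotFrame,
    spacing: float = DEFAULT_SPACING,
    cutoff: float = DEFAULT_CUTOFF,
    damping: float = DEFAULT_DAMPING,
    variant: str = "dsf",
) -> FeatureVector:
    """All six map variables for one frame."""
    f0, f1, f2 = projected_field_derivatives(frame, spacing, cutoff, damping, variant)
    return FeatureVector(
        f0=f0,
        f1=f1,
        f2=f2,
        u_H=repulsive_lj(frame, ROLE_H, cutoff),
        u_CH=repulsive_lj(frame, ROLE_CH, cutoff),
        u_CR=repulsive_lj(frame, ROLE_CR, cutoff),
    )
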
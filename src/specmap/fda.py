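"""Frequency decomposition analysis on decomposed potential curves (ALMO-FDA).

An energy decomposition analysis (e.g. ALMO-EDA) splits the full
Born--Oppenheimer potential along the vibrational coordinate into the
isolated-fragment potential V_ISO(Q) plus interaction components

    V(Q) = V_ISO(Q) + dE_ELEC(Q) + dE_PAULI(Q) + dE_DISP(Q)
                    + dE_POL(Q) + dE_CT(Q).

The frequency shift attributable to component *m* is obtained by removing
that curve from the Hamiltonian, re-solving, and subtracting:

    domega_m = omega_FULL - omega_{m-REM}.

The components are consumed as tabulated curves from any EDA engine; no
electronic-structure computation happens here.  Shifts from individual
components are not expected to sum to the total solvent shift: removal is a
non-additive operation and that non-additivity is physical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .dvr import PotentialGrid, VibrationalSolution, solve

__all__ = ["DecomposedPotential", "frequency_full", "frequency_shift", "fda_report"]

#: frozen-orbital grouping conventionally used with ALMO decompositions
FROZEN_COMPONENTS = ("ELEC", "PAULI", "DISP")


@dataclass(frozen=True)
class DecomposedPotential:
    """Isolated-fragment potential plus named interaction components.

    ``grid.energies`` holds V_ISO; each entry of ``components`` is a
    per-grid-point energy curve (hartree).  Component names are free
    strings, so grouped terms (e.g. a pre-summed FRZ curve) are allowed.
    """

    grid: PotentialGrid
    components: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        comps = {}
        for name, curve in self.components.items():
            arr = np.asarray(curve, dtype=float)
            if arr.shape != (self.grid.n_points,):
                raise ValueError(
                    f"component {name!r} has length {arr.size}, "
                    f"expected {self.grid.n_points} to match the grid"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"component {name!r} contains non-finite energies")
            comps[name] = arr
        object.__setattr__(self, "components", comps)

    def total_potential(self, exclude: Iterable[str] = ()) -> np.ndarray:
        """V_ISO plus all components not listed in ``exclude`` (hartree)."""
        exclude = set(exclude)
        unknown = exclude - set(self.components)
        if unknown:
            raise KeyError(
                f"unknown component(s) {sorted(unknown)}; "
                f"available: {sorted(self.components)}"
            )
        v = self.grid.energies.copy()
        for name, curve in self.components.items():
            if name not in exclude:
                v = v + curve
        return v

    def _solve_excluding(
        self, exclude: Iterable[str], scaling_factor: float
    ) -> VibrationalSolution:
        grid = PotentialGrid(
            points=self.grid.points,
            energies=self.total_potential(exclude),
            reduced_mass=self.grid.reduced_mass,
        )
        return solve(grid, scaling_factor=scaling_factor)


def frequency_full(dp: DecomposedPotential, scaling_factor: float = 1.0) -> float:
    """omega_FULL (cm^-1) from the full potential V_ISO + sum of components."""
    return dp._solve_excluding((), scaling_factor).fundamental


def frequency_shift(
    dp: DecomposedPotential,
    component: str | Iterable[str],
    scaling_factor: float = 1.0,
) -> float:
    """Frequency change due to one component (or a named group of them).

    Builds the removed-term Hamiltonian on ``V_ISO + sum_{n != m} dE_n``,
    solves for omega_{m-REM}, and returns
    ``domega_m = omega_FULL - omega_{m-REM}`` in cm^-1.  Passing several
    names removes them together (e.g. the frozen term ELEC+PAULI+DISP).
    The scaling factor multiplies each frequency before subtraction; for a
    multiplicative factor the order is immaterial.
    """
    names = [component] if isinstance(component, str) else list(component)
    omega_full = frequency_full(dp, scaling_factor)
    omega_removed = dp._solve_excluding(names, scaling_factor).fundamental
    return omega_full - omega_removed


def fda_report(
    dp: DecomposedPotential, scaling_factor: float = 1.0
) -> dict[str, float]:
    """omega_FULL, omega_ISO and the one-at-a-time shift of every component."""
    report = {
        "omega_FULL": frequency_full(dp, scaling_factor),
        "omega_ISO": dp._solve_excluding(dp.components.keys(), scaling_factor).fundamental,
    }
    for name in dp.components:
        report[f"domega_{name}"] = frequency_shift(dp, name, scaling_factor)
    return report
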
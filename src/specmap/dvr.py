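"""One-dimensional sinc-DVR vibrational solver.

A single localized vibrational coordinate ``Q`` is discretized on ``P``
equally spaced grid points and the Hamiltonian ``H = T + diag(V)`` is
diagonalized in the grid-point (discrete variable) basis.  The kinetic
operator uses the sinc-function (Colbert--Miller) closed form for an
infinite uniform grid,

    T_ij = hbar^2 / (2 m dQ^2) * (-1)^(i-j) * { pi^2/3      if i == j
                                              { 2/(i-j)^2   otherwise,

which is exact in the limit of a fine grid and converges exponentially for
bound states that fit inside the grid span.  The anharmonic fundamental is
the difference of the two lowest eigenvalues, optionally multiplied by a
DFT-method scaling factor (e.g. 0.989 for TPSS-D3, 0.966 for B3LYP-D3,
0.931 for PBEh-3c).

Units: grid points in angstrom, potential energies in hartree, reduced mass
in amu; frequencies are returned in cm^-1.  All conversions come from
:mod:`specmap.units`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import AMU_TO_ME, ANGSTROM_TO_BOHR, HARTREE_TO_INVCM

__all__ = [
    "PotentialGrid",
    "VibrationalSolution",
    "build_kinetic_matrix",
    "solve",
    "matrix_element",
]

#: relative tolerance on grid uniformity required by the sinc basis
_SPACING_RTOL = 1e-10


@dataclass(frozen=True)
class PotentialGrid:
    """A tabulated 1D potential on an equally spaced coordinate grid.

    Parameters
    ----------
    points:
        Strictly increasing, equally spaced coordinate values (angstrom).
    energies:
        Potential energy at each point (hartree).
    reduced_mass:
        Reduced mass conjugate to the coordinate (amu).  The localized-mode
        construction that defines the coordinate and its mass is an input to
        this package, not computed here.
    """

    points: np.ndarray
    energies: np.ndarray
    reduced_mass: float

    def __post_init__(self) -> None:
        points = np.asarray(self.points, dtype=float)
        energies = np.asarray(self.energies, dtype=float)
        object.__setattr__(self, "points", points)
        object.__setattr__(self, "energies", energies)
        if points.ndim != 1 or energies.ndim != 1:
            raise ValueError("points and energies must be 1D arrays")
        if points.size != energies.size:
            raise ValueError(
                f"points ({points.size}) and energies ({energies.size}) differ in length"
            )
        if points.size < 3:
            raise ValueError(f"need at least 3 grid points, got {points.size}")
        if not np.all(np.isfinite(points)) or not np.all(np.isfinite(energies)):
            raise ValueError("grid points and energies must be finite")
        diffs = np.diff(points)
        if np.any(diffs <= 0):
            raise ValueError("grid points must be strictly increasing")
        dq = diffs[0]
        bad = np.nonzero(np.abs(diffs - dq) > _SPACING_RTOL * dq)[0]
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                "grid is not uniform: interval "
                f"[{points[i]:.12g}, {points[i + 1]:.12g}] (index {i}) has spacing "
                f"{diffs[i]:.12g}, expected {dq:.12g}"
            )
        if self.reduced_mass <= 0:
            raise ValueError(f"reduced mass must be positive, got {self.reduced_mass}")

    @property
    def n_points(self) -> int:
        return int(self.points.size)

    @property
    def spacing(self) -> float:
        """Grid spacing dQ in angstrom."""
        return float(self.points[1] - self.points[0])


@dataclass(frozen=True)
class VibrationalSolution:
    """Eigenpairs of the grid Hamiltonian.

    ``eigenvectors[:, n]`` holds the amplitudes of state ``n`` on the grid,
    unit normalized under the DVR quadrature ``sum_i psi_n(Q_i)^2 = 1``.
    ``fundamental`` is ``scaling_factor * (E_1 - E_0)`` in cm^-1.
    """

    grid: PotentialGrid
    eigenvalues: np.ndarray  # hartree, ascending
    eigenvectors: np.ndarray  # (P, P), column n = state n
    scaling_factor: float = 1.0
    fundamental: float = field(init=False)

    def __post_init__(self) -> None:
        gap = float(self.eigenvalues[1] - self.eigenvalues[0])
        object.__setattr__(
            self, "fundamental", self.scaling_factor * gap * HARTREE_TO_INVCM
        )

    def frequency(self, bra: int = 0, ket: int = 1) -> float:
        """Scaled transition frequency E_ket - E_bra in cm^-1."""
        gap = float(self.eigenvalues[ket] - self.eigenvalues[bra])
        return self.scaling_factor * gap * HARTREE_TO_INVCM


def build_kinetic_matrix(grid: PotentialGrid) -> np.ndarray:
    """Sinc-DVR kinetic energy matrix in hartree.

    The diagonal is ``hbar^2 pi^2 / (6 m dQ^2)`` and off-diagonal elements
    alternate in sign and decay as ``1/(i-j)^2``; the matrix is symmetric by
    construction.
    """
    p = grid.n_points
    m = grid.reduced_mass * AMU_TO_ME
    dq = grid.spacing * ANGSTROM_TO_BOHR
    idx = np.arange(p)
    ij = idx[:, None] - idx[None, :]
    with np.errstate(divide="ignore"):
        t = np.where(ij == 0, np.pi**2 / 3.0, 2.0 / np.where(ij == 0, 1, ij) ** 2)
    t = t * ((-1.0) ** ij) / (2.0 * m * dq**2)
    return t


def solve(grid: PotentialGrid, scaling_factor: float = 1.0) -> VibrationalSolution:
    """Diagonalize ``H = T + diag(V)`` and return all eigenpairs.

    The fundamental frequency is ``scaling_factor * (E_1 - E_0)`` converted
    to cm^-1.  Adding any constant to the potential leaves it unchanged.
    """
    if scaling_factor <= 0:
        raise ValueError(f"scaling factor must be positive, got {scaling_factor}")
    h = build_kinetic_matrix(grid)
    h[np.diag_indices_from(h)] += grid.energies
    eigenvalues, eigenvectors = np.linalg.eigh(h)
    if not np.all(np.isfinite(eigenvalues)):
        raise ValueError("Hamiltonian diagonalization produced non-finite eigenvalues")
    return VibrationalSolution(
        grid=grid,
        eigenvalues=eigenvalues,
        eigenvectors=eigenvectors,
        scaling_factor=scaling_factor,
    )


def matrix_element(
    solution: VibrationalSolution,
    operator_values: np.ndarray,
    bra: int = 0,
    ket: int = 1,
) -> float:
    """DVR matrix element <bra| O(Q) |ket> of a coordinate-local operator.

    In the DVR the operator is diagonal on the grid, so the element is
    ``sum_i psi_bra(Q_i) O(Q_i) psi_ket(Q_i)``.  For the isotropic transition
    polarizability the caller supplies the tensor trace
    ``(a_xx + a_yy + a_zz)/3`` at each grid point.
    """
    values = np.asarray(operator_values, dtype=float)
    p = solution.grid.n_points
    if values.shape != (p,):
        raise ValueError(
            f"operator_values has shape {values.shape}, expected ({p},) to match the grid"
        )
    n_states = solution.eigenvalues.size
    if not (0 <= bra < n_states and 0 <= ket < n_states):
        raise IndexError(f"state indices ({bra}, {ket}) out of range for {n_states} states")
    return float(
        solution.eigenvectors[:, bra] @ (values * solution.eigenvectors[:, ket])
    )
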
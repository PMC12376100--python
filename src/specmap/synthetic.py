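"""Synthetic fixtures with known ground truth for every analysis module.

Everything the solvers, the map and the lineshape machinery consume can be
generated here deterministically (same seed, same bytes), with the
generating parameters returned alongside the artifact so that downstream
tests are parameter-recovery tests rather than golden files.

The solvated-frame generators emulate the probe/solvent geometry of a
terminal alkyne in triethylamine coarsely: a linear C_R-C_H-H probe with
the triple-bond carbon 1.215 A and the hydrogen 2.276 A from the R-group
carbon along the axis, and a donor "amine" cluster made of one negatively
charged nitrogen-like site flanked by three charge-compensating alkyl
sites.  When the cluster faces the hydrogen at a typical contact distance
(~2.1 A) its nitrogen sits inside the standard association region
(z in [3, 6] A, r in [0, 3] A).  No attempt is made to reproduce a real
force field's conformational detail -- occupancy, residence time, density
and noise levels are explicit knobs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dvr import PotentialGrid
from .fda import DecomposedPotential
from .frames import (
    ROLE_CH,
    ROLE_CR,
    ROLE_DONOR,
    ROLE_H,
    ROLE_SOLVENT,
    SnapshotFrame,
)
from .raman import FrequencyTrajectory
from .solvation import AssociationSeries
from .units import AMU_TO_ME, ANGSTROM_TO_BOHR, HARTREE_TO_INVCM

__all__ = [
    "make_harmonic_pes",
    "make_morse_pes",
    "make_decomposed_pes",
    "make_solvated_frame",
    "make_ideal_gas_frames",
    "make_structured_frames",
    "make_frequency_traj",
    "make_telegraph_series",
    "make_angle_surface_samples",
    "make_qm_convergence_series",
    "SOLUTE_GEOMETRY",
]

#: probe geometry along the +z axis, angstrom from C_R
SOLUTE_GEOMETRY = {"C_R": 0.0, "C_H": 1.215, "H": 2.276}

#: default reduced mass of the localized CC-stretch coordinate, amu
DEFAULT_MASS = 6.0

#: default fundamental of the harmonic fixtures, cm^-1 (alkyne-like)
DEFAULT_OMEGA = 2130.0


def _omega_au(omega_cm: float) -> float:
    return omega_cm / HARTREE_TO_INVCM


def _grid_points(span: float, n_points: int, center: float = 0.0) -> np.ndarray:
    return np.linspace(center - span, center + span, n_points)


def _harmonic_span(omega_cm: float, mass: float, margin: float = 1.6) -> float:
    """Span from the classical turning point of state n = 3, in angstrom.

    Covers the highest state entering the fundamental comfortably while
    keeping the P = 20 spacing fine enough for sinc-DVR accuracy.
    """
    m_au = mass * AMU_TO_ME
    q_turn = math.sqrt(7.0 / (m_au * _omega_au(omega_cm)))  # bohr, n = 3
    return margin * q_turn / ANGSTROM_TO_BOHR


@dataclass(frozen=True)
class HarmonicPES:
    grid: PotentialGrid
    force_constant: float  # hartree / bohr^2
    analytic_fundamental: float  # cm^-1


def make_harmonic_pes(
    omega_cm: float = DEFAULT_OMEGA,
    mass: float = DEFAULT_MASS,
    n_points: int = 20,
    span: float | None = None,
) -> HarmonicPES:
    """Harmonic grid V = k Q^2 / 2 with its analytic fundamental stored."""
    m_au = mass * AMU_TO_ME
    k = m_au * _omega_au(omega_cm) ** 2  # E_h / a0^2
    if span is None:
        span = _harmonic_span(omega_cm, mass)
    points = _grid_points(span, n_points)
    q_bohr = points * ANGSTROM_TO_BOHR
    grid = PotentialGrid(points=points, energies=0.5 * k * q_bohr**2, reduced_mass=mass)
    return HarmonicPES(grid=grid, force_constant=k, analytic_fundamental=omega_cm)


@dataclass(frozen=True)
class MorsePES:
    grid: PotentialGrid
    depth: float  # hartree
    steepness: float  # 1 / bohr
    omega_e: float  # cm^-1
    omega_e_chi_e: float  # cm^-1
    analytic_fundamental: float  # cm^-1, omega_e - 2 omega_e chi_e


def make_morse_pes(
    omega_e_cm: float = DEFAULT_OMEGA,
    anharmonicity_cm: float = 15.0,
    mass: float = DEFAULT_MASS,
    n_points: int = 20,
) -> MorsePES:
    """Morse grid V = D (1 - e^{-aQ})^2 with closed-form level spacing.

    In atomic units ``omega_e = a sqrt(2 D / m)`` and
    ``omega_e chi_e = a^2 / (2 m)``, so the requested wavenumbers fix
    ``a = sqrt(2 m we_chi)`` and ``D = we^2 / (4 we_chi)``.  The grid is
    asymmetric about the minimum (softer outer wall) with span scaled from
    the matching harmonic turning point.
    """
    m_au = mass * AMU_TO_ME
    we = _omega_au(omega_e_cm)
    wexe = _omega_au(anharmonicity_cm)
    a = math.sqrt(2.0 * m_au * wexe)  # 1/bohr
    depth = we**2 / (4.0 * wexe)  # hartree
    span = _harmonic_span(omega_e_cm, mass, margin=1.4)
    points = np.linspace(-span, 1.45 * span, n_points)
    q_bohr = points * ANGSTROM_TO_BOHR
    energies = depth * (1.0 - np.exp(-a * q_bohr)) ** 2
    grid = PotentialGrid(points=points, energies=energies, reduced_mass=mass)
    return MorsePES(
        grid=grid,
        depth=depth,
        steepness=a,
        omega_e=omega_e_cm,
        omega_e_chi_e=anharmonicity_cm,
        analytic_fundamental=omega_e_cm - 2.0 * anharmonicity_cm,
    )


@dataclass(frozen=True)
class DecomposedPESFixture:
    potential: DecomposedPotential
    curvature_fractions: dict[str, float]
    analytic_omega_iso: float  # cm^-1
    analytic_omega_full: float  # cm^-1

    def analytic_omega_removed(self, component: str) -> float:
        """Exact frequency with one quadratic component removed."""
        total = 1.0 + sum(self.curvature_fractions.values())
        return self.analytic_omega_iso * math.sqrt(
            total - self.curvature_fractions[component]
        )

    def analytic_shift(self, component: str) -> float:
        return self.analytic_omega_full - self.analytic_omega_removed(component)


def make_decomposed_pes(
    omega_iso_cm: float = DEFAULT_OMEGA,
    mass: float = DEFAULT_MASS,
    n_points: int = 20,
    curvature_fractions: dict[str, float] | None = None,
    linear_scale: float = 0.02,
    seed: int = 0,
) -> DecomposedPESFixture:
    """Decomposed harmonic fixture with component-wise analytic shifts.

    Each interaction component contributes a quadratic curve
    ``c_m k Q^2 / 2`` plus a small random linear-plus-constant part that
    moves the minimum but (exactly, for quadratic potentials) not the
    frequency.  The default curvature signs mimic the physical pattern:
    Pauli repulsion stiffens the mode (positive shift) while
    electrostatics and charge transfer soften it.
    """
    if curvature_fractions is None:
        curvature_fractions = {
            "ELEC": -0.060,
            "PAULI": +0.100,
            "DISP": -0.005,
            "POL": -0.015,
            "CT": -0.070,
        }
    rng = np.random.default_rng(seed)
    m_au = mass * AMU_TO_ME
    k = m_au * _omega_au(omega_iso_cm) ** 2
    span = _harmonic_span(omega_iso_cm, mass)
    points = _grid_points(span, n_points)
    q = points * ANGSTROM_TO_BOHR
    components = {}
    for name, frac in curvature_fractions.items():
        slope = linear_scale * k * span * ANGSTROM_TO_BOHR * rng.uniform(-1.0, 1.0)
        offset = rng.uniform(-1.0, 1.0) * 1e-3
        components[name] = 0.5 * frac * k * q**2 + slope * q + offset
    grid = PotentialGrid(points=points, energies=0.5 * k * q**2, reduced_mass=mass)
    total = 1.0 + sum(curvature_fractions.values())
    if total <= 0:
        raise ValueError("curvature fractions must leave a confining total potential")
    return DecomposedPESFixture(
        potential=DecomposedPotential(grid=grid, components=components),
        curvature_fractions=dict(curvature_fractions),
        analytic_omega_iso=omega_iso_cm,
        analytic_omega_full=omega_iso_cm * math.sqrt(total),
    )


# ---------------------------------------------------------------------------
# solvated frames
# ---------------------------------------------------------------------------

_PROBE_LJ = {  # sigma (A), epsilon (kJ/mol): generic alkyne-like values
    ROLE_H: (2.42, 0.063),
    ROLE_CH: (3.30, 0.276),
    ROLE_CR: (3.30, 0.276),
}
_PROBE_CHARGES = {ROLE_H: 0.23, ROLE_CH: -0.36, ROLE_CR: 0.13}


def _solute_arrays(box: float) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str]]:
    center = 0.5 * box
    coords = np.array(
        [
            [center, center, center + SOLUTE_GEOMETRY["C_R"]],
            [center, center, center + SOLUTE_GEOMETRY["C_H"]],
            [center, center, center + SOLUTE_GEOMETRY["H"]],
        ]
    )
    roles = [ROLE_CR, ROLE_CH, ROLE_H]
    charges = np.array([_PROBE_CHARGES[r] for r in roles])
    sigma = np.array([_PROBE_LJ[r][0] for r in roles])
    epsilon = np.array([_PROBE_LJ[r][1] for r in roles])
    return coords, charges, sigma, epsilon, roles


def make_solvated_frame(
    n_solvent: int = 50,
    box: float = 30.0,
    n_donor: int = 5,
    min_distance: float = 2.0,
    max_distance: float | None = None,
    seed: int = 0,
) -> SnapshotFrame:
    """One random frame for feature-extraction tests.

    ``n_solvent`` point charges with random OPLS-scale charges and LJ
    parameters are scattered uniformly, keeping ``min_distance`` clear of
    the probe atoms; ``n_donor`` of them are donor-flagged.  With
    ``max_distance`` set, solvent is confined to a cluster around the probe
    so that no interaction crosses a periodic image -- the configuration
    for exact rigid-motion invariance checks.
    """
    rng = np.random.default_rng(seed)
    coords, charges, sigma, epsilon, roles = _solute_arrays(box)
    placed = []
    while len(placed) < n_solvent:
        pos = rng.uniform(0.0, box, size=3)
        d = np.min(np.linalg.norm(coords[:3] - pos, axis=1))
        if d < min_distance:
            continue
        if max_distance is not None and d > max_distance:
            continue
        placed.append(pos)
    solvent = np.array(placed)
    s_charges = rng.uniform(-0.5, 0.5, size=n_solvent)
    s_sigma = rng.uniform(2.5, 3.8, size=n_solvent)
    s_eps = rng.uniform(0.05, 0.8, size=n_solvent)
    s_roles = np.array([ROLE_SOLVENT] * n_solvent, dtype=object)
    donor_idx = rng.choice(n_solvent, size=min(n_donor, n_solvent), replace=False)
    s_roles[donor_idx] = ROLE_DONOR
    return SnapshotFrame(
        coordinates=np.vstack([coords, solvent]),
        charges=np.concatenate([charges, s_charges]),
        lj_sigma=np.concatenate([sigma, s_sigma]),
        lj_epsilon=np.concatenate([epsilon, s_eps]),
        roles=np.array(roles + list(s_roles), dtype=object),
        box=np.full(3, float(box)),
    )


def make_ideal_gas_frames(
    n_frames: int = 100,
    density: float = 0.004,
    box: float = 30.0,
    species: str = ROLE_DONOR,
    seed: int = 0,
) -> list[SnapshotFrame]:
    """Uncorrelated uniform (ideal-gas) solvent frames at a set density.

    The probe sits at the box center; species atoms are uniform random with
    count ``round(density * box^3)``, so the cylindrical distribution
    function of the species is 1 everywhere up to sampling noise and region
    occupancies are Poisson.
    """
    if density <= 0:
        raise ValueError(f"density must be positive, got {density}")
    rng = np.random.default_rng(seed)
    n_atoms = int(round(density * box**3))
    coords0, charges0, sigma0, eps0, roles0 = _solute_arrays(box)
    frames = []
    for _ in range(n_frames):
        solvent = rng.uniform(0.0, box, size=(n_atoms, 3))
        frames.append(
            SnapshotFrame(
                coordinates=np.vstack([coords0, solvent]),
                charges=np.concatenate([charges0, np.zeros(n_atoms)]),
                lj_sigma=np.concatenate([sigma0, np.full(n_atoms, 3.5)]),
                lj_epsilon=np.concatenate([eps0, np.full(n_atoms, 0.3)]),
                roles=np.array(roles0 + [species] * n_atoms, dtype=object),
                box=np.full(3, float(box)),
            )
        )
    return frames


#: donor cluster parameters: an amine-like nitrogen with three alkyl sites
_DONOR_N = {"charge": -0.63, "sigma": 3.25, "epsilon": 0.711}
_DONOR_C = {"charge": +0.21, "sigma": 3.50, "epsilon": 0.276}
_NC_BOND = 1.47  # angstrom
_NC_ANGLE = math.radians(70.5)  # N-C bond tilt from the lone-pair axis


def _donor_cluster(
    rng: np.random.Generator,
    h_pos: np.ndarray,
    direction: np.ndarray,
    distance: float,
) -> np.ndarray:
    """Positions (4, 3) of N + 3 alkyl sites, lone pair facing ``-direction``."""
    direction = direction / np.linalg.norm(direction)
    n_pos = h_pos + distance * direction
    # orthonormal frame about the lone-pair axis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(direction @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(direction, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(direction, e1)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    sites = [n_pos]
    for k in range(3):
        phi = phase + 2.0 * np.pi * k / 3.0
        offset = _NC_BOND * (
            math.cos(_NC_ANGLE) * direction
            + math.sin(_NC_ANGLE) * (math.cos(phi) * e1 + math.sin(phi) * e2)
        )
        sites.append(n_pos + offset)
    return np.array(sites)


def _markov_occupancy(
    rng: np.random.Generator, n_frames: int, occupancy: float, residence_frames: float
) -> np.ndarray:
    """Two-state Markov occupancy with set stationary probability and residence."""
    if not 0.0 < occupancy < 1.0:
        raise ValueError("occupancy must lie strictly between 0 and 1")
    p_leave = min(1.0, 1.0 / max(residence_frames, 1.0))  # occupied -> free
    p_enter = min(1.0, p_leave * occupancy / (1.0 - occupancy))
    state = rng.random() < occupancy
    states = np.empty(n_frames, dtype=bool)
    for k in range(n_frames):
        states[k] = state
        if state:
            state = rng.random() >= p_leave
        else:
            state = rng.random() < p_enter
    return states


def make_structured_frames(
    n_frames: int = 500,
    occupancy: float = 0.6,
    residence_frames: float = 3.0,
    contact_distance: float = 2.1,
    contact_jitter: float = 0.25,
    n_bath: int = 40,
    box: float = 30.0,
    seed: int = 0,
) -> tuple[list[SnapshotFrame], np.ndarray, dict[str, float]]:
    """TEA-like frames with a donor cluster alternating in and out of contact.

    In occupied frames the cluster's nitrogen faces the terminal hydrogen
    at ``contact_distance`` (+/- jitter, slight tilt), which places it
    inside the default association region; in free frames the cluster sits
    7-12 A away in a random direction.  ``n_bath`` neutral LJ sites fill a
    loose solvent shell so the repulsive-LJ features are nonzero.  The
    occupancy sequence is a persistent two-state Markov chain.

    Returns ``(frames, occupied, params)`` where ``occupied`` is the
    boolean ground-truth occupancy per frame.
    """
    rng = np.random.default_rng(seed)
    coords0, charges0, sigma0, eps0, roles0 = _solute_arrays(box)
    h_pos = coords0[2]
    axis = np.array([0.0, 0.0, 1.0])
    occupied = _markov_occupancy(rng, n_frames, occupancy, residence_frames)
    frames = []
    for k in range(n_frames):
        if occupied[k]:
            dist = float(
                np.clip(
                    rng.normal(contact_distance, contact_jitter),
                    contact_distance - 2.0 * contact_jitter,
                    contact_distance + 2.0 * contact_jitter,
                )
            )
            tilt = rng.normal(0.0, 0.12, size=3)
            tilt[2] = 0.0
            direction = axis + tilt
        else:
            dist = rng.uniform(7.0, 12.0)
            direction = rng.normal(size=3)
            # keep the free cluster clear of the probe's backward axis too
            direction[2] = abs(direction[2]) * rng.choice([1.0, -0.3])
        cluster = _donor_cluster(rng, h_pos, direction, dist)

        bath = []
        while len(bath) < n_bath:
            pos = rng.uniform(0.0, box, size=3)
            d_solute = np.min(np.linalg.norm(coords0 - pos, axis=1))
            d_cluster = np.min(np.linalg.norm(cluster - pos, axis=1))
            if 3.2 <= d_solute and d_cluster >= 3.0:
                bath.append(pos)
        bath = np.array(bath)

        coordinates = np.vstack([coords0, cluster, bath])
        charges = np.concatenate(
            [
                charges0,
                [_DONOR_N["charge"]] + [_DONOR_C["charge"]] * 3,
                np.zeros(n_bath),
            ]
        )
        sigma = np.concatenate(
            [sigma0, [_DONOR_N["sigma"]] + [_DONOR_C["sigma"]] * 3, np.full(n_bath, 3.5)]
        )
        epsilon = np.concatenate(
            [eps0, [_DONOR_N["epsilon"]] + [_DONOR_C["epsilon"]] * 3, np.full(n_bath, 0.3)]
        )
        roles = np.array(
            roles0 + [ROLE_DONOR] + [ROLE_SOLVENT] * 3 + [ROLE_SOLVENT] * n_bath,
            dtype=object,
        )
        frames.append(
            SnapshotFrame(
                coordinates=coordinates,
                charges=charges,
                lj_sigma=sigma,
                lj_epsilon=epsilon,
                roles=roles,
                box=np.full(3, float(box)),
            )
        )
    params = {
        "occupancy": occupancy,
        "residence_frames": residence_frames,
        "contact_distance": contact_distance,
        "n_bath": n_bath,
        "box": box,
    }
    return frames, occupied, params


# ---------------------------------------------------------------------------
# stochastic time series
# ---------------------------------------------------------------------------


def make_frequency_traj(
    process: str = "ou",
    n: int = 20000,
    dt: float = 0.1,
    mean: float = 2130.0,
    delta: float = 5.0,
    tau_c: float = 1.0,
    omega_split: float = 10.0,
    t1: float = 5.0,
    seed: int = 0,
) -> FrequencyTrajectory:
    """Stochastic frequency trajectories with exact stationary statistics.

    ``process="ou"``: stationary Ornstein-Uhlenbeck fluctuations about
    ``mean`` with standard deviation ``delta`` (cm^-1) and correlation time
    ``tau_c`` (ps), using the exact one-step discretization
    ``x' = x rho + delta sqrt(1 - rho^2) xi`` with ``rho = exp(-dt/tau_c)``
    -- variance and correlation time are exact at any dt, so the Kubo
    closed form applies without discretization bias.

    ``process="constant"``: omega identically ``mean`` (zero variance).

    ``process="two_state"``: telegraph jumps between ``mean +/-
    omega_split/2`` with exchange correlation time ``tau_c`` and equal
    populations.
    """
    rng = np.random.default_rng(seed)
    if process == "constant":
        omega = np.full(n, float(mean))
    elif process == "ou":
        if tau_c < dt:
            raise ValueError(f"tau_c = {tau_c} ps must be >= dt = {dt} ps")
        rho = math.exp(-dt / tau_c)
        noise = rng.standard_normal(n)
        x = np.empty(n)
        x[0] = delta * noise[0]
        scale = delta * math.sqrt(1.0 - rho**2)
        for k in range(1, n):
            x[k] = x[k - 1] * rho + scale * noise[k]
        omega = mean + x
    elif process == "two_state":
        if tau_c < dt:
            raise ValueError(f"tau_c = {tau_c} ps must be >= dt = {dt} ps")
        p_flip = 0.5 * (1.0 - math.exp(-dt / tau_c))
        flips = rng.random(n) < p_flip
        state = np.cumsum(flips) % 2
        if rng.random() < 0.5:
            state = 1 - state
        omega = mean + omega_split * (state - 0.5)
    else:
        raise ValueError(f"unknown process {process!r}; use 'ou', 'constant' or 'two_state'")
    return FrequencyTrajectory(omega=omega, dt=dt, t1=t1)


def make_telegraph_series(
    n: int = 20000,
    dt: float = 0.1,
    tau: float = 3.0,
    p_up: float = 0.6,
    seed: int = 0,
) -> AssociationSeries:
    """Two-state (0/1) association series with exponential ACF exp(-t/tau).

    ``tau`` is the relaxation time 1/(k_01 + k_10) and ``p_up`` the
    stationary occupied fraction; transition probabilities per step use the
    exact exponential propagator, so the autocorrelation decays as a single
    exponential with time constant ``tau`` and the correlation time (ACF
    integral) equals ``tau``.
    """
    if tau < dt:
        raise ValueError(f"tau = {tau} ps must be >= dt = {dt} ps")
    if not 0.0 < p_up < 1.0:
        raise ValueError("p_up must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    decay = math.exp(-dt / tau)
    p11 = p_up + (1.0 - p_up) * decay
    p01 = p_up * (1.0 - decay)
    counts = np.empty(n, dtype=int)
    state = int(rng.random() < p_up)
    for k in range(n):
        counts[k] = state
        if state:
            state = int(rng.random() < p11)
        else:
            state = int(rng.random() < p01)
    return AssociationSeries(times=dt * np.arange(n), counts=counts)


def make_angle_surface_samples(
    n_grid: int = 7,
    theta_min: float = 150.0,
    curvature_rcc: float = 0.012,
    curvature_hcc: float = 0.018,
    jitter: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict[str, float]]:
    """Quadratic-bowl angle-correction samples centered at (180, 180).

    ``d_omega = -c_r (theta_RCC - 180)^2 - c_h (theta_HCC - 180)^2``
    (cm^-1, angles in degrees): bending away from linearity lowers the
    frequency.  Returns sample rows and the generating parameters.
    """
    rng = np.random.default_rng(seed)
    theta = np.linspace(theta_min, 180.0, n_grid)
    tr, th = np.meshgrid(theta, theta, indexing="ij")
    dw = -curvature_rcc * (tr - 180.0) ** 2 - curvature_hcc * (th - 180.0) ** 2
    if jitter > 0:
        dw = dw + rng.normal(0.0, jitter, size=dw.shape)
    samples = np.column_stack([tr.ravel(), th.ravel(), dw.ravel()])
    return samples, {"curvature_rcc": curvature_rcc, "curvature_hcc": curvature_hcc}


def make_qm_convergence_series(
    a: float = 1.2,
    b: float = 6.0,
    c: float = 2145.0,
    n_max: int = 5,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict[str, float]]:
    """Exact samples of the QM-region convergence law omega = c - b e^{-N/a}."""
    rng = np.random.default_rng(seed)
    n_qm = np.arange(n_max + 1, dtype=float)
    omegas = c - b * np.exp(-n_qm / a)
    if noise > 0:
        omegas = omegas + rng.normal(0.0, noise, size=omegas.shape)
    return n_qm, omegas, {"a": a, "b": b, "c": c}
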
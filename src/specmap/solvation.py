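"""Cylindrical solvation structure and donor-association kinetics.

The terminal alkyne is cylindrically, not spherically, symmetric, so its
solvation shell is resolved in cylindrical coordinates about the triple-bond
axis: the origin sits on the R-group carbon (C_R), the z axis points from
C_R to the hydrogen-bearing carbon (C_H), z is the signed projection on that
axis and r >= 0 the perpendicular distance.  The cylindrical distribution
function on a square grid of width dr = dz is

    g(r, z) = <N(r, z)> / (pi (2 r dr^2 + dr^3) rho)

with r the lower radial bin edge, so the denominator is the *exact* annular
shell volume times the bulk number density rho of the counted species.
Integrating g times that volume element over a region inverts the
normalization and recovers the mean atom count in the region.

Donor association is a per-frame count of donor-flagged atoms (solvent
nitrogens) inside a fixed region, by default z in [3, 6] A and r in [0, 3] A
-- a box sitting beyond the terminal hydrogen (z ~ 2.28 A) that brackets the
first nitrogen peak.  The autocorrelation of that count, fit to a
triexponential, yields the association correlation time (the integral of
the fit) and the longest persistence time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .frames import ROLE_CH, ROLE_CR, ROLE_DONOR, SnapshotFrame, minimum_image

__all__ = [
    "DEFAULT_REGION",
    "CylindricalHistogram",
    "AssociationSeries",
    "cylindrical_coordinates",
    "cdf",
    "integrate_region",
    "association_series",
    "occupancy_fractions",
    "correlation_time",
    "TriexponentialFit",
]

#: association region, angstrom: (z_min, z_max), (r_min, r_max)
DEFAULT_REGION = ((3.0, 6.0), (0.0, 3.0))


def cylindrical_coordinates(
    frame: SnapshotFrame, target_positions: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(r, z) of target positions in the alkyne-axis frame.

    Minimum-image displacements from C_R are projected on the C_R -> C_H
    unit vector (z, signed) and its orthogonal complement (r >= 0).
    """
    targets = np.atleast_2d(np.asarray(target_positions, dtype=float))
    origin = frame.position_of(ROLE_CR)
    axis = minimum_image(frame.position_of(ROLE_CH) - origin, frame.box)
    axis_len = float(np.linalg.norm(axis))
    if axis_len < 1e-10:
        raise ValueError("zero-length alkyne axis: C_R and C_H coincide")
    zhat = axis / axis_len
    disp = minimum_image(targets - origin[None, :], frame.box)
    z = disp @ zhat
    perp = disp - z[:, None] * zhat[None, :]
    r = np.linalg.norm(perp, axis=1)
    return r, z


@dataclass(frozen=True)
class CylindricalHistogram:
    """Normalized cylindrical distribution on a square (r, z) grid."""

    r_edges: np.ndarray  # (n_r + 1,) bin boundaries, angstrom
    z_edges: np.ndarray  # (n_z + 1,) bin boundaries, angstrom
    counts: np.ndarray  # (n_r, n_z) mean atom count per bin, <N(r, z)>
    density: float  # bulk number density of the species, 1/A^3
    g: np.ndarray  # (n_r, n_z) normalized distribution

    @property
    def bin_width(self) -> float:
        return float(self.r_edges[1] - self.r_edges[0])

    def shell_volumes(self) -> np.ndarray:
        """Exact annular volume pi (2 r dr^2 + dr^3) per radial bin, (n_r, 1)."""
        dr = self.bin_width
        r_lower = self.r_edges[:-1]
        return (np.pi * (2.0 * r_lower * dr**2 + dr**3))[:, None]


def cdf(
    frames: Sequence[SnapshotFrame],
    species_role: str | Iterable[str] = ROLE_DONOR,
    bin_width: float = 0.25,
    z_range: tuple[float, float] = (-8.0, 10.0),
    r_range: tuple[float, float] = (0.0, 10.0),
) -> CylindricalHistogram:
    """Cylindrical distribution function of one species about the alkyne axis.

    The bulk density rho is the mean species count per box volume across
    frames; bins are addressed by their lower edges and the grid is square
    (dz = dr = ``bin_width``).
    """
    if bin_width <= 0:
        raise ValueError(f"bin width must be positive, got {bin_width}")
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    roles = (species_role,) if isinstance(species_role, str) else tuple(species_role)
    r_edges = np.arange(r_range[0], r_range[1] + 0.5 * bin_width, bin_width)
    z_edges = np.arange(z_range[0], z_range[1] + 0.5 * bin_width, bin_width)
    counts = np.zeros((r_edges.size - 1, z_edges.size - 1))
    densities = []
    for frame in frames:
        sel = frame.mask(*roles)
        densities.append(np.sum(sel) / float(np.prod(frame.box)))
        if not np.any(sel):
            continue
        r, z = cylindrical_coordinates(frame, frame.coordinates[sel])
        hist, _, _ = np.histogram2d(r, z, bins=(r_edges, z_edges))
        counts += hist
    counts /= len(frames)
    density = float(np.mean(densities))
    if density <= 0:
        raise ValueError("no atoms of the requested species in any frame")
    hist = CylindricalHistogram(
        r_edges=r_edges, z_edges=z_edges, counts=counts, density=density, g=counts
    )
    g = counts / (hist.shell_volumes() * density)
    object.__setattr__(hist, "g", g)
    return hist


def integrate_region(
    h: CylindricalHistogram,
    z_interval: tuple[float, float],
    r_interval: tuple[float, float],
) -> float:
    """Mean atom count in a (z, r) region: the exact inverse of the CDF norm.

    Sums ``g * pi (2 r dr^2 + dr^3) * rho`` over the bins whose lower edges
    fall inside the region.
    """
    z_lo, z_hi = z_interval
    r_lo, r_hi = r_interval
    if z_lo < h.z_edges[0] or z_hi > h.z_edges[-1] or r_lo < h.r_edges[0] or r_hi > h.r_edges[-1]:
        raise ValueError(
            f"region z={z_interval}, r={r_interval} exceeds the histogram range "
            f"z=({h.z_edges[0]}, {h.z_edges[-1]}), r=({h.r_edges[0]}, {h.r_edges[-1]})"
        )
    half = 0.5 * h.bin_width
    r_sel = (h.r_edges[:-1] >= r_lo - half * 1e-9) & (h.r_edges[1:] <= r_hi + half * 1e-9)
    z_sel = (h.z_edges[:-1] >= z_lo - half * 1e-9) & (h.z_edges[1:] <= z_hi + half * 1e-9)
    if not (np.any(r_sel) and np.any(z_sel)):
        raise ValueError(f"region z={z_interval}, r={r_interval} contains no complete bins")
    block = h.g[np.ix_(r_sel, z_sel)] * h.shell_volumes()[r_sel] * h.density
    return float(block.sum())


@dataclass(frozen=True)
class AssociationSeries:
    """Per-frame donor count inside the association region."""

    times: np.ndarray  # (n,) ps, uniform step
    counts: np.ndarray  # (n,) integer donor counts
    region: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_REGION

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        counts = np.asarray(self.counts)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "counts", counts)
        if times.size != counts.size:
            raise ValueError("times and counts must have equal length")
        if times.size >= 2:
            dt = np.diff(times)
            if np.any(dt <= 0) or np.ptp(dt) > 1e-9 * dt[0]:
                raise ValueError("times must be strictly increasing with a uniform step")
        if np.any(counts < 0):
            raise ValueError("association counts must be non-negative")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


def association_series(
    frames: Sequence[SnapshotFrame],
    dt: float,
    region: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_REGION,
) -> tuple[AssociationSeries, dict[str, float]]:
    """Donor count per frame in the cylindrical region, plus occupancy fractions.

    Counts donor-flagged atoms with (r, z) inside ``region`` for each frame
    (``dt`` is the frame spacing in ps) and returns the series together with
    the fractions of frames having 0, exactly 1, and >= 2 donors.  A frame
    with >= 1 donor in the region is "nitrogen associated"; with 0 it is
    "carbon associated".
    """
    (z_lo, z_hi), (r_lo, r_hi) = region
    counts = np.empty(len(frames), dtype=int)
    for k, frame in enumerate(frames):
        sel = frame.mask(ROLE_DONOR)
        if not np.any(sel):
            counts[k] = 0
            continue
        r, z = cylindrical_coordinates(frame, frame.coordinates[sel])
        counts[k] = int(np.sum((z >= z_lo) & (z <= z_hi) & (r >= r_lo) & (r <= r_hi)))
    times = dt * np.arange(len(frames))
    series = AssociationSeries(times=times, counts=counts, region=region)
    return series, occupancy_fractions(series)


def occupancy_fractions(series: AssociationSeries) -> dict[str, float]:
    """P(n = 0), P(n = 1), P(n >= 2) over the frames of the series."""
    n = series.counts
    total = n.size
    return {
        "P0": float(np.sum(n == 0)) / total,
        "P1": float(np.sum(n == 1)) / total,
        "P2plus": float(np.sum(n >= 2)) / total,
    }


@dataclass(frozen=True)
class TriexponentialFit:
    """Triexponential fit of a normalized autocorrelation decay."""

    amplitudes: np.ndarray  # (3,) A_i >= 0, normalized to sum to C(0)
    taus: np.ndarray  # (3,) ps
    tau_corr: float  # integral of the fit, sum A_i tau_i, ps
    tau_longest: float  # max tau_i, ps
    residual_rms: float
    acf_lags: np.ndarray  # ps
    acf: np.ndarray

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.sum(
            self.amplitudes[:, None] * np.exp(-t[None, :] / self.taus[:, None]), axis=0
        )


def _autocorrelation(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Normalized autocovariance C(k)/C(0) by FFT, lags 0..max_lag."""
    x = np.asarray(x, dtype=float)
    n = x.size
    dx = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(dx, nfft)
    acov = np.fft.irfft(spec * np.conj(spec), nfft)[: max_lag + 1]
    acov /= np.arange(n, n - max_lag - 1, -1)  # unbiased lag normalization
    if acov[0] <= 0:
        raise ValueError("series has zero variance; no correlation time defined")
    return acov / acov[0]


def fit_triexponential(
    lags: np.ndarray,
    acf: np.ndarray,
    n_starts: int = 8,
    seed: int = 0,
) -> TriexponentialFit:
    """Fit ``C(t) = sum_{i=1..3} A_i exp(-t / tau_i)`` to a decay curve.

    Amplitudes are bounded non-negative; the reported ``amplitudes`` are
    normalized to sum to one while ``tau_corr`` integrates the raw fit,
    ``sum w_i tau_i``.  Multi-start bounded least squares guards against
    the notorious ill-conditioning of multi-exponential fits; the
    lowest-residual start wins.  Time constants are capped at twice the
    fitted window so tail noise cannot masquerade as an arbitrarily slow
    process.
    """
    lags = np.asarray(lags, dtype=float)
    acf = np.asarray(acf, dtype=float)
    if lags.shape != acf.shape or lags.size < 10:
        raise ValueError("need matching lag/ACF arrays with at least 10 points")
    dt = lags[1] - lags[0]
    span = lags[-1]

    def resid(params: np.ndarray) -> np.ndarray:
        w = params[:3]
        tau = params[3:]
        model = np.sum(w[:, None] * np.exp(-lags[None, :] / tau[:, None]), axis=0)
        return model - acf

    rng = np.random.default_rng(seed)
    best = None
    for k in range(n_starts):
        if k == 0:
            tau0 = np.sort(span * np.array([0.02, 0.1, 0.5]))
        else:
            tau0 = np.sort(np.exp(rng.uniform(np.log(dt), np.log(span), size=3)))
        p0 = np.concatenate([np.full(3, 1.0 / 3.0), tau0])
        sol = least_squares(
            resid,
            p0,
            bounds=(
                np.concatenate([np.zeros(3), np.full(3, dt / 20.0)]),
                np.concatenate([np.full(3, 2.0), np.full(3, 2.0 * span)]),
            ),
            max_nfev=5000,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    w = best.x[:3]
    tau = best.x[3:]
    order = np.argsort(tau)
    w, tau = w[order], tau[order]
    total = w.sum()
    rms = float(np.sqrt(np.mean(resid(best.x) ** 2)))
    return TriexponentialFit(
        amplitudes=w / total if total > 0 else w,
        taus=tau,
        tau_corr=float(np.sum(w * tau)),
        tau_longest=float(tau.max()),
        residual_rms=rms,
        acf_lags=lags,
        acf=acf,
    )


def correlation_time(
    series: AssociationSeries,
    max_lag: float | None = None,
    n_starts: int = 8,
    seed: int = 0,
) -> TriexponentialFit:
    """Association correlation time from a triexponential ACF fit.

    The normalized autocovariance of n(t) is fit to a sum of three decaying
    exponentials (see :func:`fit_triexponential`); the correlation time is
    the integral of the fit, ``tau_corr = sum A_i tau_i``, and the longest
    time scale is ``max tau_i``.  Unless ``max_lag`` (ps) is given, the fit
    window ends at three times the lag where the ACF first drops below
    0.02 -- long enough to pin the slowest component, short enough that the
    pure-noise tail of the estimated ACF cannot bias the fit.
    """
    n = series.counts.size
    if n < 100:
        raise ValueError(f"series too short for a correlation time ({n} frames < 100)")
    dt = series.dt
    hard_cap = n // 5  # sliding-origin statistics
    acf_full = _autocorrelation(series.counts.astype(float), hard_cap)
    if max_lag is None:
        below = np.nonzero(acf_full < 0.02)[0]
        decay_lag = int(below[0]) if below.size else hard_cap
        n_lag = int(min(max(3 * decay_lag, 20), hard_cap))
    else:
        n_lag = int(min(max(round(max_lag / dt), 10), hard_cap))
    acf = acf_full[: n_lag + 1]
    lags = dt * np.arange(n_lag + 1)
    if acf[min(10, n_lag)] > 0.99:
        import warnings

        warnings.warn("association correlation barely decays over the fitted window")
    return fit_triexponential(lags, acf, n_starts=n_starts, seed=seed)
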
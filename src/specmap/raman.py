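"""Raman lineshapes from fluctuating frequency trajectories.

In the fluctuating frequency approximation the Raman lineshape is the
Fourier transform of a phase-accumulating response function,

    I(omega) ~ Re int_0^inf dt e^{i omega t}
               < alpha01(t) alpha01(0) e^{i int_0^t d_omega(tau) dtau} >
               e^{-t / 2 T1},

where d_omega(t) = omega(t) - <omega> is the instantaneous frequency
fluctuation (rad/ps internally), alpha01 the transition polarizability
(identically 1 under the Condon approximation) and T1 the vibrational
population lifetime (5 ps by default, an experimental estimate).  The
ensemble average runs over sliding time origins of the trajectory; the
phase integral is accumulated by the trapezoidal rule.

The transform convention is pinned by the static limit: a constant
frequency trajectory yields a Lorentzian centered at that frequency with
FWHM 1/(2 pi c T1) ~ 1.06 cm^-1 at T1 = 5 ps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr

from .units import C_CM_PER_PS, INVCM_TO_RAD_PER_PS

__all__ = [
    "FrequencyTrajectory",
    "Spectrum",
    "response_function",
    "spectrum",
    "condon_check",
]


@dataclass(frozen=True)
class FrequencyTrajectory:
    """Time-ordered frequencies (and optional transition polarizabilities)."""

    omega: np.ndarray  # (n,) cm^-1
    dt: float = 0.1  # ps
    alpha01: np.ndarray | None = None  # (n,) arbitrary units; None => Condon
    t1: float = 5.0  # vibrational population lifetime, ps

    def __post_init__(self) -> None:
        omega = np.asarray(self.omega, dtype=float)
        object.__setattr__(self, "omega", omega)
        if omega.ndim != 1 or omega.size < 2:
            raise ValueError("need a 1D frequency trajectory of length >= 2")
        if not np.all(np.isfinite(omega)):
            raise ValueError("frequencies must be finite")
        if self.dt <= 0:
            raise ValueError(f"time step must be positive, got {self.dt}")
        if self.t1 <= 0:
            raise ValueError(f"T1 must be positive, got {self.t1}")
        if self.alpha01 is not None:
            alpha = np.asarray(self.alpha01, dtype=float)
            if alpha.shape != omega.shape:
                raise ValueError("alpha01 must match the frequency trajectory length")
            object.__setattr__(self, "alpha01", alpha)

    @property
    def span(self) -> float:
        """Trajectory length in ps."""
        return self.dt * (self.omega.size - 1)


@dataclass(frozen=True)
class Spectrum:
    """A computed lineshape with its summary observables."""

    wavenumber: np.ndarray  # absolute cm^-1 axis
    intensity: np.ndarray  # normalized to unit maximum (real part, unclipped)
    peak: float  # cm^-1, parabolic interpolation about the maximum
    fwhm: float  # cm^-1, linear interpolation of the half-max crossings


def _n_lags(traj: FrequencyTrajectory, max_lag: float) -> int:
    if max_lag <= 0:
        raise ValueError(f"max_lag must be positive, got {max_lag}")
    if max_lag > traj.span / 5.0 + 1e-12:
        raise ValueError(
            f"max_lag {max_lag} ps exceeds a fifth of the trajectory span "
            f"({traj.span} ps); sliding-origin statistics would be too poor"
        )
    return int(round(max_lag / traj.dt))


def response_function(
    traj: FrequencyTrajectory, max_lag: float
) -> tuple[np.ndarray, np.ndarray]:
    """Lifetime-damped response function F(t) on lags 0..max_lag.

    Returns ``(t, F)`` with t in ps.  F(0) equals the mean squared
    transition polarizability (exactly 1 under the Condon approximation);
    for a constant frequency trajectory F(t) = exp(-t / 2 T1) exactly.
    """
    if np.any(np.isnan(traj.omega)):
        raise ValueError("frequency trajectory contains NaN")
    n_lag = _n_lags(traj, max_lag)
    n = traj.omega.size
    delta = (traj.omega - traj.omega.mean()) * INVCM_TO_RAD_PER_PS  # rad/ps
    # cumulative trapezoidal phase: phi[k] = int_0^{t_k} delta dtau
    phi = np.concatenate(
        [[0.0], np.cumsum(0.5 * (delta[1:] + delta[:-1])) * traj.dt]
    )
    alpha = traj.alpha01 if traj.alpha01 is not None else np.ones(n)
    phase = np.exp(1j * phi)
    a_phase = alpha * phase  # alpha(t0+t) e^{i phi(t0+t)}
    a_conj = alpha * np.conj(phase)  # alpha(t0) e^{-i phi(t0)}
    f = np.empty(n_lag + 1, dtype=complex)
    for k in range(n_lag + 1):
        f[k] = np.mean(a_conj[: n - k] * a_phase[k:])
    t = traj.dt * np.arange(n_lag + 1)
    return t, f * np.exp(-t / (2.0 * traj.t1))


def spectrum(
    traj: FrequencyTrajectory,
    max_lag: float,
    zero_padding_factor: int = 4,
    apodize: bool = False,
) -> Spectrum:
    """One-sided Fourier transform of the response function.

    The offset axis from the transform is re-centered on the trajectory
    mean frequency, so adding a constant to every omega shifts the peak by
    exactly that constant.  Zero padding only refines the frequency grid;
    an optional half-cosine taper (off by default) suppresses truncation
    ringing at the cost of a slight broadening.  Negative intensities from
    the finite-lag real part are preserved in the stored spectrum and
    clipped only while locating the half-maximum crossings.
    """
    t, f = response_function(traj, max_lag)
    if apodize:
        f = f * np.cos(0.5 * np.pi * t / t[-1])
    weights = np.ones_like(t)
    weights[0] = 0.5  # trapezoidal end correction of the one-sided integral
    n_pad = int(zero_padding_factor) * f.size
    # I(nu_n) = Re sum_k F_k e^{-2 pi i k n / N} dt: a component with phase
    # e^{+i d t} must appear at offset +d, which the forward FFT kernel gives
    transform = np.fft.fft(f * weights, n=n_pad) * traj.dt
    intensity = np.fft.fftshift(transform.real)
    offsets_cm = np.fft.fftshift(np.fft.fftfreq(n_pad, d=traj.dt)) / C_CM_PER_PS
    axis = traj.omega.mean() + offsets_cm

    peak_idx = int(np.argmax(intensity))
    peak = axis[peak_idx]
    if 0 < peak_idx < intensity.size - 1:
        y0, y1, y2 = intensity[peak_idx - 1 : peak_idx + 2]
        denom = y0 - 2.0 * y1 + y2
        if abs(denom) > 1e-300:
            peak = peak + 0.5 * (y0 - y2) / denom * (axis[1] - axis[0])

    clipped = np.clip(intensity, 0.0, None)
    half = 0.5 * clipped[peak_idx]
    above = clipped >= half
    left = peak_idx
    while left > 0 and above[left - 1]:
        left -= 1
    right = peak_idx
    while right < above.size - 1 and above[right + 1]:
        right += 1
    dx = axis[1] - axis[0]
    x_left = axis[left]
    if left > 0 and clipped[left] != clipped[left - 1]:
        x_left -= dx * (clipped[left] - half) / (clipped[left] - clipped[left - 1])
    x_right = axis[right]
    if right < above.size - 1 and clipped[right] != clipped[right + 1]:
        x_right += dx * (clipped[right] - half) / (clipped[right] - clipped[right + 1])
    fwhm = float(x_right - x_left)

    top = intensity.max()
    return Spectrum(
        wavenumber=axis,
        intensity=intensity / top,
        peak=float(peak),
        fwhm=fwhm,
    )


def condon_check(
    alpha01: np.ndarray,
    omega: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict[str, float | bool | tuple[float, float]]:
    """Diagnostic for the Condon approximation.

    Pearson correlation between the transition polarizability and the
    frequency with a bootstrap 95% confidence interval; the approximation
    is reported valid when the interval covers zero (scattering strength
    uncorrelated with frequency).
    """
    a = np.asarray(alpha01, dtype=float)
    w = np.asarray(omega, dtype=float)
    if a.size != w.size:
        raise ValueError("alpha01 and omega must have equal length")
    if a.size < 30:
        raise ValueError(f"need at least 30 samples for the diagnostic, got {a.size}")
    if np.std(a) == 0 or np.std(w) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    r = float(pearsonr(a, w).statistic)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    n = a.size
    for k in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if np.std(a[idx]) == 0 or np.std(w[idx]) == 0:
            boot[k] = 0.0
        else:
            boot[k] = pearsonr(a[idx], w[idx]).statistic
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return {
        "pearson_r": r,
        "ci95": (float(lo), float(hi)),
        "condon_valid": bool(lo <= 0.0 <= hi),
    }
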
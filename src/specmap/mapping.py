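"""The spectroscopic map: evaluation, fitting, and its auxiliary fits.

The map predicts the terminal-alkyne CC-stretch frequency of a snapshot as

    omega_MAP = omega_g + d_omega(theta_RCC, theta_HCC) + d_omega_TEA
                + d_omega_QM1->QMinf

where ``omega_g`` is the gas-phase frequency of the solute,
``d_omega(theta)`` is an angle correction from a smooth bivariate spline
anchored to zero at the linear geometry (180 deg, 180 deg),
``d_omega_QM1->QMinf`` is a constant correcting the single-QM-solvent
reference to the infinite-QM-region extrapolation, and the solvent shift is
a multilinear form in the six map variables,

    d_omega_TEA = a0 f0 + a1 f1 + a2 f2 + b_H u_H + b_CH u_CH + b_CR u_CR.

All other solute degrees of freedom are assumed frequency-neutral
(d_omega_R = 0), a deliberate simplification known to under-disperse the
predicted lineshape.

The published coefficients, gas-phase frequencies and QM-region constants
ship as packaged data (:func:`MapModel.published`).  Fitting uses ordinary
least squares with no intercept -- the constant terms of the map live in
``omega_g`` and the QM correction, not in the regression.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import SmoothBivariateSpline
from scipy.optimize import curve_fit
from scipy.stats import pearsonr, t as student_t

from .features import FeatureVector

__all__ = [
    "AngleSurface",
    "MapModel",
    "MapFitReport",
    "delta_omega_tea",
    "omega_map",
    "fit_map",
    "delta_omega_tea_reference",
    "fit_qm_convergence",
    "fit_angle_surface",
]

FEATURE_NAMES = ("a0", "a1", "a2", "b_H", "b_CH", "b_CR")


class AngleSurface:
    """Smooth bivariate spline for the angle correction d_omega(theta_RCC, theta_HCC).

    Angles are in degrees with the linear geometry at 180; the surface is
    anchored so that the correction vanishes there.  Evaluation outside the
    sampled rectangle is clamped to its boundary with a warning.
    """

    def __init__(self, spline: SmoothBivariateSpline, bounds: tuple[tuple[float, float], tuple[float, float]]):
        self._spline = spline
        self._bounds = bounds
        self._offset = float(spline(180.0, 180.0)[0, 0])

    def __call__(self, theta_rcc: float, theta_hcc: float) -> float:
        (lo_r, hi_r), (lo_h, hi_h) = self._bounds
        tr = min(max(theta_rcc, lo_r), hi_r)
        th = min(max(theta_hcc, lo_h), hi_h)
        if tr != theta_rcc or th != theta_hcc:
            warnings.warn(
                f"angle ({theta_rcc}, {theta_hcc}) outside the fitted range; "
                f"clamped to ({tr}, {th})",
                stacklevel=2,
            )
        return float(self._spline(tr, th)[0, 0]) - self._offset


@dataclass(frozen=True)
class MapModel:
    """Map coefficients plus the per-solute constants of the frequency model."""

    a: np.ndarray  # (3,) field coefficients, cm^-1 per atomic-unit feature
    b: np.ndarray  # (3,) repulsive-LJ coefficients, cm^-1 per E_h
    omega_gas: Mapping[str, float]  # gas-phase frequency per solute, cm^-1
    qm_correction: Mapping[str, float]  # QM1->QMinf constant per solute, cm^-1
    angle_surface: AngleSurface | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.shape != (3,) or b.shape != (3,):
            raise ValueError("need exactly 3 field and 3 LJ coefficients")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def coefficients(self) -> np.ndarray:
        """All six coefficients in feature order (a0, a1, a2, b_H, b_CH, b_CR)."""
        return np.concatenate([self.a, self.b])

    @classmethod
    def published(cls, angle_surface: AngleSurface | None = None) -> "MapModel":
        """The packaged reference map (coefficients, omega_g, QM constants)."""
        with resources.files("specmap.data").joinpath("map_coefficients.json").open() as fh:
            data = json.load(fh)
        c = data["coefficients"]
        return cls(
            a=np.array([c["a0"], c["a1"], c["a2"]]),
            b=np.array([c["b_H"], c["b_CH"], c["b_CR"]]),
            omega_gas=data["omega_gas"],
            qm_correction=data["qm_correction"],
            angle_surface=angle_surface,
        )


def _features_matrix(features: FeatureVector | Sequence[FeatureVector] | np.ndarray) -> np.ndarray:
    if isinstance(features, FeatureVector):
        return features.as_array()[None, :]
    arr = np.asarray(
        [f.as_array() if isinstance(f, FeatureVector) else f for f in features],
        dtype=float,
    )
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] != 6:
        raise ValueError(f"feature rows must have 6 columns, got {arr.shape[1]}")
    return arr


def delta_omega_tea(
    features: FeatureVector | Sequence[FeatureVector] | np.ndarray,
    model: MapModel,
) -> float | np.ndarray:
    """Solvent-induced frequency shift(s) in cm^-1.

    The contraction of the atomic-unit feature vector with the map
    coefficients; exactly linear in every feature.
    """
    x = _features_matrix(features)
    if not np.all(np.isfinite(x)):
        raise ValueError("features must be finite")
    shifts = x @ np.concatenate([model.a, model.b])
    return float(shifts[0]) if isinstance(features, FeatureVector) else shifts


def omega_map(
    features: FeatureVector | Sequence[FeatureVector] | np.ndarray,
    angles: tuple[float, float],
    solute_id: str,
    model: MapModel,
) -> float | np.ndarray:
    """Absolute map frequency omega_MAP in cm^-1 for one solute.

    ``angles = (theta_RCC, theta_HCC)`` in degrees, each in (90, 180].
    With no fitted angle surface the correction is zero, i.e. evaluation at
    the linear geometry.
    """
    theta_rcc, theta_hcc = angles
    for name, theta in (("theta_RCC", theta_rcc), ("theta_HCC", theta_hcc)):
        if not 90.0 < theta <= 180.0:
            raise ValueError(f"{name} = {theta} deg outside the physical range (90, 180]")
    if solute_id not in model.omega_gas:
        raise KeyError(
            f"no gas-phase frequency registered for solute {solute_id!r}; "
            f"known solutes: {sorted(model.omega_gas)}"
        )
    angle_term = (
        model.angle_surface(theta_rcc, theta_hcc) if model.angle_surface is not None else 0.0
    )
    base = model.omega_gas[solute_id] + angle_term + model.qm_correction.get(solute_id, 0.0)
    return base + delta_omega_tea(features, model)


@dataclass(frozen=True)
class MapFitReport:
    """Ordinary-least-squares fit of the six map coefficients.

    ``coefficients`` is the mean over the resample refits (25 random
    3/4-of-the-data training sets by default); ``ci_resample`` is the 95%
    t-interval of that mean across resamples -- the published uncertainty
    recipe, which quantifies training-set sensitivity.  ``ci_ols`` is the
    classical 95% t-interval from the single full-training-set fit
    (``coefficients_single``) and is the interval with calibrated coverage
    of the generating coefficients under i.i.d. Gaussian residuals.
    """

    coefficients: np.ndarray  # (6,) resample-mean estimates
    coefficients_single: np.ndarray  # (6,) one-shot training-set fit
    ci_resample: np.ndarray  # (6, 2) low/high
    ci_ols: np.ndarray  # (6, 2) low/high
    train_pearson_r: float
    test_pearson_r: float
    test_rmse: float
    n_train: int
    n_test: int
    feature_names: tuple[str, ...] = FEATURE_NAMES
    contributions: dict = field(default_factory=dict)

    def contribution_table(
        self,
        features: np.ndarray,
        associated: np.ndarray | None = None,
    ) -> dict[str, dict[str, float]]:
        """Per-variable mean/std contribution to d_omega_TEA, optionally stratified.

        Returns rows keyed by coefficient symbol plus a ``total`` row whose
        per-frame value is exactly the sum of the six per-variable columns.
        ``associated`` is an optional boolean array marking donor-associated
        frames; when given, class-wise statistics are included.
        """
        x = _features_matrix(features)
        per_var = x * self.coefficients[None, :]
        total = per_var.sum(axis=1)
        table: dict[str, dict[str, float]] = {}
        columns = list(zip(self.feature_names, per_var.T)) + [("total", total)]
        for name, values in columns:
            row = {"mean": float(np.mean(values)), "std": float(np.std(values))}
            if associated is not None:
                assoc = np.asarray(associated, dtype=bool)
                row.update(
                    {
                        "mean_assoc": float(np.mean(values[assoc])),
                        "std_assoc": float(np.std(values[assoc])),
                        "mean_unassoc": float(np.mean(values[~assoc])),
                        "std_unassoc": float(np.std(values[~assoc])),
                    }
                )
            table[name] = row
        return table


def _ols(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < x.shape[1]:
        corr = np.corrcoef(x, rowvar=False)
        pairs = [
            (FEATURE_NAMES[i], FEATURE_NAMES[j])
            for i in range(6)
            for j in range(i + 1, 6)
            if abs(corr[i, j]) > 1.0 - 1e-10
        ]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < 6); "
            f"collinear columns: {pairs if pairs else 'degenerate feature columns'}"
        )
    return beta


def fit_map(
    features: Sequence[FeatureVector] | np.ndarray,
    targets: np.ndarray,
    n_resamples: int = 25,
    train_fraction: float = 0.75,
    seed: int | None = None,
) -> MapFitReport:
    """Fit the six map coefficients to d_omega_TEA targets (cm^-1).

    A random ``train_fraction`` of the rows forms the training set for the
    one-shot fit and the held-out remainder supplies the test correlation
    and RMSE; ``n_resamples`` further random training subsets quantify the
    coefficient uncertainty (see :class:`MapFitReport`).  No intercept is
    fitted.
    """
    x = _features_matrix(features)
    y = np.asarray(targets, dtype=float)
    n = x.shape[0]
    if y.shape != (n,):
        raise ValueError(f"targets must have shape ({n},), got {y.shape}")
    if n < 10:
        raise ValueError(f"need at least 10 rows to fit the map, got {n}")
    rng = np.random.default_rng(seed)
    n_train = int(round(train_fraction * n))
    perm = rng.permutation(n)
    train_idx, test_idx = perm[:n_train], perm[n_train:]
    beta_single = _ols(x[train_idx], y[train_idx])

    # classical OLS 95% t-interval from the one-shot training fit
    resid = y[train_idx] - x[train_idx] @ beta_single
    dof = max(n_train - 6, 1)
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(x[train_idx].T @ x[train_idx])
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    t_crit = student_t.ppf(0.975, dof)
    ci_ols = np.column_stack([beta_single - t_crit * se, beta_single + t_crit * se])

    # resampled refits on fresh random training subsets of the full data
    betas = np.empty((n_resamples, 6))
    for k in range(n_resamples):
        idx = rng.permutation(n)[:n_train]
        betas[k] = _ols(x[idx], y[idx])
    beta_mean = betas.mean(axis=0)
    sem = betas.std(axis=0, ddof=1) / np.sqrt(n_resamples)
    t_res = student_t.ppf(0.975, n_resamples - 1)
    ci_resample = np.column_stack([beta_mean - t_res * sem, beta_mean + t_res * sem])

    pred_train = x[train_idx] @ beta_single
    train_r = float(pearsonr(pred_train, y[train_idx]).statistic)
    if test_idx.size >= 2:
        pred_test = x[test_idx] @ beta_single
        test_r = float(pearsonr(pred_test, y[test_idx]).statistic)
        test_rmse = float(np.sqrt(np.mean((pred_test - y[test_idx]) ** 2)))
    else:  # no held-out rows (train_fraction = 1)
        test_r = float("nan")
        test_rmse = float("nan")
    return MapFitReport(
        coefficients=beta_mean,
        coefficients_single=beta_single,
        ci_resample=ci_resample,
        ci_ols=ci_ols,
        train_pearson_r=train_r,
        test_pearson_r=test_r,
        test_rmse=test_rmse,
        n_train=int(n_train),
        n_test=int(n - n_train),
    )


def delta_omega_tea_reference(omega_qm1mm3: float, omega_qm0mm0: float) -> float:
    """Reference solvent shift from paired QM/MM frequencies.

    ``d_omega_TEA = omega_QM1MM3 - omega_QM0MM0``: because the solute
    structure is identical in both calculations, the gas-phase frequency,
    the angle correction and any other intramolecular shift cancel exactly
    in the subtraction, leaving the pure solvent effect.
    """
    if not (np.isfinite(omega_qm1mm3) and np.isfinite(omega_qm0mm0)):
        raise ValueError("both reference frequencies must be finite")
    return float(omega_qm1mm3 - omega_qm0mm0)


def fit_qm_convergence(
    n_qm: np.ndarray, omegas: np.ndarray
) -> tuple[float, float, float, float]:
    """Fit omega = c - b exp(-N/a) to QM-region convergence data.

    ``n_qm`` counts the number of solvent molecules treated quantum
    mechanically; ``c`` is the extrapolated infinite-QM-region frequency.
    Returns ``(a, b, c, correction)`` where ``correction = c - omega(N=1) =
    b exp(-1/a)`` is the constant added to single-QM-molecule frequencies.
    """
    n_arr = np.asarray(n_qm, dtype=float)
    w = np.asarray(omegas, dtype=float)
    if n_arr.size != w.size:
        raise ValueError("n_qm and omegas must have equal length")
    if n_arr.size < 4:
        raise ValueError(f"need at least 4 points to fit 3 parameters, got {n_arr.size}")

    def model(n, a, b, c):
        return c - b * np.exp(-n / a)

    span = float(w.max() - w.min())
    p0 = (1.0, span if span > 0 else 1e-6, float(w.max()))
    try:
        popt, _ = curve_fit(model, n_arr, w, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        resid = w - model(n_arr, *p0)
        raise RuntimeError(
            f"QM-convergence fit did not converge: {exc}; "
            f"initial-guess residuals {resid.tolist()}"
        ) from None
    a, b, c = (float(v) for v in popt)
    correction = b * np.exp(-1.0 / a)
    return a, b, c, float(correction)


def fit_angle_surface(samples: np.ndarray, smoothing: float | None = None) -> AngleSurface:
    """Fit the smooth bivariate angle-correction spline.

    ``samples`` has rows (theta_RCC, theta_HCC, d_omega) in degrees and
    cm^-1, scattered over the accessible angle range.  The returned surface
    is anchored to zero at (180, 180).
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("samples must be rows of (theta_RCC, theta_HCC, d_omega)")
    if arr.shape[0] < 16:
        raise ValueError(f"need at least 16 scattered samples, got {arr.shape[0]}")
    tr, th, dw = arr.T
    if np.ptp(tr) < 1e-9 or np.ptp(th) < 1e-9:
        raise ValueError("sample layout is collinear: both angles must vary")
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        try:
            spline = SmoothBivariateSpline(tr, th, dw, kx=3, ky=3, s=smoothing)
        except Exception as exc:
            raise ValueError(f"angle-surface spline fit failed: {exc}") from exc
    bounds = ((float(tr.min()), float(tr.max())), (float(th.min()), float(th.max())))
    return AngleSurface(spline, bounds)
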
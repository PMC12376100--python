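"""Map evaluation/fitting, QM-region extrapolation and the angle surface."""

import numpy as np
import pytest

from specmap.features import FeatureVector
from specmap.mapping import (
    MapModel,
    delta_omega_tea,
    delta_omega_tea_reference,
    fit_angle_surface,
    fit_map,
    fit_qm_convergence,
    omega_map,
)
from specmap import synthetic

#: published coefficient values in feature order
PUBLISHED = np.array([-151.0, 1960.0, -1060.0, 378.0, 300.0, -1490.0])


@pytest.fixture(scope="module")
def model():
    return MapModel.published()


@pytest.fixture(scope="module")
def feature_scales():
    """Realistic feature means/stds measured once on structured fixture frames."""
    from specmap.features import compute_features

    frames, _, _ = synthetic.make_structured_frames(n_frames=80, seed=5)
    arr = np.array([compute_features(f).as_array() for f in frames])
    return arr.mean(axis=0), arr.std(axis=0)


class TestDeltaOmega:
    def test_zero_features_zero_shift(self, model):
        fv = FeatureVector(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        assert delta_omega_tea(fv, model) == 0.0

    def test_unit_features_sum_coefficients(self, model):
        """Unit feature vector returns the plain sum of the six coefficients."""
        fv = FeatureVector(1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
        by_hand = -151.0 + 1960.0 + (-1060.0) + 378.0 + 300.0 + (-1490.0)
        assert delta_omega_tea(fv, model) == pytest.approx(by_hand, rel=1e-14)

    def test_linearity(self, model, rng):
        x = rng.normal(size=6) * np.array([1e-2, 1e-2, 1e-2, 1e-3, 1e-3, 1e-3])
        x[3:] = np.abs(x[3:])
        one = delta_omega_tea(FeatureVector(*x), model)
        two = delta_omega_tea(FeatureVector(*(2.0 * x)), model)
        assert two == pytest.approx(2.0 * one, rel=1e-12)

    def test_gradient_is_coefficients(self, model):
        """The map is monotone in each feature with slope equal to its coefficient."""
        base = np.array([0.01, -0.002, 0.005, 1e-3, 2e-3, 5e-4])
        f_base = delta_omega_tea(base[None, :], model)[0]
        for j in range(6):
            bumped = base.copy()
            bumped[j] += 1e-6
            grad = (delta_omega_tea(bumped[None, :], model)[0] - f_base) / 1e-6
            assert grad == pytest.approx(PUBLISHED[j], rel=1e-6)


class TestOmegaMap:
    def test_linear_geometry_constants(self, model):
        fv = FeatureVector(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        assert omega_map(fv, (180.0, 180.0), "PAC", model) == pytest.approx(2138.39 + 3.3)
        assert omega_map(fv, (180.0, 180.0), "EBA", model) == pytest.approx(2110.65 + 4.0)

    def test_bent_angles_lower_frequency(self, model):
        samples, _ = synthetic.make_angle_surface_samples()
        surface = fit_angle_surface(samples)
        bent_model = MapModel(
            a=model.a, b=model.b, omega_gas=model.omega_gas,
            qm_correction=model.qm_correction, angle_surface=surface,
        )
        fv = FeatureVector(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        linear = omega_map(fv, (180.0, 180.0), "PAC", bent_model)
        bent = omega_map(fv, (170.0, 165.0), "PAC", bent_model)
        assert bent < linear

    def test_unknown_solute_rejected(self, model):
        fv = FeatureVector(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        with pytest.raises(KeyError, match="known solutes"):
            omega_map(fv, (180.0, 180.0), "XYZ", model)

    def test_unphysical_angle_rejected(self, model):
        fv = FeatureVector(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        with pytest.raises(ValueError, match="theta_RCC"):
            omega_map(fv, (85.0, 180.0), "PAC", model)


class TestFitMap:
    def test_noiseless_exact_recovery(self, feature_scales, rng):
        mu, sd = feature_scales
        x = mu + sd * rng.standard_normal((1000, 6))
        y = x @ PUBLISHED
        report = fit_map(x, y, seed=1)
        assert np.max(np.abs(report.coefficients_single - PUBLISHED) / np.abs(PUBLISHED)) < 1e-8
        assert report.test_pearson_r > 1.0 - 1e-10

    def test_round_trip_published_coefficients(self, model, feature_scales, rng):
        """Targets generated by the map itself recover the published values."""
        mu, sd = feature_scales
        x = mu + sd * rng.standard_normal((2000, 6))
        y = delta_omega_tea(x, model)
        report = fit_map(x, y, seed=2)
        assert np.allclose(report.coefficients, PUBLISHED, rtol=1e-8)

    def test_ci_brackets_estimates(self, feature_scales, rng):
        mu, sd = feature_scales
        x = mu + sd * rng.standard_normal((600, 6))
        y = x @ PUBLISHED + rng.normal(0.0, 2.4, 600)
        report = fit_map(x, y, seed=3)
        assert np.all(report.ci_resample[:, 0] <= report.coefficients)
        assert np.all(report.coefficients <= report.ci_resample[:, 1])
        assert np.all(report.ci_ols[:, 0] <= report.coefficients_single)
        assert np.all(report.coefficients_single <= report.ci_ols[:, 1])
        assert report.test_rmse >= 0.0

    def test_matches_sklearn_reference(self, feature_scales, rng):
        """Independent cross-check of the OLS path against scikit-learn."""
        from sklearn.linear_model import LinearRegression

        mu, sd = feature_scales
        x = mu + sd * rng.standard_normal((400, 6))
        y = x @ PUBLISHED + rng.normal(0.0, 2.4, 400)
        report = fit_map(x, y, train_fraction=1.0, seed=4, n_resamples=2)
        sk = LinearRegression(fit_intercept=False).fit(x, y)
        assert np.allclose(report.coefficients_single, sk.coef_, rtol=1e-8)

    def test_permuted_targets_destroy_correlation(self, feature_scales, rng):
        mu, sd = feature_scales
        x = mu + sd * rng.standard_normal((2000, 6))
        y = x @ PUBLISHED + rng.normal(0.0, 2.4, 2000)
        rs = []
        for k in range(3):
            report = fit_map(x, rng.permutation(y), seed=5 + k)
            rs.append(abs(report.test_pearson_r))
        assert np.mean(rs) < 0.1

    def test_contribution_decomposition_sums_exactly(self, feature_scales, rng):
        mu, sd = feature_scales
        x = mu + sd * rng.standard_normal((300, 6))
        y = x @ PUBLISHED
        report = fit_map(x, y, seed=6)
        per_var = x * report.coefficients[None, :]
        table = report.contribution_table(x, associated=per_var.sum(axis=1) < 0)
        total_mean = sum(table[name]["mean"] for name in report.feature_names)
        assert table["total"]["mean"] == pytest.approx(total_mean, rel=1e-10)

    def test_rank_deficient_design_rejected(self, rng):
        x = rng.standard_normal((100, 6))
        x[:, 5] = 2.0 * x[:, 4]  # perfectly collinear pair
        with pytest.raises(np.linalg.LinAlgError, match="rank deficient"):
            fit_map(x, x @ PUBLISHED, seed=0)

    def test_too_few_rows_rejected(self, rng):
        x = rng.standard_normal((5, 6))
        with pytest.raises(ValueError, match="at least 10"):
            fit_map(x, np.zeros(5))


def test_ols_ci_coverage_calibrated(feature_scales):
    """95% OLS intervals cover the generating coefficients in ~95% of refits."""
    mu, sd = feature_scales
    rng = np.random.default_rng(2024)
    reps, hits = 60, np.zeros(6)
    for rep in range(reps):
        x = mu + sd * rng.standard_normal((1500, 6))
        y = x @ PUBLISHED + rng.normal(0.0, 2.4, 1500)
        report = fit_map(x, y, seed=rep, n_resamples=2)
        hits += (report.ci_ols[:, 0] <= PUBLISHED) & (PUBLISHED <= report.ci_ols[:, 1])
    assert np.all(hits / reps >= 0.85)


class TestReferenceShift:
    def test_equal_inputs(self):
        assert delta_omega_tea_reference(2140.0, 2140.0) == 0.0

    def test_sign_convention(self):
        assert delta_omega_tea_reference(2140.0, 2145.0) == pytest.approx(-5.0)

    def test_matches_column_difference(self, rng):
        qm1 = 2130.0 + rng.normal(0.0, 5.0, 50)
        qm0 = 2140.0 + rng.normal(0.0, 5.0, 50)
        ours = np.array([delta_omega_tea_reference(a, b) for a, b in zip(qm1, qm0)])
        assert np.allclose(ours, qm1 - qm0)


class TestQmConvergence:
    def test_exact_recovery(self):
        n_qm, omegas, truth = synthetic.make_qm_convergence_series()
        a, b, c, corr = fit_qm_convergence(n_qm, omegas)
        assert a == pytest.approx(truth["a"], abs=1e-6)
        assert b == pytest.approx(truth["b"], abs=1e-6)
        assert c == pytest.approx(truth["c"], abs=1e-6)
        assert corr == pytest.approx(truth["b"] * np.exp(-1.0 / truth["a"]), abs=1e-6)

    def test_constant_sequence_degenerates(self):
        n_qm = np.arange(6.0)
        a, b, c, corr = fit_qm_convergence(n_qm, np.full(6, 2140.0))
        assert abs(b) < 1e-5
        assert c == pytest.approx(2140.0, abs=1e-6)

    def test_saturating_data_asymptote(self):
        n_qm, omegas, _ = synthetic.make_qm_convergence_series(a=1.5, b=8.0, c=2145.0)
        _, _, c, _ = fit_qm_convergence(n_qm, omegas)
        assert c >= omegas.max() - 1e-6

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            fit_qm_convergence(np.arange(3.0), np.arange(3.0))


class TestAngleSurface:
    def test_quadratic_bowl_interpolation(self):
        samples, truth = synthetic.make_angle_surface_samples()
        surface = fit_angle_surface(samples)
        rng = np.random.default_rng(3)
        for _ in range(20):
            tr, th = rng.uniform(152.0, 180.0, size=2)
            expected = (
                -truth["curvature_rcc"] * (tr - 180.0) ** 2
                - truth["curvature_hcc"] * (th - 180.0) ** 2
            )
            assert surface(tr, th) == pytest.approx(expected, abs=0.1)

    def test_anchored_at_linear_geometry(self):
        samples, _ = synthetic.make_angle_surface_samples()
        surface = fit_angle_surface(samples)
        assert surface(180.0, 180.0) == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_samples_give_symmetric_surface(self):
        samples, _ = synthetic.make_angle_surface_samples(
            curvature_rcc=0.015, curvature_hcc=0.015
        )
        surface = fit_angle_surface(samples)
        assert surface(165.0, 172.0) == pytest.approx(surface(172.0, 165.0), abs=1e-6)

    def test_outside_hull_clamps_with_warning(self):
        samples, _ = synthetic.make_angle_surface_samples(theta_min=150.0)
        surface = fit_angle_surface(samples)
        with pytest.warns(UserWarning, match="clamped"):
            clamped = surface(140.0, 180.0)
        assert clamped == pytest.approx(surface(150.0, 180.0))

    def test_collinear_layout_rejected(self):
        theta = np.linspace(150.0, 180.0, 20)
        samples = np.column_stack([theta, np.full(20, 170.0), theta])
        with pytest.raises(ValueError, match="collinear"):
            fit_angle_surface(samples)
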
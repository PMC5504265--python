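"""Reference-model fitting: OLS oracles, SD recovery, centile identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fetalcentiles import (
    CentileModel,
    centile_curve,
    centile_to_value,
    fit_centile_model,
    fit_mean,
    fit_sd,
    k_value,
    make_cohort,
    value_to_centile,
)
from fetalcentiles.centiles import HALF_NORMAL_SCALE
from fetalcentiles.errors import DegenerateDesignError, DegenerateSDError, DomainError
from fetalcentiles.synthetic import CohortConfig

from conftest import TABLE2_GA, TABLE2_VOLUMES


def _normal_equations(X, y):
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestFitMean:
    def test_quadratic_consistency_of_printed_supratentorial_volumes(self):
        """The published average supratentorial volumes lie on a quadratic:
        the LS fit through all five reproduces the 26-week value."""
        coeffs, _ = fit_mean(TABLE2_GA, TABLE2_VOLUMES["supratentorial"], "quadratic")
        t = 26.0 - 30.0
        assert coeffs[0] + coeffs[1] * t + coeffs[2] * t * t == pytest.approx(92.26, abs=0.05)

    def test_exact_quadratic_interpolation_gives_zero_residuals(self):
        ga = np.array([22.0, 25.0, 29.0, 33.0, 38.0])
        y = 3.0 - 0.5 * (ga - 30) + 0.2 * (ga - 30) ** 2
        _, residuals = fit_mean(ga, y, "quadratic")
        assert np.allclose(residuals, 0.0, atol=1e-10)

    @pytest.mark.parametrize("family", ["quadratic", "exponential"])
    def test_matches_normal_equations_oracle(self, family):
        rng = np.random.default_rng(11)
        ga = rng.uniform(21, 39, size=50)
        t = ga - 30
        if family == "quadratic":
            y = 100 + 10 * t + 0.5 * t * t + rng.normal(0, 5, 50)
            X = np.column_stack([np.ones(50), t, t * t])
            expected = _normal_equations(X, y)
        else:
            y = np.exp(2.0 + 0.1 * t + rng.normal(0, 0.05, 50))
            X = np.column_stack([np.ones(50), t])
            expected = _normal_equations(X, np.log(y))
        coeffs, _ = fit_mean(ga, y, family)
        assert np.allclose(coeffs, expected, rtol=1e-8)

    def test_exponential_residuals_on_original_scale(self):
        ga = np.linspace(22, 38, 40)
        y = 5.0 * np.exp(0.13 * (ga - 30))
        coeffs, residuals = fit_mean(ga, y, "exponential")
        assert np.allclose(residuals, 0.0, atol=1e-9)  # raw-scale y - mean(ga)
        assert np.exp(coeffs[0]) == pytest.approx(5.0)

    def test_degenerate_design_all_ga_equal(self):
        with pytest.raises(DegenerateDesignError):
            fit_mean(np.full(10, 30.0), np.arange(10.0), "quadratic")

    def test_exponential_rejects_nonpositive_values(self):
        ga = np.linspace(22, 38, 10)
        y = np.linspace(-1, 8, 10)
        with pytest.raises(DomainError):
            fit_mean(ga, y, "exponential")

    def test_too_few_points(self):
        with pytest.raises(DegenerateDesignError):
            fit_mean(np.array([22.0, 30.0, 38.0]), np.array([1.0, 2.0, 3.0]), "quadratic")


class TestFitSD:
    def test_constant_magnitude_residuals_give_constant_sd(self):
        ga = np.linspace(22, 38, 20)
        residuals = 2.0 * np.where(np.arange(20) % 2 == 0, 1.0, -1.0)
        coeffs = fit_sd(ga, residuals, "linear")
        assert coeffs[0] == pytest.approx(2.0 * HALF_NORMAL_SCALE, rel=1e-9)
        assert coeffs[1] == pytest.approx(0.0, abs=1e-12)

    def test_monte_carlo_sd_recovery(self):
        """SD regression on half-normal-scaled |residuals| recovers a
        GA-linear noise SD within 5% at 30 weeks (n=2000)."""
        rng = np.random.default_rng(21)
        ga = rng.uniform(21, 39, 2000)
        true_sd = 2.0 + 0.1 * (ga - 30)
        y = 100 + 3 * (ga - 30) + rng.normal(0, true_sd)
        model = fit_centile_model(ga, y, "quadratic", "linear")
        assert float(model.sd(30.0)) == pytest.approx(2.0, rel=0.05)

    def test_zero_residuals_degenerate(self):
        with pytest.raises(DegenerateSDError):
            fit_sd(np.linspace(22, 38, 10), np.zeros(10), "linear")

    def test_insufficient_points(self):
        with pytest.raises(DegenerateDesignError):
            fit_sd(np.array([22.0, 38.0]), np.array([1.0, -1.0]), "linear")


class TestFitCentileModel:
    def test_parameter_recovery_from_synthetic_cohort(self, truth):
        """Fits on a 2000-subject synthetic cohort recover the generating
        mean curve within 2% at 25/30/35 weeks."""
        config = CohortConfig(n_subjects=2000, n_twice_scanned=0, n_thrice_scanned=0,
                              sex_counts=(1000, 1000), seed=13)
        _, scans = make_cohort(config, truth)
        ga = np.array([s.ga_weeks for s in scans])
        y = np.array([s.measurements["cerebellum"] for s in scans])
        model = fit_centile_model(ga, y, "quadratic", "linear", "cerebellum")
        for g in (25.0, 30.0, 35.0):
            assert float(model.mean(g)) == pytest.approx(float(truth["cerebellum"].mean(g)), rel=0.02)

    def test_z_score_diagnostics(self, study_cohort):
        # the analysis cohort itself: 127 scans after exclusion filtering
        from fetalcentiles import apply_exclusions

        subjects, all_scans = study_cohort
        scans = apply_exclusions(subjects, all_scans)[1]
        assert len(scans) == 127
        ga = np.array([s.ga_weeks for s in scans])
        y = np.array([s.measurements["supratentorial"] for s in scans])
        model = fit_centile_model(ga, y, "quadratic", "linear", "supratentorial")
        z = np.array(model.diagnostics["z_scores"])
        assert abs(z.mean()) < 0.05
        frac_tail = np.mean(np.abs(z) > 1.645)
        assert 0.05 <= frac_tail <= 0.16  # binomial 95% band at p=0.10, n=127

    def test_sd_crossing_zero_fails_loudly(self):
        # residual magnitude collapses with GA so the fitted SD line goes
        # negative inside the domain: the model must refuse to fit
        ga = np.repeat([20.0, 30.0, 40.0], 4)
        magnitudes = np.repeat([10.0, 1.0, 0.05], 4)
        signs = np.tile([1.0, -1.0], 6)
        y = 100.0 + 2.0 * (ga - 30) + signs * magnitudes
        with pytest.raises(DegenerateSDError):
            fit_centile_model(ga, y, "quadratic", "linear")

    def test_centering_invariance(self):
        rng = np.random.default_rng(31)
        ga = rng.uniform(21, 39, 200)
        y = 50 + 4 * (ga - 30) + 0.3 * (ga - 30) ** 2 + rng.normal(0, 2, 200)
        m1 = fit_centile_model(ga, y, "quadratic", "linear", ga_center=30.0)
        m2 = fit_centile_model(ga + 5.0, y, "quadratic", "linear", ga_center=35.0)
        grid = np.linspace(22, 38, 33)
        assert np.allclose(m1.mean(grid), m2.mean(grid + 5.0), atol=1e-10)
        assert np.allclose(m1.sd(grid), m2.sd(grid + 5.0), atol=1e-10)

    def test_exponential_growth_ratio_constant(self, truth):
        config = CohortConfig(n_subjects=500, n_twice_scanned=0, n_thrice_scanned=0,
                              sex_counts=(250, 250), seed=19)
        _, scans = make_cohort(config, truth)
        ga = np.array([s.ga_weeks for s in scans])
        y = np.array([s.measurements["cortex"] for s in scans])
        model = fit_centile_model(ga, y, "exponential", "quadratic", "cortex")
        grid = np.linspace(22, 37, 16)
        ratios = model.mean(grid + 1.0) / model.mean(grid)
        assert np.allclose(ratios, np.exp(model.mean_coeffs[1]), rtol=1e-12)

    def test_serialization_round_trip(self, tmp_path):
        rng = np.random.default_rng(41)
        ga = rng.uniform(21, 39, 100)
        y = 30 + 2 * (ga - 30) + rng.normal(0, 1.5, 100)
        model = fit_centile_model(ga, y, "quadratic", "linear", "tcd")
        path = tmp_path / "tcd.json"
        model.to_json(path)
        back = CentileModel.from_json(path)
        grid = np.linspace(22, 38, 17)
        assert back.measurement_name == "tcd"
        assert np.allclose(back.mean(grid), model.mean(grid))
        assert np.allclose(back.sd(grid), model.sd(grid))
        assert back.ga_domain == model.ga_domain


@pytest.fixture(scope="module")
def fitted_model():
    rng = np.random.default_rng(53)
    ga = rng.uniform(21, 39, 400)
    y = 150 + 16 * (ga - 30) + 0.75 * (ga - 30) ** 2 + rng.normal(0, 6 + 0.2 * (ga - 30))
    return fit_centile_model(ga, y, "quadratic", "linear", "supratentorial")


class TestCentileConversion:
    def test_median_curve_is_mean_curve(self, fitted_model):
        grid = np.linspace(22, 38, 20)
        assert np.allclose(centile_curve(fitted_model, 0.5, grid), fitted_model.mean(grid))

    def test_5_95_symmetry(self, fitted_model):
        grid = np.linspace(22, 38, 20)
        upper = centile_curve(fitted_model, 0.95, grid)
        lower = centile_curve(fitted_model, 0.05, grid)
        assert np.allclose(upper - lower, 2 * 1.6449 * fitted_model.sd(grid), rtol=1e-4)

    def test_k_values(self):
        assert k_value(0.5) == 0.0
        assert k_value(0.95) == pytest.approx(-k_value(0.05))
        assert k_value(0.95) == pytest.approx(1.6449, abs=1e-4)

    @settings(derandomize=True, max_examples=50)
    @given(p1=st.floats(0.01, 0.98), dp=st.floats(0.005, 0.01),
           g=st.floats(22.0, 38.0))
    def test_centile_curves_monotone_in_p(self, fitted_model, p1, dp, g):
        v1 = centile_to_value(fitted_model, g, p1)
        v2 = centile_to_value(fitted_model, g, p1 + dp)
        assert v2 > v1

    def test_value_at_mean_is_50th(self, fitted_model):
        res = value_to_centile(fitted_model, 30.0, float(fitted_model.mean(30.0)))
        assert res.percentile == pytest.approx(50.0)
        assert res.z_score == pytest.approx(0.0)

    def test_value_at_1p6449_sd_is_95th(self, fitted_model):
        v = float(fitted_model.mean(30.0)) + 1.6449 * float(fitted_model.sd(30.0))
        assert value_to_centile(fitted_model, 30.0, v).percentile == pytest.approx(95.0, abs=0.01)

    def test_round_trip_identity(self, fitted_model):
        v = centile_to_value(fitted_model, 29.0, 0.123)
        assert value_to_centile(fitted_model, 29.0, v).percentile == pytest.approx(12.3, abs=1e-6)

    def test_extrapolation_flag(self, fitted_model):
        lo, hi = fitted_model.ga_domain
        assert value_to_centile(fitted_model, hi + 1.0, 100.0).extrapolated
        assert not value_to_centile(fitted_model, (lo + hi) / 2, 100.0).extrapolated

    def test_coverage_below_5th_centile(self, fitted_model):
        """Data simulated from the fitted model fall below its own 5th
        centile curve about 5% of the time (3-sigma binomial band)."""
        rng = np.random.default_rng(61)
        n = 4000
        ga = rng.uniform(22, 38, n)
        y = fitted_model.mean(ga) + rng.normal(0, 1, n) * fitted_model.sd(ga)
        below = np.mean(y < centile_curve(fitted_model, 0.05, ga))
        band = 3 * np.sqrt(0.05 * 0.95 / n)
        assert abs(below - 0.05) < band
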
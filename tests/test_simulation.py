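"""Copula calibration, exposure sampling, saturated OLS and scenarios."""

import math

import numpy as np
import pytest
from scipy.stats import kstest, norm

from spurint.bvn_moments import BivariateSpec
from spurint.induced_effects import TrueModel, induced_coefficients
from spurint.simulation import (
    CHISQ2,
    NORMAL,
    UNIFORM01,
    Scenario,
    calibrate_latent_rho,
    marginal_quantile,
    ols_saturated,
    run_scenario,
    sample_exposures,
    sigma2_for_target_corr,
    study_sigma2,
    table_scenarios,
)


class TestCalibration:
    def test_normal_is_identity(self):
        calib = calibrate_latent_rho(NORMAL, 0.5)
        assert calib.latent_rho == 0.5
        assert abs(calib.achieved_rho - 0.5) <= calib.tolerance

    def test_uniform_closed_form_inverse(self):
        # pearson = (6/pi) * arcsin(latent/2)  =>  latent = 2 sin(pi*rho/6)
        calib = calibrate_latent_rho(UNIFORM01, 0.5)
        assert calib.latent_rho == pytest.approx(0.5176, abs=2e-4)
        assert abs(calib.achieved_rho - 0.5) <= calib.tolerance

    def test_chisq_empirical_search_hits_target(self):
        calib = calibrate_latent_rho(CHISQ2, 0.7)
        assert abs(calib.achieved_rho - 0.7) <= 0.002
        # attenuation: the latent correlation must exceed the target
        assert calib.latent_rho > 0.7

    def test_degenerate_target_rejected(self):
        with pytest.raises(ValueError):
            calibrate_latent_rho(NORMAL, 1.0)


class TestSampling:
    def test_normal_pair_correlation(self, rng):
        calib = calibrate_latent_rho(NORMAL, 0.2)
        x1, x2 = sample_exposures(NORMAL, calib, 100_000, rng)
        assert np.corrcoef(x1, x2)[0, 1] == pytest.approx(0.2, abs=0.01)

    def test_chisq_marginal_moments(self, rng):
        calib = calibrate_latent_rho(CHISQ2, 0.5)
        x1, _ = sample_exposures(CHISQ2, calib, 100_000, rng)
        assert x1.mean() == pytest.approx(2.0, abs=0.05)
        assert x1.var() == pytest.approx(4.0, abs=0.15)
        assert x1.min() > 0

    def test_uniform_marginal_distribution(self, rng):
        calib = calibrate_latent_rho(UNIFORM01, 0.5)
        x1, _ = sample_exposures(UNIFORM01, calib, 100_000, rng)
        assert kstest(x1, "uniform").statistic < 0.01

    def test_family_mismatch_rejected(self, rng):
        calib = calibrate_latent_rho(NORMAL, 0.5)
        with pytest.raises(ValueError):
            sample_exposures(CHISQ2, calib, 100, rng)


class TestQuantilesAndSigma:
    @pytest.mark.parametrize(
        "dist, p, expected",
        [
            (NORMAL, 0.8, 0.8416212336),
            (UNIFORM01, 0.6, 0.6),
            (CHISQ2, 0.8, 3.2188758249),  # -2 ln 0.2
            (CHISQ2, 0.6, -2 * math.log(0.4)),
        ],
    )
    def test_marginal_quantiles(self, dist, p, expected):
        assert marginal_quantile(dist, p) == pytest.approx(expected, abs=1e-9)

    def test_quantile_range_checked(self):
        with pytest.raises(ValueError):
            marginal_quantile(NORMAL, 1.2)

    @pytest.mark.parametrize(
        "dist, expected",
        [(NORMAL, 22.0), (UNIFORM01, 22.0 / 12.0), (CHISQ2, 88.0)],
    )
    def test_study_residual_variances(self, dist, expected):
        assert study_sigma2(dist) == pytest.approx(expected, rel=1e-12)

    def test_sigma2_achieves_target_correlation(self, rng):
        s2 = sigma2_for_target_corr(NORMAL, TrueModel(0, 1, 1), 0.5, 0.3)
        calib = calibrate_latent_rho(NORMAL, 0.5)
        x1, x2 = sample_exposures(NORMAL, calib, 1_000_000, rng)
        y = x1 + x2 + rng.normal(0, math.sqrt(s2), x1.size)
        assert np.corrcoef(y, x1)[0, 1] == pytest.approx(0.3, abs=0.005)

    def test_infeasible_target_rejected(self):
        with pytest.raises(ValueError):
            sigma2_for_target_corr(NORMAL, TrueModel(0, 1, 1), 0.5, 0.999)


class TestSaturatedOLS:
    def test_recovers_cell_constants_exactly(self, rng):
        x1b = rng.integers(0, 2, 400).astype(bool)
        x2b = rng.integers(0, 2, 400).astype(bool)
        a, b, c, d = 1.0, -2.0, 0.5, 3.0  # cells 00, 01, 10, 11
        y = np.select(
            [~x1b & ~x2b, ~x1b & x2b, x1b & ~x2b, x1b & x2b], [a, b, c, d]
        )
        coef = ols_saturated(y, x1b, x2b)
        assert coef.bt0 == pytest.approx(a, abs=1e-12)
        assert coef.bt1 == pytest.approx(c - a, abs=1e-12)
        assert coef.bt2 == pytest.approx(b - a, abs=1e-12)
        assert coef.bt3 == pytest.approx(d - b - c + a, abs=1e-12)

    def test_recovers_analytic_contrasts_from_conditional_means(self, rng):
        """Replacing y by its exact cell means recovers the analytic
        contrasts to machine precision; with noise-free continuous y the
        estimates converge to them at the Monte-Carlo rate."""
        spec = BivariateSpec(0.5, norm.ppf(0.8))
        model = TrueModel(0.0, 1.0, 1.0)
        analytic = induced_coefficients(model, spec)
        calib = calibrate_latent_rho(NORMAL, 0.5)
        x1, x2 = sample_exposures(NORMAL, calib, 200_000, rng)
        x1b, x2b = x1 > spec.c, x2 > spec.c
        # exact route: y literally equal to the analytic cell means
        from spurint.induced_effects import cell_means

        mu = cell_means(model, spec)
        y_exact = np.select(
            [~x1b & ~x2b, ~x1b & x2b, x1b & ~x2b, x1b & x2b],
            [mu.mu00, mu.mu01, mu.mu10, mu.mu11],
        )
        exact = ols_saturated(y_exact, x1b, x2b)
        np.testing.assert_allclose(
            exact.as_array(), analytic.as_array(), atol=1e-10
        )
        # stochastic route: noise-free y from the continuous model
        noisy = ols_saturated(x1 + x2, x1b, x2b)
        np.testing.assert_allclose(
            noisy.as_array(), analytic.as_array(), atol=0.05
        )

    def test_independent_response_gives_null_slopes(self, rng):
        y = rng.standard_normal(50_000)
        x1b = rng.integers(0, 2, 50_000).astype(bool)
        x2b = rng.integers(0, 2, 50_000).astype(bool)
        coef = ols_saturated(y, x1b, x2b)
        assert abs(coef.bt1) < 0.05 and abs(coef.bt2) < 0.05 and abs(coef.bt3) < 0.1

    def test_empty_cell_rejected(self):
        y = np.arange(4.0)
        x1b = np.array([0, 0, 1, 1], dtype=bool)
        x2b = np.array([0, 0, 0, 0], dtype=bool)
        with pytest.raises(ValueError):
            ols_saturated(y, x1b, x2b)


def _small(dist, rho, pct, model, seed, **kw):
    return Scenario(
        dist=dist, rho=rho, percentile=pct, model=model,
        n=4000, reps=60, seed=seed, **kw,
    )


class TestScenarios:
    def test_seed_determinism(self):
        s = _small(NORMAL, 0.5, 0.8, TrueModel(0, 1, 1, 22.0), seed=99)
        r1, r2 = run_scenario(s), run_scenario(s)
        np.testing.assert_array_equal(r1.mean_bt, r2.mean_bt)
        np.testing.assert_array_equal(r1.sd_bt, r2.sd_bt)

    def test_normal_cell_matches_analytic_contrasts(self):
        s = _small(NORMAL, 0.5, 0.8, TrueModel(0, 1, 1, 22.0), seed=5)
        res = run_scenario(s)
        analytic = induced_coefficients(
            TrueModel(0, 1, 1), BivariateSpec(0.5, norm.ppf(0.8))
        )
        tol = np.maximum(4 * res.mc_se, 0.02)
        assert np.all(np.abs(res.mean_bt - analytic.as_array()) <= tol)

    def test_uncorrelated_exposures_no_interaction(self):
        s = _small(UNIFORM01, 0.0, 0.6, TrueModel(0, 1, 1, 22.0 / 12.0), seed=6)
        res = run_scenario(s)
        assert abs(res.mean_bt[3]) < 4 * res.mc_se[3]

    def test_means_invariant_to_residual_variance(self):
        base = _small(NORMAL, 0.5, 0.8, TrueModel(0, 1, 1, 22.0), seed=7)
        doubled = _small(NORMAL, 0.5, 0.8, TrueModel(0, 1, 1, 44.0), seed=8)
        r1, r2 = run_scenario(base), run_scenario(doubled)
        se = np.sqrt(r1.mc_se**2 + r2.mc_se**2)
        assert np.all(np.abs(r1.mean_bt - r2.mean_bt) <= 4 * se + 0.01)
        assert np.all(r2.sd_bt[1:] > r1.sd_bt[1:])

    def test_one_sided_categorization_induces_interaction(self):
        s = _small(
            NORMAL, 0.7, 0.8, TrueModel(0, 1, 1, 22.0), seed=9,
            dichotomize_x2=False,
        )
        res = run_scenario(s)
        assert res.coef_names[-1] == "bt3"
        assert res.mean_bt[-1] < -4 * res.mc_se[-1]

    def test_three_categories_induce_interaction(self):
        s = _small(
            NORMAL, 0.7, 0.8, TrueModel(0, 1, 1, 22.0), seed=10, n_categories=3,
        )
        res = run_scenario(s)
        inter = [
            (m, se)
            for nm, m, se in zip(res.coef_names, res.mean_bt, res.mc_se)
            if ":" in nm
        ]
        assert any(abs(m) > 4 * se for m, se in inter)

    def test_invalid_scenarios_rejected(self):
        with pytest.raises(ValueError):
            _small(NORMAL, 0.5, 1.5, TrueModel(0, 1, 1, 1.0), seed=1)
        with pytest.raises(ValueError):
            Scenario(
                dist=NORMAL, rho=0.5, percentile=0.6,
                model=TrueModel(0, 1, 1, 1.0), n=2, reps=10, seed=1,
            )

    def test_study_design_covers_all_printed_cells(self):
        # 18 base cells plus 2 modified-beta scenarios x 3 marginals
        cells = table_scenarios(seed=1, n=100, reps=1)
        assert len(cells) == 24
        assert sum(label == "table1" for label, _ in cells) == 18
        table2 = [s for label, s in cells if label == "table2"]
        assert len(table2) == 6
        assert {(s.model.beta1, s.model.beta2) for s in table2} == {
            (1.0, 0.0), (2.0, 2.0),
        }
        assert len({s.seed for _, s in cells}) == 24
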
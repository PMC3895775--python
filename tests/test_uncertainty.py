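"""Wild bootstrap, delta-method propagation, bands, and coverage."""

import numpy as np
import pytest

import mwfatlas as m
from mwfatlas.uncertainty import BootstrapDraws

from conftest import NOISE_SD, TRUTH

AGES = np.array([100.0, 250.0, 400.0, 800.0, 1500.0])


class TestWildBootstrap:
    def test_zero_residuals_give_zero_parameter_sds(self, mg, cohort_ages):
        y = m.evaluate(mg, TRUTH, cohort_ages)
        data = m.TrajectoryData(ages=cohort_ages, values=y)
        fit = m.fit_model(mg, data)
        draws = m.wild_bootstrap(mg, data, fit, n_resamples=100, seed=0)
        np.testing.assert_allclose(
            draws.draws, np.tile(fit.params, (100, 1)), atol=1e-12
        )
        np.testing.assert_allclose(draws.param_sds, 0.0, atol=1e-12)

    def test_same_seed_reproduces_draws(self, mg, noisy_trajectory, noisy_fit):
        # the Rademacher weight stream is bit-exact for a given seed; refit
        # outputs are reproducible to solver precision
        from mwfatlas.uncertainty import _draw_weights

        r1 = _draw_weights(np.random.default_rng(5), 500, "rademacher")
        r2 = _draw_weights(np.random.default_rng(5), 500, "rademacher")
        np.testing.assert_array_equal(r1, r2)
        assert set(np.unique(r1)) == {-1.0, 1.0}

        d1 = m.wild_bootstrap(mg, noisy_trajectory, noisy_fit, 100, seed=5)
        d2 = m.wild_bootstrap(mg, noisy_trajectory, noisy_fit, 100, seed=5)
        np.testing.assert_allclose(d1.draws, d2.draws, rtol=1e-7, atol=1e-12)

    def test_different_seeds_differ(self, mg, noisy_trajectory, noisy_fit):
        d1 = m.wild_bootstrap(mg, noisy_trajectory, noisy_fit, 100, seed=5)
        d2 = m.wild_bootstrap(mg, noisy_trajectory, noisy_fit, 100, seed=6)
        assert not np.array_equal(d1.draws, d2.draws)

    def test_summary_statistics_match_draws(self, noisy_draws):
        np.testing.assert_allclose(
            noisy_draws.param_means, noisy_draws.draws.mean(axis=0)
        )
        np.testing.assert_allclose(
            noisy_draws.param_sds, noisy_draws.draws.std(axis=0, ddof=1)
        )

    def test_too_few_resamples_rejected(self, mg, noisy_trajectory, noisy_fit):
        with pytest.raises(ValueError, match="at least 100"):
            m.wild_bootstrap(mg, noisy_trajectory, noisy_fit, n_resamples=50)

    @pytest.mark.parametrize("law", ["mammen", "normal"])
    def test_alternative_weight_laws_run(self, mg, noisy_trajectory, noisy_fit, law):
        d = m.wild_bootstrap(
            mg, noisy_trajectory, noisy_fit, 100, seed=1, weight_law=law
        )
        assert np.all(np.isfinite(d.draws))

    def test_bootstrap_sd_shrinks_with_cohort_size(self, mg):
        # parameter SDs should scale roughly as 1/sqrt(n): quadrupling the
        # cohort should halve them (within 30%)
        sds = {}
        for n in (100, 400):
            rng = np.random.default_rng(17)
            ages = m.uniform_ages(n, seed=17)
            y = np.clip(
                m.evaluate(mg, TRUTH, ages) + rng.normal(0, NOISE_SD, n), 0, 1
            )
            data = m.TrajectoryData(ages=ages, values=y)
            fit = m.fit_model(mg, data, options=m.FitOptions(seed=0))
            sds[n] = m.wild_bootstrap(mg, data, fit, 400, seed=2).param_sds
        ratio = sds[100] / sds[400]
        assert np.all(ratio > 2.0 * 0.7)
        assert np.all(ratio < 2.0 * 1.3)


class TestPropagation:
    def test_zero_sds_propagate_to_zero(self, mg):
        out = m.propagate_uncertainty(mg, TRUTH, np.zeros(4), AGES)
        np.testing.assert_array_equal(out, 0.0)

    def test_single_term_collapse_alpha_only(self, mg):
        # at x=0 with (0.2, 0, 1, 0) only the alpha sensitivity exp(-1) is
        # nonzero among weighted terms
        s = 0.01
        out = m.propagate_uncertainty(mg, [0.2, 0, 1, 0], [s, 0, 0, 0], 0.0)
        assert out == pytest.approx(np.exp(-1) * s, rel=1e-12)

    def test_negative_sds_rejected(self, mg):
        with pytest.raises(ValueError, match="non-negative"):
            m.propagate_uncertainty(mg, TRUTH, [-0.01, 0, 0, 0], AGES)

    def test_matches_independent_perturbation_oracle(self, mg, noisy_draws):
        # first-order delta-method validity: agree with the SD of curves
        # under independent Gaussian parameter perturbations at the same SDs
        rng = np.random.default_rng(8)
        perturbed = (
            noisy_draws.param_means
            + rng.standard_normal((5000, 4)) * noisy_draws.param_sds
        )
        curves = np.stack([m.evaluate(mg, p, AGES) for p in perturbed])
        mc_sd = curves.std(axis=0, ddof=1)
        dm = m.propagate_uncertainty(
            mg, noisy_draws.param_means, noisy_draws.param_sds, AGES
        )
        np.testing.assert_allclose(dm, mc_sd, rtol=0.15)

    def test_conservative_against_correlated_bootstrap_draws(self, mg, noisy_draws):
        # the no-covariance sum cannot undershoot the curve SD over the
        # actual (correlated) draws in this strongly correlated regime
        dm = m.propagate_uncertainty(
            mg, noisy_draws.param_means, noisy_draws.param_sds, AGES
        )
        bs = m.bootstrap_curve_sd(mg, noisy_draws, AGES)
        assert np.all(dm >= bs * 0.9)


class TestBands:
    def _constant_sensitivity_draws(self):
        # tanh has df/dalpha = 1 everywhere, so sd=(c,0,0,0) gives a
        # constant dMWF = c at every age
        th = m.get_model("tanh")
        means = np.array([0.1, 0.08, 0.004, 1.5])
        draws = np.tile(means, (200, 1))
        return BootstrapDraws(
            model=th, draws=draws, param_means=means,
            param_sds=np.array([0.01, 0.0, 0.0, 0.0]),
            n_resamples=200, seed=0,
        )

    def test_halfwidth_is_normal_quantile_times_dmwf(self):
        d = self._constant_sensitivity_draws()
        band = m.confidence_band(d.model, d, AGES, level=0.95)
        np.testing.assert_allclose(
            band.upper - band.mean_curve, 1.959964 * 0.01, rtol=1e-6
        )
        np.testing.assert_allclose(
            band.mean_curve - band.lower, 1.959964 * 0.01, rtol=1e-6
        )

    def test_zero_uncertainty_band_collapses(self, mg, cohort_ages):
        y = m.evaluate(mg, TRUTH, cohort_ages)
        data = m.TrajectoryData(ages=cohort_ages, values=y)
        fit = m.fit_model(mg, data)
        draws = m.wild_bootstrap(mg, data, fit, 100, seed=0)
        band = m.confidence_band(mg, draws, AGES)
        np.testing.assert_allclose(band.lower, band.mean_curve, atol=1e-10)
        np.testing.assert_allclose(band.upper, band.mean_curve, atol=1e-10)

    def test_band_ordering_invariant(self, mg, noisy_draws):
        for method in ("delta", "percentile"):
            band = m.confidence_band(mg, noisy_draws, AGES, method=method)
            assert np.all(band.lower <= band.mean_curve + 1e-12)
            assert np.all(band.mean_curve <= band.upper + 1e-12)

    def test_invalid_level_rejected(self, mg, noisy_draws):
        with pytest.raises(ValueError, match="level"):
            m.confidence_band(mg, noisy_draws, AGES, level=1.2)

    def test_prediction_band_is_wider_than_confidence_band(self, mg, noisy_draws):
        cb = m.confidence_band(mg, noisy_draws, AGES)
        pb = m.prediction_band(mg, noisy_draws, AGES, resid_sd=NOISE_SD)
        assert np.all(pb.upper - pb.lower > cb.upper - cb.lower)


class TestPersistence:
    def test_band_csv_and_draws_round_trip(self, tmp_path, mg, noisy_draws):
        import pandas as pd

        band = m.confidence_band(mg, noisy_draws, AGES)
        m.save_band_csv(band, tmp_path / "band.csv")
        df = pd.read_csv(tmp_path / "band.csv")
        assert list(df.columns) == ["age", "mean", "lower", "upper"]
        np.testing.assert_allclose(df["mean"], band.mean_curve)

        m.save_draws(noisy_draws, tmp_path / "draws")
        back = m.load_draws(tmp_path / "draws")
        np.testing.assert_array_equal(back.draws, noisy_draws.draws)
        assert back.model.name == "modified_gompertz"
        assert back.seed == noisy_draws.seed


class TestEmpiricalCoverage:
    def test_noiseless_coverage_is_exactly_one(self):
        res = m.empirical_coverage(
            TRUTH, noise_sd=0.0, n_subjects=122, n_replicates=3,
            n_resamples=100, seed=1,
        )
        assert res.coverage == 1.0

    def test_determinism(self):
        r1 = m.empirical_coverage(TRUTH, NOISE_SD, 122, 2, 100, seed=9)
        r2 = m.empirical_coverage(TRUTH, NOISE_SD, 122, 2, 100, seed=9)
        np.testing.assert_array_equal(r1.per_replicate, r2.per_replicate)

    def test_residuals_are_nearly_symmetric(self):
        res = m.empirical_coverage(TRUTH, NOISE_SD, 122, 10, 100, seed=3)
        assert abs(res.skewness) < 0.5

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            m.empirical_coverage(TRUTH, NOISE_SD, n_subjects=0)
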
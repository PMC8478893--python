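"""Unit and property tests for the inbreeding-purging prediction theory."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from purgekit import (
    IPParams,
    fit_purging_coefficient,
    predict_inbreeding_load,
    predict_mean_fitness,
    predict_relative_line_fitness,
    purged_inbreeding,
    purged_inbreeding_asymptote,
    wright_inbreeding,
)

ne_st = st.floats(min_value=2.0, max_value=5000.0)
d_st = st.floats(min_value=0.0, max_value=0.5)


class TestWrightInbreeding:
    @pytest.mark.parametrize(
        "ne, t, expected, tol",
        [
            (1376, 0, 0.0, 0.0),
            (43, 1, 1.0 / 86.0, 1e-12),
            (43, 153, 0.832955, 1e-5),
        ],
    )
    def test_closed_form_values(self, ne, t, expected, tol):
        assert wright_inbreeding(ne, t) == pytest.approx(expected, abs=tol)

    def test_matches_iterative_accumulation(self):
        # F satisfies F_t = 1/(2Ne) + (1 - 1/(2Ne)) F_{t-1}
        ne = 43
        a = 1 / (2 * ne)
        f = 0.0
        for t in range(1, 154):
            f = a + (1 - a) * f
        assert wright_inbreeding(ne, 153) == pytest.approx(f, abs=1e-12)

    def test_monotone_in_t(self):
        f = wright_inbreeding(100, np.arange(200))
        assert np.all(np.diff(f) > 0)

    @pytest.mark.parametrize("ne, t", [(0, 5), (-3, 5), (50, -1)])
    def test_domain_errors(self, ne, t):
        with pytest.raises(ValueError):
            wright_inbreeding(ne, t)


class TestPurgedInbreeding:
    @given(ne=ne_st)
    def test_reduces_to_f_without_purging(self, ne):
        traj = purged_inbreeding(IPParams(ne=ne, d=0.0), 50)
        np.testing.assert_allclose(traj.g, traj.f, rtol=0, atol=1e-12)

    @given(ne=ne_st, d=d_st)
    def test_first_generation_is_half_ne_inverse(self, ne, d):
        traj = purged_inbreeding(IPParams(ne=ne, d=d), 1)
        assert traj.g[0] == 0.0
        assert traj.g[1] == pytest.approx(1.0 / (2.0 * ne), abs=1e-15)

    @given(ne=ne_st, d=d_st)
    def test_g_bounded_by_f(self, ne, d):
        traj = purged_inbreeding(IPParams(ne=ne, d=d), 200)
        assert np.all(traj.g >= 0.0)
        assert np.all(traj.g <= traj.f + 1e-12)
        assert np.all(traj.f <= 1.0)
        assert np.all(traj.f[:20] < 1.0)  # strictly below 1 until float underflow

    def test_converges_to_asymptotic_fixed_point(self):
        traj = purged_inbreeding(IPParams(ne=43, d=0.3), 3000)
        asym = purged_inbreeding_asymptote(43, 0.3)
        assert asym == pytest.approx(0.00769, abs=5e-6)
        assert traj.g[-1] == pytest.approx(asym, abs=1e-8)

    def test_neutral_asymptote_is_one(self):
        assert purged_inbreeding_asymptote(500, 0.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("kwargs", [{"ne": 0}, {"ne": 10, "d": 0.6},
                                        {"ne": 10, "d": -0.1}])
    def test_invalid_params(self, kwargs):
        with pytest.raises(ValueError):
            IPParams(**kwargs)


class TestFitnessAndLoadPredictions:
    def test_initial_values(self):
        params = IPParams(ne=100, d=0.2, delta0=1.5, p0=80.0)
        traj = purged_inbreeding(params, 10)
        for model in ("neutral", "purging"):
            assert predict_mean_fitness(params, traj, model)[0] == pytest.approx(80.0)
            assert predict_inbreeding_load(params, traj, model)[0] == pytest.approx(1.5)

    def test_neutral_and_purging_agree_at_d_zero(self):
        params = IPParams(ne=100, d=0.0, delta0=1.5, p0=80.0)
        traj = purged_inbreeding(params, 100)
        np.testing.assert_allclose(
            predict_mean_fitness(params, traj, "purging"),
            predict_mean_fitness(params, traj, "neutral"),
        )
        np.testing.assert_allclose(
            predict_inbreeding_load(params, traj, "purging"),
            predict_inbreeding_load(params, traj, "neutral"),
        )

    def test_line_fitness_closed_form(self):
        # Madrid-lines parameters, drift-only: P0 * exp(-delta0 * F_153)
        params = IPParams(ne=43, d=0.0, delta0=1.402, p0=1.0)
        traj = purged_inbreeding(params, 153)
        value = predict_mean_fitness(params, traj, "neutral")[-1]
        assert value == pytest.approx(0.3110, abs=2e-4)

    def test_base_load_closed_form(self):
        # Vigo-base parameters, drift-only: delta0 * (1 - F_125)
        params = IPParams(ne=1000, d=0.0, delta0=1.85)
        traj = purged_inbreeding(params, 125)
        value = predict_inbreeding_load(params, traj, "neutral")[-1]
        assert value == pytest.approx(1.738, abs=1e-3)

    @given(ne=ne_st, d=st.floats(min_value=0.01, max_value=0.5))
    def test_load_models_agree_at_t1(self, ne, d):
        params = IPParams(ne=ne, d=d, delta0=2.0)
        traj = purged_inbreeding(params, 1)
        neutral = predict_inbreeding_load(params, traj, "neutral")
        purging = predict_inbreeding_load(params, traj, "purging")
        assert purging[1] == pytest.approx(neutral[1], rel=1e-12)

    def test_purging_load_below_neutral_from_t2(self):
        params = IPParams(ne=50, d=0.3, delta0=2.0, p0=1.0)
        traj = purged_inbreeding(params, 100)
        neutral = predict_inbreeding_load(params, traj, "neutral")
        purging = predict_inbreeding_load(params, traj, "purging")
        assert np.all(purging[2:] < neutral[2:])
        # and the purging fitness prediction is the larger one
        assert np.all(
            predict_mean_fitness(params, traj, "purging")[2:]
            > predict_mean_fitness(params, traj, "neutral")[2:]
        )

    def test_load_affine_and_fitness_loglinear_in_delta0(self):
        traj_kwargs = dict(ne=200, d=0.0)
        one = IPParams(delta0=1.0, p0=1.0, **traj_kwargs)
        three = IPParams(delta0=3.0, p0=1.0, **traj_kwargs)
        traj = purged_inbreeding(one, 50)
        np.testing.assert_allclose(
            predict_inbreeding_load(three, traj, "neutral"),
            3.0 * predict_inbreeding_load(one, traj, "neutral"),
        )
        np.testing.assert_allclose(
            predict_mean_fitness(three, traj, "neutral"),
            predict_mean_fitness(one, traj, "neutral") ** 3,
        )

    def test_mismatched_trajectory_rejected(self):
        params = IPParams(ne=100, d=0.2, delta0=1.0, p0=1.0)
        other = purged_inbreeding(IPParams(ne=50, d=0.2), 10)
        with pytest.raises(ValueError):
            predict_mean_fitness(params, other, "purging")


class TestRelativeLineFitness:
    def test_identical_lineages_give_unity(self):
        p = IPParams(ne=100, d=0.2, delta0=1.0)
        assert predict_relative_line_fitness(p, p, 50, 50) == pytest.approx(1.0)

    def test_unloaded_line_only_base_declines(self):
        base = IPParams(ne=100, d=0.3, delta0=1.5)
        line = IPParams(ne=40, d=0.3, delta0=0.0)
        ratio = predict_relative_line_fitness(base, line, 60, 60, "purging")
        g_base = purged_inbreeding(base, 60).g[-1]
        assert ratio == pytest.approx(float(np.exp(1.5 * g_base)))
        assert ratio >= 1.0

    def test_neutral_madrid_ratio(self):
        base = IPParams(ne=1376, d=0.0, delta0=2.0)
        line = IPParams(ne=43, d=0.0, delta0=1.402)
        ratio = predict_relative_line_fitness(base, line, 153, 234, "neutral")
        assert ratio == pytest.approx(0.36614, abs=2e-4)


class TestFitPurgingCoefficient:
    def test_recovers_generating_d_noiselessly(self):
        gen = IPParams(ne=1376, d=0.3, delta0=2.0)
        t = np.array([0, 30, 60, 90, 120])
        truth = predict_inbreeding_load(gen, purged_inbreeding(gen, 120), "purging")[t]
        fit = fit_purging_coefficient(t, truth, ne=1376, delta0=2.0)
        assert fit.d == pytest.approx(0.300, abs=1e-3)

    def test_neutral_data_give_zero(self):
        gen = IPParams(ne=200, d=0.0, delta0=2.0)
        t = np.array([0, 20, 40, 80])
        truth = predict_inbreeding_load(gen, purged_inbreeding(gen, 80), "neutral")[t]
        assert fit_purging_coefficient(t, truth, ne=200, delta0=2.0).d == 0.0

    def test_mean_recovery_under_noise(self):
        # simulation-based recovery study: d = 0.15 plus small observation noise
        gen = IPParams(ne=300, d=0.15, delta0=2.0)
        t = np.array([0, 20, 40, 60, 80, 100])
        truth = predict_inbreeding_load(gen, purged_inbreeding(gen, 100), "purging")[t]
        rng = np.random.default_rng(99)
        estimates = [
            fit_purging_coefficient(
                t, truth + rng.normal(0, 0.03, size=t.size), ne=300, delta0=2.0
            ).d
            for _ in range(100)
        ]
        assert np.mean(estimates) == pytest.approx(0.15, abs=0.02)

    def test_bootstrap_interval_covers_truth(self):
        gen = IPParams(ne=300, d=0.25, delta0=2.0)
        t = np.array([0, 20, 40, 60, 80, 100])
        rng = np.random.default_rng(3)
        obs = predict_inbreeding_load(gen, purged_inbreeding(gen, 100), "purging")[t]
        obs = obs + rng.normal(0, 0.03, size=t.size)
        fit = fit_purging_coefficient(t, obs, ne=300, delta0=2.0,
                                      n_bootstrap=200, seed=1)
        assert fit.ci_low is not None and fit.ci_low <= 0.25 <= fit.ci_high
        assert fit.bootstrap_d.shape == (200,)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            fit_purging_coefficient([], [], ne=100, delta0=1.0)
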
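"""Particle filter: initialization, stepping, summaries, Kalman cross-check."""

import numpy as np
import pytest

import wakeprob as wp
from wakeprob.config import ModelConfig, PriorSpec
from wakeprob.inference import (
    DegenerateWeightsError,
    init_particles,
    kalman_oracle,
    pf_step,
    run_filter,
    stratified_normal,
    weighted_quantile,
)


class _Row:
    def __init__(self, b=np.nan, m=np.nan, y_alpha=np.nan, y_deltatheta=np.nan):
        self.b, self.m = b, m
        self.y_alpha, self.y_deltatheta = y_alpha, y_deltatheta


def _emg_only_grid(m):
    T = len(m)
    nan = np.full(T, np.nan)
    return wp.ObservationGrid(times=0.25 * np.arange(T), b=nan.copy(), m=np.asarray(m, float),
                              y_alpha=nan.copy(), y_deltatheta=nan.copy())


class TestWeightedQuantile:
    def test_matches_sort_based_oracle_uniform_weights(self, rng):
        vals = rng.normal(size=501)
        w = np.full(vals.size, 1.0 / vals.size)
        for q in (0.025, 0.5, 0.975):
            ours = weighted_quantile(vals, q, w)[0]
            # inverse-CDF oracle: smallest value with cumweight >= q
            srt = np.sort(vals)
            oracle = srt[int(np.ceil(q * vals.size)) - 1]
            assert ours == oracle

    def test_point_mass(self):
        vals = np.array([1.0, 2.0, 3.0])
        w = np.array([0.0, 1.0, 0.0])
        assert weighted_quantile(vals, [0.025, 0.5, 0.975], w).tolist() == [2.0] * 3


class TestStratifiedNormal:
    def test_marginally_standard_normal(self):
        rng = np.random.default_rng(3)
        x = stratified_normal(rng, 50_000)
        assert abs(x.mean()) < 1e-2
        assert x.std() == pytest.approx(1.0, abs=1e-3)


class TestInitParticles:
    def test_uniform_weights(self):
        ens = init_particles(PriorSpec(), 4, seed_or_rng=0)
        assert np.allclose(ens.weights, 0.25)

    def test_same_seed_identical(self):
        a = init_particles(PriorSpec(), 100, seed_or_rng=5)
        b = init_particles(PriorSpec(), 100, seed_or_rng=5)
        assert np.array_equal(a.states, b.states)
        assert np.array_equal(a.params, b.params)

    def test_zero_variance_prior_degenerates(self):
        pri = PriorSpec(
            state_mean=(1.0, 2.0, 3.0), state_sd=(0.0, 0.0, 0.0),
            mu0=(-1.0, 0.0), log_mu1=(0.0, 0.0), log_emg_noise_sd=(0.0, 0.0),
            alpha_offset=(0.0, 0.0), log_alpha_gain=(0.0, 0.0),
            log_alpha_noise_sd=(0.0, 0.0), dt_offset=(0.0, 0.0),
            log_dt_gain=(0.0, 0.0), log_dt_noise_sd=(0.0, 0.0),
        )
        ens = init_particles(pri, 50, seed_or_rng=1)
        assert np.allclose(ens.states, [1.0, 2.0, 3.0])
        assert np.allclose(ens.params.std(axis=0), 0.0)

    def test_negative_prior_sd_rejected(self):
        with pytest.raises(ValueError):
            init_particles(PriorSpec(mu0=(0.0, -1.0)), 10, seed_or_rng=0)


class TestPfStep:
    def test_fully_missing_row_leaves_weights(self):
        rng = np.random.default_rng(2)
        ens = init_particles(PriorSpec(), 100, rng)
        ens.weights = np.linspace(1, 2, 100)
        ens.weights /= ens.weights.sum()
        before = ens.weights.copy()
        out = pf_step(ens, _Row(), rng, ModelConfig())
        assert np.array_equal(out.weights, before)

    def test_reweighting_concentrates_on_likely_particle(self):
        rng = np.random.default_rng(3)
        ens = init_particles(PriorSpec(state_sd=(0.0, 0.0, 0.0)), 2, rng)
        ens.states = np.array([[0.0, 0.0, 0.0], [40.0, 0.0, 0.0]])
        model = ModelConfig(state_walk_sds=(0.0, 0.0, 0.0), param_walk_sd=0.0)
        out = pf_step(ens, _Row(m=-1.5), rng, model, ess_fraction=0.0)
        # particle 2 predicts log-EMG near mu0 + mu1*40, absurdly far away
        assert out.weights[0] > 1 - 1e-12

    def test_all_zero_weights_is_diagnostic_error(self):
        # every particle deep in the asleep region deems a correct response
        # impossible (p underflows to 0) -> all weights vanish
        rng = np.random.default_rng(4)
        ens = init_particles(PriorSpec(state_sd=(0.0, 0.0, 0.0)), 10, rng)
        ens.states[:] = [-2000.0, -2000.0, 2000.0]
        model = ModelConfig(state_walk_sds=(0.0, 0.0, 0.0), param_walk_sd=0.0)
        with pytest.raises(DegenerateWeightsError, match="b="):
            pf_step(ens, _Row(b=1.0), rng, model)

    def test_resampling_preserves_count_and_normalizes(self):
        rng = np.random.default_rng(5)
        ens = init_particles(PriorSpec(), 200, rng)
        out = pf_step(ens, _Row(m=-1.5), rng, ModelConfig(), ess_fraction=1.0)
        assert out.n == 200
        assert out.weights.sum() == pytest.approx(1.0, abs=1e-12)


class TestKalmanOracle:
    def test_zero_obs_noise_pins_posterior(self):
        grid = _emg_only_grid([1.0, 2.0])
        means, variances = kalman_oracle(grid, mu0=0.0, mu1=0.5, obs_sd=0.0,
                                         walk_sd=0.1, prior_mean=0.0, prior_sd=1.0)
        assert np.allclose(means, [2.0, 4.0])  # (m - mu0) / mu1
        assert np.allclose(variances, 0.0)

    def test_missing_obs_is_pure_propagation(self):
        grid = _emg_only_grid([np.nan, np.nan, np.nan])
        means, variances = kalman_oracle(grid, 0.0, 1.0, 0.5, 0.2, 1.5, 1.0)
        assert np.allclose(means, 1.5)
        assert np.allclose(variances, 1.0 + 0.04 * np.arange(1, 4))

    def test_two_step_hand_computed_recursion(self):
        # hand-rolled: prior N(0,1), q=0, mu0=0, mu1=1, r=1, obs 1 then 1
        grid = _emg_only_grid([1.0, 1.0])
        means, variances = kalman_oracle(grid, 0.0, 1.0, 1.0, 0.0, 0.0, 1.0)
        # step 1: K=1/2 -> mean 1/2, var 1/2 ; step 2: K=1/3 -> mean 2/3, var 1/3
        assert means == pytest.approx([0.5, 2.0 / 3.0], abs=1e-12)
        assert variances == pytest.approx([0.5, 1.0 / 3.0], abs=1e-12)

    def test_nonlinear_grid_rejected(self):
        grid = _emg_only_grid([1.0, 2.0])
        grid.b[0] = 1.0
        with pytest.raises(ValueError, match="EMG-only"):
            kalman_oracle(grid, 0.0, 1.0, 1.0, 0.1, 0.0, 1.0)


class TestRunFilter:
    def test_empty_grid_empty_outputs(self):
        grid = _emg_only_grid([])
        res = run_filter(grid, seed=0)
        assert res.curve.times.size == 0
        assert res.predictive.times.size == 0

    def test_determinism_bit_identical(self, short_dataset):
        a = run_filter(short_dataset.grid, wp.ModelConfig(),
                       wp.FilterConfig(n_particles=300), seed=9)
        b = run_filter(short_dataset.grid, wp.ModelConfig(),
                       wp.FilterConfig(n_particles=300), seed=9)
        assert np.array_equal(a.curve.p_median, b.curve.p_median)
        assert np.array_equal(a.curve.p_lo, b.curve.p_lo)
        assert np.array_equal(a.predictive.samples, b.predictive.samples)

    def test_curve_quantile_ordering(self, short_fit):
        c = short_fit.curve
        assert np.all(c.p_lo <= c.p_median)
        assert np.all(c.p_median <= c.p_hi)
        assert np.all((c.p_lo >= 0) & (c.p_hi <= 1))

    def test_constant_wake_data_keeps_p_high(self):
        sc = wp.SimulationScenario(duration=90.0, trajectory="random_walk",
                                   seed=21)
        ds = wp.simulate_dataset(sc)
        res = run_filter(ds.grid, wp.ModelConfig(),
                         wp.FilterConfig(n_particles=800), seed=3)
        # skip the prior burn-in
        assert np.all(res.curve.p_median[40:] > 0.8)

    def test_predictive_times_are_behavior_times(self, short_dataset, short_fit):
        grid = short_dataset.grid
        assert np.array_equal(short_fit.predictive.times, grid.times[grid.I_b])
        s = short_fit.predictive.samples
        assert np.all((s > 0) & (s < 1))

    def test_pf_tracks_kalman_on_linear_submodel(self):
        # loose agreement check at small N; the tight 3-SE bound is exercised
        # by the acceptance suite at N=20,000
        rng = np.random.default_rng(8)
        T, mu0, mu1, r, q = 60, -1.5, 0.5, 0.3, 0.1
        x = np.cumsum(rng.normal(0, q, T)) + 2.0
        grid = _emg_only_grid(mu0 + mu1 * x + rng.normal(0, r, T))
        km, _ = kalman_oracle(grid, mu0, mu1, r, q, 2.0, 1.0)
        pri = _fixed_param_priors(mu0, mu1, r)
        model = ModelConfig(priors=pri, state_walk_sds=(q, 0.0, 0.0),
                            param_walk_sd=0.0)
        res = run_filter(grid, model, wp.FilterConfig(n_particles=4000), seed=1)
        est = res.state_quantiles["x_m"]["median"]
        assert np.max(np.abs(est - km)) < 0.1


def _fixed_param_priors(mu0, mu1, r):
    return PriorSpec(
        state_mean=(2.0, 0.0, 0.0), state_sd=(1.0, 0.0, 0.0),
        mu0=(mu0, 0.0), log_mu1=(np.log(mu1), 0.0),
        log_emg_noise_sd=(np.log(r), 0.0),
        alpha_offset=(0.0, 0.0), log_alpha_gain=(0.0, 0.0),
        log_alpha_noise_sd=(0.0, 0.0), dt_offset=(0.0, 0.0),
        log_dt_gain=(0.0, 0.0), log_dt_noise_sd=(0.0, 0.0),
    )
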
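"""State and observation model: transitions, links, and likelihood forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import expit

from wakeprob.model import (
    ObservationGrid,
    ParameterVector,
    StateVector,
    _ObsRow,
    joint_loglik,
    loglik_behavior,
    loglik_eeg,
    loglik_emg,
    parameter_transition,
    state_transition,
    wake_state,
)


class TestStateTransition:
    def test_zero_walk_sd_is_identity(self, rng):
        s = StateVector(1.0, -2.0, 0.5)
        out = state_transition(s, (0.0, 0.0, 0.0), rng)
        assert out == s

    def test_increment_moments(self):
        rng = np.random.default_rng(99)
        sds = (0.3, 0.5, 0.7)
        prev = StateVector(0.0, 0.0, 0.0)
        inc = np.array([state_transition(prev, sds, rng).as_array()
                        for _ in range(100_000)])
        assert np.allclose(inc.mean(axis=0), 0.0, atol=3 * 0.7 / np.sqrt(1e5))
        assert np.allclose(inc.std(axis=0), sds, rtol=0.02)
        corr = np.corrcoef(inc.T)
        off_diag = corr[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off_diag) < 0.02)


class TestWakeState:
    def test_zero_states_give_even_odds(self):
        ws = wake_state(StateVector(0.0, 0.0, 0.0))
        assert ws.x_wake == 0.0
        assert ws.p == pytest.approx(0.5)

    def test_sign_convention(self):
        # motor and alpha direct, delta-theta inverse, beta = 1/3
        ws = wake_state(StateVector(3.0, 3.0, 3.0))
        assert ws.x_wake == pytest.approx(1.0)

    @given(x_m=st.floats(-5, 5), x_a=st.floats(-5, 5), x_dt=st.floats(-5, 5),
           delta=st.floats(0.01, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_each_state(self, x_m, x_a, x_dt, delta):
        base = wake_state(StateVector(x_m, x_a, x_dt)).p
        assert wake_state(StateVector(x_m + delta, x_a, x_dt)).p > base
        assert wake_state(StateVector(x_m, x_a + delta, x_dt)).p > base
        assert wake_state(StateVector(x_m, x_a, x_dt + delta)).p < base


class TestLikelihoodForms:
    def test_emg_matches_closed_form_normal(self, rng):
        for _ in range(1000):
            m, x = rng.normal(size=2)
            mu0, mu1 = rng.normal(), rng.uniform(0.1, 2)
            sd = rng.uniform(0.05, 3)
            ours = loglik_emg(m, x, mu0, mu1, sd)
            oracle = stats.norm.logpdf(m, loc=mu0 + mu1 * x, scale=sd)
            assert ours == pytest.approx(oracle, abs=1e-12)

    def test_emg_at_predicted_mean(self):
        sd = 0.7
        val = loglik_emg(1.0, 2.0, 0.0, 0.5, sd)
        assert val == pytest.approx(-np.log(sd * np.sqrt(2 * np.pi)), abs=1e-12)

    def test_emg_rejects_nonfinite_observation(self):
        with pytest.raises(ValueError):
            loglik_emg(np.nan, 0.0, 0.0, 1.0, 1.0)

    def test_eeg_matches_closed_form_normal(self, rng):
        for _ in range(1000):
            y, x = rng.normal(size=2)
            gain = rng.uniform(0.1, 4)
            offset = rng.normal()
            sd = rng.uniform(0.05, 3)
            ours = loglik_eeg(y, x, gain, offset, sd)
            oracle = stats.norm.logpdf(y, loc=offset + gain * expit(x), scale=sd)
            assert ours == pytest.approx(oracle, abs=1e-12)

    def test_eeg_sigmoid_saturation(self):
        hi = loglik_eeg(3.0, 50.0, 3.0, 0.0, 1.0)
        assert hi == pytest.approx(stats.norm.logpdf(3.0, 3.0, 1.0), abs=1e-9)
        lo = loglik_eeg(0.0, -50.0, 3.0, 0.0, 1.0)
        assert lo == pytest.approx(stats.norm.logpdf(0.0, 0.0, 1.0), abs=1e-9)

    def test_behavior_closed_form(self):
        assert loglik_behavior(1, 0.5) == pytest.approx(np.log(0.5), abs=1e-12)
        assert loglik_behavior(0, 0.05) == pytest.approx(np.log(0.95), abs=1e-12)

    def test_behavior_matches_binomial_up_to_constant(self, rng):
        # n Bernoulli terms at constant p sum to the binomial loglik minus
        # its combinatorial constant
        import math

        p, n = 0.3, 40
        b = (rng.uniform(size=n) < p).astype(int)
        ours = sum(loglik_behavior(int(bi), p) for bi in b)
        k = int(b.sum())
        oracle = stats.binom.logpmf(k, n, p) - math.log(math.comb(n, k))
        assert ours == pytest.approx(oracle, abs=1e-9)

    def test_behavior_rejects_degenerate_p(self):
        for p in (0.0, 1.0, -0.1, 1.1):
            with pytest.raises(ValueError):
                loglik_behavior(1, p)


class TestJointLoglik:
    def setup_method(self):
        self.state = StateVector(0.5, 1.0, -0.5)
        self.params = ParameterVector()

    def test_all_missing_is_exactly_zero(self):
        assert joint_loglik(_ObsRow(), self.state, self.params) == 0.0

    def test_single_modality_equals_its_term(self):
        row = _ObsRow(b=1.0)
        expected = loglik_behavior(1, wake_state(self.state).p)
        assert joint_loglik(row, self.state, self.params) == expected

    def test_full_row_is_sum_of_terms(self):
        row = _ObsRow(b=0.0, m=-1.0, y_alpha=1.5, y_deltatheta=0.3)
        p = self.params
        expected = (
            loglik_behavior(0, wake_state(self.state).p)
            + loglik_emg(-1.0, 0.5, p.mu0, p.mu1, p.emg_noise_sd)
            + loglik_eeg(1.5, 1.0, p.alpha_gain, p.alpha_offset, p.alpha_noise_sd)
            + loglik_eeg(0.3, -0.5, p.dt_gain, p.dt_offset, p.dt_noise_sd)
        )
        assert joint_loglik(row, self.state, self.params) == pytest.approx(
            expected, abs=1e-12
        )

    def test_removing_a_modality_changes_only_its_term(self):
        full = _ObsRow(b=1.0, m=-1.0, y_alpha=1.5, y_deltatheta=0.3)
        without_emg = _ObsRow(b=1.0, y_alpha=1.5, y_deltatheta=0.3)
        diff = joint_loglik(full, self.state, self.params) - joint_loglik(
            without_emg, self.state, self.params
        )
        p = self.params
        assert diff == pytest.approx(
            float(loglik_emg(-1.0, 0.5, p.mu0, p.mu1, p.emg_noise_sd)), abs=1e-12
        )


class TestParameterTransition:
    def test_zero_eps_is_identity(self, rng):
        p = ParameterVector()
        assert parameter_transition(p, 0.0, rng) == p

    def test_positive_fields_stay_positive(self):
        rng = np.random.default_rng(5)
        p = ParameterVector()
        for _ in range(500):
            p = parameter_transition(p, 0.3, rng)
        assert p.mu1 > 0 and p.emg_noise_sd > 0
        assert p.alpha_gain > 0 and p.dt_noise_sd > 0

    def test_increment_sd_matches_eps(self):
        rng = np.random.default_rng(17)
        eps = 0.05
        base = ParameterVector()
        free = np.array([
            parameter_transition(base, eps, rng).mu0 - base.mu0
            for _ in range(100_000)
        ])
        assert free.std() == pytest.approx(eps, rel=0.02)
        logpos = np.array([
            np.log(parameter_transition(base, eps, rng).alpha_gain
                   / base.alpha_gain)
            for _ in range(100_000)
        ])
        assert logpos.std() == pytest.approx(eps, rel=0.02)


class TestObservationGrid:
    def test_indicators_derive_from_nan(self):
        grid = ObservationGrid(
            times=np.array([0.0, 0.25, 0.5]),
            b=np.array([1.0, np.nan, 0.0]),
            m=np.array([np.nan, -1.0, np.nan]),
            y_alpha=np.array([1.0, 1.0, np.nan]),
            y_deltatheta=np.array([np.nan, np.nan, np.nan]),
        )
        assert grid.I_b.tolist() == [True, False, True]
        assert grid.I_m.tolist() == [False, True, False]
        assert grid.I_alpha.tolist() == [True, True, False]
        assert not grid.I_dt.any()
        assert grid.dt == 0.25

    def test_irregular_grid_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            ObservationGrid(
                times=np.array([0.0, 0.25, 1.0]),
                b=np.full(3, np.nan), m=np.full(3, np.nan),
                y_alpha=np.full(3, np.nan), y_deltatheta=np.full(3, np.nan),
            )
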
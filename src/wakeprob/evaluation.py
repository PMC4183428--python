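"""Simulation benchmarks validating the estimator against known ground truth.

Each function here builds a fully synthetic experiment with a known answer —
an exact Kalman recursion, a generative wake-probability path, a closed-form
likelihood, a null spectral contrast — runs the package's own machinery on
it, and returns summary numbers. They back both the test suite and the
reproduction script, so every reported figure is recomputed from scratch.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats
from scipy.special import expit

from .config import FilterConfig, ModelConfig, PriorSpec
from .gof import (
    ONSET_RULES,
    OnsetDefinition,
    compare_models,
    loglik_distribution,
    onset_time,
    predictive_samples_for_trials,
    transition_probability_curve,
)
from .inference import init_particles, kalman_oracle, pf_step, run_filter
from .model import ObservationGrid, loglik_behavior, loglik_eeg, loglik_emg
from .popspec import AlignedSpectralSample, bootstrap_compare, build_population_spectrogram
from .preprocessing import BreathTrial, RawSignal, band_powers, multitaper_spectrogram, scoring_window
from .simulate import SimulationScenario, simulate_dataset

__all__ = [
    "kalman_agreement",
    "recovery_experiment",
    "likelihood_exactness",
    "gof_experiment",
    "step_model_closed_form",
    "popspec_recovery",
    "popspec_false_positive_rate",
    "preprocessing_checks",
]

# linear-Gaussian EMG-only submodel used for the Kalman cross-check
_LG = dict(mu0=-1.5, mu1=0.5, obs_sd=0.3, walk_sd=0.1,
           prior_mean=2.0, prior_sd=1.0)


def _fixed_coefficient_priors() -> PriorSpec:
    z = (0.0, 0.0)
    return PriorSpec(
        state_mean=(_LG["prior_mean"], 0.0, 0.0),
        state_sd=(_LG["prior_sd"], 0.0, 0.0),
        mu0=(_LG["mu0"], 0.0),
        log_mu1=(math.log(_LG["mu1"]), 0.0),
        log_emg_noise_sd=(math.log(_LG["obs_sd"]), 0.0),
        alpha_offset=z, log_alpha_gain=z, log_alpha_noise_sd=z,
        dt_offset=z, log_dt_gain=z, log_dt_noise_sd=z,
    )


def kalman_agreement(seed: int, n_particles: int = 20_000, n_times: int = 200) -> dict:
    """Particle filter vs exact Kalman recursion on the linear submodel.

    Simulates a latent random walk observed through the linear-Gaussian EMG
    equation, filters it with the full particle machinery (coefficients
    pinned by zero-variance priors), and standardizes the per-step error of
    the posterior mean by the genealogy Monte Carlo SE. Returns the largest
    |z| over all steps and the fraction of steps within 3 SEs.
    """
    rng = np.random.default_rng(seed)
    x = _LG["prior_mean"] + np.cumsum(rng.normal(0, _LG["walk_sd"], n_times))
    m = _LG["mu0"] + _LG["mu1"] * x + rng.normal(0, _LG["obs_sd"], n_times)
    nan = np.full(n_times, np.nan)
    grid = ObservationGrid(times=0.25 * np.arange(n_times), b=nan.copy(), m=m,
                           y_alpha=nan.copy(), y_deltatheta=nan.copy())
    k_mean, _ = kalman_oracle(grid, _LG["mu0"], _LG["mu1"], _LG["obs_sd"],
                              _LG["walk_sd"], _LG["prior_mean"], _LG["prior_sd"])

    model = ModelConfig(priors=_fixed_coefficient_priors(),
                        state_walk_sds=(_LG["walk_sd"], 0.0, 0.0),
                        param_walk_sd=0.0)
    pf_rng = np.random.default_rng(seed + 1)
    ens = init_particles(model.priors, n_particles, pf_rng)

    class _Row:
        b = np.nan
        y_alpha = np.nan
        y_deltatheta = np.nan
        m = np.nan

    row = _Row()
    zs = np.empty(n_times)
    for t in range(n_times):
        row.m = m[t]
        ens = pf_step(ens, row, pf_rng, model)
        mean, se = ens.mean_and_se(ens.states[:, 0])
        zs[t] = (mean - k_mean[t]) / se
    return {
        "max_abs_z": float(np.max(np.abs(zs))),
        "frac_within_3se": float(np.mean(np.abs(zs) < 3.0)),
        "n": n_times,
    }


def recovery_experiment(seed: int, n_replicates: int = 20,
                        n_particles: int = 4000, duration: float = 600.0) -> dict:
    """State recovery on replicated sigmoid-descent nights.

    Each replicate simulates a 10-minute sleep-onset night and filters it
    with the package defaults; RMSE of the posterior-median Pr(Wake) against
    the generative truth and empirical coverage of the 95% band are pooled
    across replicates.
    """
    ss = np.random.SeedSequence(seed)
    sim_seeds, fit_seeds = ss.spawn(2)
    sim_s = sim_seeds.generate_state(n_replicates) % (2**31)
    fit_s = fit_seeds.generate_state(n_replicates) % (2**31)
    rmses, hits, total = [], 0, 0
    for k in range(n_replicates):
        ds = simulate_dataset(SimulationScenario(duration=duration,
                                                 seed=int(sim_s[k])))
        res = run_filter(ds.grid, ModelConfig(),
                         FilterConfig(n_particles=n_particles),
                         seed=int(fit_s[k]))
        err = res.curve.p_median - ds.true_p
        rmses.append(float(np.sqrt(np.mean(err**2))))
        inside = (ds.true_p >= res.curve.p_lo) & (ds.true_p <= res.curve.p_hi)
        hits += int(inside.sum())
        total += inside.size
    return {
        "rmse_max": float(np.max(rmses)),
        "rmse_mean": float(np.mean(rmses)),
        "coverage": hits / total,
        "n": n_replicates,
    }


def likelihood_exactness(seed: int, n_draws: int = 1000) -> dict:
    """Worst absolute error of the likelihood terms vs closed-form densities,
    plus the joint-likelihood additivity checks."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_draws):
        m, x = rng.normal(size=2)
        mu0 = rng.normal()
        mu1, sd = rng.uniform(0.1, 2.0, 2)
        err = abs(loglik_emg(m, x, mu0, mu1, sd)
                  - stats.norm.logpdf(m, mu0 + mu1 * x, sd))
        gain = rng.uniform(0.1, 4.0)
        off = rng.normal()
        y = rng.normal()
        err = max(err, abs(loglik_eeg(y, x, gain, off, sd)
                           - stats.norm.logpdf(y, off + gain * expit(x), sd)))
        p = rng.uniform(0.01, 0.99)
        b = int(rng.uniform() < 0.5)
        err = max(err, abs(loglik_behavior(b, p)
                           - stats.bernoulli.logpmf(b, p)))
        worst = max(worst, err)

    from .model import ParameterVector, StateVector, _ObsRow, joint_loglik

    state = StateVector(0.3, -0.7, 1.1)
    params = ParameterVector()
    empty = joint_loglik(_ObsRow(), state, params)
    full = _ObsRow(b=1.0, m=-1.2, y_alpha=1.4, y_deltatheta=0.6)
    drop_alpha = _ObsRow(b=1.0, m=-1.2, y_deltatheta=0.6)
    removal_err = abs(
        (joint_loglik(full, state, params)
         - joint_loglik(drop_alpha, state, params))
        - float(loglik_eeg(1.4, -0.7, params.alpha_gain, params.alpha_offset,
                           params.alpha_noise_sd))
    )
    return {"max_abs_err": float(worst), "empty_joint": float(empty),
            "removal_err": float(removal_err), "n": n_draws}


def gof_experiment(seed: int, transition_duration: float = 120.0,
                   n_particles: int = 2000, n_mc: int = 10_000,
                   n_nights: int = 3) -> dict:
    """Wake model vs the four instantaneous transition models.

    Simulates ``n_nights`` nights whose transitions (gradual or
    near-instantaneous) are centred on a 30-s epoch boundary so hypnogram
    onsets are exact, fits the filter to each, and compares total behavioral
    likelihood distributions pooled over nights — per-night log-likelihoods
    add, mirroring a study's all-nights analysis. Returns per-rule
    credibilities that the wake model exceeds the step model, each rule's
    onset(s), and the true transition time.
    """
    night_seeds = (np.random.SeedSequence(seed).generate_state(n_nights)
                   % (2**31))
    rng = np.random.default_rng(seed + 2)
    wake_ll = np.zeros(n_mc)
    step_ll = {rule: np.zeros(n_mc) for rule in ONSET_RULES}
    onsets = {rule: [] for rule in ONSET_RULES}
    wake_medians = []
    n_trials = 0
    for ns in night_seeds:
        sc = SimulationScenario(duration=600.0, seed=int(ns),
                                transition_time=300.0,
                                transition_duration=transition_duration)
        ds = simulate_dataset(sc)
        res = run_filter(ds.grid, ModelConfig(),
                         FilterConfig(n_particles=n_particles),
                         seed=int(ns) + 1)
        scored = [t for t in ds.trials if t.response != "missing"]
        n_trials += len(scored)
        wake_ps = predictive_samples_for_trials(res.predictive.times,
                                                res.predictive.samples,
                                                ds.trials)
        night_wake = loglik_distribution(wake_ps, scored, n_mc, rng)
        wake_ll += night_wake
        wake_medians.append(float(np.median(night_wake)))
        trial_times = np.array([t.time for t in scored])
        for rule in ONSET_RULES:
            d = OnsetDefinition(rule)
            curve = transition_probability_curve(ds.hypnogram, d, trial_times)
            step_ll[rule] += loglik_distribution(
                [np.array([p]) for p in curve.p], scored, n_mc, rng)
            onsets[rule].append(onset_time(ds.hypnogram, d))

    out = {"true_transition": 300.0, "rules": {}, "n_nights": n_nights}
    for rule in ONSET_RULES:
        cmp_ = compare_models(wake_ll, step_ll[rule])
        out["rules"][rule] = {
            "onsets": onsets[rule],
            "matched": all(o == 300.0 for o in onsets[rule]),
            "wake_exceeds": bool(cmp_.difference_median > 0),
            "credibility": cmp_.credibility,
            "prob_positive": cmp_.prob_positive,
            "difference_median": cmp_.difference_median,
        }
    out["wake_median_loglik"] = float(np.median(wake_ll))
    out["n_trials"] = n_trials
    return out


def step_model_closed_form() -> dict:
    """Hand-checkable instantaneous-model likelihood.

    Ten correct responses before onset at accuracy 0.95 and ten incorrect
    after onset at accuracy 0.05 give a total log-likelihood of exactly
    20*log(0.95).
    """
    from .gof import Hypnogram

    hyp = Hypnogram(["W"] * 2 + ["N1"] * 2, epoch_length=30.0)
    trials = [BreathTrial(3.0 * i, "correct") for i in range(10)]
    trials += [BreathTrial(60.0 + 3.0 * i, "incorrect") for i in range(10)]
    times = np.array([t.time for t in trials])
    curve = transition_probability_curve(hyp, OnsetDefinition("first_N1"), times)
    samples = loglik_distribution([np.array([p]) for p in curve.p], trials,
                                  n_mc=10)
    return {"total_loglik": float(samples[0]),
            "expected": 20.0 * math.log(0.95), "n": len(trials)}


def popspec_recovery(seed: int, n_samples: int = 4000) -> dict:
    """Phi recovery of a known monotone power-vs-p relationship.

    Samples carry alpha-band power exactly equal to their p value; the
    population spectrogram at the 0.0025 bin width must reproduce each bin's
    center to within half a bin, and be monotone across populated bins.
    """
    rng = np.random.default_rng(seed)
    ps = rng.uniform(size=n_samples)
    samples = [AlignedSpectralSample("s", p, np.array([p, 0.5])) for p in ps]
    pop = build_population_spectrogram(samples, bin_width=0.0025)
    filled = ~np.isnan(pop.phi[:, 0])
    err = np.abs(pop.phi[filled, 0] - pop.bin_centers[filled])
    monotone = bool(np.all(np.diff(pop.phi[filled, 0]) > 0))
    return {"max_err": float(err.max()), "bin_halfwidth": 0.0025 / 2,
            "n_bins": int(pop.bin_edges.size - 1), "monotone": monotone,
            "n": n_samples}


def popspec_false_positive_rate(seed: int, per_bin: int = 80,
                                n_iterations: int = 1000) -> dict:
    """Type-I error of the per-bin bootstrap under a true null.

    Two groups drawn from one spectral distribution across all 400 Pr(Wake)
    bins; the fraction of (bin, frequency) cells declared significant at the
    2.5/97.5 percentile rule estimates the false-positive rate.
    """
    rng = np.random.default_rng(seed)

    def group():
        out = []
        for b in range(400):
            for u in rng.uniform(size=per_bin):
                out.append(AlignedSpectralSample(
                    "s", min((b + u) * 0.0025, 1.0),
                    rng.normal(10.0, 1.0, 2).clip(0)))
        return out

    cmp_ = bootstrap_compare(group(), group(), n_iterations=n_iterations,
                             seed=seed, bin_width=0.0025)
    cells = cmp_.significant[cmp_.comparable]
    return {"false_positive_rate": float(cells.mean()),
            "n_cells": int(cells.size), "n": n_iterations}


def preprocessing_checks(seed: int) -> dict:
    """Scoring-window rules, Parseval consistency, and band partition."""
    # start rule: window opens at the first run of >= 3 consecutive correct
    trials = [BreathTrial(4.0 * i, r) for i, r in enumerate(
        ["incorrect", "correct", "incorrect", "correct", "correct", "correct",
         "correct", "incorrect"])]
    win = scoring_window(trials)
    start_ok = win[0].time == trials[3].time
    # stop rule: closes exactly 600 s after the last correct response
    trials2 = [BreathTrial(t, "correct") for t in (0.0, 300.0, 600.0)]
    trials2 += [BreathTrial(t, "incorrect") for t in (900.0, 1200.0, 1200.5)]
    win2 = scoring_window(trials2)
    stop_ok = win2[-1].time == 1200.0 and all(t.time <= 1200.0 for t in win2)

    rng = np.random.default_rng(seed)
    sigma = 1.3
    sig = RawSignal(rng.normal(0, sigma, int(60 * 200)), 200.0)
    spec = multitaper_spectrogram(sig)
    total = spec.power.sum(axis=1) * spec.df
    parseval_ratio = float(np.mean(total) / sigma**2)
    bp = band_powers(spec)
    mask = (spec.freqs >= 0.5) & (spec.freqs < 12.0)
    ref = spec.power[:, mask].sum(axis=1) * spec.df
    partition_err = float(np.max(np.abs(bp.delta + bp.theta + bp.alpha - ref)
                                 / np.maximum(ref, 1e-300)))
    return {"start_rule_ok": bool(start_ok), "stop_rule_ok": bool(stop_ok),
            "parseval_ratio": parseval_ratio,
            "band_partition_max_rel_err": partition_err, "n": sig.samples.size}
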
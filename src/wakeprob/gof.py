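"""Bayesian Monte Carlo goodness-of-fit against instantaneous transition models.

Any clinical definition of a single sleep-onset moment implies a stepwise
model of behavior: the subject responds correctly with 95% accuracy while
deemed awake and with 5% accuracy once deemed asleep. Four common onset
definitions are supported (first N1 epoch, first N2 epoch, first of 3
consecutive NREM epochs, first of 10 consecutive NREM epochs). For each
model, the total behavioral log-likelihood distribution is built by Monte
Carlo: per iteration, one response probability is drawn per scored trial from
that model's per-trial distribution — the wake model's one-step-ahead
predictive samples, or the step model's point value — and the Bernoulli
log-likelihoods are summed across trials. Models are then compared through
the difference distribution and the credible level at which it excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import loglik_behavior
from .preprocessing import BreathTrial

__all__ = [
    "Hypnogram",
    "OnsetDefinition",
    "ONSET_RULES",
    "TransitionModelCurve",
    "ModelComparison",
    "onset_time",
    "transition_probability_curve",
    "loglik_distribution",
    "compare_models",
    "predictive_samples_for_trials",
]

STAGES = ("W", "N1", "N2", "N3", "R")
NREM = frozenset({"N1", "N2", "N3"})
ONSET_RULES = ("first_N1", "first_N2", "first_3_NREM", "first_10_NREM")


@dataclass
class Hypnogram:
    """Ordered 30-s-epoch stage codes from visual sleep staging."""

    epochs: Sequence[str]
    epoch_length: float = 30.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.epochs = list(self.epochs)
        if not self.epochs:
            raise ValueError("hypnogram must be nonempty")
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be > 0")
        bad = [s for s in self.epochs if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stage codes: {sorted(set(bad))}")

    def epoch_start(self, index: int) -> float:
        return self.start_time + index * self.epoch_length


@dataclass(frozen=True)
class OnsetDefinition:
    """One of the four clinical sleep-onset rules."""

    rule: str

    def __post_init__(self) -> None:
        if self.rule not in ONSET_RULES:
            raise ValueError(f"rule must be one of {ONSET_RULES}")


@dataclass
class TransitionModelCurve:
    """Stepwise response probability implied by an onset definition."""

    times: np.ndarray
    p: np.ndarray
    onset: float | None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != self.times.shape:
            raise ValueError("p must match times")


@dataclass
class ModelComparison:
    """Likelihood comparison of the wake model against one competitor.

    ``credibility`` is the largest central credible level at which the
    difference (wake minus competitor) distribution excludes zero;
    ``prob_positive`` is the plain posterior probability the difference is
    positive.
    """

    wake_samples: np.ndarray
    competitor_samples: np.ndarray
    difference_samples: np.ndarray
    wake_median: float
    competitor_median: float
    difference_median: float
    wake_ci: tuple[float, float]
    competitor_ci: tuple[float, float]
    difference_ci: tuple[float, float]
    credibility: float
    prob_positive: float


def _run_starts(epochs: Sequence[str], run_length: int) -> int | None:
    run = 0
    for i, s in enumerate(epochs):
        run = run + 1 if s in NREM else 0
        if run == run_length:
            return i - run_length + 1
    return None


def onset_time(h: Hypnogram, d: OnsetDefinition) -> float | None:
    """Start time of the first epoch satisfying the onset rule.

    For the run rules the time of the *first* epoch of the qualifying run is
    returned. ``None`` when the rule is never satisfied (the subject is then
    treated as awake throughout by the transition model).
    """
    if d.rule == "first_N1":
        idx = next((i for i, s in enumerate(h.epochs) if s == "N1"), None)
    elif d.rule == "first_N2":
        idx = next((i for i, s in enumerate(h.epochs) if s == "N2"), None)
    elif d.rule == "first_3_NREM":
        idx = _run_starts(h.epochs, 3)
    else:
        idx = _run_starts(h.epochs, 10)
    return None if idx is None else h.epoch_start(idx)


def transition_probability_curve(
    h: Hypnogram,
    d: OnsetDefinition,
    times: np.ndarray,
    p_awake: float = 0.95,
    p_asleep: float = 0.05,
) -> TransitionModelCurve:
    """The step curve: ``p_awake`` before onset, ``p_asleep`` from onset on.

    The onset epoch itself counts as asleep (the definitions name the first
    epoch *of sleep*). With no onset the curve is constant ``p_awake``.
    """
    if not 0 < p_asleep < p_awake < 1:
        raise ValueError("need 0 < p_asleep < p_awake < 1")
    times = np.asarray(times, dtype=float)
    onset = onset_time(h, d)
    p = np.full(times.shape, p_awake)
    if onset is not None:
        p[times >= onset] = p_asleep
    return TransitionModelCurve(times, p, onset)


def loglik_distribution(
    p_samples_per_trial: Sequence[np.ndarray],
    responses: Sequence[BreathTrial],
    n_mc: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Monte Carlo samples of the total behavioral log-likelihood.

    One collection of p samples per scored (non-missing) trial; per
    iteration, one p is drawn uniformly from each trial's collection and the
    Bernoulli log-likelihoods are summed. A degenerate (length-1) collection
    makes the trial's contribution deterministic, so a stepwise model yields
    a point-mass distribution.
    """
    scored = [t for t in responses if t.response != "missing"]
    if len(p_samples_per_trial) != len(scored):
        raise ValueError(
            f"got {len(p_samples_per_trial)} p-sample collections for "
            f"{len(scored)} scored trials"
        )
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    if not scored:
        return np.zeros(n_mc)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    b = np.array([1.0 if t.response == "correct" else 0.0 for t in scored])
    total = np.zeros(n_mc)
    for j, samples in enumerate(p_samples_per_trial):
        samples = np.asarray(samples, dtype=float)
        if samples.size == 0 or np.any((samples <= 0) | (samples >= 1)):
            raise ValueError(f"invalid p samples for trial {j}")
        if samples.size == 1:
            p = np.full(n_mc, samples[0])
        else:
            p = samples[rng.integers(0, samples.size, n_mc)]
        total += loglik_behavior(int(b[j]), p)
    return total


def predictive_samples_for_trials(
    predictive_times: np.ndarray,
    predictive_samples: np.ndarray,
    trials: Sequence[BreathTrial],
    tol: float = 0.5,
) -> list[np.ndarray]:
    """Match one-step-ahead predictive sample sets to scored trials by time."""
    out = []
    predictive_times = np.asarray(predictive_times)
    for t in trials:
        if t.response == "missing":
            continue
        if predictive_times.size == 0:
            raise ValueError(f"no predictive samples for trial at t={t.time}")
        k = int(np.argmin(np.abs(predictive_times - t.time)))
        if abs(predictive_times[k] - t.time) > tol:
            raise ValueError(f"no predictive samples for trial at t={t.time}")
        out.append(predictive_samples[k])
    return out


def compare_models(
    wake_samples: np.ndarray, competitor_samples: np.ndarray
) -> ModelComparison:
    """Pairwise difference distribution and its credibility statement.

    Samples are paired by iteration; the central 95% credible intervals use
    plain empirical quantiles. The credibility is the largest central level
    at which the difference distribution excludes zero,
    ``1 - 2 min(P(d <= 0), P(d >= 0))`` (0 for a distribution with mass
    exactly at zero, e.g. comparing a model with itself).
    """
    wake = np.asarray(wake_samples, dtype=float)
    comp = np.asarray(competitor_samples, dtype=float)
    if wake.size == 0 or comp.size == 0:
        raise ValueError("sample sets must be nonempty")
    if wake.shape != comp.shape:
        raise ValueError("sample counts must match (pair by iteration)")
    diff = wake - comp
    q = lambda x: (float(np.quantile(x, 0.025)), float(np.quantile(x, 0.975)))
    p_le = float(np.mean(diff <= 0))
    p_ge = float(np.mean(diff >= 0))
    cred = max(0.0, 1.0 - 2.0 * min(p_le, p_ge))
    return ModelComparison(
        wake_samples=wake,
        competitor_samples=comp,
        difference_samples=diff,
        wake_median=float(np.median(wake)),
        competitor_median=float(np.median(comp)),
        difference_median=float(np.median(diff)),
        wake_ci=q(wake),
        competitor_ci=q(comp),
        difference_ci=q(diff),
        credibility=cred,
        prob_positive=float(np.mean(diff > 0)),
    )
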
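"""Synthetic sleep-onset datasets with known ground truth.

The generator draws latent state trajectories shaped like the sleep-onset
regimes seen in real recordings — a smooth sigmoidal descent, a descent
interrupted by a brief (~1 min) arousal, an alpha-dropout phenotype where
alpha power declines minutes before delta-theta rises, or a pure random
walk — and then samples observations from the wake model's own equations:
log EMG amplitudes and Bernoulli responses at jittered breath-trial times
(~15 breaths/min), and log alpha / delta-theta band powers at every grid
time. Per-modality missingness clears observations at random. A hypnogram is
derived from the true wake probability by thresholding 30-s epoch means, so
goodness-of-fit comparisons have a matched clinical-style staging.

Everything is reproducible bit-exactly from (scenario, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .gof import Hypnogram
from .model import DEFAULT_BETA, ObservationGrid, ParameterVector, wake_probability
from .preprocessing import BreathTrial

__all__ = [
    "SimulationScenario",
    "SimulatedDataset",
    "simulate_states",
    "simulate_observations",
    "simulate_hypnogram",
    "simulate_dataset",
]

TRAJECTORIES = ("random_walk", "sigmoid_descent", "descent_with_arousal",
                "alpha_dropout")

#: State levels corresponding to full wakefulness / established sleep. With
#: beta = 1/3 these give Pr(Wake) of logistic(+3) ~ 0.95 and
#: logistic(-3) ~ 0.05, matching the accuracies conventionally assumed for an
#: awake and an asleep subject.
AWAKE_LEVEL = 3.0
ASLEEP_LEVEL = -3.0


@dataclass
class SimulationScenario:
    """Fully specifies one synthetic night.

    ``transition_time``/``transition_duration`` locate and scale the sigmoid
    descent (the descent spans roughly ``transition_duration`` seconds);
    ``arousal_time``/``arousal_duration`` place the ~1-minute reversal of the
    ``descent_with_arousal`` regime; ``alpha_lead`` is how many seconds the
    alpha descent precedes the delta-theta rise in the ``alpha_dropout``
    regime. ``trial_rate`` is breaths per minute; ``missingness`` maps
    modality names (``"b"``, ``"m"``, ``"eeg"``) to drop probabilities.
    """

    duration: float = 600.0
    dt: float = 0.25
    trajectory: str = "sigmoid_descent"
    params: ParameterVector = field(default_factory=ParameterVector)
    trial_rate: float = 15.0
    missingness: dict = field(default_factory=dict)
    seed: int = 0
    beta: float = DEFAULT_BETA
    transition_time: float | None = None   # default: duration / 2
    transition_duration: float = 120.0
    arousal_time: float | None = None      # default: 0.7 * duration
    arousal_duration: float = 60.0
    alpha_lead: float = 240.0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be > 0")
        if self.trajectory not in TRAJECTORIES:
            raise ValueError(f"trajectory must be one of {TRAJECTORIES}")
        if self.trial_rate < 0:
            raise ValueError("trial_rate must be >= 0")


@dataclass
class SimulatedDataset:
    """Ground truth plus observations for one synthetic night."""

    times: np.ndarray
    true_states: np.ndarray        # (T, 3): x_m, x_alpha, x_deltatheta
    true_p: np.ndarray
    grid: ObservationGrid
    trials: list[BreathTrial]
    hypnogram: Hypnogram
    scenario: SimulationScenario


def _sigmoid_path(times: np.ndarray, midpoint: float, duration: float,
                  start: float, end: float) -> np.ndarray:
    # the logistic covers ~88% of its range over 4*tau; map duration onto that
    tau = max(duration, 1e-9) / 4.0
    return start + (end - start) * expit((times - midpoint) / tau)


def simulate_states(scenario: SimulationScenario) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw the latent state trajectories and the true wake probability.

    Returns ``(times, states, p)`` with ``states`` of shape (T, 3). The
    deterministic regime shapes receive additive random-walk noise at the
    scenario's ``state_walk_sds``; with zero walk sds the paths (and hence p)
    are exactly the deterministic shapes.
    """
    rng = np.random.default_rng(scenario.seed)
    times = np.arange(0.0, scenario.duration + scenario.dt / 2, scenario.dt)
    T = times.size
    t_mid = (scenario.transition_time
             if scenario.transition_time is not None else scenario.duration / 2)

    if scenario.trajectory == "random_walk":
        base = np.full((T, 3), [AWAKE_LEVEL, AWAKE_LEVEL, ASLEEP_LEVEL])
    else:
        down = _sigmoid_path(times, t_mid, scenario.transition_duration,
                             AWAKE_LEVEL, ASLEEP_LEVEL)
        up = _sigmoid_path(times, t_mid, scenario.transition_duration,
                           ASLEEP_LEVEL, AWAKE_LEVEL)
        base = np.column_stack([down, down.copy(), up])
        if scenario.trajectory == "alpha_dropout":
            base[:, 1] = _sigmoid_path(
                times, t_mid - scenario.alpha_lead, scenario.transition_duration,
                AWAKE_LEVEL, ASLEEP_LEVEL,
            )
        elif scenario.trajectory == "descent_with_arousal":
            t_a = (scenario.arousal_time
                   if scenario.arousal_time is not None else 0.7 * scenario.duration)
            bump = np.exp(-0.5 * ((times - t_a) / (scenario.arousal_duration / 4.0)) ** 2)
            # pull each state back toward its wake level during the arousal
            base[:, 0] += bump * (AWAKE_LEVEL - base[:, 0])
            base[:, 1] += bump * (AWAKE_LEVEL - base[:, 1])
            base[:, 2] += bump * (ASLEEP_LEVEL - base[:, 2])

    sds = np.asarray(scenario.params.state_walk_sds)
    noise = np.cumsum(rng.normal(size=(T, 3)) * sds, axis=0)
    states = base + noise
    p = wake_probability(states[:, 0], states[:, 1], states[:, 2], scenario.beta)
    return times, states, p


def _trial_times(scenario: SimulationScenario, times: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Jittered regular breath apexes, snapped to the grid."""
    if scenario.trial_rate <= 0:
        return np.empty(0)
    interval = 60.0 / scenario.trial_rate
    raw = np.arange(interval, scenario.duration - scenario.dt, interval)
    raw = raw + rng.uniform(-0.125 * interval, 0.125 * interval, raw.size)
    idx = np.unique(np.clip(np.round(raw / scenario.dt).astype(int), 0,
                            times.size - 1))
    return times[idx]


def simulate_observations(
    times: np.ndarray,
    states: np.ndarray,
    scenario: SimulationScenario,
    rng: np.random.Generator | None = None,
) -> tuple[ObservationGrid, list[BreathTrial]]:
    """Sample observations from the model equations under the true states.

    EEG log band powers are drawn at every grid time; log EMG amplitudes and
    Bernoulli responses only at breath-trial times. Configured missingness
    then blanks observations (a missing behavioral trial is emitted as a
    ``missing`` :class:`BreathTrial`, mirroring unscorable real trials).
    """
    if rng is None:
        # offset stream so observation noise is independent of the state draw
        rng = np.random.default_rng((scenario.seed + 1) % 2**31)
    pp = scenario.params
    T = times.size
    p = wake_probability(states[:, 0], states[:, 1], states[:, 2], scenario.beta)

    y_alpha = (pp.alpha_offset + pp.alpha_gain * expit(states[:, 1])
               + rng.normal(0, pp.alpha_noise_sd, T))
    y_dt = (pp.dt_offset + pp.dt_gain * expit(states[:, 2])
            + rng.normal(0, pp.dt_noise_sd, T))

    trial_t = _trial_times(scenario, times, rng)
    trial_idx = np.round((trial_t - times[0]) / scenario.dt).astype(int)

    m = np.full(T, np.nan)
    b = np.full(T, np.nan)
    m[trial_idx] = (pp.mu0 + pp.mu1 * states[trial_idx, 0]
                    + rng.normal(0, pp.emg_noise_sd, trial_idx.size))
    b[trial_idx] = (rng.uniform(size=trial_idx.size) < p[trial_idx]).astype(float)

    miss = {"b": 0.0, "m": 0.0, "eeg": 0.0, **scenario.missingness}
    if miss["eeg"] > 0:
        drop = rng.uniform(size=T) < miss["eeg"]
        y_alpha[drop] = np.nan
        y_dt[drop] = np.nan
    drop_b = rng.uniform(size=trial_idx.size) < miss["b"]
    drop_m = rng.uniform(size=trial_idx.size) < miss["m"]
    b[trial_idx[drop_b]] = np.nan
    m[trial_idx[drop_m]] = np.nan

    trials = []
    for k, ti in enumerate(trial_idx):
        if drop_b[k]:
            resp = "missing"
        else:
            resp = "correct" if b[ti] == 1.0 else "incorrect"
        trials.append(BreathTrial(float(times[ti]), resp))

    grid = ObservationGrid(times=times.copy(), b=b, m=m,
                           y_alpha=y_alpha, y_deltatheta=y_dt)
    return grid, trials


def simulate_hypnogram(
    true_p: np.ndarray,
    times: np.ndarray,
    epoch_length: float = 30.0,
    thresholds: tuple[float, float] = (0.7, 0.3),
) -> Hypnogram:
    """Stage 30-s epochs from the mean true wake probability.

    Epoch mean p >= thresholds[0] is scored W, >= thresholds[1] is N1, and
    anything lower N2. The thresholds are scenario-level choices, standing in
    for a human scorer.
    """
    hi, lo = thresholds
    if not 0 <= lo < hi <= 1:
        raise ValueError("thresholds must satisfy 0 <= lo < hi <= 1")
    n_epochs = int(np.ceil((times[-1] - times[0] + 1e-9) / epoch_length))
    stages = []
    for e in range(max(n_epochs, 1)):
        mask = ((times - times[0] >= e * epoch_length)
                & (times - times[0] < (e + 1) * epoch_length))
        mean_p = float(np.mean(true_p[mask])) if mask.any() else float(true_p[-1])
        stages.append("W" if mean_p >= hi else ("N1" if mean_p >= lo else "N2"))
    return Hypnogram(stages, epoch_length=epoch_length, start_time=float(times[0]))


def simulate_dataset(scenario: SimulationScenario) -> SimulatedDataset:
    """Generate a complete synthetic night from one scenario."""
    times, states, p = simulate_states(scenario)
    grid, trials = simulate_observations(times, states, scenario)
    hyp = simulate_hypnogram(p, times)
    return SimulatedDataset(times, states, p, grid, trials, hyp, scenario)
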
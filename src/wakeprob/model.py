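"""The wake-probability state-space model.

Three latent activity processes — motor (``x_m``), alpha (``x_alpha``) and
delta-theta (``x_deltatheta``) — evolve as independent Gaussian random walks.
Their combination

    x_wake = beta * (x_m + x_alpha - x_deltatheta),   beta = 1/3

is mapped through a logistic link to ``p = Pr(Wake)``, which is also the
instantaneous probability of a correct behavioral response. Each observation
stream has its own likelihood:

* log EMG squeeze amplitude: Gaussian about a linear function of ``x_m``;
* log alpha / delta-theta band power: Gaussian about a sigmoid of its state;
* binary behavioral response: Bernoulli with probability ``p``.

Missing observations contribute exactly zero to the joint log-likelihood via
per-modality presence indicators, so the model runs on whatever data exists
at each time. Static coefficients are estimated jointly with the states by
giving them a small-variance random walk of their own.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
from scipy.special import expit

__all__ = [
    "StateVector",
    "WakeState",
    "ParameterVector",
    "ObservationGrid",
    "DEFAULT_BETA",
    "state_transition",
    "wake_state",
    "wake_probability",
    "loglik_emg",
    "loglik_eeg",
    "loglik_behavior",
    "joint_loglik",
    "parameter_transition",
]

DEFAULT_BETA = 1.0 / 3.0

_LOG_2PI = float(np.log(2.0 * np.pi))

#: Parameter fields that must stay positive and are therefore random-walked
#: on the log scale.
POSITIVE_PARAMS = (
    "mu1",
    "emg_noise_sd",
    "alpha_gain",
    "alpha_noise_sd",
    "dt_gain",
    "dt_noise_sd",
)
#: Parameter fields walked on their natural (unconstrained) scale.
FREE_PARAMS = ("mu0", "alpha_offset", "dt_offset")
WALKED_PARAMS = FREE_PARAMS + POSITIVE_PARAMS


@dataclass(frozen=True)
class StateVector:
    """Latent activity levels (dimensionless, unbounded support)."""

    x_m: float = 0.0
    x_alpha: float = 0.0
    x_deltatheta: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.x_m, self.x_alpha, self.x_deltatheta])


@dataclass(frozen=True)
class WakeState:
    """Combined wake activity and its probability-scale image."""

    x_wake: float
    p: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"p must lie strictly in (0,1), got {self.p}")


@dataclass
class ParameterVector:
    """Observation-model coefficients and the random-walk scales.

    ``mu0 + mu1 * x_m`` is the mean log EMG amplitude (``mu0`` absorbs the
    baseline muscle tone that squeezes revert to); each EEG stream's mean log
    power is ``offset + gain * logistic(x)``. ``state_walk_sds`` are the
    per-step standard deviations of the three state random walks and
    ``param_walk_sd`` the (small) per-step scale of the coefficient walk.
    """

    mu0: float = -1.5
    mu1: float = 0.5
    emg_noise_sd: float = 0.3
    alpha_gain: float = 2.0
    alpha_offset: float = 0.0
    alpha_noise_sd: float = 0.5
    dt_gain: float = 2.0
    dt_offset: float = 0.0
    dt_noise_sd: float = 0.5
    state_walk_sds: tuple[float, float, float] = (0.02, 0.02, 0.02)
    param_walk_sd: float = 0.002

    def __post_init__(self) -> None:
        for name in ("mu1", "alpha_gain", "dt_gain"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        # noise sds may be exactly 0 generatively (noise-free simulation);
        # the likelihood functions themselves still require sd > 0
        for name in ("emg_noise_sd", "alpha_noise_sd", "dt_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(s < 0 for s in self.state_walk_sds) or self.param_walk_sd < 0:
            raise ValueError("walk sds must be >= 0")


@dataclass
class ObservationGrid:
    """Time-aligned observation bundle on a constant-spacing grid.

    Missing values are NaN; boolean presence indicators are derived, never
    stored separately. ``b`` is 0/1, ``m`` the log EMG amplitude, ``y_alpha``
    and ``y_deltatheta`` the log band powers.
    """

    times: np.ndarray
    b: np.ndarray
    m: np.ndarray
    y_alpha: np.ndarray
    y_deltatheta: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for name in ("b", "m", "y_alpha", "y_deltatheta"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.times.shape:
                raise ValueError(f"{name} must match times in shape")
            setattr(self, name, arr)
        if self.times.size > 2:
            steps = np.diff(self.times)
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise ValueError("grid spacing must be constant")

    def __len__(self) -> int:
        return self.times.size

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self) > 1 else 0.0

    @property
    def I_b(self) -> np.ndarray:
        return ~np.isnan(self.b)

    @property
    def I_m(self) -> np.ndarray:
        return ~np.isnan(self.m)

    @property
    def I_alpha(self) -> np.ndarray:
        return ~np.isnan(self.y_alpha)

    @property
    def I_dt(self) -> np.ndarray:
        return ~np.isnan(self.y_deltatheta)


def state_transition(
    prev: StateVector, walk_sds: Iterable[float], rng: np.random.Generator
) -> StateVector:
    """One random-walk step: each state gains independent N(0, sd²) noise."""
    sds = np.asarray(list(walk_sds), dtype=float)
    if np.any(sds < 0):
        raise ValueError("walk sds must be >= 0")
    new = prev.as_array() + rng.normal(0.0, 1.0, 3) * sds
    return StateVector(*new)


def wake_state(s: StateVector, beta: float = DEFAULT_BETA) -> WakeState:
    """Combine the states into the wake state and its probability.

    Motor and alpha activity push toward wakefulness, delta-theta away from
    it; with beta = 1/3 the wake state is the mean of the three (signed)
    state levels, and p = logistic(x_wake).
    """
    x = beta * (s.x_m + s.x_alpha - s.x_deltatheta)
    return WakeState(x_wake=float(x), p=float(expit(x)))


def wake_probability(
    x_m: np.ndarray, x_alpha: np.ndarray, x_dt: np.ndarray, beta: float = DEFAULT_BETA
) -> np.ndarray:
    """Vectorized p = logistic(beta * (x_m + x_alpha - x_deltatheta))."""
    return expit(beta * (x_m + x_alpha - x_dt))


def _norm_logpdf(x, mean, sd):
    z = (x - mean) / sd
    return -0.5 * z * z - np.log(sd) - 0.5 * _LOG_2PI


def loglik_emg(m_obs: float, x_m, mu0, mu1, sd):
    """Gaussian log-density of a log EMG amplitude about ``mu0 + mu1*x_m``."""
    if not np.all(np.isfinite(m_obs)):
        raise ValueError("m_obs must be finite")
    if np.any(np.asarray(sd) <= 0):
        raise ValueError("sd must be > 0")
    return _norm_logpdf(m_obs, mu0 + mu1 * np.asarray(x_m), sd)


def loglik_eeg(y_obs: float, x, gain, offset, sd):
    """Gaussian log-density of a log band power about ``offset +
    gain*logistic(x)``.

    The same sigmoid form serves both streams; wakefulness direction is
    carried by the sign of each state's contribution to the wake state, not
    by this function.
    """
    if np.any(np.asarray(sd) <= 0) or np.any(np.asarray(gain) <= 0):
        raise ValueError("sd and gain must be > 0")
    return _norm_logpdf(y_obs, offset + gain * expit(np.asarray(x)), sd)


def loglik_behavior(b_obs: int, p):
    """Bernoulli log-likelihood b*log(p) + (1-b)*log(1-p)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("p must lie strictly in (0,1)")
    if b_obs not in (0, 1):
        raise ValueError("b_obs must be 0 or 1")
    return b_obs * np.log(p) + (1 - b_obs) * np.log1p(-p)


def joint_loglik(
    obs,
    state: StateVector,
    params: ParameterVector,
    beta: float = DEFAULT_BETA,
) -> float:
    """Indicator-gated sum of the modality log-likelihoods at one time.

    ``obs`` is any object with fields ``b, m, y_alpha, y_deltatheta`` where a
    NaN marks an absent observation; each absent modality contributes exactly
    0, so a fully missing row has joint log-likelihood 0.
    """
    total = 0.0
    if not np.isnan(obs.b):
        total += float(loglik_behavior(int(obs.b), wake_state(state, beta).p))
    if not np.isnan(obs.m):
        total += float(
            loglik_emg(obs.m, state.x_m, params.mu0, params.mu1, params.emg_noise_sd)
        )
    if not np.isnan(obs.y_alpha):
        total += float(
            loglik_eeg(
                obs.y_alpha,
                state.x_alpha,
                params.alpha_gain,
                params.alpha_offset,
                params.alpha_noise_sd,
            )
        )
    if not np.isnan(obs.y_deltatheta):
        total += float(
            loglik_eeg(
                obs.y_deltatheta,
                state.x_deltatheta,
                params.dt_gain,
                params.dt_offset,
                params.dt_noise_sd,
            )
        )
    return total


def parameter_transition(
    prev: ParameterVector, eps_sd: float | None, rng: np.random.Generator
) -> ParameterVector:
    """Small random-walk step on the static coefficients.

    Unconstrained coefficients gain additive N(0, eps_sd²) noise;
    positive-constrained ones are walked on the log scale (multiplied by
    exp(N(0, eps_sd²))) so they remain positive after any number of steps.
    ``eps_sd=None`` uses ``prev.param_walk_sd``; 0 leaves parameters fixed.
    """
    sd = prev.param_walk_sd if eps_sd is None else eps_sd
    if sd < 0:
        raise ValueError("eps_sd must be >= 0")
    updates = {}
    for name in FREE_PARAMS:
        updates[name] = getattr(prev, name) + rng.normal(0.0, 1.0) * sd
    for name in POSITIVE_PARAMS:
        updates[name] = getattr(prev, name) * np.exp(rng.normal(0.0, 1.0) * sd)
    return replace(prev, **updates)


@dataclass
class _ObsRow:
    """A single-time observation row (NaN = missing)."""

    b: float = np.nan
    m: float = np.nan
    y_alpha: float = np.nan
    y_deltatheta: float = np.nan
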
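"""Sequential importance resampling (particle filter) for the wake model.

States and walked coefficients are carried jointly by each particle. One
filter step propagates every particle through the state random walk and the
coefficient-evolution kernel (by default Liu & West's variance-preserving
shrinkage form of the artificial-evolution walk; optionally the plain walk),
reweights by the exponentiated joint log-likelihood of whatever observations
exist at that time (log-domain accumulation with max-subtraction), and
resamples systematically whenever the effective sample size falls below half
the ensemble. The output is the wake probability
curve — per-time weighted posterior quantiles (2.5/50/97.5%) of p — plus the
one-step-ahead predictive samples of p at behavioral-trial times used by the
goodness-of-fit analysis, and posterior summaries of each modality's
predicted observation mean.

Two standard variance-reduction devices are built in: state propagation
noise is drawn by randomized stratification (a permuted stratified inverse
CDF, the randomized quasi-Monte Carlo scheme of sequential QMC filtering),
and systematic resampling is applied after sorting particles along the wake
state, the one-dimensional analogue of Hilbert-ordered resampling. Both
leave the filter's target distribution untouched and only shrink Monte Carlo
error. Per-particle ancestry ("Eve" indices) is tracked so the Monte Carlo
standard error of any posterior mean can be estimated consistently with the
genealogy (ancestral-cluster) estimator of Chan & Lai / Lee & Whiteley —
unlike the naive sd/sqrt(ESS), this remains valid through resampling.

A closed-form Kalman recursion for the linear-Gaussian EMG-only submodel is
provided as an exact cross-check of the filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, ndtri

from .config import FilterConfig, ModelConfig, PriorSpec
from .model import ObservationGrid, loglik_eeg, loglik_emg

__all__ = [
    "ParticleEnsemble",
    "WakeProbabilityCurve",
    "PredictiveSeries",
    "FilterResult",
    "init_particles",
    "pf_step",
    "run_filter",
    "weighted_quantile",
    "kalman_oracle",
]

# Column layout of the walked-parameter matrix. Positive-constrained columns
# are stored in natural scale but walked multiplicatively (log-scale walk).
PARAM_COLS = (
    "mu0",
    "mu1",
    "emg_noise_sd",
    "alpha_offset",
    "alpha_gain",
    "alpha_noise_sd",
    "dt_offset",
    "dt_gain",
    "dt_noise_sd",
)
_POSITIVE = np.array(
    [c in ("mu1", "emg_noise_sd", "alpha_gain", "alpha_noise_sd",
           "dt_gain", "dt_noise_sd") for c in PARAM_COLS]
)


class DegenerateWeightsError(RuntimeError):
    """All particle weights underflowed to zero at some observation."""


def stratified_normal(rng: np.random.Generator, n: int) -> np.ndarray:
    """n standard-normal draws by randomized stratification of (0,1).

    Each stratum of width 1/n contributes exactly one uniform, mapped through
    the normal inverse CDF and randomly permuted: marginally exact N(0,1)
    samples whose empirical moments have far lower Monte Carlo error than
    i.i.d. draws.
    """
    u = (rng.permutation(n) + rng.uniform(size=n)) / n
    return ndtri(u)


@dataclass
class ParticleEnsemble:
    """Weighted joint samples of (states, walked parameters).

    ``states`` is (N, 3) in the order (x_m, x_alpha, x_deltatheta);
    ``params`` is (N, 9) in :data:`PARAM_COLS` order; weights are
    nonnegative and sum to one. ``eve`` labels each particle's time-zero
    ancestor, from which genealogy-based Monte Carlo standard errors are
    computed.
    """

    states: np.ndarray
    params: np.ndarray
    weights: np.ndarray
    time_index: int = 0
    eve: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.states.shape[0]
        if n < 2:
            raise ValueError("ensemble needs at least 2 particles")
        if self.params.shape != (n, len(PARAM_COLS)) or self.weights.shape != (n,):
            raise ValueError("inconsistent ensemble shapes")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if self.eve is None:
            self.eve = np.arange(n)

    @property
    def n(self) -> int:
        return self.states.shape[0]

    def col(self, name: str) -> np.ndarray:
        return self.params[:, PARAM_COLS.index(name)]

    def p(self, beta: float) -> np.ndarray:
        """Per-particle wake probability."""
        x = beta * (self.states[:, 0] + self.states[:, 1] - self.states[:, 2])
        return expit(x)

    def ess(self) -> float:
        return float(1.0 / np.sum(self.weights**2))

    def mean_and_se(self, values: np.ndarray) -> tuple[float, float]:
        """Weighted posterior mean of ``values`` and its Monte Carlo SE.

        The SE is the ancestral-cluster (genealogy) estimator: weighted
        deviations are summed within each Eve cluster and the cluster sums'
        squares added. With no resampling history it reduces to the familiar
        sd/sqrt(ESS); after resampling it correctly absorbs the error that
        duplicated ancestry induces.
        """
        mean = float(np.sum(self.weights * values))
        dev = self.weights * (values - mean)
        cluster = np.bincount(self.eve, weights=dev, minlength=self.n)
        return mean, float(np.sqrt(np.sum(cluster**2)))


@dataclass
class WakeProbabilityCurve:
    """Per-time posterior quantiles of p: median and central 95% interval."""

    times: np.ndarray
    p_median: np.ndarray
    p_lo: np.ndarray
    p_hi: np.ndarray

    def __post_init__(self) -> None:
        for name in ("p_median", "p_lo", "p_hi"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != np.asarray(self.times).shape:
                raise ValueError(f"{name} must match times")
            setattr(self, name, arr)
        bad = (self.p_lo > self.p_median) | (self.p_median > self.p_hi)
        if bad.any():
            raise ValueError("quantile ordering violated")


@dataclass
class PredictiveSeries:
    """One-step-ahead samples of p at behavioral-observation times.

    Samples are drawn from the propagated (pre-update) ensemble at each time
    a behavioral response exists, so the response itself never informs the p
    used to predict it.
    """

    times: np.ndarray
    samples: np.ndarray  # (n_times, n_samples), values in (0,1)


@dataclass
class FilterResult:
    """Everything one forward pass produces."""

    curve: WakeProbabilityCurve
    predictive: PredictiveSeries
    state_quantiles: dict
    obs_mean_quantiles: dict
    ess_trace: np.ndarray
    seed: int
    n_particles: int


def weighted_quantile(
    values: np.ndarray, quantiles, weights: np.ndarray
) -> np.ndarray:
    """Weighted empirical (inverse-CDF) quantiles, no smoothing.

    Returns the smallest value whose cumulative weight reaches each requested
    quantile.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values, kind="stable")
    v = values[order]
    cw = np.cumsum(weights[order])
    cw /= cw[-1]
    qs = np.atleast_1d(np.asarray(quantiles, dtype=float))
    idx = np.searchsorted(cw, qs, side="left")
    return v[np.clip(idx, 0, v.size - 1)]


def init_particles(
    priors: PriorSpec, n_particles: int, seed_or_rng
) -> ParticleEnsemble:
    """Draw an i.i.d. prior ensemble with uniform weights."""
    if n_particles < 2:
        raise ValueError("n_particles must be >= 2")
    priors.validate()
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    states = (
        np.asarray(priors.state_mean)
        + np.column_stack([stratified_normal(rng, n_particles) for _ in range(3)])
        * np.asarray(priors.state_sd)
    )
    draws = {
        "mu0": rng.normal(*priors.mu0, n_particles),
        "mu1": np.exp(rng.normal(*priors.log_mu1, n_particles)),
        "emg_noise_sd": np.exp(rng.normal(*priors.log_emg_noise_sd, n_particles)),
        "alpha_offset": rng.normal(*priors.alpha_offset, n_particles),
        "alpha_gain": np.exp(rng.normal(*priors.log_alpha_gain, n_particles)),
        "alpha_noise_sd": np.exp(rng.normal(*priors.log_alpha_noise_sd, n_particles)),
        "dt_offset": rng.normal(*priors.dt_offset, n_particles),
        "dt_gain": np.exp(rng.normal(*priors.log_dt_gain, n_particles)),
        "dt_noise_sd": np.exp(rng.normal(*priors.log_dt_noise_sd, n_particles)),
    }
    params = np.column_stack([draws[c] for c in PARAM_COLS])
    weights = np.full(n_particles, 1.0 / n_particles)
    return ParticleEnsemble(states, params, weights, time_index=0)


def _systematic_resample(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = weights.size
    positions = (rng.uniform() + np.arange(n)) / n
    return np.searchsorted(np.cumsum(weights), positions, side="left").clip(0, n - 1)


def _sorted_systematic_resample(
    ens: ParticleEnsemble, beta: float, rng: np.random.Generator
) -> np.ndarray:
    """Systematic resampling after ordering particles along the wake state.

    Sorting makes the single systematic sweep a near-stratified draw over the
    posterior, sharply reducing resampling noise in posterior means.
    """
    order = np.argsort(
        beta * (ens.states[:, 0] + ens.states[:, 1] - ens.states[:, 2]),
        kind="stable",
    )
    return order[_systematic_resample(ens.weights[order], rng)]


def _row_loglik(ens: ParticleEnsemble, obs, beta: float) -> np.ndarray:
    """Vectorized joint log-likelihood of one observation row per particle."""
    ll = np.zeros(ens.n)
    if not np.isnan(obs.m):
        ll += loglik_emg(
            obs.m, ens.states[:, 0], ens.col("mu0"), ens.col("mu1"),
            ens.col("emg_noise_sd"),
        )
    if not np.isnan(obs.y_alpha):
        ll += loglik_eeg(
            obs.y_alpha, ens.states[:, 1], ens.col("alpha_gain"),
            ens.col("alpha_offset"), ens.col("alpha_noise_sd"),
        )
    if not np.isnan(obs.y_deltatheta):
        ll += loglik_eeg(
            obs.y_deltatheta, ens.states[:, 2], ens.col("dt_gain"),
            ens.col("dt_offset"), ens.col("dt_noise_sd"),
        )
    if not np.isnan(obs.b):
        # direct Bernoulli form: a particle whose p saturates to 0 or 1 gets
        # -inf (zero weight) rather than an exception — only when every
        # particle rules the response out does the filter raise
        p = ens.p(beta)
        with np.errstate(divide="ignore"):
            ll += np.where(obs.b >= 0.5, np.log(p), np.log1p(-p))
    return ll


def pf_step(
    ens: ParticleEnsemble,
    obs,
    rng: np.random.Generator,
    model: ModelConfig | None = None,
    ess_fraction: float = 0.5,
) -> ParticleEnsemble:
    """One propagate-weight-resample step.

    ``obs`` is a single observation row (fields ``b, m, y_alpha,
    y_deltatheta``; NaN = missing). A fully missing row leaves the weights
    untouched (propagation only). Weights are accumulated in the log domain
    with max-subtraction. Resampling (systematic, after sorting along the
    wake state) fires at the *start* of the step whenever the incoming
    effective sample size is below ``ess_fraction * N``: deferring it keeps
    the returned ensemble's weighted summaries free of resampling noise
    while leaving the filtering distribution unchanged.
    """
    model = model or ModelConfig()
    n = ens.n

    if ens.ess() < ess_fraction * n:
        idx = _sorted_systematic_resample(ens, model.beta, rng)
        ens = ParticleEnsemble(ens.states[idx], ens.params[idx],
                               np.full(n, 1.0 / n), ens.time_index,
                               ens.eve[idx])

    noise = np.column_stack([stratified_normal(rng, n) for _ in range(3)])
    states = ens.states + noise * np.asarray(model.state_walk_sds)
    if model.param_shrinkage is not None:
        # Liu-West kernel on the walk scale (log scale for positive
        # coefficients): shrink toward the weighted ensemble mean and add
        # kernel noise so the first two posterior moments are preserved
        # instead of inflating every step as a plain walk does
        a = model.param_shrinkage
        h = np.sqrt(1.0 - a * a)
        theta = ens.params.copy()
        theta[:, _POSITIVE] = np.log(theta[:, _POSITIVE])
        mean = ens.weights @ theta
        var = ens.weights @ (theta - mean) ** 2
        theta = (a * theta + (1.0 - a) * mean
                 + rng.normal(size=theta.shape) * (h * np.sqrt(var)))
        params = theta
        params[:, _POSITIVE] = np.exp(params[:, _POSITIVE])
    else:
        eps = rng.normal(size=(n, len(PARAM_COLS))) * model.param_walk_sd
        params = ens.params.copy()
        params[:, ~_POSITIVE] += eps[:, ~_POSITIVE]
        params[:, _POSITIVE] *= np.exp(eps[:, _POSITIVE])
    new = ParticleEnsemble(
        states, params, ens.weights.copy(), ens.time_index + 1, ens.eve.copy()
    )

    ll = _row_loglik(new, obs, model.beta)
    if np.any(ll != 0.0):
        logw = np.log(new.weights) + ll
        m = logw.max()
        if not np.isfinite(m):
            raise DegenerateWeightsError(
                f"all particle weights vanished at time index {new.time_index} "
                f"(obs: b={obs.b}, m={obs.m}, y_alpha={obs.y_alpha}, "
                f"y_deltatheta={obs.y_deltatheta})"
            )
        w = np.exp(logw - m)
        new.weights = w / w.sum()
    return new


_Q = (0.025, 0.5, 0.975)


def run_filter(
    grid: ObservationGrid,
    model: ModelConfig | None = None,
    filt: FilterConfig | None = None,
    seed: int = 0,
) -> FilterResult:
    """Filter an observation grid and summarize the posterior over time.

    Records, after every update, the weighted 2.5/50/97.5% quantiles of p and
    of each latent state and predicted observation mean; at each
    behavioral-observation time it first draws ``n_predictive_samples``
    equal-weight samples of p from the propagated, not-yet-updated ensemble
    (the one-step-ahead predictive distribution used for goodness-of-fit).
    """
    model = model or ModelConfig()
    filt = filt or FilterConfig()
    model.validate()
    filt.validate()
    T = len(grid)
    if T == 0:
        empty = np.empty(0)
        return FilterResult(
            WakeProbabilityCurve(empty, empty.copy(), empty.copy(), empty.copy()),
            PredictiveSeries(empty, np.empty((0, filt.n_predictive_samples))),
            {}, {}, empty, seed, filt.n_particles,
        )

    rng = np.random.default_rng(seed)
    ens = init_particles(model.priors, filt.n_particles, rng)

    pq = np.empty((T, 3))
    state_q = {k: np.empty((T, 3)) for k in ("x_m", "x_alpha", "x_deltatheta")}
    obs_q = {k: np.empty((T, 3)) for k in ("emg_mean", "alpha_mean", "dt_mean")}
    ess = np.empty(T)
    pred_times: list[float] = []
    pred_samples: list[np.ndarray] = []

    class _Row:
        __slots__ = ("b", "m", "y_alpha", "y_deltatheta")

    row = _Row()
    for t in range(T):
        row.b = grid.b[t]
        row.m = grid.m[t]
        row.y_alpha = grid.y_alpha[t]
        row.y_deltatheta = grid.y_deltatheta[t]

        if not np.isnan(row.b):
            # predictive: propagate a copy without assimilating anything,
            # using an independent stream so the main pass is unaffected
            prop_states = ens.states + np.random.default_rng(
                rng.integers(2**31)
            ).normal(size=(ens.n, 3)) * np.asarray(model.state_walk_sds)
            p_prop = expit(
                model.beta
                * (prop_states[:, 0] + prop_states[:, 1] - prop_states[:, 2])
            )
            idx = rng.choice(ens.n, size=filt.n_predictive_samples, p=ens.weights)
            pred_times.append(float(grid.times[t]))
            pred_samples.append(np.clip(p_prop[idx], 1e-12, 1 - 1e-12))

        ens = pf_step(ens, row, rng, model, filt.ess_fraction)

        w = ens.weights
        pq[t] = weighted_quantile(ens.p(model.beta), _Q, w)
        for j, k in enumerate(("x_m", "x_alpha", "x_deltatheta")):
            state_q[k][t] = weighted_quantile(ens.states[:, j], _Q, w)
        obs_q["emg_mean"][t] = weighted_quantile(
            ens.col("mu0") + ens.col("mu1") * ens.states[:, 0], _Q, w
        )
        obs_q["alpha_mean"][t] = weighted_quantile(
            ens.col("alpha_offset") + ens.col("alpha_gain") * expit(ens.states[:, 1]),
            _Q, w,
        )
        obs_q["dt_mean"][t] = weighted_quantile(
            ens.col("dt_offset") + ens.col("dt_gain") * expit(ens.states[:, 2]),
            _Q, w,
        )
        ess[t] = ens.ess()

    curve = WakeProbabilityCurve(grid.times.copy(), pq[:, 1], pq[:, 0], pq[:, 2])
    predictive = PredictiveSeries(
        np.asarray(pred_times),
        np.asarray(pred_samples).reshape(len(pred_times), -1)
        if pred_times
        else np.empty((0, filt.n_predictive_samples)),
    )
    return FilterResult(
        curve, predictive,
        {k: {"lo": v[:, 0], "median": v[:, 1], "hi": v[:, 2]}
         for k, v in state_q.items()},
        {k: {"lo": v[:, 0], "median": v[:, 1], "hi": v[:, 2]}
         for k, v in obs_q.items()},
        ess, seed, filt.n_particles,
    )


def kalman_oracle(
    grid: ObservationGrid,
    mu0: float,
    mu1: float,
    obs_sd: float,
    walk_sd: float,
    prior_mean: float,
    prior_sd: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact filtering posterior for the linear-Gaussian EMG-only submodel.

    The model is a scalar random walk ``x_t = x_{t-1} + N(0, walk_sd²)``
    observed through ``m_t = mu0 + mu1 x_t + N(0, obs_sd²)`` with fixed
    coefficients. Returns per-time posterior means and variances. Raises when
    the grid carries any non-EMG observation, because then the exact
    recursion no longer applies.
    """
    if grid.I_b.any() or grid.I_alpha.any() or grid.I_dt.any():
        raise ValueError(
            "kalman_oracle applies only to EMG-only grids "
            "(nonlinear modalities present)"
        )
    if obs_sd < 0 or walk_sd < 0 or prior_sd <= 0:
        raise ValueError("sds must be nonnegative (prior_sd > 0)")
    T = len(grid)
    means = np.empty(T)
    variances = np.empty(T)
    mean, var = prior_mean, prior_sd**2
    for t in range(T):
        var += walk_sd**2
        if not np.isnan(grid.m[t]):
            innov = grid.m[t] - (mu0 + mu1 * mean)
            s = mu1**2 * var + obs_sd**2
            if s == 0.0:
                mean = (grid.m[t] - mu0) / mu1
                var = 0.0
            else:
                gain = var * mu1 / s
                mean += gain * innov
                var *= 1.0 - gain * mu1
        means[t] = mean
        variances[t] = var
    return means, variances
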
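# Methods

## The model

The sleep onset process (SOP) is modeled as three latent activity processes
on a common discrete time grid (Δt = 0.25 s, matching the spectrogram step):
a motor process `x_m`, an alpha process `x_alpha`, and a delta-theta process
`x_deltatheta`. Each evolves as an independent Gaussian random walk,

    x_t = x_{t-1} + ε_t,   ε_t ~ N(0, σ_ε²),

expressing that physiological activity cannot jump instantaneously and that
the three systems may move on different time scales. The combined wake state
is the signed average

    x_wake = β (x_m + x_alpha − x_deltatheta),   β = 1/3,

motor and alpha activity bearing a direct relation to wakefulness and
delta-theta an inverse one, and the wake probability is its logistic image

    p = Pr(Wake) = 1 / (1 + exp(−x_wake)).

`p` doubles, by construction, as the instantaneous probability of a correct
behavioral response, which is what makes the model's output directly
interpretable against behavioral task data.

Four observation streams attach to the states, each gated by a presence
indicator so any subset may be missing at any time:

| stream | model | default coefficients |
|---|---|---|
| log EMG squeeze amplitude `m` | N(μ₀ + μ₁·x_m, σ_m²) | μ₀ = −1.5, μ₁ = 0.5, σ_m = 0.3 |
| log alpha band power `y_α` | N(offset + gain·logistic(x_alpha), σ²) | offset 0, gain 2, σ = 0.5 |
| log delta-theta band power `y_Δθ` | N(offset + gain·logistic(x_deltatheta), σ²) | offset 0, gain 2, σ = 0.5 |
| binary response `b` | Bernoulli(p) | — |

Band powers enter on the log scale: physiological spectral variability is
multiplicative, and log transformation keeps Gaussian residuals plausible.
The sigmoid's slope is fixed at 1 — a free slope is confounded with the
scale of the latent state — and its gain is constrained positive. The EMG
intercept μ₀ absorbs the baseline muscle tone that squeezes decay toward.
The joint log-likelihood at a time point is the indicator-gated sum of the
per-stream terms; a fully missing time point contributes exactly zero.

Static coefficients (μ₀, μ₁, offsets, gains, noise sds) are estimated
jointly with the states through artificial evolution: conceptually a
small-variance random walk (σ = 0.002 per step; positive-constrained
coefficients on the log scale), which leaves room for exploration of the
parameter space without allowing large drifts within a night. Inside the
filter, the default evolution kernel is Liu & West's variance-preserving
refinement of that walk — shrink each coefficient toward the weighted
ensemble mean by a = 0.995 and add kernel noise of variance
(1 − a²) × ensemble variance — because the plain walk inflates and then
impoverishes the parameter posterior over thousands of steps. In a
pinned-coefficient control experiment the plain walk's residual
coefficient error biased the saturated asleep phase low (95%-band
coverage ~0.87); the shrinkage kernel restores near-nominal coverage. The
plain walk remains available (``param_shrinkage=None``) and is what the
generative model and the public ``parameter_transition`` operation state.

## Inference

A sequential importance resampling (particle) filter carries N joint
samples of (states, coefficients); the default production ensemble is
N = 10,000. Each step propagates all particles through the two random
walks, multiplies weights by the exponentiated joint log-likelihood
(log-domain accumulation with max-subtraction), and resamples
systematically when the effective sample size falls below N/2. Resampling
is applied at the entry to the next step rather than the exit of the
current one, so every reported summary is a pure weighted estimate, free
of resampling noise. Two variance-reduction devices are standard fare from
sequential quasi-Monte Carlo and are always on:

* state propagation noise is drawn by randomized stratification (one
  uniform per 1/N stratum, inverse-CDF mapped, randomly permuted), which
  is marginally exact and sharply reduces the Monte Carlo error of
  ensemble means;
* systematic resampling is performed after sorting particles along
  `x_wake`, the one-dimensional analogue of Hilbert-ordered resampling.

Each particle's time-zero ancestor ("Eve" index) is tracked; the Monte
Carlo standard error of any posterior mean is estimated with the
ancestral-cluster (genealogy) estimator of Chan & Lai and Lee & Whiteley,
which reduces to sd/√ESS in the absence of resampling and remains
consistent through it. This estimator backs the filter-vs-Kalman
equivalence check.

The filter reports, per time point, weighted 2.5/50/97.5% quantiles
(inverse-CDF, no smoothing) of `p`, of each state, and of each stream's
predicted observation mean. At each behavioral-trial time it first records
equal-weight samples of `p` from the propagated, not-yet-updated ensemble:
the one-step-ahead predictive distribution, used by the goodness-of-fit
analysis so that a response never informs the probability used to predict
it. Filtering is forward-only; no smoother is applied.

### Process noise and priors

The filter's per-step state process noise defaults to 0.08 — deliberately
about four times the physiological walk scale the generator uses (0.02).
A random-walk filter tracking a *drifting* system must carry enough process
noise to absorb the drift; with matched noise the posterior lags the
sigmoidal descent and its credible band becomes badly overconfident. The
generous setting restores near-nominal interval coverage (~91% pooled for
the 95% band in the recovery benchmark) at a small cost in smoothness.

Coefficient priors are informative (e.g. μ₀ ~ N(−1.5, 0.25²); log-scale
sds of 0.15 for positive coefficients). This reflects a real property of
the measurement chain — amplifier gains, electrode baselines, and noise
floors are stable and approximately known within a night — and it is also
an identifiability necessity: with diffuse coefficient priors the walked
coefficients can absorb the observation trends while the states saturate
in the flat region of the sigmoid, leaving Pr(Wake) stuck. State priors
start awake-leaning (mean (2, 2, −2), sd 1), since task recordings begin
at lights-out with the subject responsive.

## Goodness of fit

Any clinical definition of a sleep-onset moment implies a stepwise response
model: accuracy 0.95 while awake, 0.05 once asleep. Four onset rules are
implemented (first N1 epoch, first N2 epoch, first of 3 consecutive NREM
epochs, first of 10), each applied to a 30-s hypnogram; the onset epoch
itself counts as asleep, and a rule that never fires leaves the subject
"awake" throughout. The total behavioral log-likelihood distribution of any
model is built by Monte Carlo (default 10,000 iterations): per iteration,
one response probability per scored trial is drawn from that model's
per-trial distribution — predictive samples for the wake model, a point
mass for step models — and Bernoulli log-likelihoods are summed. Missing
trials are excluded from every model identically. Two models are compared
through the iteration-paired difference distribution: its median, central
95% interval, and the largest central credible level at which it excludes
zero. Step models have point-mass likelihoods here, so comparison spread
comes from the wake model's predictive uncertainty; a Monte Carlo
construction giving step models their own spread would require uncertainty
on the 0.95/0.05 accuracies, which this package does not assume.

## Population spectrograms

The wake probability curve gives every spectrogram window a behavioral
coordinate. Aligned samples (posterior-median p, spectrum) are pooled
across all subjects and nights — not median-of-medians — and binned into
400 half-open Pr(Wake) bins of width 0.0025 (last bin closed); Φ(p, f) is
the per-bin median spectrum, with empty bins left missing, never
interpolated. Two groups are compared per (bin, frequency) cell by
bootstrapping the difference of group medians (default 10,000 iterations);
a cell is significant when zero falls outside the 2.5th–97.5th percentile
interval. The resampling unit is the individual aligned window; a
moving-block option (configurable block length) is provided as a guard
against temporal autocorrelation, which the plain bootstrap ignores. Each
group's resampling stream is seeded from its own bin content, making the
significance mask exactly invariant to swapping group labels.

## Preprocessing

EMG is bandpass filtered 10–70 Hz (zero-phase Butterworth, so envelope
timing is unbiased) with a ±1 Hz band-stop at the 60 Hz mains frequency.
Squeeze amplitude is the log of the mean Hilbert-envelope magnitude in a
1-s window centered on the trial's inhale apex; windows that extend past
the recording yield a missing observation rather than an error, and
amplitudes are floored at 1e-12 before the log. EEG spectrograms use 6-s
windows stepped by 0.25 s with DPSS tapers (time-bandwidth 3, 5 tapers,
eigenvalue-weighted), one-sided PSD scaling validated by a Parseval check;
occipital channels are collapsed by an elementwise median, and band powers
are bin sums over half-open intervals delta [0.5, 5), theta [5, 8),
alpha [8, 12) Hz, so shared endpoints are unambiguous and the three bands
partition their union exactly. Trial scoring marks an inhale correct when a
squeeze interval overlaps the apex ± half the local inter-inhale interval
(visual scoring has an implicit alignment tolerance; this is its explicit
analogue), incorrect when none does, and missing inside artifact
intervals. The scored window opens at the first run of ≥3 consecutive
correct responses after lights-out and closes 10 minutes after the last
correct response.

## The synthetic-data generator

The generator emulates the structure the model assumes, with known ground
truth. Latent paths follow one of four regimes: a pure random walk at the
wake level; a sigmoidal descent from the awake levels (+3, +3, −3) to the
asleep levels (−3, −3, +3) — chosen so that Pr(Wake) spans 0.95 to 0.05,
the accuracies conventionally ascribed to awake and asleep subjects — over
a configurable transition duration (default 120 s centered mid-recording);
the same descent with a ~1-minute Gaussian-bump arousal reversal; or an
alpha-dropout variant whose alpha descent leads the delta-theta rise by a
configurable lag (default 240 s). Physiological walk noise (sd 0.02 per
0.25 s) is added cumulatively to the deterministic shapes. Observations are
drawn from the model's own equations: EEG log band powers at every grid
point, log EMG amplitudes and Bernoulli responses at breath-trial times
drawn from a jittered regular process at 15 breaths/min (a resting
respiratory rate). Per-modality missingness clears indicators at random. A
hypnogram is derived by thresholding 30-s epoch means of the true p
(W ≥ 0.7 > N1 ≥ 0.3 > N2) — the thresholds stand in for a human scorer and
are scenario parameters, never hidden constants. Everything is
reproducible bit-exactly from (scenario, seed).

What the generator does *not* emulate: overlapping multitaper windows
(generated band powers are independent across grid steps, where real 6-s
windows at 0.25-s steps are strongly autocorrelated), non-Gaussian artifact
structure, REM sleep, inter-subject coefficient variability beyond the
priors, and raw-waveform EEG (band powers are generated at the model
level). Passing recovery tests therefore demonstrates correctness of the
estimator under its own assumptions, not robustness to every property of
real polysomnography.

## Benchmark problem sizes

The validation experiments (see `wakeprob/evaluation.py`, exercised by the
test suite and `scripts/acceptance.py`) use sizes chosen to make each check
statistically meaningful while keeping a full run comfortably within a
desktop budget: the Kalman cross-check runs 200 steps at N = 20,000
particles; the recovery benchmark 20 replicate 10-minute nights at
N = 4,000; goodness-of-fit nights use N = 2,000 and 10,000 Monte Carlo
iterations; the null bootstrap uses all 400 bins with 80 samples per group
per bin and 1,000 iterations (the production default is 10,000). The
production N = 10,000 remains the default for real analyses.

## Numerical choices and degenerate inputs

Weights are accumulated in log space with max-subtraction; an observation
that zeroes every particle's weight raises a diagnostic error naming the
offending observation. Weighted quantiles are inverse-CDF step quantiles
(no kernel smoothing). A particle whose p saturates to exactly 0 or 1
receives −inf log-likelihood for a contradicting response rather than an
exception. Zero-variance priors, zero walk noise, and zero generative
observation noise are all legal degenerate configurations (useful for
oracles and tests); likelihood *evaluation* still requires positive noise
sds. Empty observation grids yield empty outputs; empty Pr(Wake) bins are
flagged, not interpolated. Every randomized entry point takes an explicit
seed, echoes it, and reproduces bit-exactly from the same inputs.

## Known limitations

Filtering is forward-only, so early-time estimates reflect the prior until
data accumulates. The per-window EEG independence assumption overstates
the information content of overlapping multitaper windows on real data;
credible intervals on real recordings will be somewhat optimistic. The
instantaneous-model comparison assumes fixed 0.95/0.05 accuracies. The
model covers the wake-to-sleep descent (W/N1/N2 dynamics); REM and deeper
NREM stages are out of scope, as are additional EEG bands and coherence
observations.
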
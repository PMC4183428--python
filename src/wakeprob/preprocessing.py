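"""EMG/EEG preprocessing: filters, squeeze amplitudes, multitaper spectrograms,
band powers, and behavioral trial scoring.

These steps convert raw polysomnography channels and squeeze events into the
three observation streams the wake-probability model consumes:

* scored breath trials (correct / incorrect / missing),
* log EMG squeeze amplitudes (Hilbert envelope, 1-s window around each trial),
* occipital EEG band powers (delta 0.5-5 Hz, theta 5-8 Hz, alpha 8-12 Hz) from
  a sliding multitaper spectrogram (6-s windows, 0.25-s step, NW=3, 5 tapers),
  taken as the median across occipital channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal
from scipy.signal.windows import dpss

__all__ = [
    "RawSignal",
    "BreathTrial",
    "EMGObservation",
    "SpectrogramMatrix",
    "BandPowerSeries",
    "DEFAULT_BANDS",
    "filter_emg",
    "squeeze_amplitude",
    "multitaper_spectrogram",
    "median_channel_spectrogram",
    "band_powers",
    "score_trials",
    "scoring_window",
    "assemble_grid",
]

#: Canonical EEG bands (Hz), half-open intervals [lo, hi) so shared endpoints
#: are unambiguous: 5 Hz belongs to theta, 8 Hz to alpha.
DEFAULT_BANDS = {"delta": (0.5, 5.0), "theta": (5.0, 8.0), "alpha": (8.0, 12.0)}

#: Floor applied to squeeze amplitudes before taking the log.
AMPLITUDE_EPS = 1e-12


class InvalidConfigurationError(ValueError):
    """A processing step was configured inconsistently with its inputs."""


@dataclass
class RawSignal:
    """A uniformly sampled channel.

    Parameters
    ----------
    samples : array of float
        Signal values in recording units.
    fs : float
        Sampling rate in Hz, > 0.
    label : str
        Channel name.
    start_time : float
        Time of the first sample in seconds from lights-out.
    """

    samples: np.ndarray
    fs: float
    label: str = ""
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a nonempty 1-D sequence")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.fs

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class BreathTrial:
    """One behavioral trial: the apex of a respiratory inhale.

    ``response`` is ``"correct"``, ``"incorrect"``, or ``"missing"`` (the trial
    fell in an artifact period and carries no usable response).
    """

    time: float
    response: str

    RESPONSES = ("correct", "incorrect", "missing")

    def __post_init__(self) -> None:
        if self.response not in self.RESPONSES:
            raise ValueError(f"response must be one of {self.RESPONSES}")


@dataclass(frozen=True)
class EMGObservation:
    """Log mean Hilbert-envelope amplitude in a window centered on a trial."""

    time: float
    log_amplitude: float
    present: bool = True


@dataclass
class SpectrogramMatrix:
    """Sliding-window power spectral density: ``power[i, j]`` at
    ``times[i]`` (window centers, s) and ``freqs[j]`` (Hz), units²/Hz."""

    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != (self.times.size, self.freqs.size):
            raise ValueError("power must be (n_times, n_freqs)")
        if np.any(self.power < 0):
            raise ValueError("spectral power must be nonnegative")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0]) if self.freqs.size > 1 else 1.0


@dataclass
class BandPowerSeries:
    """Total in-band power per spectrogram window, one column per band."""

    times: np.ndarray
    delta: np.ndarray
    theta: np.ndarray
    alpha: np.ndarray
    present: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for name in ("delta", "theta", "alpha"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.times.shape:
                raise ValueError(f"{name} must match times in length")
            setattr(self, name, arr)
        if self.present is None:
            self.present = np.ones(self.times.shape, dtype=bool)
        else:
            self.present = np.asarray(self.present, dtype=bool)


def filter_emg(
    raw: RawSignal,
    low: float = 10.0,
    high: float = 70.0,
    notch: float | None = 60.0,
    notch_halfwidth: float = 1.0,
    order: int = 4,
) -> RawSignal:
    """Bandpass-filter an EMG channel and notch out the mains frequency.

    Zero-phase (forward-backward Butterworth) filtering so squeeze timing is
    preserved; the notch is a narrow band-stop of half-width
    ``notch_halfwidth`` Hz. Defaults follow the standard 10-70 Hz EMG passband
    with a 60 Hz mains notch.
    """
    nyq = raw.fs / 2.0
    if not (0 < low < high):
        raise InvalidConfigurationError(f"need 0 < low < high, got ({low}, {high})")
    if high >= nyq:
        raise InvalidConfigurationError(
            f"sampling rate {raw.fs} Hz too low for passband edge {high} Hz"
        )
    sos = signal.butter(order, [low / nyq, high / nyq], btype="bandpass", output="sos")
    out = signal.sosfiltfilt(sos, raw.samples)
    if notch is not None and low < notch < high:
        sos_n = signal.butter(
            order,
            [(notch - notch_halfwidth) / nyq, (notch + notch_halfwidth) / nyq],
            btype="bandstop",
            output="sos",
        )
        out = signal.sosfiltfilt(sos_n, out)
    return RawSignal(out, raw.fs, raw.label, raw.start_time)


def squeeze_amplitude(
    filtered_emg: RawSignal, trial_time: float, window: float = 1.0
) -> EMGObservation:
    """Log of the mean Hilbert-envelope amplitude in a ``window``-s window
    centered on ``trial_time``.

    Returns a missing observation (``present=False``) when the window extends
    beyond the recording, rather than raising: a trial near an edge is a data
    problem, not a caller error. Amplitudes are floored at a tiny positive
    epsilon before the log so the result is always finite.
    """
    if window <= 0:
        raise InvalidConfigurationError("window must be > 0")
    t0 = trial_time - window / 2.0
    t1 = trial_time + window / 2.0
    rec_start = filtered_emg.start_time
    rec_end = rec_start + filtered_emg.duration
    if t0 < rec_start or t1 > rec_end:
        return EMGObservation(trial_time, np.nan, present=False)
    i0 = int(round((t0 - rec_start) * filtered_emg.fs))
    i1 = int(round((t1 - rec_start) * filtered_emg.fs))
    i1 = max(i1, i0 + 1)
    envelope = np.abs(signal.hilbert(filtered_emg.samples))
    amp = float(np.mean(envelope[i0:i1]))
    return EMGObservation(trial_time, float(np.log(max(amp, AMPLITUDE_EPS))), True)


def multitaper_spectrogram(
    raw: RawSignal,
    win: float = 6.0,
    step: float = 0.25,
    time_bandwidth: float = 3.0,
    n_tapers: int = 5,
) -> SpectrogramMatrix:
    """Sliding-window multitaper power spectral density.

    Each window of ``win`` s is tapered by ``n_tapers`` DPSS tapers
    (time-bandwidth product ``time_bandwidth``) and the eigenvalue-weighted
    average of the tapered periodograms is taken as the PSD estimate for that
    window. Window centers advance by ``step`` s. One-sided density scaling:
    integrating the PSD over frequency recovers the windowed signal's variance
    (Parseval), which is how the estimate is validated.
    """
    if step <= 0:
        raise InvalidConfigurationError("step must be > 0")
    nwin = int(round(win * raw.fs))
    if nwin < 2 * n_tapers:
        raise InvalidConfigurationError(
            f"window of {nwin} samples too short for {n_tapers} tapers"
        )
    x = raw.samples
    if nwin > x.size:
        # degenerate: single window covering the whole (short) signal
        nwin = x.size
    nstep = max(1, int(round(step * raw.fs)))
    starts = np.arange(0, x.size - nwin + 1, nstep)
    tapers, eigvals = dpss(nwin, time_bandwidth, n_tapers, return_ratios=True)
    freqs = np.fft.rfftfreq(nwin, d=1.0 / raw.fs)
    # windows x tapers x samples
    segs = np.lib.stride_tricks.sliding_window_view(x, nwin)[starts]
    tapered = segs[:, None, :] * tapers[None, :, :]
    spec = np.abs(np.fft.rfft(tapered, axis=-1)) ** 2
    # one-sided PSD: double all bins except DC (and Nyquist when nwin even)
    scale = np.full(freqs.size, 2.0)
    scale[0] = 1.0
    if nwin % 2 == 0:
        scale[-1] = 1.0
    psd = spec * scale[None, None, :] / raw.fs
    w = eigvals / eigvals.sum()
    power = np.einsum("wts,t->ws", psd, w)
    times = raw.start_time + (starts + (nwin - 1) / 2.0) / raw.fs
    return SpectrogramMatrix(times, freqs, power)


def median_channel_spectrogram(specs: Sequence[SpectrogramMatrix]) -> SpectrogramMatrix:
    """Elementwise median across channel spectrograms sharing one grid.

    Used to collapse the occipital channel set into a single robust
    spectrogram before band powers are computed.
    """
    if not specs:
        raise ValueError("need at least one spectrogram")
    ref = specs[0]
    for s in specs[1:]:
        if not (
            np.array_equal(s.times, ref.times) and np.array_equal(s.freqs, ref.freqs)
        ):
            raise ValueError("spectrograms must share time and frequency grids")
    stacked = np.stack([s.power for s in specs])
    return SpectrogramMatrix(ref.times, ref.freqs, np.median(stacked, axis=0))


def band_powers(
    spec: SpectrogramMatrix,
    bands: dict[str, tuple[float, float]] | None = None,
) -> BandPowerSeries:
    """Total power per window in each named band.

    Bands are half-open ``[lo, hi)`` intervals; power is the sum of in-band PSD
    bins times the bin width, so disjoint bands covering a range partition its
    total power exactly.
    """
    bands = dict(DEFAULT_BANDS) if bands is None else bands
    out: dict[str, np.ndarray] = {}
    for name, (lo, hi) in bands.items():
        mask = (spec.freqs >= lo) & (spec.freqs < hi)
        if not mask.any():
            raise InvalidConfigurationError(
                f"band {name}=[{lo},{hi}) contains no frequency bins"
            )
        out[name] = spec.power[:, mask].sum(axis=1) * spec.df
    missing = {"delta", "theta", "alpha"} - set(out)
    if missing:
        raise InvalidConfigurationError(f"bands must include {sorted(missing)}")
    return BandPowerSeries(
        spec.times.copy(), out["delta"], out["theta"], out["alpha"],
        np.ones(spec.times.size, dtype=bool),
    )


def _overlaps(a0: float, a1: float, b0: float, b1: float) -> bool:
    return a0 < b1 and b0 < a1


def score_trials(
    inhale_times: Sequence[float],
    squeeze_intervals: Sequence[tuple[float, float]],
    artifact_intervals: Sequence[tuple[float, float]] = (),
    half_breath: float | None = None,
) -> list[BreathTrial]:
    """Score one trial per inhale apex.

    A trial is *correct* when a squeeze interval overlaps the apex's alignment
    window ``[apex - h, apex + h]``, *incorrect* when no squeeze does, and
    *missing* when the apex falls inside an artifact interval. The alignment
    half-width ``h`` defaults to half the local inter-inhale interval
    (``half_breath`` overrides it), mirroring the tolerance implicit in visual
    scoring of a squeeze "during" an inhale.
    """
    inhale_times = np.asarray(list(inhale_times), dtype=float)
    if inhale_times.size and np.any(np.diff(inhale_times) <= 0):
        raise ValueError("inhale_times must be strictly increasing")
    for s, e in list(squeeze_intervals) + list(artifact_intervals):
        if not s < e:
            raise ValueError(f"malformed interval ({s}, {e})")
    trials: list[BreathTrial] = []
    for i, apex in enumerate(inhale_times):
        if half_breath is not None:
            h = half_breath
        else:
            gaps = []
            if i > 0:
                gaps.append(apex - inhale_times[i - 1])
            if i < inhale_times.size - 1:
                gaps.append(inhale_times[i + 1] - apex)
            h = min(gaps) / 2.0 if gaps else 2.0
        if any(a0 <= apex <= a1 for a0, a1 in artifact_intervals):
            trials.append(BreathTrial(float(apex), "missing"))
        elif any(_overlaps(s, e, apex - h, apex + h) for s, e in squeeze_intervals):
            trials.append(BreathTrial(float(apex), "correct"))
        else:
            trials.append(BreathTrial(float(apex), "incorrect"))
    return trials


def scoring_window(
    trials: Sequence[BreathTrial],
    lights_out: float = 0.0,
    min_run: int = 3,
    stop_after: float = 600.0,
) -> list[BreathTrial]:
    """Trim a trial series to the scored task window.

    The window opens at the first trial of the first run of at least
    ``min_run`` consecutive correct responses after ``lights_out``, and closes
    ``stop_after`` seconds (default 10 minutes) after the last correct
    response. Trials are never reordered or relabeled, only trimmed. Returns
    an empty list (with a warning) when no qualifying run exists.
    """
    trials = [t for t in trials if t.time >= lights_out]
    if sorted(t.time for t in trials) != [t.time for t in trials]:
        raise ValueError("trials must be sorted by time")
    start = None
    run = 0
    for i, t in enumerate(trials):
        run = run + 1 if t.response == "correct" else 0
        if run == min_run:
            start = i - min_run + 1
            break
    if start is None:
        warnings.warn(
            f"no run of {min_run} consecutive correct responses; empty scoring window",
            stacklevel=2,
        )
        return []
    kept = trials[start:]
    last_correct = max(t.time for t in kept if t.response == "correct")
    return [t for t in kept if t.time <= last_correct + stop_after]


def assemble_grid(
    band_power: BandPowerSeries,
    emg: Sequence[EMGObservation],
    trials: Sequence[BreathTrial],
    dt: float = 0.25,
    log_eps: float = AMPLITUDE_EPS,
):
    """Collect the three observation streams onto a common model grid.

    The grid spacing ``dt`` defaults to the spectrogram step (0.25 s). EEG band
    powers are log-transformed here (delta-theta as the log of the summed
    delta and theta power); EMG and behavioral observations are assigned to
    the nearest grid time. Returns an :class:`~wakeprob.model.ObservationGrid`.
    """
    from .model import ObservationGrid

    t0 = float(band_power.times.min())
    t1 = float(band_power.times.max())
    times = t0 + dt * np.arange(int(round((t1 - t0) / dt)) + 1)
    n = times.size

    y_alpha = np.full(n, np.nan)
    y_dt = np.full(n, np.nan)
    idx = np.clip(np.round((band_power.times - t0) / dt).astype(int), 0, n - 1)
    ok = band_power.present
    y_alpha[idx[ok]] = np.log(np.maximum(band_power.alpha[ok], log_eps))
    y_dt[idx[ok]] = np.log(
        np.maximum(band_power.delta[ok] + band_power.theta[ok], log_eps)
    )

    m = np.full(n, np.nan)
    for obs in emg:
        if obs.present and t0 - dt / 2 <= obs.time <= t1 + dt / 2:
            m[int(np.clip(round((obs.time - t0) / dt), 0, n - 1))] = obs.log_amplitude

    b = np.full(n, np.nan)
    for tr in trials:
        if tr.response == "missing" or not (t0 - dt / 2 <= tr.time <= t1 + dt / 2):
            continue
        b[int(np.clip(round((tr.time - t0) / dt), 0, n - 1))] = (
            1.0 if tr.response == "correct" else 0.0
        )

    return ObservationGrid(times=times, b=b, m=m, y_alpha=y_alpha, y_deltatheta=y_dt)
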
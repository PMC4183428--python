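"""Readers and writers for the pipeline's tabular formats.

CSV is the canonical interchange format; EDF is supported read-only for raw
signals (via MNE). Missing values are encoded as ``NA`` and presence
indicators are always derived from the data, never stored redundantly.

Schemas
-------
signal CSV        : ``time_s,value`` (uniform sampling; fs declared by caller
                    or inferred from the time column)
trials CSV        : ``time_s,response`` with response in {1, 0, NA}
band-power CSV    : ``time_s,delta,theta,alpha,present``
curve CSV         : ``time_s,p_lo,p_median,p_hi``
hypnogram CSV     : ``epoch_index,stage`` with stage in {W,N1,N2,N3,R}
artifact CSV      : ``start_s,end_s``
predictive CSV    : ``time_s,sample_0,...,sample_{k-1}``
"""

from __future__ import annotations

import json
import sys
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .gof import STAGES, Hypnogram
from .inference import PredictiveSeries, WakeProbabilityCurve
from .preprocessing import (
    BandPowerSeries,
    BreathTrial,
    EMGObservation,
    RawSignal,
    SpectrogramMatrix,
)

__all__ = [
    "read_signals",
    "read_trials",
    "write_trials",
    "read_emg",
    "write_emg",
    "read_spectrogram",
    "write_spectrogram",
    "read_band_powers",
    "write_band_powers",
    "read_curve",
    "write_curve",
    "read_hypnogram",
    "write_hypnogram",
    "read_intervals",
    "read_predictive",
    "write_predictive",
    "write_run_log",
]


class SchemaError(ValueError):
    """A table violated its documented schema."""


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_signals(
    path: str | Path,
    channel_labels: Sequence[str] | None = None,
    fs: float | None = None,
) -> list[RawSignal]:
    """Read raw channels from an EDF file or a two-column signal CSV.

    For CSV, ``fs`` may be declared explicitly or is inferred from the time
    column. For EDF, ``channel_labels`` selects channels; requesting an
    absent channel raises an error naming the available labels.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path, channel_labels)
    df = pd.read_csv(path)
    _require_columns(df, ["time_s", "value"], path)
    t = df["time_s"].to_numpy(dtype=float)
    if fs is None:
        if t.size < 2:
            raise SchemaError(f"{path}: cannot infer fs from a single sample")
        fs = 1.0 / float(np.median(np.diff(t)))
    label = channel_labels[0] if channel_labels else path.stem
    return [RawSignal(df["value"].to_numpy(dtype=float), fs=fs, label=label,
                      start_time=float(t[0]))]


def _read_edf(path: Path, channel_labels: Sequence[str] | None) -> list[RawSignal]:
    import mne

    # mne returns data in SI units (e.g. volts for channels recorded in uV)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    available = list(raw.ch_names)
    labels = list(channel_labels) if channel_labels else available
    unknown = [l for l in labels if l not in available]
    if unknown:
        raise KeyError(
            f"channel(s) {unknown} not in {path.name}; available: {available}"
        )
    out = []
    for label in labels:
        data = raw.get_data(picks=[label])[0]
        out.append(RawSignal(data, fs=float(raw.info["sfreq"]), label=label,
                             start_time=float(raw.first_time)))
    return out


_RESPONSE_TO_CODE = {"correct": 1, "incorrect": 0}


def read_trials(path: str | Path) -> list[BreathTrial]:
    df = pd.read_csv(path)
    _require_columns(df, ["time_s", "response"], path)
    trials = []
    for i, row in df.iterrows():
        val = row["response"]
        if pd.isna(val):
            resp = "missing"
        elif float(val) in (0.0, 1.0):
            resp = "correct" if float(val) == 1.0 else "incorrect"
        else:
            raise SchemaError(
                f"{path}: row {i}: response must be 1, 0 or NA, got {val!r}"
            )
        trials.append(BreathTrial(float(row["time_s"]), resp))
    return trials


def write_trials(trials: Sequence[BreathTrial], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_s": [t.time for t in trials],
            "response": [_RESPONSE_TO_CODE.get(t.response, pd.NA)
                         for t in trials],
        }
    )
    df.to_csv(path, index=False, na_rep="NA")


def read_emg(path: str | Path) -> list[EMGObservation]:
    """EMG observation CSV: ``time_s,log_amplitude`` with NA for missing."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["time_s", "log_amplitude"], path)
    return [
        EMGObservation(float(r["time_s"]),
                       np.nan if pd.isna(r["log_amplitude"])
                       else float(r["log_amplitude"]),
                       present=not pd.isna(r["log_amplitude"]))
        for _, r in df.iterrows()
    ]


def write_emg(obs: Sequence[EMGObservation], path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": [o.time for o in obs],
         "log_amplitude": [o.log_amplitude if o.present else pd.NA
                           for o in obs]}
    ).to_csv(path, index=False, na_rep="NA", float_format="%.17g")


def read_spectrogram(path: str | Path) -> SpectrogramMatrix:
    """Long-format spectrogram CSV: ``time_s,freq_hz,power``."""
    df = pd.read_csv(path)
    _require_columns(df, ["time_s", "freq_hz", "power"], path)
    times = np.unique(df["time_s"].to_numpy(float))
    freqs = np.unique(df["freq_hz"].to_numpy(float))
    pivot = df.pivot(index="time_s", columns="freq_hz", values="power")
    return SpectrogramMatrix(times, freqs, pivot.to_numpy(float))


def write_spectrogram(spec: SpectrogramMatrix, path: str | Path) -> None:
    t, f = np.meshgrid(spec.times, spec.freqs, indexing="ij")
    pd.DataFrame(
        {"time_s": t.ravel(), "freq_hz": f.ravel(),
         "power": spec.power.ravel()}
    ).to_csv(path, index=False, float_format="%.17g")


def read_band_powers(path: str | Path) -> BandPowerSeries:
    df = pd.read_csv(path)
    _require_columns(df, ["time_s", "delta", "theta", "alpha", "present"], path)
    return BandPowerSeries(
        df["time_s"].to_numpy(float),
        df["delta"].to_numpy(float),
        df["theta"].to_numpy(float),
        df["alpha"].to_numpy(float),
        df["present"].to_numpy(bool),
    )


def write_band_powers(bp: BandPowerSeries, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": bp.times, "delta": bp.delta, "theta": bp.theta,
         "alpha": bp.alpha, "present": bp.present.astype(int)}
    ).to_csv(path, index=False)


def read_curve(path: str | Path) -> WakeProbabilityCurve:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["time_s", "p_lo", "p_median", "p_hi"], path)
    return WakeProbabilityCurve(
        df["time_s"].to_numpy(float),
        df["p_median"].to_numpy(float),
        df["p_lo"].to_numpy(float),
        df["p_hi"].to_numpy(float),
    )


def write_curve(curve: WakeProbabilityCurve, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": curve.times, "p_lo": curve.p_lo,
         "p_median": curve.p_median, "p_hi": curve.p_hi}
    ).to_csv(path, index=False, float_format="%.17g")


def read_hypnogram(path: str | Path, epoch_length: float = 30.0) -> Hypnogram:
    df = pd.read_csv(path)
    _require_columns(df, ["epoch_index", "stage"], path)
    stages = []
    for i, row in df.iterrows():
        s = str(row["stage"]).strip()
        s = "R" if s == "REM" else s
        if s not in STAGES:
            raise SchemaError(
                f"{path}: row {i}: stage must be one of {STAGES}, got {s!r}"
            )
        stages.append(s)
    return Hypnogram(stages, epoch_length=epoch_length)


def write_hypnogram(h: Hypnogram, path: str | Path) -> None:
    pd.DataFrame(
        {"epoch_index": range(len(h.epochs)), "stage": list(h.epochs)}
    ).to_csv(path, index=False)


def read_intervals(path: str | Path) -> list[tuple[float, float]]:
    df = pd.read_csv(path)
    _require_columns(df, ["start_s", "end_s"], path)
    return [(float(r["start_s"]), float(r["end_s"])) for _, r in df.iterrows()]


def read_predictive(path: str | Path) -> PredictiveSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["time_s"], path)
    sample_cols = [c for c in df.columns if c.startswith("sample_")]
    if not sample_cols:
        raise SchemaError(f"{path}: no sample_* columns")
    return PredictiveSeries(df["time_s"].to_numpy(float),
                            df[sample_cols].to_numpy(float))


def write_predictive(pred: PredictiveSeries, path: str | Path) -> None:
    cols = {"time_s": pred.times}
    for k in range(pred.samples.shape[1]):
        cols[f"sample_{k}"] = pred.samples[:, k]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def write_run_log(
    out_dir: str | Path, command: str, seed: int | None,
    inputs: dict, extras: dict | None = None,
) -> Path:
    """Write a JSON run log naming inputs, versions, and the seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    import wakeprob

    log = {
        "command": command,
        "seed": seed,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "versions": {
            "wakeprob": wakeprob.__version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    if extras:
        log.update(extras)
    path = out_dir / "run_log.json"
    path.write_text(json.dumps(log, indent=2))
    return path
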
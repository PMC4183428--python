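"""SOP population spectrograms and bootstrap group comparison.

The wake probability curve gives every spectrogram window a behavioral
coordinate: instead of aligning subjects in time (where sleep-onset dynamics
differ), spectra are pooled by Pr(Wake). The population spectrogram
Phi(p, f) is the median spectral power over all subjects and nights whose
curve value falls in each Pr(Wake) bin (default width 0.0025, 400 bins over
[0, 1]). Two populations are compared per (bin, frequency) cell with a
bootstrap of the difference of group medians; a cell is significant when
zero falls outside the 2.5th-97.5th percentile interval of the difference
distribution (default 10,000 iterations).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .inference import WakeProbabilityCurve
from .preprocessing import SpectrogramMatrix

__all__ = [
    "AlignedSpectralSample",
    "PopulationSpectrogram",
    "BootstrapComparison",
    "align_spectra",
    "build_population_spectrogram",
    "bootstrap_compare",
]

DEFAULT_BIN_WIDTH = 0.0025


@dataclass
class AlignedSpectralSample:
    """One spectrogram window tagged with its wake probability."""

    subject: str
    p_value: float
    spectrum: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")
        self.spectrum = np.asarray(self.spectrum, dtype=float)
        if np.any(self.spectrum < 0):
            raise ValueError("spectral power must be nonnegative")


@dataclass
class PopulationSpectrogram:
    """Median power by (Pr(Wake) bin, frequency); NaN marks empty bins."""

    bin_edges: np.ndarray
    freqs: np.ndarray
    phi: np.ndarray
    counts: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class BootstrapComparison:
    """Per-(bin, frequency) difference of group medians with significance."""

    bin_edges: np.ndarray
    freqs: np.ndarray
    difference: np.ndarray          # observed median_A - median_B
    lo: np.ndarray                  # 2.5th percentile of bootstrap differences
    hi: np.ndarray                  # 97.5th percentile
    significant: np.ndarray         # zero outside [lo, hi]
    comparable: np.ndarray          # both groups populated
    n_iterations: int


def align_spectra(
    spec: SpectrogramMatrix,
    curve: WakeProbabilityCurve,
    subject_id: str = "",
) -> list[AlignedSpectralSample]:
    """Tag each spectrogram window with the curve's posterior-median p.

    A window is matched to the nearest curve time; windows with no curve
    point within half the curve's grid spacing are dropped. The posterior
    median is used as the binning summary because it is the curve's central
    displayed statistic.
    """
    if curve.times.size == 0 or spec.times.size == 0:
        warnings.warn("no temporal overlap between spectrogram and curve",
                      stacklevel=2)
        return []
    dt = (float(np.median(np.diff(curve.times)))
          if curve.times.size > 1 else np.inf)
    idx = np.searchsorted(curve.times, spec.times)
    idx = np.clip(idx, 0, curve.times.size - 1)
    left = np.clip(idx - 1, 0, curve.times.size - 1)
    use_left = (np.abs(curve.times[left] - spec.times)
                < np.abs(curve.times[idx] - spec.times))
    idx = np.where(use_left, left, idx)
    dist = np.abs(curve.times[idx] - spec.times)
    keep = dist <= dt / 2.0
    if not keep.any():
        warnings.warn("no temporal overlap between spectrogram and curve",
                      stacklevel=2)
        return []
    return [
        AlignedSpectralSample(subject_id,
                              float(np.clip(curve.p_median[idx[i]], 0.0, 1.0)),
                              spec.power[i])
        for i in np.nonzero(keep)[0]
    ]


def _bin_edges(bin_width: float) -> np.ndarray:
    if not 0 < bin_width <= 1:
        raise ValueError("bin_width must be in (0, 1]")
    n = int(np.ceil(round(1.0 / bin_width, 9)))
    edges = np.minimum(bin_width * np.arange(n + 1), 1.0)
    return edges


def _bin_index(p: np.ndarray, edges: np.ndarray) -> np.ndarray:
    # half-open bins [lo, hi), last bin closed at 1
    idx = np.searchsorted(edges, p, side="right") - 1
    return np.clip(idx, 0, edges.size - 2)


def build_population_spectrogram(
    samples: Sequence[AlignedSpectralSample],
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> PopulationSpectrogram:
    """Median spectrum per Pr(Wake) bin, pooled over all subjects and nights.

    Bins are half-open ``[p, p+w)`` with the last bin closed, so every sample
    lands in exactly one bin. Empty bins are NaN, never interpolated.
    """
    if not samples:
        raise ValueError("samples must be nonempty")
    edges = _bin_edges(bin_width)
    freqs = np.arange(samples[0].spectrum.size, dtype=float)
    n_bins = edges.size - 1
    p_vals = np.array([s.p_value for s in samples])
    spectra = np.stack([s.spectrum for s in samples])
    idx = _bin_index(p_vals, edges)
    phi = np.full((n_bins, spectra.shape[1]), np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in np.unique(idx):
        members = spectra[idx == b]
        counts[b] = members.shape[0]
        phi[b] = np.median(members, axis=0)
    return PopulationSpectrogram(edges, freqs, phi, counts)


def bootstrap_compare(
    group_a: Sequence[AlignedSpectralSample],
    group_b: Sequence[AlignedSpectralSample],
    n_iterations: int = 10_000,
    seed: int = 0,
    bin_width: float = DEFAULT_BIN_WIDTH,
    block_length: int = 1,
) -> BootstrapComparison:
    """Bootstrap the difference of group medians per (bin, frequency) cell.

    Within each populated bin, each group's samples are resampled with
    replacement ``n_iterations`` times and the difference of medians is
    recorded; a cell is significant when zero lies outside the 2.5th-97.5th
    percentile interval. ``block_length > 1`` resamples moving blocks of
    consecutive samples instead of single windows, as a guard against
    temporal autocorrelation. Bins empty in either group are flagged not
    comparable (NaN everywhere, ``comparable=False``).

    Each group's resampling stream within a bin is seeded from (seed, bin,
    content of that group's bin samples), so swapping the group labels flips
    the sign of every difference but changes nothing else — the significance
    mask is exactly label-order invariant.
    """
    if n_iterations < 100:
        raise ValueError("n_iterations must be >= 100")
    if block_length < 1:
        raise ValueError("block_length must be >= 1")
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    edges = _bin_edges(bin_width)
    n_bins = edges.size - 1
    n_freq = group_a[0].spectrum.size

    def _by_bin(samples):
        p = np.array([s.p_value for s in samples])
        spectra = np.stack([s.spectrum for s in samples])
        idx = _bin_index(p, edges)
        return {b: spectra[idx == b] for b in np.unique(idx)}

    binned_a = _by_bin(group_a)
    binned_b = _by_bin(group_b)

    diff = np.full((n_bins, n_freq), np.nan)
    lo = np.full((n_bins, n_freq), np.nan)
    hi = np.full((n_bins, n_freq), np.nan)
    significant = np.zeros((n_bins, n_freq), dtype=bool)
    comparable = np.zeros(n_bins, dtype=bool)

    def _group_rng(b, samples):
        content = zlib.crc32(np.ascontiguousarray(samples).tobytes())
        return np.random.default_rng([seed, int(b), content])

    for b in sorted(set(binned_a) & set(binned_b)):
        a, bb = binned_a[b], binned_b[b]
        comparable[b] = True
        diff[b] = np.median(a, axis=0) - np.median(bb, axis=0)
        boot_a = _resample_medians(a, n_iterations, block_length,
                                   _group_rng(b, a))
        boot_b = _resample_medians(bb, n_iterations, block_length,
                                   _group_rng(b, bb))
        d = boot_a - boot_b
        lo[b] = np.percentile(d, 2.5, axis=0)
        hi[b] = np.percentile(d, 97.5, axis=0)
        significant[b] = (0.0 < lo[b]) | (0.0 > hi[b])

    freqs = np.arange(n_freq, dtype=float)
    return BootstrapComparison(edges, freqs, diff, lo, hi, significant,
                               comparable, n_iterations)


def _resample_medians(
    spectra: np.ndarray, n_iterations: int, block_length: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bootstrap medians of one group's spectra: (n_iterations, n_freq)."""
    n = spectra.shape[0]
    if block_length <= 1 or block_length >= n:
        idx = rng.integers(0, n, size=(n_iterations, n))
    else:
        n_blocks = int(np.ceil(n / block_length))
        starts = rng.integers(0, n - block_length + 1,
                              size=(n_iterations, n_blocks))
        idx = (starts[:, :, None] + np.arange(block_length)[None, None, :])
        idx = idx.reshape(n_iterations, -1)[:, :n]
    return np.median(spectra[idx], axis=1)
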
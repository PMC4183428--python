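"""From raw signals to model observations.

Builds a synthetic occipital EEG trace (an alpha tone fading into a delta
rise) and an EMG trace with discrete squeezes, then runs the full
preprocessing chain: bandpass + notch filtering, Hilbert squeeze
amplitudes, the multitaper spectrogram, median across channels, band
powers, and breath-trial scoring with the task's start/stop rules.
"""

import numpy as np

import wakeprob as wp

fs = 200.0
t = np.arange(int(120 * fs)) / fs
fade = 1.0 / (1.0 + np.exp((t - 60.0) / 8.0))          # alpha fades at ~60 s
rng = np.random.default_rng(0)
eeg = (fade * np.sin(2 * np.pi * 10.0 * t)             # 10 Hz alpha
       + (1 - fade) * 1.5 * np.sin(2 * np.pi * 2.0 * t)  # 2 Hz delta
       + 0.3 * rng.normal(size=t.size))
channels = [wp.RawSignal(eeg + 0.05 * rng.normal(size=t.size), fs,
                         label=f"Occ{i}") for i in range(8)]

specs = [wp.multitaper_spectrogram(ch) for ch in channels]
median_spec = wp.median_channel_spectrogram(specs)
bp = wp.band_powers(median_spec)
i_early = int(np.argmin(np.abs(bp.times - 20.0)))
i_late = int(np.argmin(np.abs(bp.times - 100.0)))
print(f"alpha power at t=20s: {bp.alpha[i_early]:8.2f}   "
      f"t=100s: {bp.alpha[i_late]:8.2f}")
print(f"delta power at t=20s: {bp.delta[i_early]:8.2f}   "
      f"t=100s: {bp.delta[i_late]:8.2f}")

# EMG: 60 Hz mains hum plus 0.4-s squeeze bursts every 4 s, fading out
emg_carrier = np.sin(2 * np.pi * 35.0 * t)
squeezes = np.zeros_like(t)
inhales = np.arange(4.0, 110.0, 4.0)
for k, apex in enumerate(inhales):
    if k > 20:                                # squeezes stop after ~84 s
        break
    mask = np.abs(t - apex) < 0.2
    squeezes[mask] = np.exp(-k / 10.0)        # amplitude decays as sleep nears
raw_emg = wp.RawSignal(squeezes * emg_carrier
                       + 0.5 * np.sin(2 * np.pi * 60.0 * t)
                       + 0.02 * rng.normal(size=t.size), fs, label="FDP")
filtered = wp.filter_emg(raw_emg)              # 10-70 Hz, 60 Hz notch

squeeze_intervals = [(a - 0.2, a + 0.2) for a in inhales[:21]]
trials = wp.score_trials(inhales, squeeze_intervals)
window = wp.scoring_window(trials)
print(f"\nscored {len(trials)} trials, task window keeps {len(window)} "
      f"(stops 10 min after the last correct response)")

for apex in (8.0, 40.0, 80.0):
    obs = wp.squeeze_amplitude(filtered, apex)
    print(f"  squeeze log-amplitude at t={apex:4.0f}s: {obs.log_amplitude:6.2f}")

# Alpha dominates early and delta late; squeeze amplitudes decay across the
# descent - exactly the observation streams the wake model consumes.
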
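# tonemg

Automatic analysis of Mandarin four-tone F0 contours and laryngeal-EMG
interference patterns for unilateral vocal fold paralysis (UVFP) cohorts.

Injury to the external branch of the superior laryngeal nerve impairs the
cricothyroid (CT) muscle, the main vocal-fold tension controller, and with it
the ability to modulate pitch. In a tonal language such as Mandarin — where
the four lexical tones (level, high-rising, dipping, high-falling) are
distinguished by pitch trajectories — this deficit is directly measurable in
the fundamental-frequency (F0) contour of sustained phonation. `tonemg`
implements the full measurement chain for researchers and voice clinicians
comparing CT-involved (CT+) and CT-spared (CT−) patient groups:

* **Acoustic tone analysis** — RMS energy track and threshold detection of
  voice onset/offset; F0 tracking every 5 ms by short-time Fourier analysis
  with harmonic-series scoring (F0 = lowest frequency of the
  highest-energy harmonic series, parabolic peak interpolation); the tone
  feature set ΔF0<sub>ON-OFF</sub>, ΔF0<sub>ON-MIN</sub>,
  ΔF0<sub>MIN-OFF</sub>, their slopes ΔF0/ΔT, the phonation duration ΔT,
  and the maximal F0 drop per 5 ms; averaging over three repeated trials;
  group mean ± SEM contours on normalized time.
* **Turns analysis of laryngeal EMG** — a turn is a polarity reversal with
  an amplitude excursion ≥ 100 µV on both sides (noise-peak exclusion);
  raw traces are binned into non-overlapping 50 ms epochs, and the peak
  turn frequency (highest epoch turn count ÷ epoch duration) indexes
  muscle activation per tone.
* **Group statistics** — Student's t (pooled, Welch optional), chi-squared
  for nominal demographics, pooled-SD Cohen's *d*
  (*d* = |m₂ − m₁| / s<sub>p</sub>,
  s<sub>p</sub>² = ((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2)), and test-retest
  reliability via the intraclass correlation coefficient (ICC(A,1), two-way
  absolute agreement) and cross-trial SD.
* **Synthetic cohorts** — because clinical recordings cannot be
  redistributed, a generator produces harmonic voice signals carrying known
  tone contours, zig-zag EMG patterns with a known qualifying-turn rate, and
  whole 17-vs-71 cohorts whose group statistics emulate the reference UVFP
  study, so every stage is testable against ground truth.

## Worked example

```python
from tonemg import (ContourSpec, make_contour, synthesize_voice,
                    analyze_recording, synthesize_emg,
                    epoch_turn_frequencies, cohens_d)

# a high-rising tone-2 utterance: 204 -> 244 Hz over 0.84 s
spec = ContourSpec(tone=2, f0_onset=204.0, f0_offset=244.0, duration=0.84)
rec, truth = synthesize_voice(make_contour(spec), fs=16000.0,
                              noise_rms=0.002, seed=1, tone=2)
bounds, track, feats = analyze_recording(rec)
print(f"onset={bounds.onset:.3f}s offset={bounds.offset:.3f}s")
print(f"delta={feats.delta_on_off:.1f} Hz  slope={feats.slope_on_off:.1f} Hz/s")

emg, _ = synthesize_emg(duration=0.8, turn_rate=650.0, seed=1)
print(f"peak turn frequency = {epoch_turn_frequencies(emg).peak_turn_frequency} Hz")

d = cohens_d(442.4, 285.0, 17, 730.6, 231.6, 71)   # tone-1 peak turn freq
print(f"Cohen's d = {d.d:.2f}")
```

prints

```
onset=0.295s offset=1.145s
delta=38.6 Hz  slope=45.9 Hz/s
peak turn frequency = 660.0 Hz
Cohen's d = 1.19
```

The detected onset is within one 5 ms hop of the constructed 0.3 s lead
silence; the recovered tone-2 rise (38.6 Hz) is within two FFT-bin widths of
the constructed 40 Hz; the EMG peak turn frequency quantizes the 650
turns/s construction onto the 20 Hz grid of 50 ms epochs; and the effect
size recomputes the published group difference from its summary statistics.

A full synthetic cohort plus analysis is available from the command line:

```
tonemg demo out/           # small cohort, full pipeline, invariant checks
tonemg synth data/ --n-ct-pos 17 --n-ct-neg 71 --seed 1
tonemg compare data/ results/
```

## Layout

```
src/tonemg/
  synth.py      synthetic contours, voices, EMG, cohort simulation
  acoustic.py   energy, voice bounds, F0 tracking, tone features, bands
  emg.py        turn detection, epoching, peak turn frequency
  stats.py      t / chi-squared / Cohen's d / ICC / reports
  pipeline.py   dataset generation, end-to-end analysis, demo
  io.py         WAV / EMG CSV / manifest I/O
  reference.py  published cohort summary statistics
  cli.py        `tonemg` command-line interface
docs/methods.md   model, parameters, design choices, limitations
```
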
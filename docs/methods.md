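# Methods

## Problem and scope

The package quantifies two physiological signatures of cricothyroid (CT)
dysfunction in unilateral vocal fold paralysis: restricted pitch dynamics
during Mandarin lexical-tone production, and reduced recruitment of the CT
muscle in laryngeal EMG. It operates on per-subject recordings (one voice
file per tone and trial, one EMG trace per tone), produces tone-contour
features and peak turn frequencies, and compares CT+ and CT− groups.
Because clinical recordings are not redistributable, the package ships a
synthetic-data generator that emulates the reference cohort (17 CT+, 71 CT−
female patients) whose published group summaries are stored in
`tonemg.reference`. Patient recruitment, stroboscopy, needle-EMG
acquisition and clinical interpretation are out of scope.

## Acoustic analysis

**Energy and voice bounds.** The energy track is the frame-wise RMS of the
waveform (10 ms frames, 5 ms hop, frames aligned to frame starts). The
baseline is the median RMS of the leading 100 ms, assumed pre-phonatory.
A frame is voice-active when RMS ≥ baseline + `threshold_frac` · (peak −
baseline); `threshold_frac` defaults to 0.1, a compromise between missing
breathy onsets and triggering on noise. Onset is the start of the first
active run sustained ≥ 50 ms; offset is the end of the last such run's
final frame. With these conventions the detected onset is biased at most
one hop early and the duration at most two hops long, which is the
tolerance the recovery tests assert at high SNR.

**F0 tracking.** Every 5 ms between the bounds, a 40 ms Hann-windowed frame
centred on the step time is zero-padded 4× (FFT bin ≈ fs/4·N). The 40 ms
window resolves the 100–500 Hz female F0 search band while remaining short
enough for the falling tone's fast dynamics; only the 5 ms hop is part of
the feature definitions, the window length is an analyzer choice. Spectral
peaks inside the band are fundamental candidates; each is scored by the
summed magnitude of its first five harmonics within ±1 analysis bin, the
maximal-score series wins, and ties break toward the lower fundamental.
The winning peak is refined by parabolic interpolation on the magnitude
spectrum. Frames whose best series score is below 0.15 of the strongest
frame's score are unvoiced — this removes the edge frames whose window is
mostly silence. A 5-frame running median (disable with `median_smooth=0`)
guards against octave errors; it is an analyzer safeguard, not part of the
feature definitions.

**Tone features.** Onset/offset F0 are read at the first/last voiced frame
(F0 is undefined on unvoiced frames, so energy bounds are not used as
feature endpoints). ΔF0 values are signed differences, slopes divide each
Δ by its segment duration, and the identity slope · duration = Δ is exact
for every single-trial output. The tone-3 minimum is the earliest global
minimum of the voiced contour and must be strictly interior; an endpoint
minimum flags the utterance and leaves the dip features undefined rather
than fabricating them. The maximal 5 ms drop is the largest one-hop F0
fall, floored at zero; it is computed for every tone and reported for
tone 4. Per-subject features are the arithmetic mean over the three trials
(fewer trials are averaged with a warning); after averaging the
slope-duration identity holds only approximately, because detected
durations can differ by up to one hop between trials. Group contours are
linearly resampled onto a fixed 101-point normalized-time grid; bands are
pointwise mean ± SEM (SD/√n, zero with a flag for n = 1).

## EMG turns analysis

A turn is a polarity reversal with an amplitude excursion of at least
100 µV both before and after the reversal. The detector walks the
waveform's local extrema (plateaus collapse to their first sample) with a
hysteresis scan: the running extreme of the current excursion is tracked,
and a reversal is confirmed as a turn once the signal moves ≥ 100 µV away
from that extreme in the opposite direction. Sub-threshold wiggles neither
confirm reversals nor reset the extreme, which makes the excursion from the
previous qualifying turn and to the next one both ≥ 100 µV by
construction — the standard turns-amplitude reading of "amplitude before
and after the change", where the reference points are consecutive
qualifying turns rather than a fixed baseline (the baseline reading is not
implemented; the relaxed single-flank option for the final extreme is).
The first and last provisional extremes require a full second flank by
default (`require_both_flanks=False` relaxes this). The detector is
verified, on every test signal, against an independent brute-force oracle:
the longest subsequence of samples whose consecutive steps alternate in
sign and each reach the threshold — its interior elements are exactly the
two-sided-qualifying turns.

Turns are binned by time into non-overlapping 50 ms epochs starting at
t = 0; a trailing partial epoch is discarded. Epoch turn frequency is
count ÷ 0.05 s, and the peak turn frequency of a phonation is the maximal
epoch frequency, which therefore lives on a 20 Hz grid. No high-pass
filtering is applied by default since the method statement mentions none;
a 10 Hz high-pass is available for drifting baselines.

## Statistics

Group comparisons use the pooled-variance two-sample t-test by default
(Welch and one-sided variants behind flags), working identically from raw
samples or from summary statistics. Chi-squared on contingency tables is
Pearson without continuity correction by default; the published
paralysis-side p-value (0.099) is reproduced by the Yates-corrected
variant (p = 0.104 vs 0.057 uncorrected), so the corrected value is used
where that number is recomputed. Cohen's *d* uses the pooled SD and is
reported as a magnitude with the direction kept as metadata, matching the
positive printed values. ICC defaults to ICC(A,1) — two-way,
absolute-agreement, single-measure, computed from the ANOVA mean squares
and cross-checked against an independent implementation in the tests;
ICC(3,1) is available and the model label is always reported. Cross-trial
SD is the mean over subjects of the within-subject SD. Exact degenerate
cases (duplicated trials → ICC = 1, cross-trial SD = 0; zero
between-subject variance → flagged NaN) are handled explicitly rather than
left to floating-point cancellation. No multiple-testing correction is
applied, matching the source analysis; missing data are handled by
per-feature listwise deletion.

## Synthetic data: what it emulates and what it does not

Contours are piecewise-linear between anchor points (onset, offset, and
for tone 3 a dip at 0.6 of the duration — the dip position is a
convention, configurable; cosine easing is optional) since no functional
form is specified for the trajectories. Voices are harmonic series with
1/k amplitude decay, a linear attack/release envelope, 0.3 s lead silence
and optional Gaussian noise; default durations follow the reference means
(0.82/0.84/0.71/0.45 s for tones 1–4). EMG is a piecewise-linear zig-zag
whose extrema are placed at the requested rate with amplitudes in
150–400 µV, plus bounded noise below 50 µV that cannot create or destroy
qualifying turns. Cohort simulation draws subject-level Gaussians with the
published group means/SDs and adds within-subject trial noise using the
published cross-trial SDs (25% of the between-SD where unpublished), so
ICC targets σ²_b/(σ²_b+σ²_w) are known.

Draws of non-negative quantities are kept as drawn by default
(`truncate="none"`): the published means/SDs are moments of the observed
data, and re-imposing truncation on a Gaussian parameterized by them would
shift the simulated moments (for the tone-1 CT+ turn frequencies by about
+36 Hz in the mean) and visibly bias recovered effect sizes. Redraw-based
truncation (`truncate="redraw"`) exists for drawing physically realizable
waveform-synthesis parameters — rates and F0 levels must be positive to
render a signal — and is used by the dataset generator, which also redraws
feature values violating a tone's shape constraints (a tone-2 rise must be
non-negative, the tone-3 dip must lie below both endpoints).

These are statistical stand-ins, not biomechanical simulations: features
are drawn independently (no within-subject correlation across features or
tones), voice spectra have no formant structure or jitter/shimmer, and EMG
is not built from motor-unit action potentials. Passing recovery tests
therefore demonstrates the correctness of the measurement chain on signals
with known truth, not clinical performance on real voices.

## Numerical and simulation choices

* Sampling rates default to 44.1 kHz (voice) and 10 kHz (EMG); tests and
  the acceptance script use 16 kHz voices, which keeps the padded FFT bin
  at 3.9 Hz — ample for the 2-bin recovery tolerances — at a fraction of
  the cost.
* Monte-Carlo problem sizes: 10,000 null t-tests; 1,000 ICC panels of 500
  subjects (large panels keep the ICC estimator's O(1/n) downward bias
  well inside the Monte-Carlo band around 1600/1700); 2,000 replicate
  17-vs-71 cohorts for effect-size recovery. The mean recovered sample
  *d* is multiplied by the first-order bias factor J = 1 − 3/(4·df − 1)
  before comparison with the published value, since E[d̂] ≈ δ/J.
* Determinism: every generator takes a seed and is byte-reproducible;
  pipeline outputs embed a SHA-256 hash of the analyzer configuration.

## Known limitations

* The F0 tracker assumes a single voiced segment per recording; diplophonia
  or voice breaks would need segment-aware tracking.
* The energy-based bounds assume leading silence of roughly 100 ms or more
  for the baseline estimate.
* Epoch length is fixed at 50 ms for all muscles; no TA-LCA-specific
  tuning is provided.
* Published p-values of the reference study are treated as regression
  diagnostics, not reproduction targets: several are not exactly
  recoverable from the printed one-decimal summaries with any single
  t-test variant, and per-feature complete-case sample sizes are unknown.
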
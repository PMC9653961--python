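"""Published group-level summary statistics for the reference UVFP cohort.

These are the group means and standard deviations reported for a cohort of
88 female patients with unilateral vocal fold paralysis (UVFP), split by
laryngeal-EMG evidence of cricothyroid (CT) involvement: 17 CT+ and 71 CT-
subjects.  They serve two purposes in this package:

* as the default parameter set of the synthetic cohort generator
  (:mod:`tonemg.synth`), so simulated cohorts emulate the study population;
* as the summary-statistics input from which derived statistics (pooled-SD
  Cohen's d, chi-squared on nominal demographics) are recomputed.

Acoustic features are in Hz (slopes in Hz/s, durations in s); peak turn
frequencies are in Hz (turns/s).  ``d`` columns hold the published effect
sizes, kept for display next to recomputed values, never used in their place.
"""

from __future__ import annotations

N_CT_POS = 17
N_CT_NEG = 71

#: Features whose physical range is strictly non-negative; used when drawing
#: waveform-synthesis parameters (a rate or an F0 level cannot be negative).
NONNEGATIVE_FEATURES = frozenset(
    {"f0_onset", "f0_offset", "duration", "max_drop_5ms", "peak_turn_frequency"}
)

# Per-tone acoustic features: (CT+ mean, CT+ SD, CT- mean, CT- SD, published d).
# Keys follow the feature names produced by tonemg.acoustic.extract_tone_features.
ACOUSTIC_GROUP_STATS: dict[int, dict[str, tuple[float, float, float, float, float]]] = {
    1: {
        "f0_onset": (212.3, 41.5, 233.4, 39.3, 0.53),
        "f0_offset": (219.8, 48.6, 236.5, 46.2, 0.35),
        "delta_on_off": (7.5, 22.0, 3.1, 15.8, 0.26),
        "slope_on_off": (8.3, 28.7, 4.3, 22.6, 0.17),
    },
    2: {
        "f0_onset": (194.1, 38.6, 206.7, 37.1, 0.33),
        "f0_offset": (218.7, 54.1, 250.0, 54.9, 0.56),
        "delta_on_off": (24.6, 23.8, 42.9, 33.3, 0.57),
        "slope_on_off": (30.7, 27.3, 56.6, 44.9, 0.61),
    },
    3: {
        "f0_onset": (190.5, 39.5, 204.9, 38.0, 0.37),
        "f0_offset": (165.7, 46.2, 188.7, 50.0, 0.46),
        "delta_on_off": (-24.8, 31.5, -16.2, 32.1, 0.27),
        "slope_on_off": (-48.9, 70.0, -33.5, 50.0, 0.29),
        "delta_on_min": (-33.7, 21.6, -34.5, 17.4, 0.03),
        "slope_on_min": (-82.5, 62.2, -105.9, 74.2, 0.33),
        "delta_min_off": (8.9, 16.3, 18.2, 28.8, 0.35),
        "slope_min_off": (20.4, 32.0, 49.1, 66.5, 0.47),
    },
    4: {
        "f0_onset": (231.0, 51.3, 259.2, 49.6, 0.57),
        "f0_offset": (177.8, 34.0, 188.5, 37.9, 0.29),
        "delta_on_off": (-53.2, 28.3, -70.8, 36.3, 0.50),
        "slope_on_off": (-125.9, 68.0, -179.1, 87.0, 0.64),
        "max_drop_5ms": (16.1, 5.7, 27.8, 14.8, 0.86),
    },
}

# Whole-cohort test-retest reliability reference: feature ->
# (pooled mean, pooled SD, cross-trial SD, published ICC).
RELIABILITY_STATS: dict[int, dict[str, tuple[float, float, float, float]]] = {
    1: {
        "f0_onset": (229.3, 40.4, 9.5, 0.99),
        "f0_offset": (233.3, 46.9, 10.9, 0.98),
        "delta_on_off": (3.9, 17.1, 11.3, 0.90),
        "duration": (0.82, 0.18, 0.08, 0.95),
    },
    2: {
        "f0_onset": (204.3, 37.5, 8.7, 0.99),
        "f0_offset": (243.6, 55.8, 14.0, 0.99),
        "delta_on_off": (39.3, 32.4, 15.1, 0.94),
        "duration": (0.84, 0.17, 0.08, 0.90),
    },
    3: {
        "f0_onset": (202.1, 38.6, 9.5, 0.97),
        "f0_offset": (184.2, 49.9, 13.3, 0.99),
        "delta_on_off": (-17.9, 40.0, 16.5, 0.93),
        "duration": (0.71, 0.17, 0.09, 0.95),
    },
    4: {
        "f0_onset": (253.8, 50.9, 12.2, 0.97),
        "f0_offset": (186.4, 37.2, 14.0, 0.95),
        "delta_on_off": (-67.4, 35.4, 15.7, 0.77),
        "duration": (0.45, 0.11, 0.05, 0.92),
    },
}

# Peak turn frequency of the lesion-side CT muscle, per tone:
# (CT+ mean, CT+ SD, CT- mean, CT- SD, published d).
TURNS_GROUP_STATS: dict[int, tuple[float, float, float, float, float]] = {
    1: (442.4, 285.0, 730.6, 231.6, 1.19),
    2: (439.6, 252.5, 666.7, 214.3, 1.02),
    3: (381.6, 263.1, 594.4, 223.5, 0.92),
    4: (457.6, 287.5, 803.0, 233.3, 1.41),
}

# Nominal demographics (CT+ counts, CT- counts) for chi-squared checks.
PARALYSIS_SIDE_COUNTS = {"CT+": (7, 10), "CT-": (47, 24)}  # (left, right)

#: Mean phonation durations per tone (s), used as synthesis defaults.
TONE_DURATIONS = {t: RELIABILITY_STATS[t]["duration"][0] for t in (1, 2, 3, 4)}
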
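"""Synthetic voice and EMG signals with known ground truth.

The study's raw recordings are not public, so every downstream stage is
exercised on synthetic stand-ins:

* four-tone F0 contours (level, rising, dipping, falling) built from anchor
  points, with the group-dependent rise/fall ranges of the reference cohort;
* harmonic voice waveforms carrying those contours (decaying harmonic
  series, attack/release energy envelope, lead/tail silence, optional
  Gaussian noise);
* EMG interference patterns as piecewise-linear zig-zags whose qualifying
  turn rate is known by construction, plus sub-threshold noise;
* whole cohorts (17 CT+ / 71 CT- by default) whose per-subject feature
  draws emulate the reference group means/SDs, with a three-trial
  repetition structure for test-retest reliability.

These are statistical stand-ins, not biomechanical simulations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference
from .acoustic import F0Contour, VoiceRecording
from .emg import EMGRecording

__all__ = [
    "ContourSpec",
    "CohortSpec",
    "GroundTruth",
    "SimulatedCohort",
    "make_contour",
    "synthesize_voice",
    "synthesize_emg",
    "simulate_cohort",
]


@dataclass
class ContourSpec:
    """Anchor-point description of one tone's F0 trajectory.

    Tone 1 is level at ``f0_onset``; tone 2 rises monotonically onset ->
    offset; tone 3 falls to ``f0_min`` at ``min_position`` of the duration
    and rises again; tone 4 falls monotonically.  Frequencies in Hz,
    duration in seconds.
    """

    tone: int
    f0_onset: float
    f0_offset: float
    duration: float
    f0_min: float | None = None
    min_position: float = 0.6

    def __post_init__(self) -> None:
        if self.tone not in (1, 2, 3, 4):
            raise ValueError(f"invalid tone label {self.tone}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.f0_onset <= 0 or self.f0_offset <= 0:
            raise ValueError("frequencies must be positive")
        if self.tone == 2 and self.f0_offset < self.f0_onset:
            raise ValueError("tone 2 requires f0_offset >= f0_onset")
        if self.tone == 4 and self.f0_offset > self.f0_onset:
            raise ValueError("tone 4 requires f0_offset <= f0_onset")
        if self.tone == 3:
            if self.f0_min is None:
                raise ValueError("tone 3 requires f0_min")
            if self.f0_min > min(self.f0_onset, self.f0_offset):
                raise ValueError("tone 3 requires f0_min <= min(onset, offset)")
            if not 0 < self.min_position < 1:
                raise ValueError("min_position must lie in (0, 1)")
        elif self.f0_min is not None:
            raise ValueError("f0_min is a tone-3 field")


@dataclass
class GroundTruth:
    """Exact construction parameters carried beside a synthetic signal."""

    contour_spec: ContourSpec | None = None
    contour: F0Contour | None = None
    onset: float | None = None
    offset: float | None = None
    turn_times: np.ndarray | None = None
    turn_amplitudes: np.ndarray | None = None


def make_contour(
    spec: ContourSpec, hop: float = 0.005, interpolation: str = "linear"
) -> F0Contour:
    """Sample the tone's F0 trajectory every ``hop`` seconds.

    ``interpolation`` is ``"linear"`` (default) or ``"cosine"`` (eased
    transitions between the same anchor points).
    """
    if hop <= 0:
        raise ValueError("hop must be positive")
    if interpolation not in ("linear", "cosine"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    t = np.arange(0.0, spec.duration + hop / 2, hop)
    t = t[t <= spec.duration + 1e-12]
    if spec.tone == 1:
        f0 = np.full(t.size, float(spec.f0_onset))
    elif spec.tone in (2, 4):
        f0 = _segment(t, 0.0, spec.duration, spec.f0_onset, spec.f0_offset, interpolation)
    else:
        t_min = spec.min_position * spec.duration
        f0 = np.where(
            t <= t_min,
            _segment(t, 0.0, t_min, spec.f0_onset, spec.f0_min, interpolation),
            _segment(t, t_min, spec.duration, spec.f0_min, spec.f0_offset, interpolation),
        )
    return F0Contour(times=t, f0=f0, voiced_mask=np.ones(t.size, dtype=bool), hop=hop)


def _segment(t, t0, t1, y0, y1, interpolation):
    u = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
    if interpolation == "cosine":
        u = 0.5 - 0.5 * np.cos(np.pi * u)
    return y0 + (y1 - y0) * u


def synthesize_voice(
    contour: F0Contour,
    fs: float = 44100.0,
    n_harmonics: int = 5,
    amplitude: float = 0.3,
    attack: float = 0.010,
    release: float = 0.010,
    noise_rms: float = 0.0,
    lead_silence: float = 0.3,
    tail_silence: float = 0.2,
    seed: int | None = None,
    subject_id: str = "",
    tone: int | None = None,
    trial: int = 1,
) -> tuple[VoiceRecording, GroundTruth]:
    """Render a harmonic voice waveform that carries the given F0 contour.

    The voiced span is sum_k a_k sin(2 pi k phi(t)) with phi the running
    integral of the contour and a_k = amplitude / k (1/k source-spectrum
    decay), shaped by a linear attack/release envelope, padded with lead and
    tail silence, with Gaussian noise of ``noise_rms`` over the whole file.
    """
    voiced_f0 = contour.voiced_f0
    if np.any(n_harmonics * voiced_f0.max() >= fs / 2):
        raise ValueError("n_harmonics * max(F0) violates the Nyquist limit")
    dur = float(contour.times[-1] - contour.times[0])
    n_voiced = int(round(dur * fs))
    tv = contour.times[0] + np.arange(n_voiced) / fs
    f0_t = np.interp(tv, contour.voiced_times, voiced_f0)
    phase = 2 * np.pi * np.cumsum(f0_t) / fs
    voiced = np.zeros(n_voiced)
    for k in range(1, n_harmonics + 1):
        voiced += (amplitude / k) * np.sin(k * phase)
    env = np.ones(n_voiced)
    n_att, n_rel = int(round(attack * fs)), int(round(release * fs))
    if n_att:
        env[:n_att] = np.linspace(0, 1, n_att, endpoint=False)
    if n_rel:
        env[n_voiced - n_rel :] = np.linspace(0, 1, n_rel, endpoint=False)[::-1]
    voiced *= env

    n_lead, n_tail = int(round(lead_silence * fs)), int(round(tail_silence * fs))
    x = np.concatenate([np.zeros(n_lead), voiced, np.zeros(n_tail)])
    if noise_rms > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, noise_rms, x.size)
    rec = VoiceRecording(
        samples=x,
        fs=fs,
        subject_id=subject_id,
        tone=tone if tone is not None else 1,
        trial=trial,
    )
    shifted = F0Contour(
        times=contour.times - contour.times[0] + lead_silence,
        f0=contour.f0.copy(),
        voiced_mask=contour.voiced_mask.copy(),
        hop=contour.hop,
    )
    truth = GroundTruth(
        contour=shifted, onset=lead_silence, offset=lead_silence + dur
    )
    return rec, truth


def synthesize_emg(
    duration: float,
    fs: float = 10000.0,
    turn_rate: float = 600.0,
    amplitude_range: tuple[float, float] = (150.0, 400.0),
    subthreshold_noise_amp: float = 30.0,
    seed: int | None = None,
    subject_id: str = "",
    muscle: str = "CT",
    side: str = "lesion",
    tone: int = 1,
) -> tuple[EMGRecording, GroundTruth]:
    """Piecewise-linear zig-zag interference pattern with known turns.

    Alternating extrema are placed every ``1/turn_rate`` seconds with
    amplitudes drawn uniformly from ``amplitude_range`` (alternating sign),
    linearly interpolated onto the sample grid, plus uniform noise bounded by
    ``subthreshold_noise_amp`` which by construction cannot create or destroy
    qualifying (>= 100 uV both-flank) turns.  The ground truth lists every
    extremum that satisfies the two-sided rule on the noiseless zig-zag.
    """
    if duration <= 0 or fs <= 0:
        raise ValueError("duration and fs must be positive")
    if turn_rate < 0:
        raise ValueError("turn_rate must be >= 0")
    if turn_rate >= fs / 2:
        raise ValueError("turn_rate so high that extrema collide with samples")
    lo, hi = amplitude_range
    if not 100.0 < lo <= hi:
        raise ValueError("amplitude_range minimum must exceed 100 uV")
    if not 0 <= subthreshold_noise_amp < 50.0:
        raise ValueError("subthreshold noise must stay below 50 uV")

    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    if turn_rate > 0:
        times = np.arange(0.5 / turn_rate, duration, 1.0 / turn_rate)
        amps = rng.uniform(lo, hi, times.size)
        signs = np.where(np.arange(times.size) % 2 == 0, 1.0, -1.0)
        knots_t = np.concatenate([[0.0], times, [duration]])
        knots_v = np.concatenate([[0.0], signs * amps, [0.0]])
        x = np.interp(t, knots_t, knots_v)
        truth_t, truth_v = times, signs * amps
    else:
        x = np.zeros(n)
        truth_t = np.empty(0)
        truth_v = np.empty(0)
    if subthreshold_noise_amp > 0:
        x = x + rng.uniform(-subthreshold_noise_amp, subthreshold_noise_amp, n)
    rec = EMGRecording(
        samples=x, fs=fs, subject_id=subject_id, muscle=muscle, side=side, tone=tone
    )
    # snap true turn locations onto the sample grid the detector sees
    idx = np.clip(np.round(truth_t * fs).astype(int), 0, n - 1)
    truth = GroundTruth(turn_times=idx / fs, turn_amplitudes=truth_v)
    return rec, truth


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class CohortSpec:
    """Parameters of a simulated two-group cohort.

    ``acoustic_stats`` and ``turns_stats`` default to the reference cohort's
    group means/SDs; ``within_sd`` gives the within-subject (cross-trial) SD
    per (tone, feature), defaulting to the reference cross-trial SDs where
    published and to ``default_within_frac`` of the between-subject SD
    elsewhere.  ``truncate`` controls how draws of physically non-negative
    features that come out negative are handled: ``"none"`` keeps them (the
    group mean/SD are moments of the observed data, so truncation would
    distort them), ``"redraw"`` redraws until non-negative.
    """

    n_ct_pos: int = reference.N_CT_POS
    n_ct_neg: int = reference.N_CT_NEG
    acoustic_stats: dict = field(
        default_factory=lambda: reference.ACOUSTIC_GROUP_STATS
    )
    turns_stats: dict = field(default_factory=lambda: reference.TURNS_GROUP_STATS)
    within_sd: dict[tuple[int, str], float] = field(default_factory=dict)
    default_within_frac: float = 0.25
    n_trials: int = 3
    truncate: str = "none"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_ct_pos <= 1 or self.n_ct_neg <= 1:
            raise ValueError("each group needs more than one subject")
        if self.truncate not in ("none", "redraw"):
            raise ValueError("truncate must be 'none' or 'redraw'")
        for tone, feats in self.acoustic_stats.items():
            for name, row in feats.items():
                if row[1] < 0 or row[3] < 0:
                    raise ValueError(f"negative SD for tone {tone} {name}")
        for tone, row in self.turns_stats.items():
            if row[1] < 0 or row[3] < 0:
                raise ValueError(f"negative turns SD for tone {tone}")

    def within_sd_for(self, tone: int, feature: str, between_sd: float) -> float:
        if (tone, feature) in self.within_sd:
            return self.within_sd[(tone, feature)]
        ref = reference.RELIABILITY_STATS.get(tone, {})
        if feature in ref:
            return ref[feature][2]
        return self.default_within_frac * between_sd


@dataclass
class SimulatedCohort:
    """Tables produced by :func:`simulate_cohort`."""

    trials: pd.DataFrame  # subject_id, group, tone, feature, trial, value
    subject_means: pd.DataFrame  # trials averaged within subject
    turns: pd.DataFrame  # subject_id, group, tone, peak_turn_frequency
    n_redraws: int = 0


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Draw a cohort of per-subject tone features and peak turn frequencies.

    Subject latent values are Gaussian with the group's mean/SD; each of the
    ``n_trials`` trials adds independent Gaussian within-subject noise, so
    downstream ICC / cross-trial-SD estimates have a known variance-component
    target sigma_b^2 / (sigma_b^2 + sigma_w^2).
    """
    rng = np.random.default_rng(spec.seed)
    groups = [("CT+", spec.n_ct_pos, 0), ("CT-", spec.n_ct_neg, 2)]
    redraws = 0

    def draw(mean, sd, size, nonneg):
        nonlocal redraws
        vals = rng.normal(mean, sd, size)
        if nonneg and spec.truncate == "redraw" and sd > 0:
            bad = vals < 0
            while bad.any():
                redraws += int(bad.sum())
                vals[bad] = rng.normal(mean, sd, int(bad.sum()))
                bad = vals < 0
        return vals

    trial_rows = []
    turn_rows = []
    for glabel, n, col in groups:
        subjects = [f"{'P' if glabel == 'CT+' else 'N'}{i:03d}" for i in range(n)]
        for tone, feats in spec.acoustic_stats.items():
            for feat_name, row in feats.items():
                mean, sd = row[col], row[col + 1]
                nonneg = feat_name in reference.NONNEGATIVE_FEATURES
                latent = draw(mean, sd, n, nonneg)
                w_sd = spec.within_sd_for(tone, feat_name, sd)
                for j in range(spec.n_trials):
                    vals = latent + rng.normal(0.0, w_sd, n) if w_sd > 0 else latent
                    trial_rows.append(
                        pd.DataFrame(
                            {
                                "subject_id": subjects,
                                "group": glabel,
                                "tone": tone,
                                "feature": feat_name,
                                "trial": j + 1,
                                "value": vals,
                            }
                        )
                    )
        for tone, row in spec.turns_stats.items():
            mean, sd = row[col], row[col + 1]
            vals = draw(mean, sd, n, True)
            turn_rows.append(
                pd.DataFrame(
                    {
                        "subject_id": subjects,
                        "group": glabel,
                        "tone": tone,
                        "peak_turn_frequency": vals,
                    }
                )
            )

    trials = (
        pd.concat(trial_rows, ignore_index=True)
        if trial_rows
        else pd.DataFrame(
            columns=["subject_id", "group", "tone", "feature", "trial", "value"]
        )
    )
    turns = (
        pd.concat(turn_rows, ignore_index=True)
        if turn_rows
        else pd.DataFrame(columns=["subject_id", "group", "tone", "peak_turn_frequency"])
    )
    if trials.empty:
        subject_means = trials.drop(columns=["trial"])
    else:
        subject_means = (
            trials.groupby(["subject_id", "group", "tone", "feature"], as_index=False)[
                "value"
            ]
            .mean()
        )
    if redraws:
        warnings.warn(f"redrew {redraws} negative draws", stacklevel=2)
    return SimulatedCohort(
        trials=trials, subject_means=subject_means, turns=turns, n_redraws=redraws
    )
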
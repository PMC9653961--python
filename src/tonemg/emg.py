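"""Turns analysis of raw laryngeal EMG interference patterns.

A *turn* is a polarity reversal of the raw EMG waveform with an amplitude
excursion of at least 100 uV both before and after the reversal — the
classic turns-amplitude convention, with the threshold excluding
noise-related peaks.  The waveform is binned into non-overlapping 50 ms
epochs; each epoch's turn frequency is its turn count divided by the epoch
duration, and the peak turn frequency of a phonation is the highest epoch
turn frequency.  The peak turn frequency of the lesion-side cricothyroid
muscle serves as a muscle-activation index compared between groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EMGRecording",
    "TurnSeries",
    "detect_turns",
    "epoch_turn_frequencies",
    "cohort_peak_turn_table",
]

DEFAULT_AMP_THRESHOLD_UV = 100.0
DEFAULT_EPOCH_S = 0.050


@dataclass
class EMGRecording:
    """Raw EMG trace in microvolts with subject/muscle/tone identity."""

    samples: np.ndarray
    fs: float
    subject_id: str = ""
    muscle: str = "CT"
    side: str = "lesion"
    tone: int = 1

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("EMG amplitudes must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class TurnSeries:
    """Per-epoch turn counts/frequencies and their maximum."""

    epoch_starts: np.ndarray
    turn_counts: np.ndarray
    turn_freqs: np.ndarray
    epoch_duration: float
    peak_turn_frequency: float


def _candidate_extrema(x: np.ndarray) -> np.ndarray:
    """Indices of local extrema; plateaus collapse to their first sample."""
    d = np.diff(x)
    nz = np.flatnonzero(d)
    if nz.size < 2:
        return np.empty(0, dtype=int)
    sign_change = np.flatnonzero(np.sign(d[nz[1:]]) != np.sign(d[nz[:-1]]))
    # extremum sits at the end of the earlier nonzero step (plateau start)
    return nz[sign_change] + 1


def detect_turns(
    samples: np.ndarray,
    fs: float,
    amp_threshold: float = DEFAULT_AMP_THRESHOLD_UV,
    require_both_flanks: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Locate qualifying turns; returns (times_s, amplitudes_uv) in order.

    The scan tracks the running extreme of the current excursion; a reversal
    is confirmed as a turn once the signal has moved at least
    ``amp_threshold`` away from that extreme in the opposite direction.
    Sub-threshold wiggles neither confirm a reversal nor reset the extreme,
    so the excursion from the previous qualifying turn and to the next one
    are both guaranteed to reach the threshold.  With
    ``require_both_flanks=False`` the final provisional extreme also counts
    if its single (preceding) excursion reaches the threshold.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 3:
        return np.empty(0), np.empty(0)
    if amp_threshold <= 0:
        raise ValueError("amp_threshold must be positive")

    turns: list[int] = []
    direction = 0
    cand_i = 0
    cand_v = x[0]
    run_min_i, run_min_v = 0, x[0]
    run_max_i, run_max_v = 0, x[0]
    # walk the candidate extrema plus the final sample as a boundary anchor
    walk = np.append(_candidate_extrema(x), x.size - 1)
    for i in walk:
        v = x[i]
        if direction == 0:
            if v < run_min_v:
                run_min_i, run_min_v = i, v
            if v > run_max_v:
                run_max_i, run_max_v = i, v
            if v - run_min_v >= amp_threshold:
                direction, cand_i, cand_v = 1, i, v
            elif run_max_v - v >= amp_threshold:
                direction, cand_i, cand_v = -1, i, v
        elif direction == 1:
            if v >= cand_v:
                cand_i, cand_v = i, v
            elif cand_v - v >= amp_threshold:
                turns.append(cand_i)
                direction, cand_i, cand_v = -1, i, v
        else:
            if v <= cand_v:
                cand_i, cand_v = i, v
            elif v - cand_v >= amp_threshold:
                turns.append(cand_i)
                direction, cand_i, cand_v = 1, i, v
    if not require_both_flanks and direction != 0:
        turns.append(cand_i)
    idx = np.array(turns, dtype=int)
    return idx / fs, x[idx]


def epoch_turn_frequencies(
    rec: EMGRecording,
    epoch_duration: float = DEFAULT_EPOCH_S,
    amp_threshold: float = DEFAULT_AMP_THRESHOLD_UV,
) -> TurnSeries:
    """Bin turns into non-overlapping epochs and take the peak frequency.

    Epochs start at t=0; a trailing partial epoch is discarded.
    """
    if epoch_duration <= 0:
        raise ValueError("epoch_duration must be positive")
    n_epochs = int(np.floor(rec.duration / epoch_duration + 1e-9))
    if n_epochs < 1:
        raise ValueError("recording shorter than one epoch")
    times, _ = detect_turns(rec.samples, rec.fs, amp_threshold=amp_threshold)
    starts = epoch_duration * np.arange(n_epochs)
    # half-open [start, start + epoch) assignment by turn time
    counts = np.histogram(times, bins=np.append(starts, n_epochs * epoch_duration))[0]
    freqs = counts / epoch_duration
    return TurnSeries(
        epoch_starts=starts,
        turn_counts=counts,
        turn_freqs=freqs,
        epoch_duration=epoch_duration,
        peak_turn_frequency=float(freqs.max()),
    )


def cohort_peak_turn_table(
    recordings: list[tuple[EMGRecording, str]],
    epoch_duration: float = DEFAULT_EPOCH_S,
    amp_threshold: float = DEFAULT_AMP_THRESHOLD_UV,
) -> pd.DataFrame:
    """Long-format per-subject, per-tone peak turn frequency table.

    ``recordings`` pairs each :class:`EMGRecording` with its group label.
    Duplicate subject x tone rows raise; a subject's missing tone simply has
    no row (logged upstream, never imputed).
    """
    rows = []
    for rec, group in recordings:
        series = epoch_turn_frequencies(
            rec, epoch_duration=epoch_duration, amp_threshold=amp_threshold
        )
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": group,
                "tone": rec.tone,
                "muscle": rec.muscle,
                "side": rec.side,
                "peak_turn_frequency": series.peak_turn_frequency,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["subject_id", "group", "tone", "muscle", "side", "peak_turn_frequency"],
    )
    if table.duplicated(subset=["subject_id", "tone"]).any():
        dup = table[table.duplicated(subset=["subject_id", "tone"], keep=False)]
        raise ValueError(
            "duplicate subject x tone EMG rows: "
            + ", ".join(f"{r.subject_id}/tone{r.tone}" for r in dup.itertuples())
        )
    return table
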
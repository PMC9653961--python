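"""Four-tone F0 contour analysis of voice recordings.

The analysis chain mirrors a clinical voice workflow for Mandarin lexical
tones: an RMS energy track locates voice onset and offset, a short-time
Fourier analysis with harmonic-series scoring tracks the fundamental
frequency (F0) between those bounds every 5 ms, and the tone-specific
contour features (onset/offset F0, rises and falls, slopes, the tone-3
dip minimum, the tone-4 maximal 5 ms drop) are read off the track.
Per-subject results are the average of three repeated trials, and group
contours are compared on a normalized 0..1 time grid as mean +/- SEM bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, replace

import numpy as np
from scipy import signal as sps
from scipy.ndimage import median_filter

__all__ = [
    "VoiceRecording",
    "EnergyTrack",
    "VoiceBounds",
    "F0Contour",
    "ToneFeatures",
    "NormalizedContour",
    "NoVoiceDetectedError",
    "compute_energy_track",
    "detect_voice_bounds",
    "estimate_f0_track",
    "extract_tone_features",
    "average_trials",
    "normalize_contour",
    "aggregate_band",
    "analyze_recording",
]

TONES = (1, 2, 3, 4)
TRIALS = (1, 2, 3)


class NoVoiceDetectedError(ValueError):
    """Raised when no frame of the energy track exceeds the voicing threshold."""


@dataclass
class VoiceRecording:
    """A mono voice waveform with subject/tone/trial identity."""

    samples: np.ndarray
    fs: float
    subject_id: str = ""
    tone: int = 1
    trial: int = 1

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.size == 0:
            raise ValueError("recording has no samples")
        if self.tone not in TONES:
            raise ValueError(f"tone must be one of {TONES}, got {self.tone}")
        if self.trial not in TRIALS:
            raise ValueError(f"trial must be one of {TRIALS}, got {self.trial}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class EnergyTrack:
    """Frame-wise RMS energy; frame_times mark frame starts."""

    frame_times: np.ndarray
    rms: np.ndarray
    frame_length: float
    hop: float


@dataclass
class VoiceBounds:
    onset: float
    offset: float

    def __post_init__(self) -> None:
        if not 0 <= self.onset < self.offset:
            raise ValueError("need 0 <= onset < offset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class F0Contour:
    """Time-stamped F0 track; f0 is meaningful only where voiced_mask is True."""

    times: np.ndarray
    f0: np.ndarray
    voiced_mask: np.ndarray
    hop: float = 0.005

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.f0 = np.asarray(self.f0, dtype=float)
        self.voiced_mask = np.asarray(self.voiced_mask, dtype=bool)
        if not (self.times.shape == self.f0.shape == self.voiced_mask.shape):
            raise ValueError("times, f0 and voiced_mask must share a shape")

    @property
    def voiced_times(self) -> np.ndarray:
        return self.times[self.voiced_mask]

    @property
    def voiced_f0(self) -> np.ndarray:
        return self.f0[self.voiced_mask]


@dataclass
class ToneFeatures:
    """Tone-contour parameter set for one utterance.

    Deltas are signed (offset minus onset, etc.); slopes divide each delta by
    the duration of its segment.  Tone-3-specific fields (the dip minimum)
    and the tone-4 ``max_drop_5ms`` are computed for every tone but reported
    for the tone they characterize.  ``flags`` records degeneracies such as a
    tone-3 minimum sitting on an endpoint.
    """

    subject_id: str = ""
    tone: int = 1
    trial: int | None = None
    f0_onset: float = np.nan
    f0_offset: float = np.nan
    duration: float = np.nan
    delta_on_off: float = np.nan
    slope_on_off: float = np.nan
    f0_min: float = np.nan
    t_min: float = np.nan
    delta_on_min: float = np.nan
    slope_on_min: float = np.nan
    delta_min_off: float = np.nan
    slope_min_off: float = np.nan
    max_drop_5ms: float = np.nan
    flags: tuple[str, ...] = field(default_factory=tuple)

    SCALAR_FIELDS = (
        "f0_onset",
        "f0_offset",
        "duration",
        "delta_on_off",
        "slope_on_off",
        "f0_min",
        "t_min",
        "delta_on_min",
        "slope_on_min",
        "delta_min_off",
        "slope_min_off",
        "max_drop_5ms",
    )

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class NormalizedContour:
    """F0 on a fixed 0..1 grid; sem is zero for a single subject (n=1 flag)."""

    grid: np.ndarray
    f0_mean: np.ndarray
    f0_sem: np.ndarray
    n: int = 1
    flags: tuple[str, ...] = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# energy and voice bounds


def compute_energy_track(
    rec: VoiceRecording, frame_length: float = 0.010, hop: float = 0.005
) -> EnergyTrack:
    """Frame-wise RMS of the waveform, frames aligned to frame starts."""
    if not frame_length >= hop > 0:
        raise ValueError("need frame_length >= hop > 0")
    n_frame = int(round(frame_length * rec.fs))
    n_hop = int(round(hop * rec.fs))
    if rec.samples.size < n_frame:
        raise ValueError("recording shorter than one frame")
    n_frames = 1 + (rec.samples.size - n_frame) // n_hop
    idx = np.arange(n_frame)[None, :] + n_hop * np.arange(n_frames)[:, None]
    frames = rec.samples[idx]
    rms = np.sqrt(np.mean(frames**2, axis=1))
    times = n_hop * np.arange(n_frames) / rec.fs
    return EnergyTrack(frame_times=times, rms=rms, frame_length=frame_length, hop=hop)


def detect_voice_bounds(
    energy: EnergyTrack,
    threshold_frac: float = 0.1,
    min_voiced: float = 0.050,
    baseline_window: float = 0.100,
) -> VoiceBounds:
    """Locate voice onset/offset from an abrupt energy rise over baseline.

    The baseline is the median RMS over the leading ``baseline_window``
    seconds (assumed pre-phonatory silence).  A frame is voice-active when
    its RMS exceeds ``baseline + threshold_frac * (peak - baseline)``; the
    onset is the start of the first active run at least ``min_voiced`` long,
    the offset the end of the last such run's final frame.
    """
    rms = energy.rms
    if rms.size == 0:
        raise NoVoiceDetectedError("empty energy track")
    n_lead = max(1, int(round(baseline_window / energy.hop)))
    baseline = float(np.median(rms[:n_lead]))
    peak = float(rms.max())
    thr = baseline + threshold_frac * (peak - baseline)
    active = rms > thr if threshold_frac == 0 else rms >= thr
    if peak <= 0 or not active.any():
        raise NoVoiceDetectedError("no frame exceeds the voicing threshold")

    min_frames = max(1, int(round(min_voiced / energy.hop)))
    runs = _runs(active)
    runs = [(a, b) for a, b in runs if b - a >= min_frames]
    if not runs:
        raise NoVoiceDetectedError(
            f"no voiced run of at least {min_voiced:.3f} s detected"
        )
    onset = float(energy.frame_times[runs[0][0]])
    offset = float(energy.frame_times[runs[-1][1] - 1] + energy.frame_length)
    return VoiceBounds(onset=onset, offset=offset)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True in a boolean vector."""
    padded = np.diff(np.concatenate(([0], mask.astype(int), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts, stops))


# ---------------------------------------------------------------------------
# F0 tracking


def estimate_f0_track(
    rec: VoiceRecording,
    bounds: VoiceBounds,
    window_length: float = 0.040,
    hop: float = 0.005,
    fmin: float = 100.0,
    fmax: float = 500.0,
    n_harmonics: int = 5,
    voicing_floor: float = 0.15,
    median_smooth: int = 5,
    zero_pad_factor: int = 4,
) -> F0Contour:
    """Track F0 between voice bounds by harmonic-series peak picking.

    Each 5 ms step takes a Hann-windowed frame centred on the step time,
    zero-padded ``zero_pad_factor`` times for spectral interpolation.  Peaks
    of the magnitude spectrum inside [fmin, fmax] are fundamental candidates;
    each is scored by the summed magnitude of its first ``n_harmonics``
    harmonics (+-1 analysis-bin tolerance), and the winner is the series with
    the highest energy, ties resolved toward the lower fundamental.  The
    winning peak is refined by parabolic interpolation.  Frames whose best
    series energy falls below ``voicing_floor`` of the strongest frame's are
    unvoiced.  A short median filter (``median_smooth`` frames, 0/1 disables)
    guards against octave errors.
    """
    if not 0 < fmin < fmax < rec.fs / 2:
        raise ValueError("need 0 < fmin < fmax < fs/2")
    n_win = int(round(window_length * rec.fs))
    if n_win < 8:
        raise ValueError("window too short")
    if window_length > bounds.duration:
        raise ValueError("analysis window longer than the voiced span")
    nfft = int(2 ** np.ceil(np.log2(n_win * max(1, zero_pad_factor))))
    bin_hz = rec.fs / nfft
    # candidate tolerance of +-1 un-padded analysis bin around each harmonic
    tol_bins = max(1, int(round((rec.fs / n_win) / bin_hz)))
    win = sps.get_window("hann", n_win, fftbins=True)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / rec.fs)

    centers = np.arange(bounds.onset, bounds.offset + 1e-12, hop)
    f0 = np.full(centers.size, np.nan)
    score = np.zeros(centers.size)
    x = rec.samples
    half = n_win // 2
    for i, tc in enumerate(centers):
        c = int(round(tc * rec.fs))
        lo, hi = c - half, c - half + n_win
        seg = np.zeros(n_win)
        a, b = max(lo, 0), min(hi, x.size)
        if a < b:
            seg[a - lo : b - lo] = x[a:b]
        mag = np.abs(np.fft.rfft(seg * win, nfft))
        f0[i], score[i] = _pick_fundamental(
            mag, freqs, fmin, fmax, n_harmonics, tol_bins, bin_hz
        )

    voiced = np.isfinite(f0)
    if voiced.any():
        voiced &= score >= voicing_floor * score.max()
    if median_smooth and median_smooth > 1 and voiced.sum() >= median_smooth:
        k = median_smooth + (median_smooth % 2 == 0)  # odd kernel
        f0[voiced] = median_filter(f0[voiced], size=k, mode="nearest")
    f0[~voiced] = np.nan
    return F0Contour(times=centers, f0=f0, voiced_mask=voiced, hop=hop)


def _pick_fundamental(mag, freqs, fmin, fmax, n_harmonics, tol_bins, bin_hz):
    """Best (f0, series score) for one magnitude spectrum; (nan, 0) if none."""
    band = (freqs >= fmin) & (freqs <= fmax)
    idx_band = np.flatnonzero(band)
    if idx_band.size < 3:
        return np.nan, 0.0
    peaks, _ = sps.find_peaks(mag[idx_band])
    if peaks.size == 0:
        return np.nan, 0.0
    peaks = idx_band[peaks]
    # keep only non-negligible peaks to bound the candidate set
    peaks = peaks[mag[peaks] >= 1e-3 * mag[peaks].max()]
    best_f, best_s = np.nan, -1.0
    for p in peaks:
        s = 0.0
        for k in range(1, n_harmonics + 1):
            hb = int(round(k * p))
            lo, hi = max(hb - tol_bins, 0), min(hb + tol_bins + 1, mag.size)
            if lo >= hi:
                break
            s += mag[lo:hi].max()
        # strictly-greater comparison keeps the lowest-frequency winner on ties
        if s > best_s + 1e-12 * max(best_s, 1.0):
            best_s = s
            best_f = _parabolic_refine(mag, p) * bin_hz
    if not np.isfinite(best_f):
        return np.nan, 0.0
    return float(np.clip(best_f, fmin, fmax)), float(best_s)


def _parabolic_refine(mag: np.ndarray, i: int) -> float:
    """Sub-bin peak position via a parabola through the peak and neighbours."""
    if i <= 0 or i >= mag.size - 1:
        return float(i)
    a, b, c = mag[i - 1], mag[i], mag[i + 1]
    denom = a - 2 * b + c
    if denom == 0:
        return float(i)
    return i + 0.5 * (a - c) / denom


# ---------------------------------------------------------------------------
# tone features


def extract_tone_features(
    contour: F0Contour, tone: int, subject_id: str = "", trial: int | None = None
) -> ToneFeatures:
    """Read the tone parameter set off a voiced F0 contour.

    Onset/offset F0 are taken at the first/last voiced frame (F0 is undefined
    on unvoiced frames).  The tone-3 minimum is the earliest global minimum of
    the voiced contour and must lie strictly between the endpoints; an
    endpoint minimum flags the utterance and leaves the dip features NaN.
    ``max_drop_5ms`` is the largest one-hop F0 fall, floored at zero.
    """
    if tone not in TONES:
        raise ValueError(f"invalid tone {tone}")
    t = contour.voiced_times
    f = contour.voiced_f0
    if t.size < 2:
        raise ValueError("contour needs at least 2 voiced frames")
    duration = float(t[-1] - t[0])
    f0_on, f0_off = float(f[0]), float(f[-1])
    delta = f0_off - f0_on
    feat = ToneFeatures(
        subject_id=subject_id,
        tone=tone,
        trial=trial,
        f0_onset=f0_on,
        f0_offset=f0_off,
        duration=duration,
        delta_on_off=delta,
        slope_on_off=delta / duration,
    )

    # one-hop drops between time-adjacent voiced frames
    adjacent = np.isclose(np.diff(t), contour.hop, rtol=0.01, atol=1e-9)
    drops = -np.diff(f)
    feat.max_drop_5ms = float(max(drops[adjacent].max(), 0.0)) if adjacent.any() else 0.0

    i_min = int(np.argmin(f))  # earliest global minimum wins ties
    flags = []
    if i_min in (0, t.size - 1):
        flags.append("min_at_endpoint")
    else:
        feat.f0_min = float(f[i_min])
        feat.t_min = float(t[i_min])
        feat.delta_on_min = feat.f0_min - f0_on
        feat.slope_on_min = feat.delta_on_min / (feat.t_min - t[0])
        feat.delta_min_off = f0_off - feat.f0_min
        feat.slope_min_off = feat.delta_min_off / (t[-1] - feat.t_min)
    if tone == 3 and "min_at_endpoint" in flags:
        warnings.warn(
            f"tone-3 contour ({subject_id}, trial {trial}): F0 minimum at an "
            "endpoint; dip features undefined",
            stacklevel=2,
        )
    feat.flags = tuple(flags)
    return feat


def average_trials(trials: list[ToneFeatures]) -> ToneFeatures:
    """Field-wise arithmetic mean over the (up to three) valid trials.

    NaN fields are averaged over the trials where they are defined; fewer
    than three trials triggers a warning, zero valid trials an error.
    """
    trials = [tr for tr in trials if tr is not None]
    if not trials:
        raise ValueError("no valid trials to average")
    if len({(tr.subject_id, tr.tone) for tr in trials}) > 1:
        raise ValueError("trials mix subjects or tones")
    if len(trials) < 3:
        warnings.warn(
            f"averaging {len(trials)} trial(s) instead of 3 for "
            f"({trials[0].subject_id}, tone {trials[0].tone})",
            stacklevel=2,
        )
    out = replace(trials[0], trial=None, flags=())
    flags = sorted({fl for tr in trials for fl in tr.flags})
    for name in ToneFeatures.SCALAR_FIELDS:
        vals = np.array([getattr(tr, name) for tr in trials], dtype=float)
        ok = np.isfinite(vals)
        setattr(out, name, float(vals[ok].mean()) if ok.any() else np.nan)
    out.flags = tuple(flags)
    return out


# ---------------------------------------------------------------------------
# normalized-time bands


def normalize_contour(contour: F0Contour, n_grid: int = 101) -> NormalizedContour:
    """Resample the voiced contour onto a fixed 0..1 normalized-time grid."""
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    t = contour.voiced_times
    f = contour.voiced_f0
    if t.size < 2:
        raise ValueError("contour needs at least 2 voiced frames")
    u = (t - t[0]) / (t[-1] - t[0])
    grid = np.linspace(0.0, 1.0, n_grid)
    return NormalizedContour(
        grid=grid,
        f0_mean=np.interp(grid, u, f),
        f0_sem=np.zeros(n_grid),
        n=1,
        flags=("n=1",),
    )


def aggregate_band(contours: list[NormalizedContour]) -> NormalizedContour:
    """Group mean +- SEM band over subject contours on a shared grid."""
    if not contours:
        raise ValueError("empty group")
    grid = contours[0].grid
    if any(c.grid.size != grid.size for c in contours):
        raise ValueError("contours use different grids")
    stack = np.vstack([c.f0_mean for c in contours])
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    if n == 1:
        return NormalizedContour(grid, mean, np.zeros_like(mean), n=1, flags=("n=1",))
    sem = stack.std(axis=0, ddof=1) / np.sqrt(n)
    return NormalizedContour(grid, mean, sem, n=n)


# ---------------------------------------------------------------------------
# convenience


def analyze_recording(
    rec: VoiceRecording,
    frame_length: float = 0.010,
    hop: float = 0.005,
    threshold_frac: float = 0.1,
    min_voiced: float = 0.050,
    window_length: float = 0.040,
    fmin: float = 100.0,
    fmax: float = 500.0,
    **f0_kwargs,
) -> tuple[VoiceBounds, F0Contour, ToneFeatures]:
    """Energy -> bounds -> F0 track -> tone features, with shared defaults."""
    energy = compute_energy_track(rec, frame_length=frame_length, hop=hop)
    bounds = detect_voice_bounds(
        energy, threshold_frac=threshold_frac, min_voiced=min_voiced
    )
    contour = estimate_f0_track(
        rec,
        bounds,
        window_length=window_length,
        hop=hop,
        fmin=fmin,
        fmax=fmax,
        **f0_kwargs,
    )
    features = extract_tone_features(
        contour, rec.tone, subject_id=rec.subject_id, trial=rec.trial
    )
    return bounds, contour, features
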
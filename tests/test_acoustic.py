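"""Energy track, voice bounds, F0 tracking and tone-feature extraction."""

import numpy as np
import pytest

from tonemg import (
    ContourSpec,
    F0Contour,
    NoVoiceDetectedError,
    ToneFeatures,
    VoiceRecording,
    aggregate_band,
    average_trials,
    compute_energy_track,
    detect_voice_bounds,
    estimate_f0_track,
    extract_tone_features,
    make_contour,
    normalize_contour,
    synthesize_voice,
)

FS = 16000.0


def contour_from(values, hop=0.005, t0=0.0):
    v = np.asarray(values, dtype=float)
    t = t0 + hop * np.arange(v.size)
    return F0Contour(times=t, f0=v, voiced_mask=np.ones(v.size, bool), hop=hop)


class TestEnergyTrack:
    def test_constant_signal_rms_is_abs(self):
        rec = VoiceRecording(np.full(8000, -0.25), FS)
        e = compute_energy_track(rec)
        assert np.allclose(e.rms, 0.25)

    def test_sine_rms(self):
        t = np.arange(16000) / FS
        rec = VoiceRecording(0.5 * np.sin(2 * np.pi * 200 * t), FS)
        e = compute_energy_track(rec, frame_length=0.050)
        assert np.allclose(e.rms, 0.5 / np.sqrt(2), rtol=1e-2)

    def test_zero_signal_and_frame_spacing(self):
        rec = VoiceRecording(np.zeros(4000), FS)
        e = compute_energy_track(rec)
        assert np.all(e.rms == 0)
        assert np.allclose(np.diff(e.frame_times), e.hop)

    def test_too_short_recording(self):
        with pytest.raises(ValueError):
            compute_energy_track(VoiceRecording(np.zeros(10), FS))


class TestVoiceBounds:
    def test_recovers_lead_silence_onset(self, clean_voices):
        for tone, (spec, rec, truth) in clean_voices.items():
            e = compute_energy_track(rec)
            b = detect_voice_bounds(e)
            assert b.onset == pytest.approx(truth.onset, abs=0.005 + 1e-9)
            assert b.duration == pytest.approx(spec.duration, abs=0.010 + 1e-9)

    def test_all_zero_raises(self):
        rec = VoiceRecording(np.zeros(8000), FS)
        with pytest.raises(NoVoiceDetectedError):
            detect_voice_bounds(compute_energy_track(rec))

    def test_zero_threshold_finds_first_energy(self):
        x = np.zeros(8000)
        x[4000:6000] = 0.5
        e = compute_energy_track(VoiceRecording(x, FS))
        b = detect_voice_bounds(e, threshold_frac=0.0)
        # first frame containing any nonzero sample starts at 0.245 s
        assert b.onset == pytest.approx(0.245, abs=0.005)


class TestF0Track:
    def test_pure_sine_single_peak(self):
        t = np.arange(int(1.2 * FS)) / FS
        x = np.zeros(t.size)
        voiced = (t >= 0.2) & (t < 1.0)
        x[voiced] = 0.4 * np.sin(2 * np.pi * 300 * t[voiced])
        rec = VoiceRecording(x, FS)
        b = detect_voice_bounds(compute_energy_track(rec))
        c = estimate_f0_track(rec, b, n_harmonics=1)
        bin_hz = FS / 4096
        assert np.median(np.abs(c.voiced_f0 - 300.0)) < bin_hz

    def test_level_tone_within_2hz(self, clean_voices):
        _, rec, _ = clean_voices[1]
        b = detect_voice_bounds(compute_energy_track(rec))
        c = estimate_f0_track(rec, b)
        assert np.median(np.abs(c.voiced_f0 - 220.0)) <= 2.0

    def test_falling_tone_framewise_recovery(self, clean_voices):
        spec, rec, truth = clean_voices[4]
        b = detect_voice_bounds(compute_energy_track(rec))
        c = estimate_f0_track(rec, b)
        true = np.interp(c.voiced_times, truth.contour.times, truth.contour.f0)
        assert np.mean(np.abs(c.voiced_f0 - true) < 3.0) >= 0.95

    def test_window_longer_than_voiced_span(self, clean_voices):
        _, rec, _ = clean_voices[1]
        from tonemg.acoustic import VoiceBounds
        with pytest.raises(ValueError):
            estimate_f0_track(rec, VoiceBounds(0.30, 0.32), window_length=0.040)


class TestToneFeatures:
    def test_flat_contour_zero_deltas(self):
        f = extract_tone_features(contour_from([220.0] * 50), tone=1)
        assert f.delta_on_off == 0.0
        assert f.slope_on_off == 0.0
        assert f.max_drop_5ms == 0.0

    def test_max_drop_is_largest_pairwise_fall(self):
        f = extract_tone_features(contour_from([240.0, 230.0, 228.0]), tone=4)
        assert f.max_drop_5ms == pytest.approx(10.0)

    def test_max_drop_nonnegative_for_rising_contour(self):
        f = extract_tone_features(contour_from(np.linspace(200, 240, 60)), tone=2)
        assert f.max_drop_5ms == 0.0

    def test_tone3_dip_features(self):
        spec = ContourSpec(3, 205.0, 189.0, 0.7, f0_min=170.0, min_position=0.6)
        c = make_contour(spec)
        f = extract_tone_features(c, tone=3)
        assert f.delta_on_min == pytest.approx(-35.0, abs=0.5)
        assert f.delta_min_off == pytest.approx(19.0, abs=0.5)
        assert f.slope_on_min == pytest.approx(f.delta_on_min / (f.t_min - c.times[0]))
        assert f.slope_min_off == pytest.approx(19.0 / 0.28, rel=0.05)

    def test_tone3_minimum_at_endpoint_is_flagged(self):
        with pytest.warns(UserWarning, match="endpoint"):
            f = extract_tone_features(contour_from(np.linspace(240, 180, 40)), tone=3)
        assert "min_at_endpoint" in f.flags
        assert np.isnan(f.f0_min)

    def test_earliest_minimum_wins_ties(self):
        vals = [200, 180, 190, 180, 200]
        f = extract_tone_features(contour_from(vals), tone=3)
        assert f.t_min == pytest.approx(0.005)

    def test_slope_times_duration_equals_delta(self, clean_voices):
        for tone, (spec, rec, truth) in clean_voices.items():
            f = extract_tone_features(truth.contour, tone)
            assert f.slope_on_off * f.duration == pytest.approx(f.delta_on_off)


class TestAverageTrials:
    def _feat(self, **kw):
        base = dict(subject_id="s1", tone=2, f0_onset=200.0, f0_offset=240.0,
                    duration=0.8, delta_on_off=40.0, slope_on_off=50.0)
        base.update(kw)
        return ToneFeatures(**base)

    def test_identical_trials_idempotent(self):
        f = self._feat()
        out = average_trials([f, f, f])
        assert out.delta_on_off == f.delta_on_off
        assert out.f0_onset == f.f0_onset

    def test_mean_of_three(self):
        fs = [self._feat(delta_on_off=v) for v in (30.0, 40.0, 50.0)]
        assert average_trials(fs).delta_on_off == pytest.approx(40.0)

    def test_two_valid_trials_warn_and_average(self):
        fs = [self._feat(f0_onset=200.0), self._feat(f0_onset=210.0)]
        with pytest.warns(UserWarning, match="2 trial"):
            out = average_trials(fs)
        assert out.f0_onset == pytest.approx(205.0)

    def test_nan_fields_masked(self):
        fs = [self._feat(f0_min=np.nan), self._feat(f0_min=170.0),
              self._feat(f0_min=180.0)]
        assert average_trials(fs).f0_min == pytest.approx(175.0)

    def test_zero_trials_error(self):
        with pytest.raises(ValueError):
            average_trials([])


class TestNormalizedBand:
    def test_endpoints_preserved(self):
        c = contour_from(np.linspace(204, 244, 80))
        n = normalize_contour(c, n_grid=50)
        assert n.f0_mean[0] == pytest.approx(204.0)
        assert n.f0_mean[-1] == pytest.approx(244.0)

    def test_single_subject_sem_zero(self):
        n = normalize_contour(contour_from(np.linspace(204, 244, 80)))
        band = aggregate_band([n])
        assert np.all(band.f0_sem == 0)
        assert "n=1" in band.flags

    def test_identical_contours_sem_zero(self):
        n = normalize_contour(contour_from(np.linspace(204, 244, 80)))
        band = aggregate_band([n, n])
        assert np.allclose(band.f0_sem, 0)
        assert band.n == 2

    def test_sem_is_sd_over_sqrt_n(self):
        rng = np.random.default_rng(0)
        subjects = [normalize_contour(contour_from(220 + rng.normal(0, 5, 80)))
                    for _ in range(6)]
        band = aggregate_band(subjects)
        stack = np.vstack([s.f0_mean for s in subjects])
        assert np.allclose(band.f0_sem, stack.std(0, ddof=1) / np.sqrt(6))

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            aggregate_band([])
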
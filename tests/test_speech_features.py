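"""Parameter-recovery and formula checks for the speech feature bank."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import lfilter

from mciscreen.cohort import AudioRecording, Transcript
from mciscreen.simulate import EffectConfig, _pulse_train, _vocal_tract_denominator
from mciscreen.speech import (
    FrameConfig,
    PitchConfig,
    Segmentation,
    SpeechConfig,
    detect_segments,
    extract_speech_features,
    formant_contours,
    frame_signal,
    jitter_measures,
    pitch_contour,
    pre_emphasis,
    rhythm_ratios,
    speech_feature_names,
    summarize_contour,
    summarize_durations,
)

FS = 16000


def _voiced(f0=150.0, duration_s=2.0, jitter=0.0, seed=0):
    """Pulse train through the fixed all-pole vocal tract: known F0/formants."""
    rng = np.random.default_rng(seed)
    pulses = _pulse_train(rng, int(duration_s * FS), FS, f0, jitter)
    return lfilter([1.0], _vocal_tract_denominator(EffectConfig(), FS), pulses)


class TestPreEmphasis:
    def test_alpha_zero_is_identity(self):
        x = np.random.default_rng(0).standard_normal(100)
        np.testing.assert_array_equal(pre_emphasis(x, 0.0), x)

    def test_constant_signal(self):
        y = pre_emphasis(np.full(10, 5.0), 0.97)
        assert y[0] == 5.0
        np.testing.assert_allclose(y[1:], 0.03 * 5.0)

    def test_impulse_response(self):
        x = np.zeros(5)
        x[0] = 1.0
        np.testing.assert_allclose(pre_emphasis(x, 0.97), [1.0, -0.97, 0, 0, 0])


class TestFraming:
    def test_frame_count_formula(self):
        x = np.zeros(16000)
        frames = frame_signal(x, FS, FrameConfig(25.0, 10.0))
        assert frames.shape == (98, 400)  # floor((16000-400)/160)+1

    def test_first_frame_is_window_times_segment(self):
        x = np.random.default_rng(1).standard_normal(FS)
        frames = frame_signal(x, FS, FrameConfig(25.0, 10.0))
        np.testing.assert_allclose(frames[0], x[:400] * np.hamming(400))

    def test_hop_equal_to_length_partitions(self):
        x = np.arange(1000, dtype=float)
        frames = frame_signal(x, 1000.0, FrameConfig(20.0, 20.0))
        assert frames.shape == (50, 20)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            frame_signal(np.zeros(100), FS)

    def test_frame_config_bounds(self):
        with pytest.raises(ValueError):
            FrameConfig(frame_length_ms=50.0)
        with pytest.raises(ValueError):
            FrameConfig(frame_length_ms=20.0, hop_ms=25.0)


class TestSegmentation:
    def _tone(self, dur):
        return np.sin(2 * np.pi * 220 * np.arange(int(dur * FS)) / FS)

    def test_tone_silence_tone_layout(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([self._tone(1.0), np.zeros(int(0.5 * FS)), self._tone(1.0)])
        x = x + 1e-5 * rng.standard_normal(x.size)
        seg = detect_segments(x, FS)
        assert len(seg.pause_intervals) == 1
        assert seg.pause_durations[0] == pytest.approx(0.5, abs=0.05)
        assert sum(seg.effective_speech_durations) == pytest.approx(2.0, abs=0.06)

    def test_all_speech_has_no_pauses(self):
        x = self._tone(2.0) + 1e-5 * np.random.default_rng(3).standard_normal(2 * FS)
        seg = detect_segments(x, FS)
        assert seg.pause_intervals == []
        assert sum(seg.effective_speech_durations) == pytest.approx(2.0, abs=0.05)

    def test_all_silent_warns_with_no_speech(self):
        x = 1e-6 * np.random.default_rng(4).standard_normal(2 * FS)
        with pytest.warns(UserWarning, match="silent"):
            seg = detect_segments(x, FS)
        assert seg.speech_intervals == []

    def test_short_vs_long_pause_classification(self):
        rng = np.random.default_rng(5)
        x = np.concatenate(
            [self._tone(1.0), np.zeros(int(0.4 * FS)), self._tone(1.0),
             np.zeros(int(1.4 * FS)), self._tone(1.0)]
        )
        x = x + 1e-5 * rng.standard_normal(x.size)
        seg = detect_segments(x, FS)
        classes = [cls for _, _, cls in seg.pause_intervals]
        assert classes == ["short", "long"]

    def test_durations_partition_the_recording(self):
        # speech + pauses + edge silence accounts for the whole duration
        rng = np.random.default_rng(6)
        x = np.concatenate(
            [np.zeros(int(0.3 * FS)), self._tone(1.0), np.zeros(int(0.6 * FS)),
             self._tone(0.8), np.zeros(int(0.3 * FS))]
        )
        x = x + 1e-5 * rng.standard_normal(x.size)
        seg = detect_segments(x, FS)
        total = x.size / FS
        covered = sum(seg.effective_speech_durations) + sum(seg.pause_durations)
        edge = seg.speech_intervals[0][0] + (total - seg.speech_intervals[-1][1])
        assert covered + edge == pytest.approx(total, abs=0.02)


class TestPitch:
    def test_recovers_150hz(self):
        times, f0 = pitch_contour(_voiced(150.0), FS)
        assert f0.size > 50
        assert np.median(f0) == pytest.approx(150.0, abs=3.0)

    def test_white_noise_mostly_unvoiced(self):
        x = np.random.default_rng(7).standard_normal(FS)
        _, f0 = pitch_contour(x, FS)
        n_frames = (FS - int(0.04 * FS)) // 160 + 1
        assert f0.size <= 0.1 * n_frames

    @pytest.mark.parametrize("f0_true", [150.0, 300.0])
    def test_no_octave_swap(self, f0_true):
        _, f0 = pitch_contour(_voiced(f0_true), FS)
        assert np.median(f0) == pytest.approx(f0_true, rel=0.03)
        # no estimates at the half/double frequency
        assert not np.any(np.abs(f0 - f0_true / 2) < 10)
        assert not np.any(np.abs(f0 - f0_true * 2) < 10)


class TestFormants:
    def test_recovers_planted_resonances(self):
        times, f0 = pitch_contour(_voiced(120.0), FS)
        _, formants, _ = formant_contours(_voiced(120.0), FS, voiced_times=times)
        assert formants.shape[0] > 20
        med = np.median(formants, axis=0)
        for est, true in zip(med, (700.0, 1220.0, 2600.0)):
            assert est == pytest.approx(true, rel=0.10)

    def test_ordering_invariant(self):
        times, _ = pitch_contour(_voiced(120.0), FS)
        _, formants, _ = formant_contours(_voiced(120.0), FS, voiced_times=times)
        assert np.all(formants[:, 0] < formants[:, 1])
        assert np.all(formants[:, 1] < formants[:, 2])

    def test_low_rate_cannot_resolve_f3(self):
        # at fs=4 kHz the 2.6 kHz resonance is beyond Nyquist: frames skipped
        from scipy.signal import resample_poly

        x = resample_poly(_voiced(120.0), 1, 4)
        _, formants, skipped = formant_contours(x, FS / 4)
        assert skipped > 0
        assert formants.shape[0] == 0 or formants[:, 2].max() < 2000.0


class TestJitter:
    def test_constant_periods_all_zero(self):
        out = jitter_measures(np.full(20, 0.01))
        assert all(v == 0.0 for v in out.values())

    def test_alternating_periods_hand_computed(self):
        out = jitter_measures(np.array([0.009, 0.011] * 10))
        assert out["local"] == pytest.approx(0.2)
        assert out["local_absolute"] == pytest.approx(0.002)

    @given(st.lists(st.floats(0.002, 0.02), min_size=5, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_ddp_is_exactly_three_rap_and_all_nonnegative(self, periods):
        out = jitter_measures(np.array(periods))
        assert out["ddp"] == 3.0 * out["rap"]
        assert all(v >= 0.0 for v in out.values())

    def test_too_few_periods_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            jitter_measures(np.full(4, 0.01))


class TestSummaries:
    def test_basic_stats(self):
        stats, flags = summarize_durations([1.0, 2.0, 3.0, 4.0])
        assert (stats["min"], stats["max"], stats["range"]) == (1.0, 4.0, 3.0)
        assert stats["mean"] == 2.5 and stats["sum"] == 10.0
        assert flags == {}

    def test_sample_std_convention(self):
        stats, _ = summarize_contour(np.array([1.0, 2.0, 3.0, 4.0]))
        assert stats["std"] == pytest.approx(1.2910, abs=1e-4)

    def test_symmetric_data_zero_skew(self):
        stats, _ = summarize_contour(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert stats["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_empty_and_singleton_flagging(self):
        _, flags = summarize_contour(np.array([]))
        assert set(flags) == set(
            ("min", "max", "range", "mean", "std", "skewness", "kurtosis")
        )
        _, flags = summarize_contour(np.array([2.0]))
        assert set(flags) == {"std", "skewness", "kurtosis"}


class TestRhythmRatios:
    def _seg(self):
        return Segmentation(
            speech_intervals=[(0.0, 2.0), (3.0, 5.0), (7.0, 13.0)],
            pause_intervals=[(2.0, 3.0, "short"), (5.0, 7.0, "long"),
                             (13.0, 13.5, "short")],
        )

    def test_count_ratios(self):
        seg = Segmentation(
            speech_intervals=[(0, 1), (2, 3), (4, 5)],
            pause_intervals=[(1, 2, "long"), (3, 3.5, "short"), (3.6, 4, "short")],
        )
        values, _ = rhythm_ratios(seg, Transcript("abc"))
        assert values["ratio_long_pause_speech_counts"] == pytest.approx(1 / 3)
        assert values["ratio_short_pause_speech_counts"] == pytest.approx(2 / 3)

    def test_articulation_rate(self):
        values, _ = rhythm_ratios(self._seg(), Transcript("一二三四五六七八九十" * 3))
        assert values["total_characters"] == 30.0
        assert values["articulation_rate"] == pytest.approx(3.0)

    def test_empty_transcript_flagged(self):
        values, flags = rhythm_ratios(self._seg(), Transcript(""))
        assert values["total_characters"] == 0.0
        assert values["articulation_rate"] == 0.0
        assert "total_characters" in flags


class TestFullBank:
    def test_vector_has_49_features(self):
        rng = np.random.default_rng(8)
        x = _voiced(150.0, 2.0, jitter=0.01)
        audio = AudioRecording(samples=x + 1e-4 * rng.standard_normal(x.size), fs=FS)
        vec = extract_speech_features(audio, Transcript("我们在这里说话"))
        assert len(vec) == 49
        assert vec.names == speech_feature_names()

    def test_schema_stable_without_pauses(self):
        rng = np.random.default_rng(9)
        x = _voiced(150.0, 1.5, jitter=0.01)
        audio = AudioRecording(samples=x + 1e-4 * rng.standard_normal(x.size), fs=FS)
        vec = extract_speech_features(audio, Transcript("abc"))
        assert len(vec) == 49
        assert vec["pause_time.sum"] == 0.0
        assert "pause_time.min" in vec.flags

    def test_inserted_silence_changes_pause_sum(self):
        rng = np.random.default_rng(10)
        a = _voiced(150.0, 1.0, jitter=0.01, seed=1)
        b = _voiced(150.0, 1.0, jitter=0.01, seed=2)
        gap = 0.6
        noise = lambda n: 1e-5 * rng.standard_normal(n)  # noqa: E731
        without = np.concatenate([a, b])
        with_gap = np.concatenate([a, np.zeros(int(gap * FS)), b])
        v0 = extract_speech_features(
            AudioRecording(samples=without + noise(without.size), fs=FS),
            Transcript("abc"),
        )
        v1 = extract_speech_features(
            AudioRecording(samples=with_gap + noise(with_gap.size), fs=FS),
            Transcript("abc"),
        )
        assert v1["pause_time.sum"] - v0["pause_time.sum"] == pytest.approx(gap, abs=0.05)
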
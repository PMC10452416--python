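"""Analytic and oracle checks of the EEG frequency-domain feature bank."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mciscreen.cohort import EEGRecording
from mciscreen.eeg import (
    DEFAULT_BANDS,
    BandDefinition,
    band_power,
    bandpass_filter,
    clean_artifacts,
    dasm,
    eeg_feature_names,
    extract_eeg_features,
    mean_power,
    power_spectrum,
    rasm,
    signal_energy,
    spectral_entropy,
)

from conftest import sinusoid_recording


class TestBandDefinitions:
    def test_default_band_edges(self):
        edges = {(b.name, b.low, b.high) for b in DEFAULT_BANDS}
        assert edges == {
            ("delta", 1.0, 4.0), ("theta", 4.0, 8.0), ("alpha", 8.0, 13.0),
            ("beta", 13.0, 30.0), ("gamma", 30.0, 45.0),
        }

    def test_inverted_band_rejected(self):
        with pytest.raises(ValueError):
            BandDefinition("bad", 10.0, 5.0)


class TestBandpassFilter:
    def test_stopband_attenuates_50hz(self):
        rec = sinusoid_recording(50.0)
        out = bandpass_filter(rec, 0.1, 45.0)
        assert _rms(out.samples[0]) < 0.05 * _rms(rec.samples[0])

    def test_passband_preserves_10hz(self):
        rec = sinusoid_recording(10.0)
        out = bandpass_filter(rec, 0.1, 45.0)
        assert _rms(out.samples[0]) == pytest.approx(_rms(rec.samples[0]), rel=0.05)

    def test_dc_removed(self):
        rec = EEGRecording(samples=np.full((4, 2048), 7.0))
        out = bandpass_filter(rec, 0.1, 45.0)
        assert abs(out.samples.mean()) < 0.1

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(sinusoid_recording(10.0), 0.1, 200.0)

    def test_length_preserved(self):
        rec = sinusoid_recording(10.0)
        assert bandpass_filter(rec).n_samples == rec.n_samples


class TestPowerSpectrum:
    def test_peak_at_tone_frequency(self):
        freqs, psd = power_spectrum(sinusoid_recording(6.0, 2.0).samples[0], 256.0)
        assert freqs[np.argmax(psd)] == pytest.approx(6.0, abs=0.5)

    def test_parseval_consistency(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(4096)
        freqs, psd = power_spectrum(x, 256.0)
        assert np.trapezoid(psd, freqs) == pytest.approx(np.mean(x**2), rel=0.1)

    def test_white_noise_flat_per_hz(self):
        # Monte-Carlo oracle: per-Hz power equal across bands within spread
        rng = np.random.default_rng(1)
        per_hz = []
        for _ in range(20):
            x = rng.standard_normal(256 * 16)
            rec = EEGRecording(samples=np.tile(x, (4, 1)))
            per_hz.append([
                mean_power(rec, "TP9", b) / (b.high - b.low) for b in DEFAULT_BANDS
            ])
        means = np.mean(per_hz, axis=0)
        assert means.max() / means.min() == pytest.approx(1.0, abs=0.15)

    def test_two_tones_equal_peaks(self):
        fs, t = 256.0, np.arange(2048) / 256.0
        x = np.sin(2 * np.pi * 6 * t) + np.sin(2 * np.pi * 20 * t)
        freqs, psd = power_spectrum(x, fs)
        p6 = psd[np.argmin(np.abs(freqs - 6))]
        p20 = psd[np.argmin(np.abs(freqs - 20))]
        assert p6 == pytest.approx(p20, rel=0.05)

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            power_spectrum(np.array([]), 256.0)


class TestMeanPower:
    def test_sinusoid_analytic_power(self):
        rec = sinusoid_recording(6.0, amplitude=2.0)
        assert mean_power(rec, "TP9", "theta") == pytest.approx(2.0, rel=0.05)

    def test_out_of_band_power_negligible(self):
        rec = sinusoid_recording(6.0, amplitude=2.0)
        assert mean_power(rec, "TP9", "alpha") < 0.01 * mean_power(rec, "TP9", "theta")

    def test_quadratic_amplitude_scaling(self):
        p1 = mean_power(sinusoid_recording(6.0, 1.0), "TP9", "theta")
        p2 = mean_power(sinusoid_recording(6.0, 2.0), "TP9", "theta")
        assert p2 / p1 == pytest.approx(4.0, rel=0.02)

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError, match="unknown channel"):
            mean_power(sinusoid_recording(6.0), "Cz", "theta")

    def test_agrees_with_direct_dft_oracle(self):
        # brute-force oracle: periodogram from a plain DFT, rectangular band
        # mask.  32 s of noise keeps both estimators' sampling variability
        # well inside the 10% agreement bound in the narrowest band.
        for seed in range(5):
            x = np.random.default_rng(seed).standard_normal(256 * 32)
            rec = EEGRecording(samples=np.tile(x, (4, 1)))
            spec = np.fft.rfft(x)
            freqs = np.fft.rfftfreq(x.size, 1 / 256.0)
            pgram = (np.abs(spec) ** 2) / (x.size**2)
            pgram[1:-1] *= 2  # one-sided
            for band in DEFAULT_BANDS:
                mask = (freqs >= band.low) & (freqs < band.high)
                oracle = pgram[mask].sum()
                assert mean_power(rec, "AF7", band) == pytest.approx(oracle, rel=0.10)


class TestSignalEnergy:
    def test_direct_formula_without_band_filter(self):
        x = np.array([1.0, -2.0, 2.0])
        assert float(np.sum(x**2)) == 9.0  # the stated formula on raw samples

    def test_zero_signal(self):
        rec = EEGRecording(samples=np.zeros((4, 2048)))
        assert signal_energy(rec, "TP9", "theta") == 0.0

    def test_concatenation_additivity(self):
        x = sinusoid_recording(6.0, duration_s=8.0)
        xx = EEGRecording(samples=np.tile(x.samples, (1, 2)))
        e1 = signal_energy(x, "TP9", "theta")
        e2 = signal_energy(xx, "TP9", "theta")
        assert e2 == pytest.approx(2 * e1, rel=0.02)

    def test_nonnegative(self):
        rng = np.random.default_rng(3)
        rec = EEGRecording(samples=rng.standard_normal((4, 2048)))
        for b in DEFAULT_BANDS:
            assert signal_energy(rec, "AF8", b) >= 0.0


class TestSpectralEntropy:
    def test_uniform_spectrum_gives_log2_bins(self):
        # white noise over a band approaches log2(#bins); exact uniform == log2
        p = np.full(8, 0.125)
        assert -(p * np.log2(p)).sum() == pytest.approx(3.0)

    def test_single_tone_near_zero(self):
        rec = sinusoid_recording(6.0, duration_s=16.0)
        assert spectral_entropy(rec, "TP9", "theta") < 1.5

    def test_bounds_hold_for_noise(self):
        rng = np.random.default_rng(5)
        rec = EEGRecording(samples=rng.standard_normal((4, 4096)))
        for band in DEFAULT_BANDS:
            h = spectral_entropy(rec, "TP9", band)
            freqs, _ = power_spectrum(rec.channel("TP9"), rec.fs)
            n_bins = int(((freqs >= band.low) & (freqs < band.high)).sum())
            assert 0.0 <= h <= np.log2(n_bins) + 1e-9

    def test_zero_power_flagged_zero(self):
        rec = EEGRecording(samples=np.zeros((4, 2048)))
        with pytest.warns(UserWarning, match="zero in-band power"):
            assert spectral_entropy(rec, "TP9", "theta") == 0.0


class TestAsymmetry:
    def test_dasm_example(self):
        assert dasm(5.0, 3.0) == 2.0

    def test_rasm_example(self):
        val, floored = rasm(5.0, 3.0)
        assert val == pytest.approx(5.0 / 3.0)
        assert not floored

    @given(st.floats(0.001, 1e6), st.floats(0.001, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_dasm_antisymmetry_rasm_reciprocity(self, a, b):
        assert dasm(a, b) == -dasm(b, a)
        assert rasm(a, b)[0] * rasm(b, a)[0] == pytest.approx(1.0)

    @given(st.floats(0.001, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_identity_on_equal_powers(self, p):
        assert dasm(p, p) == 0.0
        assert rasm(p, p)[0] == 1.0

    def test_rasm_zero_denominator_floored_and_flagged(self):
        val, floored = rasm(5.0, 0.0, total_power=10.0)
        assert floored and np.isfinite(val)


class TestFeatureBank:
    def test_full_bank_has_80_features(self):
        rng = np.random.default_rng(0)
        rec = EEGRecording(samples=rng.standard_normal((4, 2048)))
        vec = extract_eeg_features(rec)
        assert len(vec) == 80
        prefixes = [n.split(".")[0] for n in vec.names]
        assert [prefixes.count(k) for k in ("MP", "SE", "ShE", "DASM", "RASM")] == \
            [20, 20, 20, 10, 10]

    @pytest.mark.parametrize("n_bands,expected", [(1, 16), (2, 32), (5, 80)])
    def test_band_subset_cardinality_formula(self, n_bands, expected):
        rng = np.random.default_rng(1)
        rec = EEGRecording(samples=rng.standard_normal((4, 2048)))
        vec = extract_eeg_features(rec, bands=DEFAULT_BANDS[:n_bands])
        assert len(vec) == expected == 4 * 3 * n_bands + 2 * 2 * n_bands

    def test_hemispheric_symmetry_gives_null_asymmetry(self):
        rng = np.random.default_rng(2)
        left_ear = rng.standard_normal(2048)
        forehead = rng.standard_normal(2048)
        rec = EEGRecording(samples=np.stack([left_ear, forehead, forehead, left_ear]))
        vec = extract_eeg_features(rec)
        for name in vec.names:
            if name.startswith("DASM"):
                assert vec[name] == pytest.approx(0.0, abs=1e-12)
            if name.startswith("RASM"):
                assert vec[name] == pytest.approx(1.0)

    def test_ordering_is_deterministic(self):
        assert eeg_feature_names() == eeg_feature_names()
        assert eeg_feature_names()[0] == "MP.TP9.delta"
        assert eeg_feature_names()[-1] == "RASM.AF7-AF8.gamma"


class TestArtifactCleaning:
    def test_none_is_identity(self):
        rec = sinusoid_recording(10.0)
        out, report = clean_artifacts(rec, "none")
        np.testing.assert_array_equal(out.samples, rec.samples)
        assert report.rejected_spans == []

    def test_clean_signal_untouched_by_amplitude_reject(self):
        rec = sinusoid_recording(10.0, amplitude=50.0)
        out, report = clean_artifacts(rec, "amplitude_reject",
                                      amplitude_threshold_uv=200.0)
        assert report.rejected_spans == []
        assert out.n_samples == rec.n_samples

    def test_spike_segment_listed_and_removed(self):
        rec = sinusoid_recording(10.0, amplitude=50.0, duration_s=8.0)
        rec.samples[2, 256 * 3 + 10] = 500.0  # spike in second 3
        out, report = clean_artifacts(rec, "amplitude_reject",
                                      amplitude_threshold_uv=200.0)
        assert report.rejected_spans == [(3.0, 4.0)]
        assert out.n_samples == rec.n_samples - 256

    def test_short_recording_ica_falls_back(self):
        rec = sinusoid_recording(10.0, duration_s=4.0)
        with pytest.warns(UserWarning, match="falling back"):
            _, report = clean_artifacts(rec, "ica")
        assert report.method == "amplitude_reject(fallback)"

    def test_ica_removes_heavy_tailed_component(self):
        rng = np.random.default_rng(6)
        n = 256 * 20
        brain = rng.standard_normal((4, n))
        blink = np.zeros(n)
        blink[rng.integers(0, n, 15)] = 400.0  # sparse, very heavy-tailed
        mixed = brain + np.outer([1.0, 2.0, 2.0, 1.0], blink)
        rec = EEGRecording(samples=mixed)
        out, report = clean_artifacts(rec, "ica")
        assert len(report.rejected_components) >= 1
        assert np.abs(out.samples).max() < np.abs(rec.samples).max() / 2


def _rms(x):
    return float(np.sqrt(np.mean(x**2)))
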
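"""Acoustic feature extractors against known signals and the synthesis
oracle: F0, HNR, jitter/shimmer, spectral features, formants, MFCC."""

import numpy as np
import pytest
from scipy.fft import dct as scipy_dct

from voicesym.audio import AudioRecording
from voicesym.features import (
    estimate_f0,
    extract_cycles,
    formants,
    hnr,
    jitter_local,
    mel_filterbank,
    mfcc,
    shimmer_local,
    spectral_features,
)
from voicesym.synth import FormantSpec, synthesize_voice

from conftest import FIVE_FORMANTS, RATE, clean_glottal


class TestF0:
    def test_pure_tone(self, sine_200):
        f0 = estimate_f0(sine_200)
        v = f0.voiced_values()
        assert len(v) > 0.8 * len(f0.values)
        assert np.all(np.abs(v - 200.0) < 3.0)

    def test_white_noise_mostly_unvoiced(self, white_noise):
        f0 = estimate_f0(white_noise)
        assert np.mean(f0.voiced_mask) < 0.10

    def test_synthesis_recovery(self, clean_voice):
        v = estimate_f0(clean_voice).voiced_values()
        assert abs(np.mean(v) - 120.0) / 120.0 < 0.02

    def test_invalid_band(self, sine_200):
        with pytest.raises(ValueError):
            estimate_f0(sine_200, fmin=300.0, fmax=200.0)


class TestJitterShimmer:
    def test_jitter_hand_arithmetic(self):
        assert jitter_local(np.array([0.010, 0.012])) == pytest.approx(2.0 / 11.0)
        assert jitter_local(np.full(10, 0.008)) == 0.0
        with pytest.raises(ValueError):
            jitter_local(np.array([0.01]))

    def test_shimmer_hand_arithmetic(self):
        assert shimmer_local(np.array([1.0, 0.8])) == pytest.approx(0.2 / 0.9)
        assert shimmer_local(np.full(5, 0.7)) == 0.0
        with pytest.raises(ValueError):
            shimmer_local(np.array([1.0]))

    def test_injected_jitter_recovered(self):
        rec = synthesize_voice(
            clean_glottal(jitter_pct=2.0), FormantSpec(), 2.0, RATE, seed=2
        )
        periods, _ = extract_cycles(rec)
        assert abs(jitter_local(periods) * 100.0 - 2.0) < 0.5

    def test_clean_voice_nearly_jitter_and_shimmer_free(self):
        rec = synthesize_voice(clean_glottal(), FormantSpec(), 2.0, RATE, seed=3)
        periods, amps = extract_cycles(rec)
        assert jitter_local(periods) < 0.01
        assert shimmer_local(amps) < 0.01

    def test_injected_shimmer_recovered(self):
        rec = synthesize_voice(
            clean_glottal(shimmer_pct=5.0), FormantSpec(), 2.0, RATE, seed=5
        )
        _, amps = extract_cycles(rec)
        assert 3.5 < shimmer_local(amps) * 100.0 < 6.5


class TestHnr:
    def test_noiseless_voice_high_hnr(self, clean_voice):
        vals = hnr(clean_voice).voiced_values()
        assert np.median(vals) > 30.0

    def test_known_snr_recovered(self, noisy_voice_10db):
        vals = hnr(noisy_voice_10db).voiced_values()
        assert abs(np.mean(vals) - 10.0) < 3.0

    def test_equal_power_harmonic_and_noise_give_zero_db(self):
        """r = 0.5 maps to 0 dB: tone plus equal-power white noise."""
        rng = np.random.default_rng(8)
        t = np.arange(int(2 * RATE)) / RATE
        tone = np.sin(2 * np.pi * 150.0 * t)
        noise = rng.standard_normal(len(t))
        noise *= np.sqrt(np.mean(tone**2) / np.mean(noise**2))
        rec = AudioRecording(0.4 * (tone + noise) / np.max(np.abs(tone + noise)), RATE)
        vals = hnr(rec, voicing_threshold=0.3).voiced_values()
        assert abs(np.mean(vals)) < 2.0


class TestSpectral:
    def test_single_tone_band_and_centroid(self):
        t = np.arange(int(RATE)) / RATE
        rec = AudioRecording(0.5 * np.sin(2 * np.pi * 250.0 * t), RATE)
        sf = spectral_features(rec)
        b = [
            sf["band_power_0_500"].values,
            sf["band_power_500_1000"].values,
            sf["band_power_1000_4000"].values,
        ]
        frac = b[0] / (b[0] + b[1] + b[2])
        assert np.all(frac >= 0.99)
        assert np.nanmean(sf["spectral_centroid"].values) == pytest.approx(250.0, abs=5.0)

    def test_stationary_tone_has_zero_flux(self, sine_200):
        flux = spectral_features(sine_200)["spectral_flux"].values
        assert flux[0] == 0.0
        assert np.all(flux[1:] < 1e-3)

    def test_two_tone_centroid_is_power_weighted_mean(self):
        t = np.arange(int(RATE)) / RATE
        x = 0.3 * np.sin(2 * np.pi * 300.0 * t) + 0.3 * np.sin(2 * np.pi * 900.0 * t)
        sf = spectral_features(AudioRecording(x, RATE))
        assert np.nanmean(sf["spectral_centroid"].values) == pytest.approx(600.0, abs=10.0)

    def test_band_power_conservation(self, white_noise, sine_200):
        """Three bands partition 0-4000 Hz: their sum never exceeds the
        total and equals it for band-limited input (within FFT leakage)."""
        for rec, band_limited in ((white_noise, False), (sine_200, True)):
            sf = spectral_features(rec)
            total, _, _ = _total_power(rec)
            s = (
                sf["band_power_0_500"].values
                + sf["band_power_500_1000"].values
                + sf["band_power_1000_4000"].values
            )
            assert np.all(s <= total * (1 + 1e-9))
            if band_limited:
                assert np.all(s >= 0.999 * total)

    def test_low_rate_rejected(self):
        rec = AudioRecording(np.zeros(8000), 8000.0)
        with pytest.raises(ValueError):
            spectral_features(rec)

    def test_amplitude_scaling_quadratic_for_powers(self, sine_200):
        doubled = AudioRecording(2.0 * sine_200.samples, RATE)
        a = spectral_features(sine_200)
        b = spectral_features(doubled)
        np.testing.assert_allclose(
            b["band_power_0_500"].values, 4.0 * a["band_power_0_500"].values, rtol=1e-9
        )
        np.testing.assert_allclose(
            b["energy_rms"].values, 2.0 * a["energy_rms"].values, rtol=1e-9
        )
        np.testing.assert_allclose(
            b["spectral_centroid"].values, a["spectral_centroid"].values, rtol=1e-9
        )


def _total_power(rec):
    from voicesym.features import _power_spectra

    power, freqs, times = _power_spectra(rec)
    return power.sum(axis=1), freqs, times


class TestFormants:
    def test_single_resonator_recovered(self):
        fs = FormantSpec(centers=(700.0,), bandwidths=(90.0,))
        rec = synthesize_voice(clean_glottal(), fs, 1.0, RATE, seed=1)
        f1 = formants(rec)[0]
        assert np.nanmedian(f1.values) == pytest.approx(700.0, abs=50.0)

    def test_five_resonators_within_ten_percent(self):
        rec = synthesize_voice(clean_glottal(), FIVE_FORMANTS, 1.0, RATE, seed=2)
        tracks = formants(rec)
        for track, center in zip(tracks, FIVE_FORMANTS.centers):
            med = np.nanmedian(track.values)
            assert abs(med - center) / center < 0.10

    def test_reported_frequencies_strictly_increasing(self, clean_voice):
        tracks = formants(clean_voice)
        mat = np.vstack([t.values for t in tracks]).T
        for row in mat:
            vals = row[np.isfinite(row)]
            assert np.all(np.diff(vals) > 0)

    def test_too_many_formants_rejected(self, clean_voice):
        with pytest.raises(ValueError):
            formants(clean_voice, n=6)


class TestMfcc:
    def test_amplitude_scale_invariance(self, sine_200):
        doubled = AudioRecording(2.0 * sine_200.samples, RATE)
        for a, b in zip(mfcc(sine_200), mfcc(doubled)):
            np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_digital_silence_finite_constant(self):
        rec = AudioRecording(np.zeros(11025), RATE)
        for series in mfcc(rec):
            assert np.all(np.isfinite(series.values))
            assert np.ptp(series.values) == 0.0

    def test_against_independent_reference(self, clean_voice):
        """Same frame/filterbank settings, independently coded pipeline
        (vectorized triangle construction + scipy's orthonormal DCT)."""
        from voicesym.features import _power_spectra

        power, freqs, _ = _power_spectra(clean_voice)
        nfft = 2 * (power.shape[1] - 1)
        n_filters, n_coeff = 26, 12
        # reference filterbank built by interpolation instead of slopes
        mel = lambda f: 2595.0 * np.log10(1.0 + f / 700.0)
        imel = lambda m: 700.0 * (10.0 ** (m / 2595.0) - 1.0)
        pts = imel(np.linspace(mel(0.0), mel(RATE / 2), n_filters + 2))
        fb = np.zeros((n_filters, len(freqs)))
        for j in range(n_filters):
            fb[j] = np.interp(freqs, [pts[j], pts[j + 1], pts[j + 2]], [0.0, 1.0, 0.0])
        loge = np.log(np.maximum(power @ fb.T, 1e-10))
        ref = scipy_dct(loge, type=2, norm="ortho", axis=1)[:, 1 : n_coeff + 1]
        ours = np.vstack([s.values for s in mfcc(clean_voice)]).T
        np.testing.assert_allclose(ours, ref, atol=1e-8)

    def test_invalid_count_rejected(self, sine_200):
        with pytest.raises(ValueError):
            mfcc(sine_200, n_coeff=0)
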
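"""The 36-feature catalog: spectra, harmonics, entropies, amplitudes."""

import warnings

import numpy as np
import pytest

from legagility import features as ft
from legagility.errors import DegenerateSpectrumError
from legagility.preprocess import preprocess_recording
from legagility.synthetic import SeverityProfile, simulate_recording

FS = 200.0


def _sine(freq, amp=1.0, dur=10.0, fs=FS, phase=0.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestSpectrum:
    def test_sine_has_single_dominant_bin(self):
        spec = ft.compute_spectrum(_sine(2.0), FS)
        assert spec.freqs[np.argmax(spec.magnitude)] == pytest.approx(2.0)
        assert spec.magnitude.max() == pytest.approx(1.0, rel=1e-6)

    def test_parseval_on_white_noise(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2048)
        x -= x.mean()
        spec = ft.compute_spectrum(x, FS)
        assert spec.power.sum() == pytest.approx(np.mean(x**2), rel=1e-6)

    def test_dc_bin_is_empty_after_mean_removal(self):
        spec = ft.compute_spectrum(_sine(2.0) + 3.0, FS)
        assert spec.power[0] == pytest.approx(0.0, abs=1e-20)

    def test_constant_signal_degenerate(self):
        with pytest.raises(DegenerateSpectrumError):
            ft.compute_spectrum(np.full(2000, 1.5), FS)


class TestDominantFrequency:
    def test_weaker_high_harmonic_ignored(self):
        spec = ft.compute_spectrum(_sine(1.0) + _sine(3.0, amp=0.5), FS)
        assert ft.dominant_frequency(spec) == pytest.approx(1.0)

    def test_tie_breaks_toward_lower_frequency(self):
        spec = ft.compute_spectrum(_sine(1.0) + _sine(3.0), FS)
        assert ft.dominant_frequency(spec) == pytest.approx(1.0)


class TestHarmonics:
    def test_pure_sine_single_harmonic(self):
        spec = ft.compute_spectrum(_sine(2.0), FS)
        h = ft.detect_harmonics(spec)
        assert h.n_harmonics == 1
        f, a, w = h.dominant
        assert f == pytest.approx(2.0)
        assert a == pytest.approx(1.0, rel=1e-6)
        assert w > 0

    def test_three_tone_signal_three_harmonics(self):
        spec = ft.compute_spectrum(_sine(1.0) + _sine(2.0) + _sine(3.0), FS)
        h = ft.detect_harmonics(spec, rel_threshold=0.1)
        assert h.n_harmonics == 3
        assert [round(p[0], 1) for p in h.peaks] == [1.0, 2.0, 3.0]

    def test_raising_threshold_never_adds_harmonics(self):
        rng = np.random.default_rng(1)
        x = _sine(1.0) + _sine(2.3, amp=0.4) + 0.05 * rng.standard_normal(2000)
        spec = ft.compute_spectrum(x, FS)
        counts = [ft.detect_harmonics(spec, rel_threshold=thr).n_harmonics
                  for thr in (0.02, 0.1, 0.3, 0.6)]
        assert counts == sorted(counts, reverse=True)

    def test_min_separation_merges_close_peaks(self):
        spec = ft.compute_spectrum(_sine(1.0) + _sine(1.1, amp=0.9), FS)
        h_tight = ft.detect_harmonics(spec, min_separation=0.05)
        h_wide = ft.detect_harmonics(spec, min_separation=0.5)
        assert h_wide.n_harmonics <= h_tight.n_harmonics


class TestSpectralEntropy:
    def test_sine_is_nearly_pure(self):
        assert ft.spectral_entropy(ft.compute_spectrum(_sine(2.0), FS)) < 0.2

    def test_white_noise_is_nearly_uniform(self):
        rng = np.random.default_rng(2)
        spec = ft.compute_spectrum(rng.standard_normal(2048), FS)
        assert ft.spectral_entropy(spec) > 0.9

    @pytest.mark.parametrize("seed", range(3))
    def test_bounded_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        x = _sine(rng.uniform(0.5, 5)) + rng.uniform(0, 2) * rng.standard_normal(2000)
        h = ft.spectral_entropy(ft.compute_spectrum(x, FS))
        assert 0.0 <= h <= 1.0


class TestRegularity:
    def test_periodic_signal_near_one(self):
        assert ft.regularity(_sine(2.0)) >= 0.95

    def test_white_noise_near_zero(self):
        rng = np.random.default_rng(3)
        assert abs(ft.regularity(rng.standard_normal(2000))) < 0.2

    def test_noisy_periodic_in_between(self):
        rng = np.random.default_rng(4)
        x = _sine(2.0) + 0.8 * rng.standard_normal(2000)
        r = ft.regularity(x)
        assert 0.2 < r < 0.95

    def test_no_peak_returns_zero_with_warning(self):
        x = np.exp(-np.linspace(0, 5, 400))  # monotone decay autocorrelation
        with pytest.warns(UserWarning):
            assert ft.regularity(x) == 0.0


class TestDominantRatio:
    def test_pure_sine_concentrated(self):
        spec = ft.compute_spectrum(_sine(2.0), FS)
        assert ft.dominant_ratio(spec) >= 0.95

    def test_two_equal_tones_split_power(self):
        spec = ft.compute_spectrum(_sine(1.0) + _sine(3.0, phase=0.7), FS)
        assert ft.dominant_ratio(spec) == pytest.approx(0.5, abs=0.02)

    def test_in_unit_interval(self):
        rng = np.random.default_rng(5)
        spec = ft.compute_spectrum(rng.standard_normal(2000), FS)
        assert 0.0 < ft.dominant_ratio(spec) <= 1.0


class TestTimeFeatures:
    def test_square_wave_range_and_rms(self):
        x = np.tile([-1.0, 1.0], 500)
        tf = ft.time_features(x)
        assert tf["range"] == 2.0
        assert tf["rms"] == pytest.approx(1.0)
        assert tf["minimum"] == -1.0 and tf["maximum"] == 1.0

    def test_unit_sine_rms_closed_form(self):
        tf = ft.time_features(_sine(2.0))
        assert tf["rms"] == pytest.approx(1.0 / np.sqrt(2.0), rel=1e-3)

    def test_constant_signal_degenerate_values(self):
        tf = ft.time_features(np.full(100, 3.0))
        assert tf["standard_deviation"] == 0.0
        assert tf["entropy"] == 0.0
        assert tf["range"] == 0.0

    def test_cycle_amplitude_tracks_peak_to_peak(self):
        x = _sine(2.0)
        tf = ft.time_features(x)
        assert tf["mean_amplitude"] == pytest.approx(2.0, rel=0.01)


class TestMeanPeakValue:
    def test_arithmetic_mean_of_amplitudes(self):
        h = ft.HarmonicSet(peaks=[(1.0, 1.0, 0.1), (2.0, 0.5, 0.1)])
        assert ft.mean_peak_value(h) == pytest.approx(0.75)

    def test_invariant_to_order(self):
        a = ft.HarmonicSet(peaks=[(1.0, 1.0, 0.1), (2.0, 0.5, 0.1)])
        b = ft.HarmonicSet(peaks=[(2.0, 0.5, 0.1), (1.0, 1.0, 0.1)], dominant_index=1)
        assert ft.mean_peak_value(a) == ft.mean_peak_value(b)

    def test_empty_set_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert ft.mean_peak_value(ft.HarmonicSet(peaks=[])) == 0.0


class TestExtractFeatures:
    def test_schema_frozen_36_names(self, sev0_recording):
        fv = ft.extract_features(preprocess_recording(sev0_recording))
        assert tuple(sorted(fv.values)) == tuple(sorted(ft.FEATURE_NAMES))
        assert len(fv.values) == 36
        assert all(np.isfinite(v) for v in fv.values.values())

    def test_deterministic_bitwise(self, sev0_recording):
        a = ft.extract_features(preprocess_recording(sev0_recording))
        b = ft.extract_features(preprocess_recording(sev0_recording))
        assert a.values == b.values

    def test_faster_movement_raises_dominant_frequency(self):
        doms = []
        for freq_scale, sev in ((0, 0.0), (1, 2.0), (2, 3.5)):
            rec = simulate_recording(SeverityProfile.from_severity(sev), seed=10)
            fv = ft.extract_features(preprocess_recording(rec))
            doms.append(fv.values["dominant_frequency_omega_x"])
        assert doms[0] > doms[1] > doms[2]
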
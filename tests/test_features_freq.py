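import numpy as np
import pytest

from fallfusion.errors import ConfigError, DataError
from fallfusion.features_freq import (
    HIGH_LOW_SENTINEL,
    Spectrum,
    band_power_ratio,
    dominant_frequency,
    energy_complexity,
    power_spectrum,
    spectral_shape,
)

FS = 201.0


def bin_freq(k, n, fs=FS):
    return k * fs / n


class TestPowerSpectrum:
    def test_bin_centered_sine_concentrates_power(self):
        n = 1024
        f0 = bin_freq(40, n)
        t = np.arange(n) / FS
        S = power_spectrum(np.sin(2 * np.pi * f0 * t), FS)
        k = np.argmax(S.nondc_power)
        assert S.nondc_freqs[k] == pytest.approx(f0)
        assert S.nondc_power[k] / S.nondc_power.sum() > 0.99

    def test_constant_series_has_zero_power(self):
        S = power_spectrum(np.full(64, 5.0), FS)
        np.testing.assert_array_equal(S.power, 0.0)

    def test_two_sines_two_bins(self):
        n = 1024
        f1, f2 = bin_freq(20, n), bin_freq(60, n)
        t = np.arange(n) / FS
        S = power_spectrum(np.sin(2 * np.pi * f1 * t) + np.sin(2 * np.pi * f2 * t), FS)
        order = np.argsort(S.nondc_power)[::-1]
        top_freqs = sorted(S.nondc_freqs[order[:2]])
        assert top_freqs == pytest.approx([f1, f2])
        assert S.nondc_power[order[:2]].sum() / S.nondc_power.sum() > 0.99

    def test_parseval(self):
        rng = np.random.default_rng(11)
        for n in (64, 101, 256):
            x = rng.normal(size=n)
            xc = x - x.mean()
            S = power_spectrum(x, FS)
            total = 2 * S.power.sum() - S.power[0]
            if n % 2 == 0:
                total -= S.power[-1]  # Nyquist bin is not doubled
            assert total == pytest.approx(n * np.sum(xc**2), rel=1e-9)

    def test_short_series_rejected(self):
        with pytest.raises(DataError):
            power_spectrum(np.ones(7), FS)


class TestSpectralShape:
    def test_point_mass(self):
        n = 512
        f0 = bin_freq(30, n)
        t = np.arange(n) / FS
        f = spectral_shape(power_spectrum(np.sin(2 * np.pi * f0 * t), FS))
        assert f["spectral_centroid"] == pytest.approx(f0, abs=1e-6)
        assert f["spectral_spread"] == pytest.approx(0, abs=1e-3)
        assert f["spectral_entropy"] == pytest.approx(0, abs=1e-3)

    def test_flat_spectrum_maximizes_entropy(self):
        n_bins = 32
        S = Spectrum(freqs=np.linspace(0, FS / 2, n_bins + 1),
                     power=np.r_[0.0, np.ones(n_bins)], fs=FS, n=2 * n_bins)
        f = spectral_shape(S)
        assert f["spectral_entropy"] == pytest.approx(1.0)

    def test_two_equal_bins_moments(self):
        freqs = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        power = np.array([0.0, 0.0, 1.0, 0.0, 1.0])
        f = spectral_shape(Spectrum(freqs=freqs, power=power, fs=8.0, n=8))
        assert f["spectral_centroid"] == pytest.approx(3.0)
        assert f["spectral_spread"] == pytest.approx(1.0)

    def test_degenerate_spectrum_zeros(self):
        f = spectral_shape(power_spectrum(np.zeros(64), FS))
        assert f == {"spectral_centroid": 0.0, "spectral_spread": 0.0, "spectral_entropy": 0.0}

    def test_centroid_within_band_and_scale_invariant(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=400)
        S1 = power_spectrum(x, FS)
        S7 = power_spectrum(7.0 * x, FS)
        f1, f7 = spectral_shape(S1), spectral_shape(S7)
        assert S1.nondc_freqs[0] <= f1["spectral_centroid"] <= FS / 2
        assert f1["spectral_spread"] <= FS / 2
        for k in f1:
            assert f1[k] == pytest.approx(f7[k], rel=1e-9)


class TestDominantFrequency:
    def test_bin_centered_sine(self):
        n = 804  # 2.5 Hz is bin-centered: 2.5 * 804 / 201 = 10
        t = np.arange(n) / FS
        f = dominant_frequency(power_spectrum(np.sin(2 * np.pi * 2.5 * t), FS))
        assert f["dominant_frequency"] == pytest.approx(2.5)
        assert f["power_at_dominant"] > 0

    def test_constant_signal_degenerate(self):
        f = dominant_frequency(power_spectrum(np.ones(64), FS))
        assert f == {"dominant_frequency": 0.0, "power_at_dominant": 0.0}

    def test_tie_breaks_toward_lower_frequency(self):
        freqs = np.array([0.0, 1.0, 2.0, 3.0])
        power = np.array([0.0, 5.0, 1.0, 5.0])
        f = dominant_frequency(Spectrum(freqs=freqs, power=power, fs=8.0, n=8))
        assert f["dominant_frequency"] == 1.0


class TestBandPowerRatio:
    def spectrum(self, power):
        freqs = np.linspace(0, 4.0, len(power))
        return Spectrum(freqs=freqs, power=np.asarray(power, float), fs=8.0, n=2 * (len(power) - 1))

    def test_all_power_low(self):
        S = self.spectrum([0, 1, 1, 0, 0, 0, 0, 0, 0])
        assert band_power_ratio(S, (0.0, 2.0), (2.0, 4.0)) == 0.0

    def test_all_power_high_sentinel(self):
        S = self.spectrum([0, 0, 0, 0, 0, 0, 1, 1, 0])
        assert band_power_ratio(S, (0.0, 2.0), (2.0, 4.0)) == HIGH_LOW_SENTINEL

    def test_equal_power_ratio_one(self):
        S = self.spectrum([0, 1, 1, 0, 0, 1, 1, 0, 0])
        assert band_power_ratio(S, (0.0, 2.0), (2.0, 4.0)) == pytest.approx(1.0)

    def test_malformed_bands_rejected(self):
        S = self.spectrum([0, 1, 1, 0, 0, 1, 1, 0, 0])
        with pytest.raises(ConfigError):
            band_power_ratio(S, (0.0, 3.0), (2.0, 4.0))  # overlapping
        with pytest.raises(ConfigError):
            band_power_ratio(S, (0.0, 2.0), (2.0, 9.0))  # beyond Nyquist


class TestEnergyComplexity:
    def test_constant_series(self):
        f = energy_complexity(np.full(64, 3.0))
        assert f == {"signal_energy": 0.0, "shannon_entropy": 0.0}

    def test_sine_energy_is_half_amplitude_squared(self):
        t = np.arange(int(10 * FS)) / FS
        f = energy_complexity(np.sin(2 * np.pi * 1.0 * t))
        assert f["signal_energy"] == pytest.approx(0.5, rel=0.01)

    def test_uniform_amplitudes_maximize_entropy(self):
        rng = np.random.default_rng(123)
        f = energy_complexity(rng.uniform(size=100_000), bins=16)
        assert f["shannon_entropy"] == pytest.approx(1.0, abs=0.01)

    def test_energy_is_length_invariant_power(self):
        t = np.arange(int(4 * FS)) / FS
        short = energy_complexity(np.sin(2 * np.pi * 1.0 * t))
        t2 = np.arange(int(16 * FS)) / FS
        long = energy_complexity(np.sin(2 * np.pi * 1.0 * t2))
        assert short["signal_energy"] == pytest.approx(long["signal_energy"], rel=0.02)
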
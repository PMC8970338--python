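import numpy as np
import pytest
from hypothesis import given, strategies as st

from lfpseize.core_types import Band, BandScheme, ConfigurationError, MorseParams, ValidationError
from lfpseize.spectral import (
    BandedSpectrogram,
    NormalizedSpectrum,
    Spectrogram,
    band_power,
    bin_bands,
    banded_cwt,
    cwt,
    epoch_spectrum,
    frequency_grid,
    morse_wavelet_freq,
    normalize_spectrum,
)

VOICE = 2 ** (1 / 10)


class TestMorseWindow:
    def test_peak_location_closed_form(self):
        # gamma=3, beta=20 -> peak at (20/3)^(1/3)
        w = np.linspace(1e-6, 6, 2_000_001)
        vals = morse_wavelet_freq(3.0, 60.0, 1.0, w)
        w_peak = (20.0 / 3.0) ** (1.0 / 3.0)
        assert abs(w[np.argmax(vals)] - w_peak) < 2 * (w[1] - w[0])
        assert vals.max() == pytest.approx(2.0, rel=1e-9)

    def test_zero_and_negative_frequencies_vanish(self):
        vals = morse_wavelet_freq(3.0, 60.0, 1.0, np.array([-1.0, 0.0, 1.0]))
        assert vals[0] == 0.0 and vals[1] == 0.0 and vals[2] > 0.0

    def test_invalid_parameters(self):
        with pytest.raises(ValidationError):
            morse_wavelet_freq(0.0, 60.0, 1.0, np.ones(3))
        with pytest.raises(ValidationError):
            morse_wavelet_freq(3.0, 60.0, -1.0, np.ones(3))


class TestCWT:
    def test_grid_size_and_span(self):
        g = frequency_grid(MorseParams())
        assert g.size == 90
        assert g[0] == 1.0
        assert g[-1] < 500.0 <= g[-1] * VOICE

    def test_zero_signal_zero_magnitude(self):
        s = cwt(np.zeros(4000), 2000.0)
        assert np.all(s.magnitude == 0)

    def test_tone_argmax_within_one_voice(self):
        rate = 2000.0
        t = np.arange(int(10 * rate)) / rate
        s = cwt(np.cos(2 * np.pi * 50 * t), rate)
        f_hat = s.freq_grid_hz[np.argmax(s.magnitude.mean(axis=0))]
        assert f_hat / VOICE <= 50.0 <= f_hat * VOICE

    def test_two_tones_two_local_maxima(self):
        rate = 2000.0
        t = np.arange(int(10 * rate)) / rate
        x = np.cos(2 * np.pi * 10 * t) + np.cos(2 * np.pi * 200 * t)
        s = cwt(x, rate)
        prof = s.magnitude.mean(axis=0)
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(prof, prominence=0.2 * prof.max())
        assert peaks.size == 2
        for f0, p in zip((10.0, 200.0), peaks):
            f_hat = s.freq_grid_hz[p]
            assert f_hat / VOICE <= f0 <= f_hat * VOICE

    def test_matches_direct_convolution_oracle(self):
        """FFT-path coefficients equal direct time-domain correlation with a
        numerically integrated Morse wavelet."""
        rate = 200.0
        params = MorseParams(fmin_hz=2.0, fmax_hz=80.0)
        t = np.arange(int(4 * rate)) / rate
        x = np.cos(2 * np.pi * 20 * t)
        s = cwt(x, rate, params)
        g = frequency_grid(params)
        j = int(np.argmin(np.abs(g - 20.0)))
        scale = params.peak_omega / (2 * np.pi * g[j] / rate)
        om = np.linspace(0, np.pi, 20_001)
        win = morse_wavelet_freq(3.0, 60.0, scale, om)
        lags = np.arange(-600, 601)
        kernel = np.array(
            [np.trapezoid(win * np.exp(1j * om * k), om) / (2 * np.pi) for k in lags]
        )
        oracle = np.abs(np.convolve(x, np.conj(kernel[::-1]), mode="same"))
        core = slice(300, x.size - 300)
        err = np.max(np.abs(oracle[core] - s.magnitude[core, j]))
        assert err / s.magnitude[core, j].max() < 1e-6

    def test_tone_magnitude_matches_window_closed_form(self):
        """Time-averaged magnitude at each scale is A/2 * Psi(s*w0)."""
        rate = 200.0
        params = MorseParams(fmin_hz=2.0, fmax_hz=80.0)
        t = np.arange(int(4 * rate)) / rate
        s = cwt(np.cos(2 * np.pi * 20 * t), rate, params)
        g = frequency_grid(params)
        w0 = 2 * np.pi * 20 / rate
        core = slice(300, t.size - 300)
        meas = s.magnitude[core].mean(axis=0)
        for j, fj in enumerate(g):
            scale = params.peak_omega / (2 * np.pi * fj / rate)
            pred = 0.5 * morse_wavelet_freq(3.0, 60.0, scale, np.array([w0]))[0]
            if pred > 0.05:
                assert meas[j] == pytest.approx(pred, rel=1e-4)

    def test_linearity_of_magnitude(self, rng):
        x = rng.standard_normal(4000)
        a = cwt(x, 2000.0).magnitude
        b = cwt(3.5 * x, 2000.0).magnitude
        assert np.allclose(b, 3.5 * a, rtol=1e-5, atol=1e-7)

    def test_time_shift_covariance(self, rng):
        rate = 2000.0
        x = rng.standard_normal(int(6 * rate))
        shift = 400
        params = MorseParams(fmin_hz=4.0)  # narrower footprint for the check
        a = cwt(x, rate, params).magnitude
        b = cwt(np.roll(x, shift), rate, params).magnitude
        edge = int(2.5 * rate)
        assert np.allclose(
            b[edge + shift : -edge], a[edge : -edge - shift], rtol=1e-3, atol=1e-3
        )

    def test_fmax_above_nyquist_rejected(self):
        with pytest.raises(ValidationError):
            cwt(np.zeros(4000), 800.0)

    def test_short_input_rejected(self):
        with pytest.raises(ValidationError):
            cwt(np.zeros(100), 2000.0)

    def test_banded_cwt_equals_cwt_then_bin(self, rng):
        rate = 2000.0
        x = rng.standard_normal(int(3 * rate))
        full = bin_bands(cwt(x, rate))
        stream = banded_cwt(x, rate)
        assert np.allclose(stream.magnitude, full.magnitude, rtol=1e-5, atol=1e-7)


class TestBinBands:
    def _spec(self, mag, freqs):
        return Spectrogram(np.asarray(mag, float), np.asarray(freqs, float), 1e-3)

    def test_uniform_magnitude_gives_ones(self):
        g = frequency_grid(MorseParams())
        s = self._spec(np.ones((5, g.size)), g)
        out = bin_bands(s)
        assert np.allclose(out.magnitude, 1.0)

    def test_gamma_only_magnitude(self):
        g = frequency_grid(MorseParams())
        mag = np.zeros((4, g.size))
        mag[:, (g >= 30) & (g < 80)] = 1.0
        out = bin_bands(self._spec(mag, g))
        scheme = BandScheme()
        gi = scheme.index("gamma")
        assert np.allclose(out.magnitude[:, gi], 1.0)
        others = [i for i in range(len(scheme)) if i != gi]
        assert np.allclose(out.magnitude[:, others], 0.0)

    def test_matches_bruteforce_mean(self, rng):
        g = frequency_grid(MorseParams())
        mag = rng.random((7, g.size))
        out = bin_bands(self._spec(mag, g))
        scheme = BandScheme()
        for ti in range(7):
            for bi, band in enumerate(scheme.bands):
                vals = []
                for j, f in enumerate(g):
                    closed = bi == len(scheme) - 1
                    if band.low_hz <= f < band.high_hz or (closed and f == band.high_hz):
                        vals.append(mag[ti, j])
                assert out.magnitude[ti, bi] == pytest.approx(np.mean(vals))

    def test_empty_band_is_configuration_error(self):
        g = np.array([1.0, 2.0, 3.0])
        scheme = BandScheme((Band("lo", 1, 4), Band("hi", 100, 200)))
        with pytest.raises(ConfigurationError, match="hi"):
            bin_bands(self._spec(np.ones((2, 3)), g), scheme)


class TestEpochSpectrum:
    def test_tone_peak_bin(self):
        rate = 2000.0
        t = np.arange(int(30 * rate)) / rate
        f, a = epoch_spectrum(np.cos(2 * np.pi * 50 * t), rate)
        assert f[np.argmax(a)] == pytest.approx(50.0, abs=0.5)

    def test_amplitude_linearity(self, rng):
        rate = 2000.0
        x = rng.standard_normal(int(20 * rate))
        _, a1 = epoch_spectrum(x, rate)
        _, a2 = epoch_spectrum(2 * x, rate)
        assert np.allclose(a2, 2 * a1, rtol=1e-9)

    def test_white_noise_flat(self):
        """450-s white noise: amplitude flat over 10-400 Hz (Monte-Carlo
        calibrated: per-bin Welch scatter keeps >=99% of bins within 10%
        and every bin within 12%)."""
        from lfpseize.synthetic_data import generate_background

        x = generate_background(450, 2000.0, 0.0, 1.0, seed=3)
        f, a = epoch_spectrum(x, 2000.0)
        m = (f >= 10) & (f <= 400)
        rel = a[m] / a[m].mean()
        assert np.mean(np.abs(rel - 1) <= 0.10) >= 0.99
        assert np.max(np.abs(rel - 1)) < 0.12

    def test_epoch_shorter_than_segment_rejected(self):
        with pytest.raises(ValidationError):
            epoch_spectrum(np.zeros(1000), 2000.0)


class TestNormalization:
    def test_identical_spectra_ratio_one(self, rng):
        f = np.linspace(1, 500, 999)
        a = rng.random(999) + 0.5
        norm = normalize_spectrum((f, a), (f, a.copy()))
        assert np.allclose(norm.ratio, 1.0, atol=1e-12)

    def test_double_amplitude_ratio_two(self, rng):
        f = np.linspace(1, 500, 999)
        a = rng.random(999) + 0.5
        norm = normalize_spectrum((f, 2 * a), (f, a))
        assert np.allclose(norm.ratio, 2.0)

    def test_tone_added_in_exposure_elevates_locally(self):
        rate = 2000.0
        from lfpseize.synthetic_data import generate_background

        base = generate_background(60, rate, 0.0, 1.0, seed=6)
        t = np.arange(base.size) / rate
        expo = base + 2.0 * np.sin(2 * np.pi * 100 * t)
        norm = normalize_spectrum(epoch_spectrum(expo, rate), epoch_spectrum(base, rate))
        near = np.abs(norm.freq_grid_hz - 100) <= 1
        far = ~((np.abs(norm.freq_grid_hz - 100) <= 10))
        assert norm.ratio[near].mean() > 3
        assert abs(norm.ratio[far].mean() - 1) < 0.1

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValidationError):
            normalize_spectrum(
                (np.arange(1, 5.0), np.ones(4)), (np.arange(2, 6.0), np.ones(4))
            )

    def test_zero_baseline_bin_rejected(self):
        f = np.arange(1, 5.0)
        with pytest.raises(ValidationError):
            normalize_spectrum((f, np.ones(4)), (f, np.array([1.0, 0.0, 1.0, 1.0])))


class TestBandPower:
    def test_unit_ratio_gives_unit_bands(self):
        f = np.arange(1.0, 500.5, 0.5)
        out = band_power(NormalizedSpectrum(np.ones(f.size), f))
        assert all(v == pytest.approx(1.0) for v in out.values())

    def test_gamma_only_elevation(self):
        f = np.arange(1.0, 500.5, 0.5)
        r = np.ones(f.size)
        r[(f >= 30) & (f < 80)] = 2.0
        out = band_power(NormalizedSpectrum(r, f))
        assert out["gamma"] == pytest.approx(2.0)
        assert all(out[k] == pytest.approx(1.0) for k in out if k != "gamma")

    def test_matches_bruteforce(self, rng):
        f = np.arange(1.0, 500.5, 0.5)
        r = rng.random(f.size) + 0.1
        out = band_power(NormalizedSpectrum(r, f))
        scheme = BandScheme()
        for bi, band in enumerate(scheme.bands):
            vals = [
                ri
                for fi, ri in zip(f, r)
                if band.low_hz <= fi < band.high_hz
                or (bi == len(scheme) - 1 and fi == band.high_hz)
            ]
            assert out[band.name] == pytest.approx(np.mean(vals))


@given(st.floats(min_value=0.1, max_value=10.0))
def test_cwt_scale_invariance_of_argmax(a):
    """Scaling the input rescales magnitudes but never moves the argmax."""
    rate = 500.0
    t = np.arange(int(4 * rate)) / rate
    x = np.cos(2 * np.pi * 30 * t)
    params = MorseParams(fmin_hz=4.0, fmax_hz=120.0)
    s1 = cwt(x, rate, params).magnitude.mean(axis=0)
    s2 = cwt(a * x, rate, params).magnitude.mean(axis=0)
    assert np.argmax(s1) == np.argmax(s2)
    # magnitudes are stored in float32; averaging leaves ~1e-4 relative noise
    assert np.allclose(s2, a * s1, rtol=1e-3, atol=1e-6)
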
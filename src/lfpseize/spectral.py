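"""Time-frequency analysis: Morse-wavelet CWT, band binning, Welch spectra.

The continuous wavelet transform uses the analytic generalized Morse wavelet
family.  In the frequency domain the (unit-scale) window is

    Psi(w) = a * w^beta * exp(-w^gamma),   w > 0;   Psi(w) = 0,  w <= 0,

with symmetry parameter gamma and decay parameter beta.  The
"time-bandwidth product" P^2 = beta*gamma names the family member, so the
defaults gamma = 3, P^2 = 60 give beta = 20.  The window peaks at
w_peak = (beta/gamma)^(1/gamma); the normalization constant ``a`` is chosen
so the peak value is 2 (analytic-signal convention), which makes the CWT
magnitude of a unit-amplitude tone ~1 at the tone's own scale, i.e.
magnitudes are directly comparable across scales.

Frequencies are laid out geometrically at ``voices_per_octave`` steps per
octave; coefficients are computed by frequency-domain multiplication with a
zero-padded FFT of the input, one inverse transform per scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft
from scipy import signal

from .core_types import (
    BandScheme,
    ConfigurationError,
    MorseParams,
    ValidationError,
)

__all__ = [
    "Spectrogram",
    "BandedSpectrogram",
    "NormalizedSpectrum",
    "morse_wavelet_freq",
    "frequency_grid",
    "wavelet_footprint_s",
    "cwt",
    "banded_cwt",
    "bin_bands",
    "epoch_spectrum",
    "normalize_spectrum",
    "band_power",
]


@dataclass
class Spectrogram:
    """time x frequency magnitude matrix on a geometric frequency grid."""

    magnitude: np.ndarray  # (n_times, n_freqs), non-negative
    freq_grid_hz: np.ndarray
    time_step_s: float

    def __post_init__(self) -> None:
        if self.magnitude.ndim != 2:
            raise ValidationError("magnitude must be 2-D (time x frequency)")
        if self.magnitude.shape[1] != self.freq_grid_hz.size:
            raise ValidationError("magnitude columns must match frequency grid length")
        if np.any(np.diff(self.freq_grid_hz) <= 0):
            raise ValidationError("frequency grid must be strictly increasing")


@dataclass
class BandedSpectrogram:
    """time x band magnitude matrix (mean of member-frequency magnitudes)."""

    magnitude: np.ndarray  # (n_times, n_bands)
    band_scheme: BandScheme
    time_step_s: float
    time_offset_s: float = 0.0

    def __post_init__(self) -> None:
        if self.magnitude.shape[1] != len(self.band_scheme):
            raise ValidationError(
                f"expected {len(self.band_scheme)} band columns, "
                f"got {self.magnitude.shape[1]}"
            )

    @property
    def n_times(self) -> int:
        return self.magnitude.shape[0]


@dataclass
class NormalizedSpectrum:
    """Per-frequency exposure/baseline amplitude ratio."""

    ratio: np.ndarray
    freq_grid_hz: np.ndarray


def morse_wavelet_freq(
    gamma: float, time_bandwidth: float, scale: float, omega: np.ndarray
) -> np.ndarray:
    """Morse window evaluated at ``scale * omega`` (angular frequency).

    Returns ``a * (s*w)^beta * exp(-(s*w)^gamma)`` for ``w > 0`` and 0 for
    ``w <= 0``, normalized so the value at the peak ``s*w = w_peak`` is 2.
    Evaluation is done in the log domain for numerical stability.
    """
    if gamma <= 0 or time_bandwidth <= 0:
        raise ValidationError("gamma and time_bandwidth must be > 0")
    if scale <= 0:
        raise ValidationError(f"scale must be > 0, got {scale}")
    beta = time_bandwidth / gamma
    omega = np.asarray(omega, dtype=float)
    sw = scale * omega
    out = np.zeros_like(sw)
    pos = sw > 0
    w_peak = (beta / gamma) ** (1.0 / gamma)
    log_peak = beta * np.log(w_peak) - w_peak**gamma
    log_val = beta * np.log(sw[pos]) - sw[pos] ** gamma - log_peak
    out[pos] = 2.0 * np.exp(log_val)
    return out


def frequency_grid(params: MorseParams) -> np.ndarray:
    """Geometric grid fmin * 2^(k/voices), k = 0..floor(voices*log2(fmax/fmin))."""
    n_octaves = np.log2(params.fmax_hz / params.fmin_hz)
    k = np.arange(int(np.floor(params.voices_per_octave * n_octaves)) + 1)
    return params.fmin_hz * 2.0 ** (k / params.voices_per_octave)


def wavelet_footprint_s(params: MorseParams, freq_hz: float | None = None) -> float:
    """Approximate time-domain footprint of the wavelet at ``freq_hz``.

    The Morse wavelet spans roughly P = sqrt(beta*gamma) cycles, so the
    footprint at frequency f is ~P/f seconds.  Defaults to the lowest
    analyzed frequency (the widest wavelet), which is the cone-of-influence
    width excluded from baseline statistics at each epoch edge.
    """
    f = params.fmin_hz if freq_hz is None else freq_hz
    return float(np.sqrt(params.time_bandwidth) / f)


def _cwt_rows(samples: np.ndarray, rate: float, params: MorseParams):
    """Yield (scale index, complex coefficient row) for each grid frequency."""
    x = np.asarray(samples, dtype=np.float64)
    n = x.size
    if n < rate:
        raise ValidationError(f"need at least 1 s of samples, got {n / rate:.3f} s")
    if params.fmax_hz > rate / 2:
        raise ValidationError(
            f"fmax {params.fmax_hz} Hz exceeds Nyquist {rate / 2} Hz"
        )
    freqs = frequency_grid(params)
    pad = int(np.ceil(wavelet_footprint_s(params) * rate))
    nfft = sp_fft.next_fast_len(n + 2 * pad, real=False)
    buf = np.zeros(nfft)
    buf[pad : pad + n] = x
    X = sp_fft.fft(buf)
    omega = np.zeros(nfft)
    half = nfft // 2
    omega[: half + 1] = 2 * np.pi * np.arange(half + 1) / nfft
    # negative-frequency half stays zero -> analytic wavelet
    w_peak = params.peak_omega
    for j, f in enumerate(freqs):
        s = w_peak / (2 * np.pi * f / rate)
        win = morse_wavelet_freq(params.symmetry_gamma, params.time_bandwidth, s, omega)
        win[half + 1 :] = 0.0
        row = sp_fft.ifft(X * win)[pad : pad + n]
        yield j, row
    return


def cwt(samples: np.ndarray, rate: float, params: MorseParams | None = None) -> Spectrogram:
    """Continuous wavelet transform magnitude on the geometric grid.

    Stores magnitudes as float32 (time x frequency); for long traces where
    only band averages are needed, :func:`banded_cwt` avoids materializing
    the full matrix.
    """
    params = params or MorseParams()
    freqs = frequency_grid(params)
    n = np.asarray(samples).size
    mag = np.empty((n, freqs.size), dtype=np.float32)
    for j, row in _cwt_rows(samples, rate, params):
        mag[:, j] = np.abs(row)
    return Spectrogram(magnitude=mag, freq_grid_hz=freqs, time_step_s=1.0 / rate)


def banded_cwt(
    samples: np.ndarray,
    rate: float,
    params: MorseParams | None = None,
    scheme: BandScheme | None = None,
    time_offset_s: float = 0.0,
) -> BandedSpectrogram:
    """CWT accumulated directly into band columns (streaming over scales)."""
    params = params or MorseParams()
    scheme = scheme or BandScheme()
    freqs = frequency_grid(params)
    idx = scheme.membership(freqs)
    _check_band_coverage(idx, scheme)
    n = np.asarray(samples).size
    acc = np.zeros((n, len(scheme)), dtype=np.float64)
    counts = np.zeros(len(scheme), dtype=np.int64)
    for j, row in _cwt_rows(samples, rate, params):
        b = idx[j]
        if b < 0:
            continue
        acc[:, b] += np.abs(row)
        counts[b] += 1
    acc /= counts
    return BandedSpectrogram(
        magnitude=acc,
        band_scheme=scheme,
        time_step_s=1.0 / rate,
        time_offset_s=time_offset_s,
    )


def _check_band_coverage(idx: np.ndarray, scheme: BandScheme) -> None:
    for b, band in enumerate(scheme.bands):
        if not np.any(idx == b):
            raise ConfigurationError(
                f"band {band.name!r} [{band.low_hz}, {band.high_hz}] Hz contains "
                "no grid frequency"
            )


def bin_bands(spec: Spectrogram, scheme: BandScheme | None = None) -> BandedSpectrogram:
    """Average spectrogram columns into bands (unweighted mean per band)."""
    scheme = scheme or BandScheme()
    idx = scheme.membership(spec.freq_grid_hz)
    _check_band_coverage(idx, scheme)
    out = np.empty((spec.magnitude.shape[0], len(scheme)), dtype=np.float64)
    for b in range(len(scheme)):
        out[:, b] = spec.magnitude[:, idx == b].mean(axis=1)
    return BandedSpectrogram(magnitude=out, band_scheme=scheme, time_step_s=spec.time_step_s)


def epoch_spectrum(
    samples: np.ndarray,
    rate: float,
    welch_segment_s: float = 2.0,
    welch_overlap: float = 0.5,
    fmin_hz: float = 1.0,
    fmax_hz: float = 500.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Amplitude spectrum of an epoch by Welch averaging.

    Hann segments of ``welch_segment_s`` seconds with fractional overlap
    ``welch_overlap``; returns (frequencies, sqrt of the averaged
    periodogram) restricted to [fmin, fmax] Hz.
    """
    x = np.asarray(samples, dtype=np.float64)
    nperseg = int(round(welch_segment_s * rate))
    if nperseg > x.size:
        raise ValidationError(
            f"epoch of {x.size / rate:.2f} s shorter than one "
            f"{welch_segment_s}-s Welch segment"
        )
    if not (0 <= welch_overlap < 1):
        raise ValidationError(f"welch_overlap must be in [0, 1), got {welch_overlap}")
    freqs, pxx = signal.welch(
        x,
        fs=rate,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(welch_overlap * nperseg)),
        detrend="constant",
    )
    mask = (freqs >= fmin_hz) & (freqs <= fmax_hz)
    return freqs[mask], np.sqrt(pxx[mask])


def normalize_spectrum(
    exposure_spec: tuple[np.ndarray, np.ndarray],
    baseline_spec: tuple[np.ndarray, np.ndarray],
) -> NormalizedSpectrum:
    """Pointwise exposure/baseline amplitude ratio on a shared grid."""
    f_e, a_e = exposure_spec
    f_b, a_b = baseline_spec
    if f_e.shape != f_b.shape or not np.allclose(f_e, f_b):
        raise ValidationError("exposure and baseline spectra must share a frequency grid")
    if np.any(a_b <= 0):
        raise ValidationError("baseline spectrum has a zero bin; cannot normalize")
    return NormalizedSpectrum(ratio=a_e / a_b, freq_grid_hz=f_e.copy())


def band_power(norm: NormalizedSpectrum, scheme: BandScheme | None = None) -> dict[str, float]:
    """Mean normalized amplitude per band (the Fig-style band summary)."""
    scheme = scheme or BandScheme()
    idx = scheme.membership(norm.freq_grid_hz)
    _check_band_coverage(idx, scheme)
    return {
        band.name: float(norm.ratio[idx == b].mean())
        for b, band in enumerate(scheme.bands)
    }
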
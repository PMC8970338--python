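"""Shared domain types and parameter bundles for the LFP analysis pipeline.

The pipeline analyses single-channel local field potential (LFP) recordings
from larval zebrafish.  Each recording has a drug-free *baseline* epoch and a
drug *exposure* epoch; every downstream stage (spectral decomposition, event
detection, envelope AUC, band statistics) consumes the types defined here.

Conventions
-----------
* Time coordinates are seconds from recording start; sample indices are
  0-based.
* Frequency bands are half-open intervals ``[low, high)`` except the final
  HFO band, which is closed at its upper edge.  Frequencies falling in the
  deliberate 7-8 Hz and 13-15 Hz gaps belong to no band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "LfpSeizeError",
    "ValidationError",
    "FormatError",
    "DataError",
    "BoundsError",
    "ConfigurationError",
    "EpochScheme",
    "Recording",
    "PreprocParams",
    "MorseParams",
    "Band",
    "BandScheme",
    "DEFAULT_BANDS",
    "DetectionParams",
    "AUCParams",
]


class LfpSeizeError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(LfpSeizeError, ValueError):
    """A parameter bundle or input violated a documented invariant."""


class FormatError(LfpSeizeError, ValueError):
    """A file could not be parsed or lacked required metadata."""


class DataError(LfpSeizeError, ValueError):
    """Sample data is unusable (e.g. NaN voltages)."""


class BoundsError(LfpSeizeError, IndexError):
    """A requested epoch or window lies outside the recording."""


class ConfigurationError(LfpSeizeError, ValueError):
    """A configuration is internally inconsistent (e.g. an empty band)."""


@dataclass(frozen=True)
class EpochScheme:
    """Positions (seconds from recording start) of the two analysis epochs.

    Defaults follow the study protocol: 7.5 min of drug-free baseline, then
    compound addition, with the exposure epoch defined as minutes 17.5-25 so
    the compound has 10 min to equilibrate.
    """

    baseline_start: float = 0.0
    baseline_end: float = 450.0
    exposure_start: float = 1050.0
    exposure_end: float = 1500.0

    def __post_init__(self) -> None:
        if not (
            0 <= self.baseline_start
            < self.baseline_end
            <= self.exposure_start
            < self.exposure_end
        ):
            raise ValidationError(
                "epochs must satisfy 0 <= baseline_start < baseline_end "
                "<= exposure_start < exposure_end, got "
                f"[{self.baseline_start}, {self.baseline_end}] / "
                f"[{self.exposure_start}, {self.exposure_end}]"
            )

    @property
    def baseline_duration(self) -> float:
        return self.baseline_end - self.baseline_start

    @property
    def exposure_duration(self) -> float:
        return self.exposure_end - self.exposure_start

    def span(self, which: str) -> tuple[float, float]:
        if which == "baseline":
            return self.baseline_start, self.baseline_end
        if which == "exposure":
            return self.exposure_start, self.exposure_end
        raise ValidationError(f"unknown epoch {which!r}; expected 'baseline' or 'exposure'")


@dataclass
class Recording:
    """One animal's voltage trace plus the metadata needed to analyse it.

    ``samples`` are microvolt-scaled voltages in arbitrary units; absolute
    calibration is never needed because every reported quantity is
    baseline-normalized within animal.
    """

    animal_id: str
    group_label: str
    samples: np.ndarray
    sampling_rate: float
    epoch_scheme: EpochScheme = field(default_factory=EpochScheme)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sampling_rate <= 0:
            raise ValidationError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValidationError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            bad = int(np.flatnonzero(~np.isfinite(self.samples))[0])
            raise DataError(f"non-finite sample at index {bad}")
        # Half-sample slack so that an exactly exposure_end-long trace passes.
        if self.duration + 0.5 / self.sampling_rate < self.epoch_scheme.exposure_end:
            raise ValidationError(
                f"trace duration {self.duration:.3f} s shorter than "
                f"exposure_end {self.epoch_scheme.exposure_end} s"
            )

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    def replace_samples(self, samples: np.ndarray, sampling_rate: float | None = None) -> "Recording":
        return Recording(
            animal_id=self.animal_id,
            group_label=self.group_label,
            samples=samples,
            sampling_rate=self.sampling_rate if sampling_rate is None else sampling_rate,
            epoch_scheme=self.epoch_scheme,
        )


@dataclass(frozen=True)
class PreprocParams:
    """Downsampling and band-pass filtering parameters.

    The study recorded at 10 kHz, decimated to 2 kHz, and band-passed 1-500 Hz
    with a Butterworth filter to retain LFP while rejecting unit spiking.
    Filter order and zero-phase application are not dictated by the protocol;
    order 4 applied forward-backward preserves event timing.
    """

    raw_rate: float = 10_000.0
    target_rate: float = 2_000.0
    highpass_hz: float = 1.0
    lowpass_hz: float = 500.0
    filter_order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.highpass_hz < self.lowpass_hz <= self.target_rate / 2):
            raise ValidationError(
                f"need 0 < highpass ({self.highpass_hz}) < lowpass ({self.lowpass_hz}) "
                f"<= target Nyquist ({self.target_rate / 2})"
            )
        if self.filter_order < 1:
            raise ValidationError(f"filter_order must be >= 1, got {self.filter_order}")
        ratio = self.raw_rate / self.target_rate
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValidationError(
                f"target_rate {self.target_rate} must divide raw_rate {self.raw_rate}"
            )


@dataclass(frozen=True)
class MorseParams:
    """Generalized Morse wavelet parameters for the CWT.

    ``time_bandwidth`` is the product P^2 = beta*gamma, so the default
    gamma=3, time_bandwidth=60 corresponds to beta=20.
    """

    symmetry_gamma: float = 3.0
    time_bandwidth: float = 60.0
    voices_per_octave: int = 10
    fmin_hz: float = 1.0
    fmax_hz: float = 500.0

    def __post_init__(self) -> None:
        if self.symmetry_gamma <= 0:
            raise ValidationError(f"symmetry_gamma must be > 0, got {self.symmetry_gamma}")
        if self.time_bandwidth <= 0:
            raise ValidationError(f"time_bandwidth must be > 0, got {self.time_bandwidth}")
        if self.voices_per_octave < 1:
            raise ValidationError(
                f"voices_per_octave must be >= 1, got {self.voices_per_octave}"
            )
        if not (0 < self.fmin_hz < self.fmax_hz):
            raise ValidationError(
                f"need 0 < fmin ({self.fmin_hz}) < fmax ({self.fmax_hz})"
            )

    @property
    def beta(self) -> float:
        """Decay parameter beta = time_bandwidth / gamma."""
        return self.time_bandwidth / self.symmetry_gamma

    @property
    def peak_omega(self) -> float:
        """Peak angular frequency (beta/gamma)^(1/gamma) of the wavelet window."""
        return (self.beta / self.symmetry_gamma) ** (1.0 / self.symmetry_gamma)


@dataclass(frozen=True)
class Band:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValidationError(
                f"band {self.name!r}: need 0 < low ({self.low_hz}) < high ({self.high_hz})"
            )


# EEG-convention bands; the 7-8 and 13-15 Hz gaps are intentional.
DEFAULT_BANDS: tuple[Band, ...] = (
    Band("delta", 1.0, 4.0),
    Band("theta", 4.0, 7.0),
    Band("alpha", 8.0, 13.0),
    Band("beta", 15.0, 30.0),
    Band("gamma", 30.0, 80.0),
    Band("high_gamma", 80.0, 150.0),
    Band("hfo", 150.0, 500.0),
)

#: Pretty labels for figures / reports.
BAND_DISPLAY = {
    "delta": "δ",
    "theta": "θ",
    "alpha": "α/μ",
    "beta": "β",
    "gamma": "γ",
    "high_gamma": "high γ",
    "hfo": "HFO",
}


@dataclass(frozen=True)
class BandScheme:
    """An ordered, non-overlapping set of named frequency bands.

    Membership is half-open [low, high) for every band except the last,
    which is closed at its upper edge, so the analyzed grid partitions
    cleanly at the printed band edges.
    """

    bands: tuple[Band, ...] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        if len(self.bands) == 0:
            raise ValidationError("band scheme must contain at least one band")
        names = [b.name for b in self.bands]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate band names in {names}")
        for a, b in zip(self.bands, self.bands[1:]):
            if b.low_hz < a.high_hz:
                raise ValidationError(
                    f"bands must be non-overlapping and increasing: "
                    f"{a.name} [{a.low_hz},{a.high_hz}) overlaps {b.name}"
                )

    def __len__(self) -> int:
        return len(self.bands)

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.bands]

    def index(self, name: str) -> int:
        for i, b in enumerate(self.bands):
            if b.name == name:
                return i
        raise ConfigurationError(f"no band named {name!r}; have {self.names}")

    def band(self, name: str) -> Band:
        return self.bands[self.index(name)]

    def membership(self, freqs_hz: Sequence[float]) -> np.ndarray:
        """Band index per frequency (-1 for gap frequencies).

        The last band is closed at its upper edge; all others are
        half-open [low, high).
        """
        f = np.asarray(freqs_hz, dtype=float)
        out = np.full(f.shape, -1, dtype=int)
        last = len(self.bands) - 1
        for i, b in enumerate(self.bands):
            if i == last:
                mask = (f >= b.low_hz) & (f <= b.high_hz)
            else:
                mask = (f >= b.low_hz) & (f < b.high_hz)
            out[mask] = i
        return out


@dataclass(frozen=True)
class DetectionParams:
    """Spectral-event detector parameters.

    An event is a 1-s window whose 7-band spectrum deviates from the
    baseline profile; candidate peaks must exceed the baseline mean by
    ``threshold_sd`` baseline standard deviations.
    """

    threshold_sd: float = 2.0
    event_duration: float = 1.0
    min_separation: float = 1.0

    def __post_init__(self) -> None:
        if self.threshold_sd <= 0:
            raise ValidationError(f"threshold_sd must be > 0, got {self.threshold_sd}")
        if self.event_duration <= 0:
            raise ValidationError(f"event_duration must be > 0, got {self.event_duration}")
        if self.min_separation <= 0:
            raise ValidationError(f"min_separation must be > 0, got {self.min_separation}")


@dataclass(frozen=True)
class AUCParams:
    """Hilbert-envelope AUC parameters (bin width in seconds)."""

    bin_seconds: float = 30.0

    def __post_init__(self) -> None:
        if self.bin_seconds <= 0:
            raise ValidationError(f"bin_seconds must be > 0, got {self.bin_seconds}")
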
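"""Synthetic LFP cohorts with known ground truth.

The study's recordings are not deposited, so every downstream stage is
exercised against synthetic single-channel traces that emulate their salient
structure: a 1/f-like background, periodic visual-stimulus evoked deflections
during the baseline epoch, and during the exposure epoch a group-specific
multiplicative modulation of band-limited power plus transient ~1-s
band-limited oscillatory bursts ("events") with recorded ground truth.

The generator is a pure function of its parameters and a master seed:
regenerating a cohort with the same inputs yields bit-identical traces.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal

from .core_types import (
    BandScheme,
    EpochScheme,
    Recording,
    ValidationError,
)

__all__ = [
    "BurstSpec",
    "GroupProfile",
    "SyntheticTruth",
    "generate_background",
    "add_stimulus_artifacts",
    "burst_waveform",
    "inject_burst",
    "apply_band_gains",
    "generate_cohort",
    "write_truths",
]

#: Default stimulus-evoked deflection amplitude, in multiples of background
#: RMS.  Evoked LFP deflections are visible above, but comparable to, ongoing
#: background activity.
DEFAULT_STIMULUS_AMPLITUDE = 2.0

#: Default 1/f exponent and RMS of the pink-noise background.
DEFAULT_EXPONENT = 1.0
DEFAULT_RMS = 1.0


@dataclass(frozen=True)
class BurstSpec:
    """One injected band-limited oscillatory burst."""

    center_time: float
    center_freq_hz: float
    duration: float = 1.0
    relative_amplitude: float = 6.0
    envelope: str = "hann"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValidationError(f"burst duration must be > 0, got {self.duration}")
        if self.relative_amplitude < 0:
            raise ValidationError(
                f"relative_amplitude must be >= 0, got {self.relative_amplitude}"
            )
        if self.envelope not in ("hann", "boxcar"):
            raise ValidationError(f"envelope must be 'hann' or 'boxcar', got {self.envelope!r}")


@dataclass(frozen=True)
class GroupProfile:
    """How one treatment group modifies the exposure epoch.

    ``band_gain`` maps band names to multiplicative amplitude factors applied
    to the band-limited background component during exposure (all-ones =
    control-like).  ``n_bursts_exposure`` oscillatory bursts at
    ``burst_amplitude`` x background RMS are injected in the named band.
    """

    group_label: str
    band_gain: dict[str, float] = field(default_factory=dict)
    n_bursts_exposure: int = 0
    burst_band: str = "gamma"
    burst_amplitude: float = 6.0

    def __post_init__(self) -> None:
        for name, g in self.band_gain.items():
            if g <= 0:
                raise ValidationError(f"band_gain[{name!r}] must be > 0, got {g}")
        if self.n_bursts_exposure < 0:
            raise ValidationError(
                f"n_bursts_exposure must be >= 0, got {self.n_bursts_exposure}"
            )
        if self.burst_amplitude < 0:
            raise ValidationError(f"burst_amplitude must be >= 0, got {self.burst_amplitude}")


@dataclass
class SyntheticTruth:
    """Ground truth for one generated recording."""

    animal_id: str
    group_label: str
    bursts: list[BurstSpec]
    profile: GroupProfile
    seed: int


def generate_background(
    duration: float,
    rate: float,
    one_over_f_exponent: float = DEFAULT_EXPONENT,
    rms: float = DEFAULT_RMS,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Gaussian 1/f^exponent background noise scaled to the requested RMS.

    Shaping is done in the frequency domain: white Gaussian noise is
    multiplied by f^(-exponent/2) (amplitude scaling, so power goes as
    1/f^exponent), the DC bin is zeroed, and the result is rescaled to
    ``rms``.  Deterministic given ``seed``.
    """
    if duration <= 0 or rate <= 0 or rms <= 0:
        raise ValidationError(
            f"duration ({duration}), rate ({rate}) and rms ({rms}) must all be > 0"
        )
    n = int(round(duration * rate))
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    if one_over_f_exponent == 0:
        x = white
    else:
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, d=1.0 / rate)
        shaping = np.zeros_like(freqs)
        shaping[1:] = freqs[1:] ** (-one_over_f_exponent / 2.0)
        x = np.fft.irfft(spec * shaping, n=n)
    x_rms = float(np.sqrt(np.mean(x**2)))
    return x * (rms / x_rms)


def _stimulus_template(rate: float, flash_duration: float, gap: float, amplitude: float) -> np.ndarray:
    """Paired evoked deflections: one 20-ms biphasic deflection per flash."""
    deflection_s = 0.02
    n_defl = max(int(round(deflection_s * rate)), 2)
    t = np.arange(n_defl) / rate
    deflection = amplitude * np.sin(2 * np.pi * t / deflection_s)
    span = int(round((flash_duration + gap) * rate)) + n_defl
    template = np.zeros(span)
    template[:n_defl] += deflection
    off = int(round((flash_duration + gap) * rate))
    template[off : off + n_defl] += deflection
    return template


def add_stimulus_artifacts(
    samples: np.ndarray,
    rate: float,
    flash_period: float = 4.5,
    flash_duration: float = 0.1,
    gap: float = 0.5,
    amplitude: float = DEFAULT_STIMULUS_AMPLITUDE,
) -> np.ndarray:
    """Add periodic paired visual-stimulus evoked deflections.

    The stimulus protocol delivers two 100-ms flashes separated by a 500-ms
    gap, repeated every 4.5 s; each flash evokes a biphasic 20-ms deflection.
    Returns a modified copy; ``amplitude`` 0 is a no-op.
    """
    if flash_period <= 0 or flash_duration <= 0 or gap <= 0:
        raise ValidationError("flash_period, flash_duration and gap must all be > 0")
    template = _stimulus_template(rate, flash_duration, gap, amplitude)
    if template.size > int(round(flash_period * rate)):
        raise ValidationError(
            f"stimulus template ({template.size / rate:.3f} s) longer than "
            f"flash_period ({flash_period} s)"
        )
    out = np.array(samples, dtype=np.float64, copy=True)
    if amplitude == 0:
        return out
    onset = 0
    step = flash_period * rate
    k = 0
    while True:
        start = int(round(k * step)) + onset
        if start + template.size > out.size:
            break
        out[start : start + template.size] += template
        k += 1
    return out


def burst_waveform(n_total: int, rate: float, spec: BurstSpec, background_rms: float) -> np.ndarray:
    """Full-length waveform containing just the burst described by ``spec``."""
    if spec.center_freq_hz >= rate / 2:
        raise ValidationError(
            f"burst center_freq {spec.center_freq_hz} Hz >= Nyquist {rate / 2} Hz"
        )
    start_s = spec.center_time - spec.duration / 2
    i0 = int(round(start_s * rate))
    n = int(round(spec.duration * rate))
    if i0 < 0 or i0 + n > n_total:
        raise ValidationError(
            f"burst at {spec.center_time} s (duration {spec.duration} s) "
            f"outside trace of {n_total / rate:.1f} s"
        )
    t = np.arange(n) / rate
    if spec.envelope == "hann":
        env = np.hanning(n)
    else:
        env = np.ones(n)
    wave = np.zeros(n_total)
    wave[i0 : i0 + n] = (
        spec.relative_amplitude * background_rms * env * np.sin(2 * np.pi * spec.center_freq_hz * t)
    )
    return wave


def inject_burst(
    samples: np.ndarray, rate: float, spec: BurstSpec, background_rms: float = DEFAULT_RMS
) -> np.ndarray:
    """Add an enveloped sinusoidal burst; returns a modified copy."""
    out = np.array(samples, dtype=np.float64, copy=True)
    out += burst_waveform(out.size, rate, spec, background_rms)
    return out


def apply_band_gains(
    samples: np.ndarray,
    rate: float,
    gains: dict[str, float],
    window: tuple[float, float],
    scheme: BandScheme | None = None,
    ramp_s: float = 0.25,
) -> np.ndarray:
    """Multiply band-limited components by per-band gains inside ``window``.

    The background is decomposed per band by forward-backward Butterworth
    band-pass filtering (order 6: narrow transition keeps the gain local to
    the named band) and re-mixed as x + (gain-1) * component, restricted to
    the window with a short cosine on/off ramp to avoid step discontinuities.
    """
    scheme = scheme or BandScheme()
    out = np.array(samples, dtype=np.float64, copy=True)
    i0 = int(round(window[0] * rate))
    i1 = int(round(window[1] * rate))
    if i0 < 0 or i1 > out.size or i0 >= i1:
        raise ValidationError(f"gain window {window} outside trace")
    n_ramp = min(int(round(ramp_s * rate)), (i1 - i0) // 4)
    taper = np.ones(i1 - i0)
    if n_ramp > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        taper[:n_ramp] = ramp
        taper[-n_ramp:] = ramp[::-1]
    nyq = rate / 2
    for name, g in gains.items():
        if g == 1.0:
            continue
        band = scheme.band(name)
        hi = min(band.high_hz, nyq * 0.999)
        sos = signal.butter(6, [band.low_hz, hi], btype="bandpass", fs=rate, output="sos")
        comp = signal.sosfiltfilt(sos, samples)
        out[i0:i1] += (g - 1.0) * comp[i0:i1] * taper
    return out


def _animal_seed(master_seed: int, group_label: str, index: int) -> int:
    """Stable per-animal seed derived from (master seed, group, index)."""
    ss = np.random.SeedSequence(
        [int(master_seed), zlib.crc32(group_label.encode("utf-8")), int(index)]
    )
    return int(ss.generate_state(1)[0] % (2**31))


def _burst_times(
    scheme: EpochScheme, n_bursts: int, duration: float, rng: np.random.Generator
) -> np.ndarray:
    """Jittered-grid burst centers, fully inside the exposure epoch."""
    lo = scheme.exposure_start + duration
    hi = scheme.exposure_end - duration
    if n_bursts == 0:
        return np.empty(0)
    slot = (hi - lo) / n_bursts
    margin = duration / 2 + 0.25
    if slot < 2 * margin:
        raise ValidationError(
            f"{n_bursts} bursts of {duration} s do not fit in a "
            f"{scheme.exposure_duration:.0f}-s exposure epoch"
        )
    centers = lo + (np.arange(n_bursts) + 0.5) * slot
    jitter = rng.uniform(-(slot / 2 - margin), slot / 2 - margin, size=n_bursts)
    return centers + jitter


def generate_cohort(
    profiles: list[GroupProfile],
    n_per_group: int,
    epoch_scheme: EpochScheme | None = None,
    rate: float = 2000.0,
    seed: int = 0,
    *,
    one_over_f_exponent: float = DEFAULT_EXPONENT,
    rms: float = DEFAULT_RMS,
    stimulus_amplitude: float = DEFAULT_STIMULUS_AMPLITUDE,
    band_scheme: BandScheme | None = None,
) -> tuple[list[Recording], list[SyntheticTruth]]:
    """Generate ``n_per_group`` recordings per treatment profile.

    Per animal: pink-noise background with periodic stimulus deflections
    throughout; during the exposure epoch the profile's band gains are
    applied to the background and its bursts injected.  Per-animal seeds
    derive deterministically from (master seed, group label, index).
    """
    if n_per_group < 1:
        raise ValidationError(f"n_per_group must be >= 1, got {n_per_group}")
    labels = [p.group_label for p in profiles]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"duplicate group labels: {labels}")
    scheme = epoch_scheme or EpochScheme()
    band_scheme = band_scheme or BandScheme()

    recordings: list[Recording] = []
    truths: list[SyntheticTruth] = []
    for profile in profiles:
        for i in range(n_per_group):
            aseed = _animal_seed(seed, profile.group_label, i)
            rng = np.random.default_rng(aseed + 1)  # burst placement stream
            x = generate_background(
                scheme.exposure_end, rate, one_over_f_exponent, rms, seed=aseed
            )
            # Band-limited gain modulation of the background during exposure.
            if any(g != 1.0 for g in profile.band_gain.values()):
                x = apply_band_gains(
                    x,
                    rate,
                    profile.band_gain,
                    (scheme.exposure_start, scheme.exposure_end),
                    scheme=band_scheme,
                )
            # Evoked stimulus deflections run throughout the recording, as in
            # the acquisition protocol (flashes during baseline and exposure).
            x = add_stimulus_artifacts(x, rate, amplitude=stimulus_amplitude * rms)
            # Injected bursts.
            bursts: list[BurstSpec] = []
            if profile.n_bursts_exposure > 0:
                band = band_scheme.band(profile.burst_band)
                freq = float(np.sqrt(band.low_hz * min(band.high_hz, rate / 2 * 0.9)))
                for c in _burst_times(scheme, profile.n_bursts_exposure, 1.0, rng):
                    spec = BurstSpec(
                        center_time=float(c),
                        center_freq_hz=freq,
                        duration=1.0,
                        relative_amplitude=profile.burst_amplitude,
                    )
                    x = inject_burst(x, rate, spec, background_rms=rms)
                    bursts.append(spec)
            animal_id = f"{profile.group_label}-{i:02d}"
            recordings.append(
                Recording(
                    animal_id=animal_id,
                    group_label=profile.group_label,
                    samples=x,
                    sampling_rate=rate,
                    epoch_scheme=scheme,
                )
            )
            truths.append(
                SyntheticTruth(
                    animal_id=animal_id,
                    group_label=profile.group_label,
                    bursts=bursts,
                    profile=profile,
                    seed=aseed,
                )
            )
    return recordings, truths


def write_truths(truths: list[SyntheticTruth], tsv_path: str | Path, json_path: str | Path | None = None) -> None:
    """Write ground-truth burst annotations as TSV (+ optional JSON sidecar)."""
    tsv_path = Path(tsv_path)
    lines = ["animal_id\tcenter_time_s\tduration_s\tcenter_freq_hz\trelative_amplitude"]
    for t in truths:
        for b in t.bursts:
            lines.append(
                f"{t.animal_id}\t{b.center_time:.6f}\t{b.duration:.6f}"
                f"\t{b.center_freq_hz:.6f}\t{b.relative_amplitude:.6f}"
            )
    tsv_path.write_text("\n".join(lines) + "\n")
    if json_path is not None:
        payload = [
            {
                "animal_id": t.animal_id,
                "group_label": t.group_label,
                "seed": t.seed,
                "profile": asdict(t.profile),
                "bursts": [asdict(b) for b in t.bursts],
            }
            for t in truths
        ]
        Path(json_path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
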
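"""Recording I/O and preprocessing (decimation, band-pass filtering, epochs).

Native on-disk format is raw little-endian float32 samples plus a JSON
sidecar with the metadata; a tab-separated ``time_s\tvoltage`` table is
supported as a human-readable alternative.  Preprocessing follows the study
protocol: decimate 10 kHz acquisitions to 2 kHz and band-pass 1-500 Hz with
a zero-phase Butterworth filter.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy import signal

from .core_types import (
    BoundsError,
    DataError,
    EpochScheme,
    FormatError,
    PreprocParams,
    Recording,
    ValidationError,
)

__all__ = [
    "write_recording",
    "read_recording",
    "downsample",
    "bandpass_filter",
    "extract_epoch",
    "preprocess",
]

_SIDECAR_KEYS = (
    "animal_id",
    "group_label",
    "sampling_rate_hz",
    "baseline_start_s",
    "baseline_end_s",
    "exposure_start_s",
    "exposure_end_s",
)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json") if path.suffix != ".json" else path


def _write_sidecar(rec: Recording, path: Path) -> None:
    meta = {
        "animal_id": rec.animal_id,
        "group_label": rec.group_label,
        "sampling_rate_hz": rec.sampling_rate,
        "baseline_start_s": rec.epoch_scheme.baseline_start,
        "baseline_end_s": rec.epoch_scheme.baseline_end,
        "exposure_start_s": rec.epoch_scheme.exposure_start,
        "exposure_end_s": rec.epoch_scheme.exposure_end,
    }
    path.write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")


def _read_sidecar(path: Path) -> dict:
    if not path.exists():
        raise FormatError(f"missing metadata sidecar {path}")
    meta = json.loads(path.read_text())
    for key in _SIDECAR_KEYS:
        if key not in meta:
            raise FormatError(f"sidecar {path} missing required key {key!r}")
    return meta


def write_recording(rec: Recording, path: str | Path, format: str = "f32") -> Path:
    """Write a recording; returns the primary data path.

    ``format='f32'``: raw little-endian float32 samples (exact to float32
    precision) with a ``<path>.json`` sidecar.  ``format='tsv'``: two-column
    tab-separated text with header ``time_s\tvoltage`` plus the same sidecar.
    """
    path = Path(path)
    if format == "f32":
        rec.samples.astype("<f4").tofile(path)
    elif format == "tsv":
        t = np.arange(rec.samples.size) / rec.sampling_rate
        with open(path, "w") as fh:
            fh.write("time_s\tvoltage\n")
            np.savetxt(fh, np.column_stack([t, rec.samples]), fmt="%.9g", delimiter="\t")
    else:
        raise ValidationError(f"unknown format {format!r}; expected 'f32' or 'tsv'")
    _write_sidecar(rec, _sidecar_path(path))
    return path


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a recording written by :func:`write_recording`.

    The format is inferred from the extension when not given (``.tsv`` ->
    TSV, ``.abf`` -> unsupported, anything else -> raw float32).  NaN samples
    raise a :class:`DataError` naming the first offending index; a sidecar
    without a sampling rate raises :class:`FormatError`.
    """
    path = Path(path)
    if format is None:
        if path.suffix == ".tsv":
            format = "tsv"
        elif path.suffix == ".abf":
            format = "abf"
        else:
            format = "f32"
    if format == "abf":
        raise FormatError(
            "ABF reading is not available in this installation; convert to the "
            "raw float32 + JSON sidecar or TSV format instead"
        )
    meta = _read_sidecar(_sidecar_path(path))
    if format == "f32":
        samples = np.fromfile(path, dtype="<f4").astype(np.float64)
    elif format == "tsv":
        try:
            samples = np.loadtxt(path, delimiter="\t", skiprows=1, usecols=1)
        except Exception as exc:  # malformed table
            raise FormatError(f"could not parse TSV {path}: {exc}") from exc
        samples = np.atleast_1d(samples).astype(np.float64)
    else:
        raise ValidationError(f"unknown format {format!r}")
    bad = np.flatnonzero(~np.isfinite(samples))
    if bad.size:
        raise DataError(f"{path}: non-finite sample at index {int(bad[0])}")
    scheme = EpochScheme(
        baseline_start=float(meta["baseline_start_s"]),
        baseline_end=float(meta["baseline_end_s"]),
        exposure_start=float(meta["exposure_start_s"]),
        exposure_end=float(meta["exposure_end_s"]),
    )
    return Recording(
        animal_id=str(meta["animal_id"]),
        group_label=str(meta["group_label"]),
        samples=samples,
        sampling_rate=float(meta["sampling_rate_hz"]),
        epoch_scheme=scheme,
    )


def downsample(rec: Recording, target_rate: float) -> Recording:
    """Anti-alias filter then decimate to ``target_rate``.

    The anti-alias stage is an order-8 Butterworth low-pass at 0.8x the new
    Nyquist frequency, applied forward-backward, after which every
    ``ratio``-th sample is kept.
    """
    ratio = rec.sampling_rate / target_rate
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValidationError(
            f"target_rate {target_rate} must evenly divide sampling_rate "
            f"{rec.sampling_rate}"
        )
    ratio = int(round(ratio))
    if ratio == 1:
        return rec.replace_samples(rec.samples.copy())
    sos = signal.butter(8, 0.8 * (target_rate / 2), btype="low", fs=rec.sampling_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples)
    return rec.replace_samples(filtered[::ratio], sampling_rate=target_rate)


def bandpass_filter(rec: Recording, params: PreprocParams | None = None) -> Recording:
    """Zero-phase Butterworth band-pass (default 1-500 Hz, order 4).

    Forward-backward application squares the magnitude response and cancels
    phase, so event timing inside 1-s windows is preserved.
    """
    params = params or PreprocParams(raw_rate=rec.sampling_rate, target_rate=rec.sampling_rate)
    nyq = rec.sampling_rate / 2
    if params.lowpass_hz >= nyq:
        raise ValidationError(
            f"lowpass {params.lowpass_hz} Hz must be below Nyquist {nyq} Hz"
        )
    sos = signal.butter(
        params.filter_order,
        [params.highpass_hz, params.lowpass_hz],
        btype="bandpass",
        fs=rec.sampling_rate,
        output="sos",
    )
    if params.zero_phase:
        filtered = signal.sosfiltfilt(sos, rec.samples)
    else:
        filtered = signal.sosfilt(sos, rec.samples)
    return rec.replace_samples(filtered)


def extract_epoch(rec: Recording, which: str) -> tuple[np.ndarray, float]:
    """Return the contiguous epoch slice and its start time in seconds."""
    start_s, end_s = rec.epoch_scheme.span(which)
    i0 = int(round(start_s * rec.sampling_rate))
    i1 = int(round(end_s * rec.sampling_rate))
    if i1 > rec.samples.size:
        raise BoundsError(
            f"epoch {which!r} [{start_s}, {end_s}] s exceeds trace of "
            f"{rec.duration:.3f} s"
        )
    return rec.samples[i0:i1], start_s


def preprocess(rec: Recording, params: PreprocParams | None = None) -> Recording:
    """Full preprocessing: decimate to the target rate (if needed), band-pass."""
    params = params or PreprocParams(raw_rate=rec.sampling_rate)
    out = rec
    if rec.sampling_rate != params.target_rate:
        out = downsample(out, params.target_rate)
    return bandpass_filter(out, params)
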
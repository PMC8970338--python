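"""Two-pass spectral event detection.

An *event* is a 1-s window whose 7-band wavelet spectrum deviates from the
animal's baseline spectral profile.  The first pass thresholds the Euclidean
distance between each time sample's band vector and the baseline-mean band
vector at baseline mean + 2 SD, and selects local maxima with a minimum
separation.  The second pass keeps only exposure events lying farther from
the centroid of the *baseline* events (in 7-band space) than the most
distant baseline event — discarding anything spectrally indistinguishable
from baseline fluctuations such as stimulus responses or amplifier noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .core_types import (
    BandScheme,
    DetectionParams,
    MorseParams,
    Recording,
    ValidationError,
)
from .io_preproc import extract_epoch
from .spectral import BandedSpectrogram, banded_cwt, wavelet_footprint_s

__all__ = [
    "Event",
    "EventSet",
    "baseline_profile",
    "distance_series",
    "baseline_distance_stats",
    "detect_candidates",
    "refine_events",
    "detect_recording",
    "count_events",
    "representative_event",
]


@dataclass
class Event:
    animal_id: str
    epoch: str  # "baseline" | "exposure"
    center_time_s: float
    start_s: float
    end_s: float
    band_vector: np.ndarray  # mean band magnitudes over the window
    peak_distance: float


@dataclass
class EventSet:
    """Detected events plus the detection context they came from."""

    events: list[Event]
    params: DetectionParams
    baseline_mean_vector: np.ndarray
    distance_mean: float
    distance_sd: float

    def __len__(self) -> int:
        return len(self.events)

    def band_matrix(self) -> np.ndarray:
        if not self.events:
            return np.empty((0, self.baseline_mean_vector.size))
        return np.vstack([e.band_vector for e in self.events])


def _edge_mask(n: int, rate: float, edge_s: float) -> slice:
    k = min(int(round(edge_s * rate)), max(n // 4, 1))
    return slice(k, n - k if n - k > k else n)


def baseline_profile(
    banded: BandedSpectrogram, edge_exclude_s: float = 0.0
) -> np.ndarray:
    """Per-band time-mean over the baseline epoch.

    ``edge_exclude_s`` trims the cone-of-influence region (one wavelet
    footprint) at each end before averaging.
    """
    n = banded.n_times
    if n == 0:
        raise ValidationError("empty baseline window")
    sl = _edge_mask(n, 1.0 / banded.time_step_s, edge_exclude_s)
    return banded.magnitude[sl].mean(axis=0)


def distance_series(banded: BandedSpectrogram, profile: np.ndarray) -> np.ndarray:
    """Euclidean distance of every time sample's band vector from ``profile``."""
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (banded.magnitude.shape[1],):
        raise ValidationError(
            f"profile length {profile.size} does not match "
            f"{banded.magnitude.shape[1]} bands"
        )
    return np.linalg.norm(banded.magnitude - profile, axis=1)


def baseline_distance_stats(
    dist: np.ndarray, rate: float, edge_exclude_s: float = 0.0
) -> tuple[float, float]:
    """Mean and SD of the baseline-epoch distance series (edges trimmed)."""
    if dist.size < 10 * rate:
        raise ValidationError(
            f"baseline window must span at least 10 s, got {dist.size / rate:.2f} s"
        )
    sl = _edge_mask(dist.size, rate, edge_exclude_s)
    core = dist[sl]
    return float(core.mean()), float(core.std())


def detect_candidates(
    dist: np.ndarray,
    banded: BandedSpectrogram,
    threshold: float,
    params: DetectionParams,
    *,
    animal_id: str = "",
    epoch: str = "exposure",
    distance_mean: float = 0.0,
    distance_sd: float = 0.0,
    baseline_mean_vector: np.ndarray | None = None,
) -> EventSet:
    """First-pass detection: thresholded local maxima of the distance series.

    Peaks above ``threshold`` separated by at least ``min_separation``
    become events; each event window is ``event_duration`` centered on its
    peak, shifted inward at epoch edges so all windows have full length.
    A constant series yields no events (nothing strictly exceeds the
    threshold).
    """
    rate = 1.0 / banded.time_step_s
    n = dist.size
    if n != banded.n_times:
        raise ValidationError("distance series and banded spectrogram lengths differ")
    sep = max(int(round(params.min_separation * rate)), 1)
    peaks, _ = find_peaks(dist, height=np.nextafter(threshold, np.inf), distance=sep)
    win = int(round(params.event_duration * rate))
    events: list[Event] = []
    for p in peaks:
        i0 = p - win // 2
        i0 = min(max(i0, 0), n - win)
        i1 = i0 + win
        center = banded.time_offset_s + p / rate
        events.append(
            Event(
                animal_id=animal_id,
                epoch=epoch,
                center_time_s=float(center),
                start_s=float(banded.time_offset_s + i0 / rate),
                end_s=float(banded.time_offset_s + i1 / rate),
                band_vector=banded.magnitude[i0:i1].mean(axis=0),
                peak_distance=float(dist[p]),
            )
        )
    events.sort(key=lambda e: e.center_time_s)
    if baseline_mean_vector is None:
        baseline_mean_vector = np.zeros(banded.magnitude.shape[1])
    return EventSet(
        events=events,
        params=params,
        baseline_mean_vector=np.asarray(baseline_mean_vector, dtype=float),
        distance_mean=distance_mean,
        distance_sd=distance_sd,
    )


def refine_events(baseline_events: EventSet, exposure_events: EventSet) -> EventSet:
    """Second pass: centroid-radius filter against the baseline event cloud.

    Retains exposure events whose band vector lies strictly farther from the
    centroid of the baseline events than the most distant baseline event.
    With zero baseline events the radius is undefined and all exposure
    candidates are retained.
    """
    if not baseline_events.events:
        return EventSet(
            events=list(exposure_events.events),
            params=exposure_events.params,
            baseline_mean_vector=exposure_events.baseline_mean_vector,
            distance_mean=exposure_events.distance_mean,
            distance_sd=exposure_events.distance_sd,
        )
    base = baseline_events.band_matrix()
    if base.shape[1] != exposure_events.baseline_mean_vector.size:
        raise ValidationError("baseline and exposure event sets use different band schemes")
    centroid = base.mean(axis=0)
    r_max = float(np.linalg.norm(base - centroid, axis=1).max())
    kept = [
        e
        for e in exposure_events.events
        if float(np.linalg.norm(e.band_vector - centroid)) > r_max
    ]
    return EventSet(
        events=kept,
        params=exposure_events.params,
        baseline_mean_vector=exposure_events.baseline_mean_vector,
        distance_mean=exposure_events.distance_mean,
        distance_sd=exposure_events.distance_sd,
    )


def detect_recording(
    rec: Recording,
    morse: MorseParams | None = None,
    scheme: BandScheme | None = None,
    params: DetectionParams | None = None,
) -> tuple[EventSet, EventSet, EventSet]:
    """Run both detection passes on one preprocessed recording.

    Returns (baseline candidates, exposure candidates, refined exposure
    events).  The threshold (baseline distance mean + threshold_sd * SD) is
    computed on the baseline epoch with the cone-of-influence edges
    excluded, and applied identically to both epochs.
    """
    morse = morse or MorseParams()
    scheme = scheme or BandScheme()
    params = params or DetectionParams()
    coi = wavelet_footprint_s(morse)
    rate = rec.sampling_rate

    base_x, base_t0 = extract_epoch(rec, "baseline")
    expo_x, expo_t0 = extract_epoch(rec, "exposure")
    banded_b = banded_cwt(base_x, rate, morse, scheme, time_offset_s=base_t0)
    banded_e = banded_cwt(expo_x, rate, morse, scheme, time_offset_s=expo_t0)

    profile = baseline_profile(banded_b, edge_exclude_s=coi)
    dist_b = distance_series(banded_b, profile)
    dist_e = distance_series(banded_e, profile)
    mean, sd = baseline_distance_stats(dist_b, rate, edge_exclude_s=coi)
    threshold = mean + params.threshold_sd * sd

    common = dict(
        distance_mean=mean,
        distance_sd=sd,
        baseline_mean_vector=profile,
        animal_id=rec.animal_id,
    )
    base_set = detect_candidates(dist_b, banded_b, threshold, params, epoch="baseline", **common)
    expo_set = detect_candidates(dist_e, banded_e, threshold, params, epoch="exposure", **common)
    refined = refine_events(base_set, expo_set)
    return base_set, expo_set, refined


def count_events(refined: dict[str, EventSet], groups: dict[str, str]):
    """Per-animal refined event counts as a DataFrame (animal_id, group, n_events)."""
    import pandas as pd

    ids = list(refined)
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate animal ids in refined event sets")
    missing = [a for a in ids if a not in groups]
    if missing:
        raise ValidationError(f"no group label for animals {missing}")
    rows = [
        {"animal_id": a, "group": groups[a], "n_events": len(refined[a])} for a in ids
    ]
    return pd.DataFrame(rows, columns=["animal_id", "group", "n_events"])


def representative_event(events: list[Event]) -> Event | None:
    """Event closest (Euclidean) to the group's mean event spectrum.

    Ties break toward the earliest center time; an empty group returns
    ``None`` rather than raising.
    """
    if not events:
        return None
    mat = np.vstack([e.band_vector for e in events])
    mean_vec = mat.mean(axis=0)
    dists = np.linalg.norm(mat - mean_vec, axis=1)
    order = sorted(range(len(events)), key=lambda i: (dists[i], events[i].center_time_s))
    return events[order[0]]
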
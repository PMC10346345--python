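"""Heel-strike detection and gait-cycle segmentation of EEG.

A gait cycle runs from one heel strike to the next heel strike of the same
foot.  Heel strikes are detected twice — as local minima of the (low-pass
filtered) heel-marker height and as sharp onsets of the vertical ground
reaction force — then reconciled, with the marker series as the primary
timing source.  The reconciled events cut the EEG into half-open per-cycle
slices which are linearly resampled onto a 0-100% gait-cycle grid
(100 samples per channel by default); the raw native-rate slice is kept
alongside for features that need the full bandwidth.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io_formats import EEGRecording, MotionSeries

__all__ = [
    "GaitEventSeries",
    "NormalizedCycle",
    "detect_events_marker",
    "detect_events_grf",
    "reconcile_events",
    "segment_and_normalize",
    "cycles_to_tensor",
    "event_f1",
]

log = logging.getLogger(__name__)

STRIDE_BOUNDS = (0.4, 2.5)  # physiological stride-duration bounds, seconds


@dataclass
class GaitEventSeries:
    """Validated heel-strike times (seconds) for one side."""

    side: str
    times: np.ndarray
    source: str  # "marker" | "force" | "reconciled"
    match_rate: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be left/right, got {self.side!r}")
        if self.source not in ("marker", "force", "reconciled"):
            raise ValueError(f"unknown source {self.source!r}")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")
        gaps = np.diff(self.times)
        if len(gaps) and (gaps.min() < STRIDE_BOUNDS[0] or
                          gaps.max() > STRIDE_BOUNDS[1]):
            warnings.warn(
                "inter-event intervals outside physiological stride bounds "
                f"{STRIDE_BOUNDS}", RuntimeWarning)

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class NormalizedCycle:
    """Per-cycle EEG: raw native-rate slice plus the 0-100% resampled trace."""

    raw: np.ndarray          # (channels, m) untouched cycle slice
    normalized: np.ndarray   # (channels, n) resampled onto the cycle grid
    cycle_span: tuple[float, float]
    sampling_rate: float
    channel_labels: list[str]
    subject: int | str | None = None
    condition: str | None = None
    cycle_index: int = 0

    def __post_init__(self) -> None:
        t0, t1 = self.cycle_span
        if t1 <= t0:
            raise ValueError("cycle_span end must exceed start")
        m_expected = int(round((t1 - t0) * self.sampling_rate))
        if abs(self.raw.shape[1] - m_expected) > 1:
            raise ValueError(
                f"raw length {self.raw.shape[1]} inconsistent with span "
                f"({m_expected} samples expected)")

    @property
    def duration(self) -> float:
        return self.cycle_span[1] - self.cycle_span[0]


def detect_events_marker(heel_z: MotionSeries, lowpass_hz: float = 6.0,
                         prominence_frac: float = 0.25,
                         min_separation: float = 0.4) -> GaitEventSeries:
    """Heel strikes as local minima of the low-pass filtered heel height."""
    fs = heel_z.sampling_rate
    x = heel_z.values
    if np.ptp(x) < 1e-9:
        warnings.warn("flat heel trajectory; no events detected", RuntimeWarning)
        return GaitEventSeries(heel_z.side, np.empty(0), "marker")
    sos = signal.butter(4, lowpass_hz, btype="lowpass", fs=fs, output="sos")
    xf = signal.sosfiltfilt(sos, x)
    peaks, props = signal.find_peaks(
        -xf,
        prominence=prominence_frac * np.ptp(xf),
        distance=max(1, int(round(min_separation * fs))),
    )
    # Sub-sample refinement: least-squares parabola over a short window
    # around each sample-level minimum; the vertex gives the event time.
    half = max(2, int(round(0.04 * fs)))
    times = []
    for p in peaks:
        lo, hi = max(0, p - half), min(len(xf), p + half + 1)
        k = np.arange(lo, hi) - p
        coef = np.polyfit(k, xf[lo:hi], 2)
        if coef[0] > 0:
            vertex = float(np.clip(-coef[1] / (2 * coef[0]), -half, half))
        else:
            vertex = 0.0
        times.append(heel_z.time[p] + vertex / fs)
    return GaitEventSeries(heel_z.side, np.asarray(times), "marker")


def detect_events_grf(grf: MotionSeries, threshold: float = 20.0,
                      min_swing: float = 0.05) -> GaitEventSeries:
    """Heel strikes as upward force-threshold crossings after a swing phase.

    A crossing counts only when preceded by at least ``min_swing`` seconds
    below the threshold, which rejects within-stance fluctuations.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    fs = grf.sampling_rate
    below = grf.values < threshold
    n_swing = max(1, int(round(min_swing * fs)))
    times = []
    run = 0  # length of the current below-threshold run
    for i, b in enumerate(below):
        if b:
            run += 1
        else:
            if run >= n_swing:
                # linear interpolation of the exact crossing time
                v0, v1 = grf.values[i - 1], grf.values[i]
                frac = (threshold - v0) / (v1 - v0) if v1 > v0 else 1.0
                times.append(grf.time[i - 1] + frac * (grf.time[i]
                                                       - grf.time[i - 1]))
            run = 0
    return GaitEventSeries(grf.side, np.asarray(times), "force")


def reconcile_events(marker: GaitEventSeries, force: GaitEventSeries,
                     tol: float = 0.05) -> GaitEventSeries:
    """Keep marker events confirmed by a force event within ``tol`` seconds.

    Marker timing is primary: reconciled times are the confirmed marker
    times.  ``match_rate`` reports the confirmed fraction.
    """
    if marker.side != force.side:
        raise ValueError("marker and force series must be the same side")
    if len(marker) == 0:
        return GaitEventSeries(marker.side, np.empty(0), "reconciled",
                               match_rate=0.0)
    if len(force) == 0:
        return GaitEventSeries(marker.side, np.empty(0), "reconciled",
                               match_rate=0.0)
    if len(force.times) == 1:
        nearest = np.abs(force.times[0] - marker.times)
    else:
        idx = np.clip(np.searchsorted(force.times, marker.times),
                      1, len(force.times) - 1)
        nearest = np.minimum(
            np.abs(force.times[idx - 1] - marker.times),
            np.abs(force.times[idx] - marker.times),
        )
    keep = nearest <= tol
    rate = float(np.mean(keep))
    return GaitEventSeries(marker.side, marker.times[keep], "reconciled",
                           match_rate=rate)


def segment_and_normalize(rec: EEGRecording, events: GaitEventSeries,
                          n: int = 100,
                          bounds: tuple[float, float] = STRIDE_BOUNDS,
                          subject: int | str | None = None,
                          condition: str | None = None) -> list[NormalizedCycle]:
    """Cut the EEG into per-cycle slices and resample each to ``n`` points.

    One cycle per consecutive event pair ``[e_k, e_{k+1})``; each channel is
    linearly interpolated onto ``n`` equally spaced points of the cycle
    (half-open grid, so a perfectly stride-periodic signal yields identical
    normalized cycles).  Cycles with implausible durations are discarded
    and counted in the log.
    """
    if len(events) < 2:
        return []
    fs = rec.sampling_rate
    t0_rec = rec.start_time
    cycles: list[NormalizedCycle] = []
    discarded = 0
    sub = subject if subject is not None else rec.metadata.get("subject_id")
    cond = condition if condition is not None else rec.metadata.get("condition")
    for e0, e1 in zip(events.times[:-1], events.times[1:]):
        d = e1 - e0
        if d < bounds[0] or d > bounds[1]:
            discarded += 1
            continue
        i0 = int(round((e0 - t0_rec) * fs))
        i1 = int(round((e1 - t0_rec) * fs))
        if i0 < 0 or i1 > rec.n_samples or i1 - i0 < 2:
            discarded += 1
            continue
        raw = rec.data[:, i0:i1]
        # fractional sample positions of the n half-open grid points
        pos = (e0 - t0_rec) * fs + d * fs * np.arange(n) / n
        j = np.clip(np.floor(pos).astype(int), 0, rec.n_samples - 2)
        w = pos - j
        normalized = rec.data[:, j] * (1.0 - w) + rec.data[:, j + 1] * w
        cycles.append(NormalizedCycle(
            raw=raw.copy(), normalized=normalized,
            cycle_span=(float(e0), float(e1)), sampling_rate=fs,
            channel_labels=list(rec.channel_labels),
            subject=sub, condition=cond, cycle_index=len(cycles),
        ))
    if discarded:
        log.info("segment_and_normalize: discarded %d implausible cycle(s)",
                 discarded)
    return cycles


def cycles_to_tensor(cycles: list[NormalizedCycle]) -> np.ndarray:
    """Stack normalized cycles into a (n_cycles, channels, n) tensor."""
    return np.stack([c.normalized for c in cycles])


def event_f1(detected: np.ndarray, truth: np.ndarray,
             tol: float = 0.010) -> tuple[float, int, int]:
    """F1 of detected vs. ground-truth event times with matching tolerance.

    Greedy one-to-one matching within ``tol`` seconds; returns
    ``(f1, misses, false_alarms)``.
    """
    detected = np.asarray(detected, dtype=float)
    truth = np.asarray(truth, dtype=float)
    used = np.zeros(len(detected), dtype=bool)
    tp = 0
    for tt in truth:
        if len(detected) == 0:
            break
        err = np.abs(detected - tt)
        err[used] = np.inf
        k = int(np.argmin(err))
        if err[k] <= tol + 1e-12:
            used[k] = True
            tp += 1
    misses = len(truth) - tp
    false_alarms = int(np.sum(~used))
    if tp == 0:
        return 0.0, misses, false_alarms
    precision = tp / (tp + false_alarms)
    recall = tp / (tp + misses)
    return 2 * precision * recall / (precision + recall), misses, false_alarms
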
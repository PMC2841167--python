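"""Saccade / blink / fixation detection from raw gaze samples.

The parser mirrors the conventions of commercial video-based eye trackers:
a sample is saccadic when either its angular velocity or its angular
acceleration exceeds a threshold (defaults 30 deg/s and 4000 deg/s^2),
blinks are runs of missing pupil signal of at least three samples extended
through any adjoining saccade-detector activity, and fixations are
everything that is neither.  Velocity and acceleration are obtained from
symmetric finite differences on the raw trace; no additional smoothing is
applied unless requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional

import numpy as np

__all__ = [
    "GazeRecording",
    "ParserSpec",
    "Event",
    "EventSequence",
    "compute_kinematics",
    "parse_events",
    "merge_saccades",
]


@dataclass
class GazeRecording:
    """A single trial's gaze-sample stream.

    Parameters
    ----------
    trial_id : str
        Identifier of the trial.
    t : ndarray
        Sample times in ms, strictly increasing and uniformly spaced.
    x, y : ndarray
        Gaze position in stimulus-image pixel coordinates (0-based,
        origin top-left, x rightward, y downward; float valued).
    pupil : ndarray
        Pupil signal; missing samples (track loss, blinks) are NaN.
    rate : float
        Sampling rate in Hz (default 1000).
    px_per_deg : float
        Pixels per degree of visual angle (default 25, i.e. a 390 px
        image subtending 15.6 deg).
    """

    trial_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pupil: np.ndarray
    rate: float = 1000.0
    px_per_deg: float = 25.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.pupil = np.asarray(self.pupil, dtype=float)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.pupil) == n):
            raise ValueError("t, x, y and pupil must have equal length")
        if n == 0:
            raise ValueError("empty recording")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError(f"trial {self.trial_id!r}: sample times not strictly increasing")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.px_per_deg <= 0:
            raise ValueError("px_per_deg must be positive")
        if np.isnan(self.x).any() or np.isnan(self.y).any():
            raise ValueError(f"trial {self.trial_id!r}: NaN gaze coordinates")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.rate

    @property
    def span_ms(self) -> float:
        """Total recorded time: n samples at the nominal sampling interval."""
        return self.n_samples * self.dt_ms

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.pupil)


@dataclass(frozen=True)
class ParserSpec:
    """Thresholds and merging rules for event detection.

    All defaults follow the standard tracker convention: velocity
    threshold 30 deg/s, acceleration threshold 4000 deg/s^2, saccades
    closer than 20 ms and 0.30 deg are merged, and three or more
    consecutive missing pupil samples constitute a blink.
    """

    v_thresh: float = 30.0       # deg/s
    a_thresh: float = 4000.0     # deg/s^2
    merge_gap: float = 20.0      # ms
    merge_dist: float = 0.30     # deg
    blink_min_missing: int = 3   # samples
    smooth_window: int = 0       # optional boxcar on velocity, 0 = none

    def __post_init__(self) -> None:
        for name in ("v_thresh", "a_thresh", "merge_gap", "merge_dist", "blink_min_missing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class Event:
    kind: str              # "fixation" | "saccade" | "blink"
    onset: float           # ms
    offset: float          # ms
    x: Optional[float] = None      # fixation centroid, px
    y: Optional[float] = None
    # saccade endpoints (internal; used for merging and diagnostics)
    x_start: Optional[float] = None
    y_start: Optional[float] = None
    x_end: Optional[float] = None
    y_end: Optional[float] = None

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class EventSequence:
    """Ordered, non-overlapping events tiling one recording."""

    events: List[Event]
    trial_id: str = ""
    px_per_deg: float = 25.0
    rate: float = 1000.0

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def of_kind(self, kind: str) -> List[Event]:
        return [e for e in self.events if e.kind == kind]

    @property
    def fixations(self) -> List[Event]:
        return self.of_kind("fixation")

    @property
    def saccades(self) -> List[Event]:
        return self.of_kind("saccade")

    @property
    def blinks(self) -> List[Event]:
        return self.of_kind("blink")

    @property
    def span_ms(self) -> float:
        if not self.events:
            return 0.0
        return self.events[-1].offset - self.events[0].onset


def compute_kinematics(rec: GazeRecording, smooth_window: int = 0):
    """Per-sample angular velocity (deg/s) and acceleration (deg/s^2).

    Velocity at interior samples uses the symmetric difference over the
    two neighbouring samples; endpoints use one-sided differences.
    Acceleration is the symmetric difference of velocity.  Samples at or
    adjacent to missing pupil data have undefined (NaN) kinematics.

    Returns ``(velocity, acceleration)`` arrays of the recording length.
    """
    n = rec.n_samples
    if n < 3:
        raise ValueError("recording too short")
    dt = np.diff(rec.t) / 1000.0  # s
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"trial {rec.trial_id!r}: non-uniform sampling")
    h = dt[0]

    x = rec.x / rec.px_per_deg
    y = rec.y / rec.px_per_deg
    if smooth_window and smooth_window > 1:
        k = np.ones(smooth_window) / smooth_window
        x = np.convolve(x, k, mode="same")
        y = np.convolve(y, k, mode="same")

    vel = np.empty(n)
    vx = np.empty(n)
    vy = np.empty(n)
    vx[1:-1] = (x[2:] - x[:-2]) / (2 * h)
    vy[1:-1] = (y[2:] - y[:-2]) / (2 * h)
    vx[0] = (x[1] - x[0]) / h
    vy[0] = (y[1] - y[0]) / h
    vx[-1] = (x[-1] - x[-2]) / h
    vy[-1] = (y[-1] - y[-2]) / h
    vel = np.hypot(vx, vy)

    acc = np.empty(n)
    acc[1:-1] = (vel[2:] - vel[:-2]) / (2 * h)
    acc[0] = (vel[1] - vel[0]) / h
    acc[-1] = (vel[-1] - vel[-2]) / h

    # undefined near missing pupil: the sample itself and its neighbours
    miss = rec.missing
    if miss.any():
        bad = miss.copy()
        bad[:-1] |= miss[1:]
        bad[1:] |= miss[:-1]
        vel = vel.copy()
        vel[bad] = np.nan
        # acceleration additionally touches velocity one sample out
        bad2 = bad.copy()
        bad2[:-1] |= bad[1:]
        bad2[1:] |= bad[:-1]
        acc[bad2] = np.nan
    return vel, acc


def _runs(mask: np.ndarray):
    """Start/stop (half-open) index pairs of True runs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def _merge_flags(sacc: np.ndarray, blink: np.ndarray, rec: GazeRecording, spec: ParserSpec) -> np.ndarray:
    """Fuse temporally and spatially contiguous saccade runs (fixpoint)."""
    sacc = sacc.copy()
    dt = rec.dt_ms
    while True:
        runs = _runs(sacc)
        changed = False
        for (s0, e0), (s1, e1) in zip(runs[:-1], runs[1:]):
            gap_ms = (s1 - e0) * dt
            if gap_ms >= spec.merge_gap:
                continue
            if blink[e0:s1].any():
                continue
            dx = rec.x[s1] - rec.x[e0 - 1]
            dy = rec.y[s1] - rec.y[e0 - 1]
            if np.hypot(dx, dy) / rec.px_per_deg < spec.merge_dist:
                sacc[e0:s1] = True
                changed = True
        if not changed:
            return sacc


def parse_events(rec: GazeRecording, spec: ParserSpec = ParserSpec()) -> EventSequence:
    """Segment a recording into an ordered, exhaustive event sequence.

    A sample is saccade-flagged when velocity > ``v_thresh`` OR
    acceleration > ``a_thresh``.  Runs of >= ``blink_min_missing``
    missing-pupil samples, extended through contiguous saccade-flagged
    or missing samples, become blinks.  Mergeable saccades are fused
    before fixation segmentation; the remaining maximal runs become
    fixations with duration-weighted (equal-weight, uniform sampling)
    centroids.  Events exactly tile ``n_samples * dt``.
    """
    n = rec.n_samples
    if n == 0:
        raise ValueError("empty recording")
    miss = rec.missing
    dt = rec.dt_ms

    if miss.all():
        ev = Event("blink", rec.t[0], rec.t[0] + n * dt)
        return EventSequence([ev], rec.trial_id, rec.px_per_deg, rec.rate)

    vel, acc = compute_kinematics(rec, smooth_window=spec.smooth_window)
    with np.errstate(invalid="ignore"):
        sacc = (vel > spec.v_thresh) | (acc > spec.a_thresh)
    sacc &= ~np.isnan(vel)

    # blinks: long-enough missing runs, extended through contiguous
    # saccade-detector activity or shorter missing stretches
    blink = np.zeros(n, dtype=bool)
    extendable = sacc | miss
    for s0, e0 in _runs(miss):
        if e0 - s0 < spec.blink_min_missing:
            continue
        lo = s0
        while lo > 0 and extendable[lo - 1]:
            lo -= 1
        hi = e0
        while hi < n and extendable[hi]:
            hi += 1
        blink[lo:hi] = True

    sacc &= ~blink
    sacc = _merge_flags(sacc, blink, rec, spec)

    labels = np.where(blink, 2, np.where(sacc, 1, 0))  # 0 fix, 1 sacc, 2 blink
    events: List[Event] = []
    start = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[start]:
            onset = rec.t[0] + start * dt
            offset = rec.t[0] + i * dt
            lab = labels[start]
            if lab == 0:
                cx = float(np.mean(rec.x[start:i]))
                cy = float(np.mean(rec.y[start:i]))
                events.append(Event("fixation", onset, offset, x=cx, y=cy))
            elif lab == 1:
                events.append(
                    Event(
                        "saccade", onset, offset,
                        x_start=float(rec.x[start]), y_start=float(rec.y[start]),
                        x_end=float(rec.x[i - 1]), y_end=float(rec.y[i - 1]),
                    )
                )
            else:
                events.append(Event("blink", onset, offset))
            start = i
    return EventSequence(events, rec.trial_id, rec.px_per_deg, rec.rate)


def merge_saccades(seq: EventSequence, spec: ParserSpec = ParserSpec()) -> EventSequence:
    """Fuse consecutive saccades separated by < ``merge_gap`` ms and
    < ``merge_dist`` deg, absorbing any intervening fixation samples.
    Applied iteratively until no further pair merges; idempotent on
    sequences without mergeable pairs.
    """
    events = [replace(e) for e in seq.events]
    changed = True
    while changed:
        changed = False
        sac_idx = [i for i, e in enumerate(events) if e.kind == "saccade"]
        for a, b in zip(sac_idx[:-1], sac_idx[1:]):
            first, second = events[a], events[b]
            between = events[a + 1:b]
            if any(e.kind == "blink" for e in between):
                continue
            gap = second.onset - first.offset
            if gap >= spec.merge_gap:
                continue
            if None in (first.x_end, first.y_end, second.x_start, second.y_start):
                continue
            d_px = np.hypot(second.x_start - first.x_end, second.y_start - first.y_end)
            if d_px / seq.px_per_deg >= spec.merge_dist:
                continue
            merged = Event(
                "saccade", first.onset, second.offset,
                x_start=first.x_start, y_start=first.y_start,
                x_end=second.x_end, y_end=second.y_end,
            )
            events = events[:a] + [merged] + events[b + 1:]
            changed = True
            break
    return EventSequence(events, seq.trial_id, seq.px_per_deg, seq.rate)
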
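"""Fixation-frequency time courses and percentile-bootstrap inference.

For each observer the frequency of fixation of a region of interest is
the across-trial proportion of trials whose current fixation lands in
the ROI, evaluated on a common time grid (absolute 10 ms bins over the
10 s learning exposure, or a 1% grid after normalising each recognition
trial by its response time) and optionally divided by the ROI area.
Group differences are assessed pointwise with a percentile bootstrap
over observers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence

import numpy as np

from .events import Event, EventSequence

__all__ = [
    "TimecourseSpec",
    "normalize_time",
    "fixation_frequency",
    "bootstrap_difference",
]


@dataclass(frozen=True)
class TimecourseSpec:
    B: int = 5000                 # bootstrap resamples
    alpha: float = 0.05
    mode: str = "learning"        # "learning" (absolute) | "recognition" (normalised)
    duration_ms: float = 10000.0  # learning exposure
    bin_ms: float = 10.0
    bin_pct: float = 1.0
    area_normalize: bool = True
    count_gaps_as_outside: bool = True  # saccades/blinks count as "not in ROI"

    def grid(self) -> np.ndarray:
        if self.mode == "learning":
            return np.arange(0.0, self.duration_ms, self.bin_ms)
        return np.arange(0.0, 100.0, self.bin_pct)


def normalize_time(seq: EventSequence, rt: float) -> EventSequence:
    """Map event times onto a 0-100% grid by dividing by the trial RT."""
    if rt <= 0:
        raise ValueError("rt must be positive")
    events = [
        replace(e, onset=e.onset / rt * 100.0, offset=e.offset / rt * 100.0)
        for e in seq.events
    ]
    return EventSequence(events, seq.trial_id, seq.px_per_deg, seq.rate)


def _in_roi(ev: Event, roi_mask: np.ndarray) -> bool:
    iy = int(round(ev.y))
    ix = int(round(ev.x))
    h, w = roi_mask.shape
    if not (0 <= iy < h and 0 <= ix < w):
        return False
    return bool(roi_mask[iy, ix])


def fixation_frequency(
    trials: Sequence[EventSequence],
    roi_mask: np.ndarray,
    spec: TimecourseSpec = TimecourseSpec(),
) -> np.ndarray:
    """One observer's ROI fixation-frequency curve.

    At each grid time the value is the proportion of trials whose
    current event is a fixation with its centroid inside the ROI
    (saccades, blinks and post-trial times count as outside), divided
    by the ROI area in px^2 when ``area_normalize``.  Zero-span trials
    are skipped with a warning.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    area = float(roi_mask.sum())
    if area == 0:
        raise ValueError("empty ROI")
    grid = spec.grid()
    hits = np.zeros_like(grid)
    n_used = 0
    for seq in trials:
        if not seq.events or seq.span_ms <= 0:
            import warnings

            warnings.warn(f"trial {seq.trial_id!r} has zero duration; skipped")
            continue
        n_used += 1
        onsets = np.array([e.onset for e in seq.events])
        idx = np.searchsorted(onsets, grid, side="right") - 1
        for j, i in enumerate(idx):
            if i < 0:
                continue
            ev = seq.events[i]
            if grid[j] >= ev.offset:
                continue  # grid point beyond the trial
            if ev.kind == "fixation" and _in_roi(ev, roi_mask):
                hits[j] += 1.0
    if n_used == 0:
        raise ValueError("no usable trials")
    curve = hits / n_used
    if spec.area_normalize:
        curve = curve / area
    return curve


def bootstrap_difference(
    curves_a: np.ndarray,
    curves_b: np.ndarray,
    spec: TimecourseSpec = TimecourseSpec(),
    rng: np.random.Generator | int | None = None,
) -> Dict[str, np.ndarray]:
    """Percentile-bootstrap CI of the group mean difference per time point.

    Observers are resampled with replacement independently per group,
    ``B`` times; the (alpha/2, 1 - alpha/2) percentiles of the
    bootstrapped mean difference form the CI, and a time point is
    flagged significant when its CI excludes zero.  Pointwise (no
    multiplicity correction), matching the convention of per-time
    asterisks on group time-course plots.
    """
    if spec.B < 1:
        raise ValueError("B must be >= 1")
    a = np.atleast_2d(np.asarray(curves_a, dtype=float))
    b = np.atleast_2d(np.asarray(curves_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 observers per group")
    if a.shape[1] != b.shape[1]:
        raise ValueError("curve lengths differ between groups")
    rng = np.random.default_rng(rng)
    na, nb = a.shape[0], b.shape[0]
    ia = rng.integers(0, na, size=(spec.B, na))
    ib = rng.integers(0, nb, size=(spec.B, nb))
    boot = a[ia].mean(axis=1) - b[ib].mean(axis=1)  # (B, T)
    lo = np.quantile(boot, spec.alpha / 2.0, axis=0)
    hi = np.quantile(boot, 1.0 - spec.alpha / 2.0, axis=0)
    return {
        "mean_diff": a.mean(axis=0) - b.mean(axis=0),
        "ci_low": lo,
        "ci_high": hi,
        "significant": (lo > 0) | (hi < 0),
    }
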
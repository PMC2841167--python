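"""Duration-weighted fixation maps and their Z-scored statistics.

A fixation map accumulates each fixation's duration (ms) at the pixel
nearest its centroid, so the map total equals the total fixation time
and long fixations weigh proportionally more.  Maps are smoothed with
an isotropic Gaussian kernel (default sigma 10 px), summed over the
observers of a group, and normalised either against the pooled moments
of two group maps (so both groups share one null reference) or, for a
difference map, against the moments of the difference itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .events import EventSequence

__all__ = [
    "StatMap",
    "accumulate_map",
    "smooth_map",
    "group_map",
    "pooled_moments",
    "zscore_with",
    "zscore_pooled",
    "differential_zmap",
]

DEFAULT_SHAPE = (390, 382)  # rows (y) x columns (x)
DEFAULT_SIGMA = 10.0


@dataclass
class StatMap:
    """A 2D scalar field on the stimulus pixel grid plus metadata."""

    grid: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("StatMap grid must be 2D")
        if not np.isfinite(self.grid).all():
            raise ValueError("StatMap grid must be finite")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.grid.shape

    @property
    def kind(self) -> str:
        return self.meta.get("kind", "raw")


def _as_grid(m) -> np.ndarray:
    return m.grid if isinstance(m, StatMap) else np.asarray(m, dtype=float)


def accumulate_map(
    sequences: Iterable[EventSequence],
    shape: Tuple[int, int] = DEFAULT_SHAPE,
    correct: Optional[Mapping[str, bool]] = None,
) -> StatMap:
    """Sum fixation durations at nearest-pixel centroids across trials.

    ``correct`` optionally maps trial_id -> bool; when given, only
    correct trials contribute.  Centroids outside the grid are clipped
    to the border so no fixation mass is lost.  Raises if no qualifying
    fixation exists ("empty map").
    """
    grid = np.zeros(shape, dtype=float)
    n_trials = 0
    any_fix = False
    for seq in sequences:
        if correct is not None and not correct.get(seq.trial_id, False):
            continue
        n_trials += 1
        for ev in seq.fixations:
            ix = int(np.clip(round(ev.x), 0, shape[1] - 1))
            iy = int(np.clip(round(ev.y), 0, shape[0] - 1))
            grid[iy, ix] += ev.duration
            any_fix = True
    if not any_fix:
        raise ValueError("empty map: no qualifying fixations")
    return StatMap(grid, {"kind": "raw", "n_trials": n_trials})


def smooth_map(m: StatMap, sigma: float = DEFAULT_SIGMA) -> StatMap:
    """Convolve with a unit-sum Gaussian kernel (zero-padded borders).

    Interior mass is conserved; mass within ~3 sigma of the border is
    partly attenuated by the zero padding.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    grid = gaussian_filter(_as_grid(m), sigma=sigma, mode="constant")
    meta = dict(m.meta) if isinstance(m, StatMap) else {}
    meta.update(kind="smoothed", sigma_smooth_px=float(sigma))
    return StatMap(grid, meta)


def group_map(observer_maps: Sequence[StatMap]) -> StatMap:
    """Pixelwise sum of per-observer maps (identical dimensions)."""
    if not observer_maps:
        raise ValueError("no maps to sum")
    grids = [_as_grid(m) for m in observer_maps]
    shape = grids[0].shape
    if any(g.shape != shape for g in grids):
        raise ValueError("dimension mismatch between observer maps")
    meta = dict(observer_maps[0].meta) if isinstance(observer_maps[0], StatMap) else {}
    meta["n_observers"] = len(observer_maps)
    return StatMap(np.sum(grids, axis=0), meta)


def pooled_moments(group_a: StatMap, group_b: StatMap) -> Tuple[float, float]:
    """Mean and SD over the concatenated pixels of both group maps."""
    a, b = _as_grid(group_a), _as_grid(group_b)
    if a.shape != b.shape:
        raise ValueError("dimension mismatch between group maps")
    pooled = np.concatenate([a.ravel(), b.ravel()])
    mu = float(pooled.mean())
    sd = float(pooled.std())
    return mu, sd


def zscore_with(m: StatMap, mu: float, sd: float) -> StatMap:
    if sd <= 0:
        raise ValueError("degenerate maps: zero pooled SD")
    meta = dict(m.meta) if isinstance(m, StatMap) else {}
    meta.update(kind="z", norm_mu=mu, norm_sd=sd)
    return StatMap((_as_grid(m) - mu) / sd, meta)


def zscore_pooled(group_a: StatMap, group_b: StatMap) -> Tuple[StatMap, StatMap]:
    """Normalise both group maps against their pooled pixel moments.

    Under the null hypothesis of identical viewing strategies the two
    maps share one distribution, so a common (mu, sd) keeps the two
    Z-maps directly comparable.
    """
    mu, sd = pooled_moments(group_a, group_b)
    if sd <= 0:
        raise ValueError("degenerate maps: zero pooled SD")
    return zscore_with(group_a, mu, sd), zscore_with(group_b, mu, sd)


def differential_zmap(group_a: StatMap, group_b: StatMap, restandardize: bool = False) -> StatMap:
    """Differential Z-map between two group fixation maps.

    Default: the difference of the two pooled-Z-scored group maps,
    z_a - z_b = (a - b) / s_pooled.  Because the denominator is the
    spread of the group maps themselves (structure scale), sampling
    noise between two cohorts with the same strategy stays far below
    the critical threshold, while genuine strategy differences are
    structure-sized -- this is what makes the subsequent Pixel test
    calibrated.  ``restandardize=True`` instead standardises the raw
    difference to mean 0 / SD 1 over its own pixels; note that this
    variant is scale-free (its maximum depends only on the *shape* of
    the fixation density), so it flags shape concentration rather than
    effect size and is kept for comparison only.
    """
    a, b = _as_grid(group_a), _as_grid(group_b)
    if a.shape != b.shape:
        raise ValueError("dimension mismatch between group maps")
    d = a - b
    if restandardize:
        sd = d.std()
        if sd <= 0:
            raise ValueError("degenerate difference: zero SD (identical maps)")
        return StatMap((d - d.mean()) / sd, {"kind": "differential_z", "norm": "self"})
    mu, sd = pooled_moments(group_a, group_b)
    if sd <= 0 or not d.any():
        raise ValueError("degenerate difference: identical maps")
    return StatMap(d / sd, {"kind": "differential_z", "norm": "pooled", "norm_sd": sd})
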
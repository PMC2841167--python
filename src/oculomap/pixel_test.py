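"""Random-field ("Pixel test") thresholds for smooth Z-maps.

The familywise-corrected critical value z_crit is the level at which
the expected Euler characteristic of a smooth Gaussian random field
over the search region equals the test level (alpha one-tailed, alpha/2
per tail two-tailed).  The full 2D + 1D + 0D resel expansion is used;
field smoothness is taken from the applied smoothing kernel via
FWHM = 2 sqrt(2 ln 2) sigma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import label as cc_label
from scipy.optimize import brentq
from scipy.stats import norm

from .fixmap import StatMap

__all__ = [
    "PixelTestSpec",
    "Cluster",
    "ClusterSet",
    "fwhm_from_sigma",
    "resel_counts",
    "expected_ec",
    "critical_z",
    "significant_clusters",
]

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class PixelTestSpec:
    alpha: float = 0.05
    tails: str = "two"            # "one" | "two"
    sigma_smooth_px: float = 10.0
    search_mask: Optional[np.ndarray] = None  # bool mask; None = full map

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.tails not in ("one", "two"):
            raise ValueError("tails must be 'one' or 'two'")
        if self.sigma_smooth_px <= 0:
            raise ValueError("sigma_smooth_px must be positive")


@dataclass
class Cluster:
    pixels: np.ndarray   # (k, 2) array of (row, col) indices
    sign: str            # "+" | "-"
    peak_z: float
    area_px: int


@dataclass
class ClusterSet:
    clusters: List[Cluster]
    z_crit: float
    shape: Tuple[int, int]

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def mask(self) -> np.ndarray:
        """Union of all cluster pixels as a boolean map."""
        m = np.zeros(self.shape, dtype=bool)
        for c in self.clusters:
            m[c.pixels[:, 0], c.pixels[:, 1]] = True
        return m

    def cluster_mask(self, i: int) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        c = self.clusters[i]
        m[c.pixels[:, 0], c.pixels[:, 1]] = True
        return m


def fwhm_from_sigma(sigma: float) -> float:
    return FWHM_PER_SIGMA * sigma


def resel_counts(mask_or_shape, fwhm: float) -> Tuple[float, float, float]:
    """Resolution-element counts (R0, R1, R2) of the search region.

    For a full rectangle of size H x W: R2 = H*W / fwhm^2,
    R1 = (H + W) / fwhm (half the perimeter over fwhm), R0 = 1.
    Arbitrary masks use pixel area, half the estimated boundary length
    and the Euler characteristic.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    if isinstance(mask_or_shape, tuple):
        h, w = mask_or_shape
        if h <= 0 or w <= 0:
            raise ValueError("empty mask")
        return 1.0, (h + w) / fwhm, (h * w) / (fwhm * fwhm)
    mask = np.asarray(mask_or_shape, dtype=bool)
    area = int(mask.sum())
    if area == 0:
        raise ValueError("empty mask")
    from skimage.measure import euler_number, perimeter

    r0 = float(euler_number(mask, connectivity=2))
    r1 = perimeter(mask, neighborhood=4) / (2.0 * fwhm)
    r2 = area / (fwhm * fwhm)
    return r0, r1, r2


def expected_ec(t, resels: Sequence[float]):
    """Expected Euler characteristic of excursions above ``t``.

    E[EC](t) = R0 (1 - Phi(t))
             + R1 sqrt(4 ln 2) / (2 pi) exp(-t^2/2)
             + R2 (4 ln 2) / (2 pi)^(3/2) t exp(-t^2/2)
    """
    r0, r1, r2 = resels
    t = np.asarray(t, dtype=float)
    e = np.exp(-t * t / 2.0)
    ec = (
        r0 * norm.sf(t)
        + r1 * (math.sqrt(4.0 * math.log(2.0)) / (2.0 * math.pi)) * e
        + r2 * (4.0 * math.log(2.0) / (2.0 * math.pi) ** 1.5) * t * e
    )
    return ec if ec.shape else float(ec)


def critical_z(spec: PixelTestSpec, map_dims: Tuple[int, int]) -> float:
    """Solve E[EC](t) = alpha (one-tailed) or alpha/2 (two-tailed)."""
    region = spec.search_mask if spec.search_mask is not None else tuple(map_dims)
    resels = resel_counts(region, fwhm_from_sigma(spec.sigma_smooth_px))
    target = spec.alpha if spec.tails == "one" else spec.alpha / 2.0

    def f(t):
        return expected_ec(t, resels) - target

    lo, hi = 1.5, 10.0
    if f(lo) < 0 or f(hi) > 0:
        raise ValueError("no root in bracket [1.5, 10] for the requested alpha")
    return float(brentq(f, lo, hi, xtol=1e-6))


_EIGHT = np.ones((3, 3), dtype=int)


def significant_clusters(z: StatMap | np.ndarray, spec: PixelTestSpec = PixelTestSpec()) -> ClusterSet:
    """Threshold a Z-map at z_crit and label 8-connected clusters.

    Two-tailed tests record positive and negative excursions separately;
    an empty ClusterSet is a legitimate (null) outcome.
    """
    grid = z.grid if isinstance(z, StatMap) else np.asarray(z, dtype=float)
    zc = critical_z(spec, grid.shape)
    clusters: List[Cluster] = []

    def collect(mask: np.ndarray, sign: str) -> None:
        lab, n = cc_label(mask, structure=_EIGHT)
        for i in range(1, n + 1):
            idx = np.argwhere(lab == i)
            vals = grid[idx[:, 0], idx[:, 1]]
            peak = float(vals.max()) if sign == "+" else float(vals.min())
            clusters.append(Cluster(idx, sign, peak, len(idx)))

    collect(grid > zc, "+")
    if spec.tails == "two":
        collect(grid < -zc, "-")
    return ClusterSet(clusters, zc, grid.shape)
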
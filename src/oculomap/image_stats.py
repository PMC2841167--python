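"""Pixel-space diagnosticity analysis of stimulus sets.

The standard deviation across face exemplars of one group, pixel by
pixel, quantifies where exemplars differ -- i.e. the information
available to tell faces apart.  Subtracting the SD images of two face
sets and Z-scoring the difference yields a map of candidate diagnostic
biases between the sets, thresholded with the same random-field Pixel
test used for fixation maps.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np

from .fixmap import StatMap
from .pixel_test import ClusterSet, PixelTestSpec, significant_clusters

__all__ = ["group_pixel_stats", "differential_sd_test"]

GRAY_MIN, GRAY_MAX = 1.0, 256.0


def _validate_set(images: Sequence[np.ndarray]) -> np.ndarray:
    if len(images) < 2:
        raise ValueError("need at least 2 images")
    stack = np.stack([np.asarray(im, dtype=float) for im in images])
    if stack.ndim != 3:
        raise ValueError("images must be single-channel 2D arrays of equal size")
    if stack.min() < GRAY_MIN or stack.max() > GRAY_MAX:
        raise ValueError(f"gray levels must lie in [{GRAY_MIN:g}, {GRAY_MAX:g}]")
    return stack


def group_pixel_stats(images: Sequence[np.ndarray]) -> Tuple[np.ndarray, np.ndarray]:
    """Pixelwise mean and population SD (n denominator) of a face set."""
    stack = _validate_set(images)
    return stack.mean(axis=0), stack.std(axis=0, ddof=0)


def differential_sd_test(
    set_a: Sequence[np.ndarray],
    set_b: Sequence[np.ndarray],
    spec: PixelTestSpec = PixelTestSpec(),
) -> Tuple[StatMap, ClusterSet]:
    """Z-scored SD-difference map between two face sets, with clusters.

    Delta = SD_a - SD_b is standardised over its own pixels and
    thresholded at the Pixel-test critical value.  The field-smoothness
    parameter of ``spec`` is an assumption about the spatial scale of
    image variation (the SD maps themselves are not smoothed); it is
    recorded in the output metadata.
    """
    _, sd_a = group_pixel_stats(set_a)
    _, sd_b = group_pixel_stats(set_b)
    if sd_a.shape != sd_b.shape:
        raise ValueError("image sets have different dimensions")
    d = sd_a - sd_b
    sd = d.std()
    if sd <= 0:
        raise ValueError("degenerate SD difference: zero variance")
    z = StatMap(
        (d - d.mean()) / sd,
        {
            "kind": "differential_z",
            "source": "pixel_sd",
            "assumed_sigma_smooth_px": spec.sigma_smooth_px,
        },
    )
    return z, significant_clusters(z, spec)
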
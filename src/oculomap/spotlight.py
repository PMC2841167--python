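"""Gaze-contingent Gaussian-aperture ("moving spotlight") masking.

The aperture is a circular window of 2, 5 or 8 deg diameter centred on
the current gaze position.  Opacity (alpha) is 0 at the centre, rises
with eccentricity following a normalised Gaussian ramp and reaches 1
(complete occlusion) at the aperture border; everything outside the
aperture is black, everything outside the stimulus frame is background
gray.  The module also answers which facial landmarks remain visible
from a given fixation location, the quantity that distinguishes the
three aperture conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

import numpy as np

__all__ = [
    "SpotlightSpec",
    "Landmark",
    "DEFAULT_LAYOUT",
    "aperture_alpha",
    "apply_spotlight",
    "landmark_visibility",
]


@dataclass(frozen=True)
class SpotlightSpec:
    """Geometry of the Gaussian aperture.

    ``sigma_frac`` sets the Gaussian shape parameter as a fraction of
    the aperture radius; the ramp is renormalised so that alpha is
    exactly 0 at the centre and exactly 1 at the border for any value.
    """

    aperture_deg: float
    px_per_deg: float = 25.0
    sigma_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.aperture_deg <= 0:
            raise ValueError("aperture_deg must be positive")
        if not 0 < self.sigma_frac < 1:
            raise ValueError("sigma_frac must lie in (0, 1)")
        if self.px_per_deg <= 0:
            raise ValueError("px_per_deg must be positive")

    @property
    def radius_px(self) -> float:
        return self.aperture_deg / 2.0 * self.px_per_deg


@dataclass(frozen=True)
class Landmark:
    """Circular facial region: centre (x, y) and radius, in pixels."""

    x: float
    y: float
    radius: float


# Default landmark layout on the 382x390 stimulus grid.  Chosen so that,
# under the alpha model below with the default transmission threshold,
# (i) an eye fits inside its own 2 deg aperture, (ii) neither the eyes
# nor the mouth are visible when fixating the nose at 5 deg, and
# (iii) both eyes and the mouth are visible from the nose at 8 deg.
DEFAULT_LAYOUT: Dict[str, Landmark] = {
    "left_eye": Landmark(142.0, 162.0, 15.0),
    "right_eye": Landmark(240.0, 162.0, 15.0),
    "nose": Landmark(191.0, 215.0, 16.0),
    "mouth": Landmark(191.0, 285.0, 18.0),
}


def aperture_alpha(r, spec: SpotlightSpec):
    """Opacity at distance ``r`` (px) from the gaze centre.

    alpha(r) = (1 - exp(-r^2 / (2 sigma_a^2))) / (1 - exp(-R^2 / (2 sigma_a^2)))
    for r < R (sigma_a = sigma_frac * R) and 1 beyond the border, so
    alpha(0) = 0 and alpha(R) = 1 exactly.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance r must be non-negative")
    R = spec.radius_px
    sig = spec.sigma_frac * R
    denom = 1.0 - np.exp(-(R * R) / (2.0 * sig * sig))
    alpha = (1.0 - np.exp(-(r * r) / (2.0 * sig * sig))) / denom
    return np.where(r >= R, 1.0, np.minimum(alpha, 1.0))


def apply_spotlight(
    image: np.ndarray,
    gaze: Tuple[float, float],
    spec: SpotlightSpec,
    background: float = 128.0,
    display_dims: Tuple[int, int] | None = None,
    image_offset: Tuple[int, int] = (0, 0),
) -> np.ndarray:
    """Render the masked display for one gaze position.

    Within the stimulus frame the displayed value is
    ``(1 - alpha) * image`` (blend towards black); display pixels
    outside the frame take the ``background`` gray level.  ``gaze`` is
    given in image coordinates and may lie off-image.  ``display_dims``
    is (height, width) of the output; default = the image size with the
    image at ``image_offset`` (x, y displacement of the image's top-left
    corner in the display).
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a single-channel (grayscale) image")
    h, w = image.shape
    ox, oy = image_offset
    if display_dims is None:
        dh, dw = h + oy, w + ox
    else:
        dh, dw = display_dims
    out = np.full((dh, dw), float(background))

    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(xx - gaze[0], yy - gaze[1])
    masked = (1.0 - aperture_alpha(r, spec)) * image.astype(float)

    y0, y1 = max(0, oy), min(dh, oy + h)
    x0, x1 = max(0, ox), min(dw, ox + w)
    if y1 > y0 and x1 > x0:
        out[y0:y1, x0:x1] = masked[y0 - oy:y1 - oy, x0 - ox:x1 - ox]
    return out


def _landmark_pixels(lm: Landmark) -> Tuple[np.ndarray, np.ndarray]:
    r = int(np.ceil(lm.radius))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    inside = xx * xx + yy * yy <= lm.radius * lm.radius
    return xx[inside] + lm.x, yy[inside] + lm.y


def landmark_visibility(
    layout: Mapping[str, Landmark],
    gaze: Tuple[float, float],
    spec: SpotlightSpec,
    tau: float = 0.1,
    coverage: float = 0.9,
) -> Dict[str, bool]:
    """Which landmarks are visible through the aperture from ``gaze``.

    A landmark counts as visible when at least ``coverage`` (default
    90%) of its region pixels retain transmission ``1 - alpha > tau``.
    The default tau of 0.1 treats a region as usable while it still
    passes at least 10% of stimulus contrast; the Gaussian ramp makes
    peripheral regions dim well before the hard border, so a mid-ramp
    threshold would never mark extrafoveal landmarks visible.
    """
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    vis: Dict[str, bool] = {}
    for name, lm in layout.items():
        if not isinstance(lm, Landmark):
            raise ValueError(f"unknown landmark entry {name!r}")
        px, py = _landmark_pixels(lm)
        r = np.hypot(px - gaze[0], py - gaze[1])
        transmission = 1.0 - aperture_alpha(r, spec)
        vis[name] = float(np.mean(transmission > tau)) >= coverage
    return vis
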
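"""Rasterization of expert markings into per-lesion confidence images.

A confidence image holds, for one (image, lesion type, expert) triple, the
expert's confidence numeric at every pixel covered by one of their markings
and 0 elsewhere. Rasterization is deliberately bit-reproducible: a pixel at
row ``r``, column ``c`` belongs to a region iff its center ``(c + 0.5,
r + 0.5)`` lies inside it — even-odd (crossing-number) rule for polygons, a
non-strict ``<=`` test on the normalized radius for circles and ellipses.
No anti-aliasing or fractional coverage is applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .annotations import ExpertAnnotationSet, Geometry

__all__ = ["ConfidenceImage", "rasterize_geometry", "confidence_image"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfidenceImage:
    """Per-pixel confidence map of one expert for one lesion type.

    ``values`` is an (H, W) float array; 0 means "not annotated here", a
    positive value is the confidence numeric of some covering marking (the
    maximum over overlapping markings of the same expert).
    """

    image_id: str
    lesion_type: str
    expert_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("confidence image must be 2-D")
        if (v < 0).any() or (v > 1).any():
            raise ValueError("confidence values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


def _pixel_centers(size: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    h, w = size
    ys, xs = np.mgrid[0:h, 0:w]
    return xs + 0.5, ys + 0.5


def _polygon_mask(vertices: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    # vectorized crossing-number (even-odd) test against every pixel center
    xs, ys = _pixel_centers(size)
    px = xs.ravel()
    py = ys.ravel()
    inside = np.zeros(px.shape, dtype=bool)
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if y1 == y2:
            continue  # horizontal edge never crosses a scan ray
        crosses = (y1 > py) != (y2 > py)
        with np.errstate(invalid="ignore"):
            x_at = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (px < x_at)
    return inside.reshape(size)


def rasterize_geometry(g: Geometry, size: tuple[int, int]) -> np.ndarray:
    """Rasterize one region to a boolean (H, W) mask on the pixel grid.

    Geometry extending beyond the image bounds is clipped by construction
    (only in-grid pixel centers are tested). A polygon that covers no pixel
    center yields an empty mask and logs a warning.
    """
    h, w = size
    if h <= 0 or w <= 0:
        raise ValueError("size must be positive")

    if g.variant == "polygon":
        assert g.vertices is not None
        mask = _polygon_mask(np.asarray(g.vertices, dtype=float), size)
        if not mask.any():
            logger.warning("degenerate polygon rasterized to an empty mask")
        return mask

    xs, ys = _pixel_centers(size)
    assert g.center is not None
    cx, cy = g.center
    if g.variant == "circle_area":
        assert g.radius is not None
        if g.radius == 0.0:
            # limiting case: only a pixel whose center coincides exactly
            return (xs == cx) & (ys == cy)
        return (xs - cx) ** 2 + (ys - cy) ** 2 <= g.radius**2

    assert g.radii is not None and g.orientation is not None
    rx, ry = g.radii
    cos_t = math.cos(g.orientation)
    sin_t = math.sin(g.orientation)
    u = (xs - cx) * cos_t + (ys - cy) * sin_t
    v = -(xs - cx) * sin_t + (ys - cy) * cos_t
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def confidence_image(
    aset: ExpertAnnotationSet,
    lesion_type: str,
    *,
    include_rep_points: bool = False,
) -> ConfidenceImage:
    """Rasterize one expert's markings of ``lesion_type`` into a confidence map.

    Each marking contributes its confidence numeric over its region; where
    markings of the same expert overlap the pixel takes the *maximum*
    confidence (confidence is an ordinal label, not additive mass).
    Representative points are cue locations, not spatial coverage, and are
    excluded by default; ``include_rep_points=True`` additionally renders
    them as filled circles for sensitivity analysis. An absent lesion type
    yields an all-zero image.
    """
    values = np.zeros(aset.image_size, dtype=float)
    for m in aset.markings:
        if m.lesion_type != lesion_type:
            continue
        mask = rasterize_geometry(m.region, aset.image_size)
        if include_rep_points:
            for rp in m.rep_points:
                mask = mask | rasterize_geometry(
                    Geometry.circle(rp.center, rp.radius), aset.image_size
                )
        np.maximum(values, np.where(mask, m.confidence.numeric, 0.0), out=values)
    return ConfidenceImage(
        image_id=aset.image_id,
        lesion_type=lesion_type,
        expert_id=aset.expert_id,
        values=values,
    )
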
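"""Image-score fusion rules: summax and the max / mean / product alternatives.

A detector typically produces a per-pixel likelihood map p(x_m | abnormal);
image-wise evaluation needs a single scalar score per image. The default rule
is *summax*: the sum of the top Y% pixel likelihoods (Y fixed to 1% in the
benchmark protocol) — a rank-order rule that behaves like a robust maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["LikelihoodImage", "summax", "fuse_rule", "FUSION_RULES"]

#: Floor applied to likelihoods under the product rule so that a single zero
#: pixel does not annihilate the score.
PRODUCT_FLOOR = 1e-12

FUSION_RULES = ("summax", "max", "mean", "product")


@dataclass(frozen=True)
class LikelihoodImage:
    """Per-pixel lesion likelihood map p(pixel colour | abnormal).

    ``fov_mask`` optionally restricts scoring to the field of view (the
    circular region of a fundus photograph actually showing retina); when
    given, only True pixels are considered.
    """

    image_id: str
    lesion_type: str
    values: np.ndarray
    fov_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.size == 0:
            raise ValueError("likelihood map must be a non-empty 2-D array")
        if not np.isfinite(v).all() or (v < 0).any():
            raise ValueError("likelihoods must be finite and >= 0")
        object.__setattr__(self, "values", v)
        if self.fov_mask is not None:
            m = np.asarray(self.fov_mask, dtype=bool)
            if m.shape != v.shape:
                raise ValueError("fov_mask shape must match values")
            object.__setattr__(self, "fov_mask", m)

    def pixel_scores(self) -> np.ndarray:
        """Flat array of the pixel likelihoods under consideration."""
        if self.fov_mask is not None:
            return self.values[self.fov_mask]
        return self.values.ravel()


def summax(image: LikelihoodImage | np.ndarray, proportion: float = 1.0) -> float:
    """Sum of the top ``proportion``% pixel likelihoods.

    ``k = max(1, ceil(proportion/100 * M))`` pixels are summed, where M is
    the number of pixels considered (inside the FOV if a mask is present).
    The ceil-with-floor rounding means tiny images still produce a score,
    and for M <= 100 at the default 1% the rule reduces to the max rule.
    """
    if not 0.0 < proportion <= 100.0:
        raise ValueError("proportion must lie in (0, 100]")
    scores = image.pixel_scores() if isinstance(image, LikelihoodImage) else np.asarray(
        image, dtype=float
    ).ravel()
    m = scores.size
    if m == 0:
        raise ValueError("empty (or fully masked) likelihood map")
    k = max(1, math.ceil(proportion / 100.0 * m))
    if k >= m:
        return float(scores.sum())
    top = np.partition(scores, m - k)[m - k:]
    return float(top.sum())


def fuse_rule(image: LikelihoodImage | np.ndarray, rule: str = "summax") -> float:
    """Fuse a likelihood map into one image score under a named decision rule.

    ``summax`` delegates to :func:`summax` at the protocol's fixed 1%;
    ``product`` clips values to a small positive floor first.
    """
    scores = image.pixel_scores() if isinstance(image, LikelihoodImage) else np.asarray(
        image, dtype=float
    ).ravel()
    if scores.size == 0:
        raise ValueError("empty (or fully masked) likelihood map")
    if rule == "summax":
        return summax(scores, 1.0)
    if rule == "max":
        return float(scores.max())
    if rule == "mean":
        return float(scores.mean())
    if rule == "product":
        return float(np.prod(np.clip(scores, PRODUCT_FLOOR, None)))
    raise ValueError(f"unknown fusion rule {rule!r}; expected one of {FUSION_RULES}")
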
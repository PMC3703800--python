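"""ROC-based evaluation protocols: image-wise and pixel-wise.

The image-based protocol treats a detector as a black box emitting one score
per test image; thresholding the scores at every observed value traces the
ROC curve of (1 - specificity, sensitivity) points. The pixel-based protocol
pools every pixel of every test image into one scored set — so abnormal
images contribute to both sensitivity and specificity while normal images
contribute only to specificity — and thresholds by the (optionally sampled)
unique global pixel scores.

Operating summaries: the equal error rate EER (SN = SP = 1 - EER, found by
linear interpolation between adjacent ROC vertices), the weighted error rate
WER(R) = (FPR + R * FNR) / (1 + R) for an adjustable false-negative /
false-positive cost ratio R, and the trapezoidal area under the curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .scoring import LikelihoodImage

__all__ = [
    "SingleClassError",
    "ScoredSet",
    "ROCCurve",
    "OperatingSummary",
    "roc_from_scores",
    "pixel_roc",
    "sample_scores",
    "eer",
    "eer_point",
    "wer",
    "wer_point",
    "auc",
    "summarize",
    "plot_roc",
]

ABNORMAL = "abnormal"
NORMAL = "normal"


class SingleClassError(ValueError):
    """Raised when an ROC is requested from a single-class sample."""


def _as_abnormal_flags(labels: Sequence[str] | Sequence[bool] | np.ndarray) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "bi":
        return arr.astype(bool)
    flags = np.empty(arr.shape, dtype=bool)
    for i, lab in enumerate(arr):
        if lab == ABNORMAL:
            flags[i] = True
        elif lab == NORMAL:
            flags[i] = False
        else:
            raise ValueError(f"label must be 'normal' or 'abnormal', got {lab!r}")
    return flags


@dataclass(frozen=True)
class ScoredSet:
    """Parallel score and label lists (image scores or pooled pixel scores)."""

    scores: np.ndarray
    abnormal: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float).ravel()
        a = _as_abnormal_flags(self.abnormal).ravel()
        if s.size != a.size:
            raise ValueError("scores and labels must have equal length")
        if s.size == 0:
            raise ValueError("empty scored set")
        if not np.isfinite(s).all():
            raise ValueError("scores must be finite")
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "abnormal", a)

    @property
    def n_abnormal(self) -> int:
        return int(self.abnormal.sum())

    @property
    def n_normal(self) -> int:
        return int((~self.abnormal).sum())


@dataclass(frozen=True)
class ROCCurve:
    """Ordered ROC vertices with their confusion counts.

    Vertices are sorted by threshold descending, hence FPR and SN are
    non-decreasing; the trivial endpoints (0, 0) and (1, 1) are always
    present (with thresholds +inf / -inf when no finite score attains them).
    The classification rule is "abnormal iff score >= threshold".
    """

    thresholds: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray

    @property
    def sn(self) -> np.ndarray:
        """Sensitivity TP / (TP + FN) per vertex (0 when no positives)."""
        denom = self.tp + self.fn
        return np.divide(self.tp, denom, out=np.zeros_like(self.tp, dtype=float),
                         where=denom > 0)

    @property
    def sp(self) -> np.ndarray:
        denom = self.tn + self.fp
        return np.divide(self.tn, denom, out=np.zeros_like(self.tn, dtype=float),
                         where=denom > 0)

    @property
    def fpr(self) -> np.ndarray:
        return 1.0 - self.sp

    @property
    def fnr(self) -> np.ndarray:
        return 1.0 - self.sn

    @property
    def points(self) -> np.ndarray:
        """(n, 2) array of (FPR, SN) vertices."""
        return np.column_stack([self.fpr, self.sn])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "tp": self.tp,
                "fp": self.fp,
                "tn": self.tn,
                "fn": self.fn,
                "fpr": self.fpr,
                "sn": self.sn,
            }
        )


def _curve_from_thresholds(
    pos: np.ndarray, neg: np.ndarray, thresholds_desc: np.ndarray
) -> ROCCurve:
    """Confusion counts for rule "abnormal iff score >= t", vectorized.

    ``pos``/``neg`` are the scores of abnormal/normal samples; thresholds
    must be strictly descending. Trivial endpoints are appended as needed.
    """
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    n_pos, n_neg = pos_sorted.size, neg_sorted.size
    # count of scores >= t via searchsorted on ascending arrays
    tp = n_pos - np.searchsorted(pos_sorted, thresholds_desc, side="left")
    fp = n_neg - np.searchsorted(neg_sorted, thresholds_desc, side="left")

    thr = thresholds_desc.astype(float)
    if tp.size == 0 or tp[0] != 0 or fp[0] != 0:
        thr = np.concatenate([[np.inf], thr])
        tp = np.concatenate([[0], tp])
        fp = np.concatenate([[0], fp])
    if tp[-1] != n_pos or fp[-1] != n_neg:
        thr = np.concatenate([thr, [-np.inf]])
        tp = np.concatenate([tp, [n_pos]])
        fp = np.concatenate([fp, [n_neg]])
    return ROCCurve(thresholds=thr, tp=tp, fp=fp, tn=n_neg - fp, fn=n_pos - tp)


def roc_from_scores(scored: ScoredSet) -> ROCCurve:
    """Image-based ROC: one vertex per unique score used as a threshold.

    Raises :class:`SingleClassError` unless both populations (normal and
    abnormal) are present — the protocol requires samples from both.
    """
    if scored.n_abnormal == 0 or scored.n_normal == 0:
        raise SingleClassError(
            "ROC construction requires samples from both populations (normal and abnormal)"
        )
    thresholds = np.unique(scored.scores)[::-1]
    return _curve_from_thresholds(
        scored.scores[scored.abnormal], scored.scores[~scored.abnormal], thresholds
    )


def sample_scores(scores: Sequence[float] | np.ndarray, step: int) -> np.ndarray:
    """Every ``step``-th element (1-based positions step, 2*step, ...) of an
    ascending unique score sequence; ``step=1`` is the identity and a step
    larger than the sequence yields an empty result. Endpoints are not
    force-included."""
    if step < 1:
        raise ValueError("sampling step must be a positive integer")
    arr = np.asarray(scores, dtype=float)
    if arr.size and not (np.diff(arr) > 0).all():
        raise ValueError("scores must be strictly ascending and unique")
    return arr[step - 1 :: step]


def pixel_roc(
    maps: Sequence[LikelihoodImage] | Sequence[np.ndarray],
    truth: Sequence[np.ndarray],
    sampling_step: int = 1,
) -> ROCCurve:
    """Pixel-based ROC over the pooled pixels of all test images.

    ``truth`` holds one binary mask per image (all-zero for normal images).
    Positive pixels are the mask-1 pixels; every other pixel — including all
    pixels of normal images — is a negative. Thresholds are the unique
    global pixel scores, ascending-sorted then thinned by
    :func:`sample_scores` with ``sampling_step``.
    """
    if len(maps) != len(truth):
        raise ValueError("maps and truth masks must be aligned")
    pos_parts: list[np.ndarray] = []
    neg_parts: list[np.ndarray] = []
    for lmap, mask in zip(maps, truth):
        values = lmap.values if isinstance(lmap, LikelihoodImage) else np.asarray(lmap, float)
        m = np.asarray(mask, dtype=bool)
        if m.shape != values.shape:
            raise ValueError("truth mask shape must match its likelihood map")
        if isinstance(lmap, LikelihoodImage) and lmap.fov_mask is not None:
            fov = lmap.fov_mask
            pos_parts.append(values[m & fov])
            neg_parts.append(values[~m & fov])
        else:
            pos_parts.append(values[m])
            neg_parts.append(values[~m])
    pos = np.concatenate(pos_parts)
    neg = np.concatenate(neg_parts)
    if pos.size == 0:
        raise SingleClassError("pixel-based ROC requires at least one abnormal (truth) pixel")
    if neg.size == 0:
        raise SingleClassError("pixel-based ROC requires at least one normal pixel")
    unique_asc = np.unique(np.concatenate([pos, neg]))
    thresholds = sample_scores(unique_asc, sampling_step)[::-1]
    return _curve_from_thresholds(pos, neg, thresholds)


def eer_point(curve: ROCCurve) -> tuple[float, float]:
    """The (FPR, SN) operating point where SN = SP = 1 - EER.

    If a vertex satisfies SN = 1 - FPR exactly it is returned; otherwise the
    crossing of the piecewise-linear curve with the SN = 1 - FPR diagonal is
    found by linear interpolation between the adjacent vertices. The
    endpoints (0, 0) and (1, 1) guarantee a crossing exists.
    """
    x = curve.fpr
    y = curve.sn
    f = y - (1.0 - x)  # non-decreasing along the curve
    exact = np.flatnonzero(f == 0.0)
    if exact.size:
        i = int(exact[0])
        return float(x[i]), float(y[i])
    i = int(np.argmax(f >= 0.0))  # first non-negative; f[0] <= 0 by endpoint (0,0)
    f1, f2 = f[i - 1], f[i]
    t = f1 / (f1 - f2)
    return (
        float(x[i - 1] + t * (x[i] - x[i - 1])),
        float(y[i - 1] + t * (y[i] - y[i - 1])),
    )


def eer(curve: ROCCurve) -> float:
    """Equal error rate: the error at the SN = SP crossing."""
    fpr_star, _sn_star = eer_point(curve)
    return fpr_star


def wer_point(fpr: float, fnr: float, cost_ratio: float) -> float:
    """Weighted error rate (FPR + R * FNR) / (1 + R) at one operating point."""
    if cost_ratio <= 0:
        raise ValueError("cost ratio must be > 0")
    return (fpr + cost_ratio * fnr) / (1.0 + cost_ratio)


def wer(curve: ROCCurve, cost_ratio: float = 1.0) -> float:
    """Best (minimum) weighted error rate over the curve's vertices.

    The point-wise quantity is ``wer_point``; summarizing a curve means
    choosing the operating vertex that minimizes it at the given cost ratio.
    """
    if cost_ratio <= 0:
        raise ValueError("cost ratio must be > 0")
    values = (curve.fpr + cost_ratio * curve.fnr) / (1.0 + cost_ratio)
    return float(values.min())


def auc(curve: ROCCurve) -> float:
    """Trapezoidal area under the (FPR, SN) polyline."""
    order = np.lexsort((curve.sn, curve.fpr))
    return float(np.trapezoid(curve.sn[order], curve.fpr[order]))


@dataclass(frozen=True)
class OperatingSummary:
    """EER / WER / AUC summary of one ROC curve."""

    eer: float
    auc: float
    wer: dict[float, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "eer": self.eer,
            "auc": self.auc,
            "wer": {str(r): v for r, v in self.wer.items()},
        }


def summarize(curve: ROCCurve, cost_ratios: Sequence[float] = (1.0,)) -> OperatingSummary:
    return OperatingSummary(
        eer=eer(curve),
        auc=auc(curve),
        wer={float(r): wer(curve, r) for r in cost_ratios},
    )


def plot_roc(curve: ROCCurve, ax=None, label: str | None = None):
    """Plot the curve with its EER point marked; returns the axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots()
    ax.plot(curve.fpr, curve.sn, marker=".", label=label)
    ex, ey = eer_point(curve)
    ax.plot([ex], [ey], marker="s", color="k")
    ax.plot([0, 1], [1, 0], linestyle=":", color="gray", linewidth=0.8)
    ax.set_xlabel("1 - specificity (FPR)")
    ax.set_ylabel("sensitivity (SN)")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    if label:
        ax.legend()
    return ax
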
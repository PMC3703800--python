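"""Fusion of multi-expert annotations into disambiguated ground truth.

The expert confidence images for one lesion type are spatially averaged per
image; thresholding the average at tau in (0, 1] yields a binary consensus
mask — tau near 0 approaches the union of the expert regions, tau = 1 the
intersection (the threshold comparison is non-strict, so the intersection
limit is attainable). An image is labeled abnormal for the lesion type iff
its mask contains at least one nonzero pixel.

The revised fusion method chooses tau to maximize mutual expert agreement:
for a candidate tau, each expert's images are scored by summax-1% of that
expert's own confidence image, an image-wise ROC is built against the
tau-induced labels, and the experts' equal error rates are averaged. The
optimal tau minimizes this average EER over all candidate thresholds; since
the objective is piecewise constant between attained average-confidence
values, sweeping the attained values (plus 1) is an exhaustive search. The
original fusion method instead fixes tau = 0.75.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import ExpertAnnotationSet
from .evaluation import ScoredSet, eer, roc_from_scores
from .rasterize import ConfidenceImage, confidence_image
from .scoring import summax

__all__ = [
    "ORIGINAL_TAU",
    "AverageConfidenceImage",
    "FusedGroundTruth",
    "TauSearchResult",
    "FusionDataset",
    "average_experts",
    "threshold_mask",
    "mutual_agreement_perf",
    "optimize_tau",
    "fuse_at",
    "original_fusion",
]

#: Fixed consensus threshold of the original fusion method.
ORIGINAL_TAU = 0.75

#: Floating-point slack when deciding which grid points tie for the minimum
#: average EER.
_TIE_TOL = 1e-12


@dataclass(frozen=True)
class AverageConfidenceImage:
    """Pixel-wise mean of the N experts' confidence images for one image."""

    image_id: str
    lesion_type: str
    n_experts: int
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("average confidence image must be 2-D")
        object.__setattr__(self, "values", v)


def average_experts(images: Sequence[ConfidenceImage]) -> AverageConfidenceImage:
    """Exact pixel-wise arithmetic mean over one expert image per expert."""
    if not images:
        raise ValueError("average requires at least one expert image")
    first = images[0]
    for img in images[1:]:
        if img.values.shape != first.values.shape:
            raise ValueError(
                f"size mismatch for image {img.image_id!r}: "
                f"{img.values.shape} vs {first.values.shape}"
            )
    stack = np.stack([img.values for img in images])
    return AverageConfidenceImage(
        image_id=first.image_id,
        lesion_type=first.lesion_type,
        n_experts=len(images),
        values=stack.mean(axis=0),
    )


def threshold_mask(avg: AverageConfidenceImage | np.ndarray, tau: float) -> np.ndarray:
    """Binary consensus mask: pixel set iff average confidence >= tau."""
    if not 0.0 < tau <= 1.0:
        raise ValueError("tau must lie in (0, 1]")
    values = avg.values if isinstance(avg, AverageConfidenceImage) else np.asarray(avg, float)
    return values >= tau


@dataclass(frozen=True)
class FusionDataset:
    """Per-image stacks of expert confidence images for one lesion type.

    ``stacks[i]`` has shape (N, H_i, W_i) with a shared expert ordering
    ``expert_ids`` across all images.
    """

    lesion_type: str
    image_ids: tuple[str, ...]
    expert_ids: tuple[str, ...]
    stacks: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        if len(self.image_ids) != len(self.stacks):
            raise ValueError("one stack per image required")
        n = len(self.expert_ids)
        for image_id, stack in zip(self.image_ids, self.stacks):
            if stack.ndim != 3 or stack.shape[0] != n:
                raise ValueError(f"stack for image {image_id!r} must be (n_experts, H, W)")

    @classmethod
    def from_annotation_sets(
        cls, sets: Sequence[ExpertAnnotationSet], lesion_type: str
    ) -> "FusionDataset":
        """Rasterize a complete (every image x every expert) annotation grid."""
        by_image: dict[str, dict[str, ExpertAnnotationSet]] = {}
        for s in sets:
            by_image.setdefault(s.image_id, {})[s.expert_id] = s
        image_ids = tuple(sorted(by_image))
        expert_ids = tuple(sorted({s.expert_id for s in sets}))
        stacks = []
        for image_id in image_ids:
            per_expert = by_image[image_id]
            missing = [e for e in expert_ids if e not in per_expert]
            if missing:
                raise ValueError(f"image {image_id!r} lacks annotations from experts {missing}")
            stacks.append(
                np.stack(
                    [confidence_image(per_expert[e], lesion_type).values for e in expert_ids]
                )
            )
        return cls(
            lesion_type=lesion_type,
            image_ids=image_ids,
            expert_ids=expert_ids,
            stacks=tuple(stacks),
        )

    @property
    def n_experts(self) -> int:
        return len(self.expert_ids)

    def averages(self) -> tuple[np.ndarray, ...]:
        return tuple(stack.mean(axis=0) for stack in self.stacks)

    def expert_image_scores(self) -> np.ndarray:
        """(N, n_images) matrix of summax-1% scores of each expert's own maps."""
        return np.array(
            [
                [summax(stack[n], 1.0) for stack in self.stacks]
                for n in range(self.n_experts)
            ]
        )


@dataclass(frozen=True)
class FusedGroundTruth:
    """Binary consensus masks and image-wise labels at one threshold."""

    lesion_type: str
    tau: float
    image_ids: tuple[str, ...]
    masks: tuple[np.ndarray, ...]
    image_labels: Mapping[str, str]

    def abnormal_flags(self) -> np.ndarray:
        return np.array([self.image_labels[i] == "abnormal" for i in self.image_ids])

    def save_masks(self, directory: str | Path) -> list[Path]:
        """Write each mask as a 1-bit PNG named <image_id>_<lesion>.png."""
        from PIL import Image

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for image_id, mask in zip(self.image_ids, self.masks):
            path = directory / f"{image_id}_{self.lesion_type}.png"
            Image.fromarray(mask.astype(np.uint8) * 255).convert("1").save(path)
            paths.append(path)
        return paths


def _labels_at(averages: Sequence[np.ndarray], tau: float) -> np.ndarray:
    return np.array([(avg >= tau).any() for avg in averages])


def fuse_at(dataset: FusionDataset, tau: float) -> FusedGroundTruth:
    """Average the experts and threshold at ``tau`` for every image."""
    averages = dataset.averages()
    masks = tuple(threshold_mask(avg, tau) for avg in averages)
    labels = {
        image_id: ("abnormal" if mask.any() else "normal")
        for image_id, mask in zip(dataset.image_ids, masks)
    }
    return FusedGroundTruth(
        lesion_type=dataset.lesion_type,
        tau=tau,
        image_ids=dataset.image_ids,
        masks=masks,
        image_labels=labels,
    )


def original_fusion(dataset: FusionDataset) -> FusedGroundTruth:
    """The original fixed-threshold fusion: average then threshold at 0.75."""
    return fuse_at(dataset, ORIGINAL_TAU)


def mutual_agreement_perf(
    dataset: FusionDataset,
    tau: float,
    *,
    _scores: np.ndarray | None = None,
    _averages: Sequence[np.ndarray] | None = None,
) -> float:
    """Average over experts of the image-wise EER against the tau ground truth.

    Each expert's images are scored with summax-1% of that expert's own
    confidence images and evaluated against the labels induced by
    thresholding the average confidence at ``tau``. Returns NaN (the
    "degenerate" sentinel) when the labels are single-class at this tau,
    which excludes the candidate from the threshold search.
    """
    if len(dataset.image_ids) < 2:
        raise ValueError("mutual agreement needs at least 2 images")
    averages = dataset.averages() if _averages is None else _averages
    labels = _labels_at(averages, tau)
    if labels.all() or not labels.any():
        return math.nan
    scores = dataset.expert_image_scores() if _scores is None else _scores
    eers = [
        eer(roc_from_scores(ScoredSet(scores=scores[n], abnormal=labels)))
        for n in range(dataset.n_experts)
    ]
    return float(np.mean(eers))


@dataclass(frozen=True)
class TauSearchResult:
    """Outcome of the exhaustive mutual-agreement threshold search.

    ``perf_per_tau`` holds the average EER at each candidate (NaN for
    degenerate candidates). All candidates within floating-point tolerance
    of the minimum form the equally performing set; its extremes are exposed
    as ``tau_min`` / ``tau_max`` and the reported optimum defaults to the
    maximum of the interval.
    """

    lesion_type: str
    tau_grid: tuple[float, ...]
    perf_per_tau: tuple[float, ...]
    equally_performing: tuple[float, ...]
    tau_hat: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.equally_performing:
            raise ValueError("no admissible tau")
        object.__setattr__(self, "tau_hat", max(self.equally_performing))

    @property
    def tau_min(self) -> float:
        return min(self.equally_performing)

    @property
    def tau_max(self) -> float:
        return max(self.equally_performing)

    @property
    def best_perf(self) -> float:
        finite = [p for p in self.perf_per_tau if not math.isnan(p)]
        return min(finite)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"tau": self.tau_grid, "perf": self.perf_per_tau})

    def to_json_dict(self) -> dict:
        return {
            "lesion_type": self.lesion_type,
            "tau_hat": self.tau_hat,
            "tau_min": self.tau_min,
            "tau_max": self.tau_max,
            "best_perf": self.best_perf,
            "n_candidates": len(self.tau_grid),
        }


def default_tau_grid(dataset: FusionDataset) -> tuple[float, ...]:
    """Attained positive average-confidence values, plus 1.

    The mutual-agreement objective only changes when tau crosses an attained
    average value, so this grid makes the sweep exhaustive over (0, 1].
    """
    values: set[float] = {1.0}
    for avg in dataset.averages():
        values.update(float(v) for v in np.unique(avg) if v > 0)
    return tuple(sorted(values))


def optimize_tau(
    dataset: FusionDataset, grid: Sequence[float] | None = None
) -> TauSearchResult:
    """Exhaustive search for the threshold maximizing mutual expert agreement.

    Degenerate candidates (single-class labels) are excluded; if every
    candidate is degenerate no admissible tau exists and an error is raised.
    Ties are reported as the full equally performing interval.
    """
    grid_t = tuple(float(t) for t in (grid if grid is not None else default_tau_grid(dataset)))
    if not grid_t:
        raise ValueError("tau grid must be non-empty")
    if any(not 0.0 < t <= 1.0 for t in grid_t):
        raise ValueError("tau candidates must lie in (0, 1]")
    averages = dataset.averages()
    scores = dataset.expert_image_scores()
    perf = tuple(
        mutual_agreement_perf(dataset, t, _scores=scores, _averages=averages) for t in grid_t
    )
    finite = [p for p in perf if not math.isnan(p)]
    if not finite:
        raise ValueError("no admissible tau: every candidate yields single-class labels")
    best = min(finite)
    ties = tuple(
        t for t, p in zip(grid_t, perf) if not math.isnan(p) and p <= best + _TIE_TOL
    )
    return TauSearchResult(
        lesion_type=dataset.lesion_type,
        tau_grid=grid_t,
        perf_per_tau=perf,
        equally_performing=ties,
    )
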
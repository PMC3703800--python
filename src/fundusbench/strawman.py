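"""Photometric baseline detector ("strawman") and its benchmark harness.

The baseline sets the performance floor for the benchmark: it models the
colour distribution p(colour | abnormal) of lesion pixels and scores every
pixel of a test image by evaluating that density at the pixel's colour; the
image-wise score is summax-1% of the resulting likelihood map. The density
estimator here is a kernel-smoothed 3-D colour histogram (32 bins per RGB
channel, Gaussian smoothing), a deliberately simple, deterministic
reconstruction of a photometric-cue classifier. Evaluation is rank-based, so
any positive rescaling of the density leaves ROC results unchanged.

``run_benchmark`` reproduces the benchmark's experimental design: several
random train/test splits, per-lesion-type image-wise EER (reported as
min/max/avg over the iterations) and pooled pixel-wise ROC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from . import evaluation, scoring

__all__ = [
    "ColorModelConfig",
    "ColorLikelihoodModel",
    "train_color_model",
    "likelihood_map",
    "strawman_image_score",
    "BenchmarkResult",
    "run_benchmark",
]


@dataclass(frozen=True)
class ColorModelConfig:
    """Histogram density configuration.

    ``bins`` per channel (32 keeps the table at 32^3 = 32768 cells);
    ``smoothing_sigma`` is the Gaussian kernel width in bin units (0
    disables smoothing); ``min_positive_pixels`` guards against fitting a
    density from almost no evidence.
    """

    bins: int = 32
    smoothing_sigma: float = 1.0
    min_positive_pixels: int = 10

    def __post_init__(self) -> None:
        if self.bins < 2 or self.bins > 256:
            raise ValueError("bins must lie in [2, 256]")
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")


@dataclass(frozen=True)
class ColorLikelihoodModel:
    """Smoothed 3-D colour histogram estimate of p(colour | abnormal)."""

    lesion_type: str
    config: ColorModelConfig
    histogram: np.ndarray  # (bins, bins, bins), sums to 1
    n_training_pixels: int

    def __post_init__(self) -> None:
        h = np.asarray(self.histogram, dtype=float)
        b = self.config.bins
        if h.shape != (b, b, b):
            raise ValueError("histogram shape must be (bins, bins, bins)")
        if not np.isfinite(h).all() or (h < 0).any():
            raise ValueError("histogram must be finite and non-negative")
        total = h.sum()
        if not total > 0:
            raise ValueError("histogram mass must be positive")
        object.__setattr__(self, "histogram", h)

    def _bin_indices(self, colors: np.ndarray) -> tuple[np.ndarray, ...]:
        c = np.asarray(colors)
        if c.dtype != np.uint8:
            c = np.clip(np.asarray(c, dtype=float), 0, 255).astype(np.uint8)
        idx = (c.astype(np.int64) * self.config.bins) // 256
        return idx[..., 0], idx[..., 1], idx[..., 2]

    def evaluate(self, colors: np.ndarray) -> np.ndarray:
        """Density value at each (..., 3) RGB colour (8-bit gamut)."""
        r, g, b = self._bin_indices(colors)
        return self.histogram[r, g, b]

    def save(self, path: str | Path) -> None:
        """Persist as .npz (histogram plus a JSON metadata string)."""
        meta = json.dumps(
            {
                "lesion_type": self.lesion_type,
                "bins": self.config.bins,
                "smoothing_sigma": self.config.smoothing_sigma,
                "min_positive_pixels": self.config.min_positive_pixels,
                "n_training_pixels": self.n_training_pixels,
            }
        )
        np.savez_compressed(path, histogram=self.histogram, meta=np.array(meta))

    @classmethod
    def load(cls, path: str | Path) -> "ColorLikelihoodModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            histogram = data["histogram"]
        return cls(
            lesion_type=meta["lesion_type"],
            config=ColorModelConfig(
                bins=meta["bins"],
                smoothing_sigma=meta["smoothing_sigma"],
                min_positive_pixels=meta["min_positive_pixels"],
            ),
            histogram=histogram,
            n_training_pixels=meta["n_training_pixels"],
        )


def train_color_model(
    images: Sequence[np.ndarray],
    masks: Sequence[np.ndarray],
    lesion_type: str = "lesion",
    config: ColorModelConfig | None = None,
) -> ColorLikelihoodModel:
    """Fit the colour density to the mask-positive pixels of the images.

    The histogram is normalized to unit mass, so duplicating the training
    set leaves the model unchanged. Deterministic given images + config.
    """
    config = config or ColorModelConfig()
    if not images or len(images) != len(masks):
        raise ValueError("need >=1 image with one aligned mask each")
    positives = []
    for img, mask in zip(images, masks):
        img = np.asarray(img)
        m = np.asarray(mask, dtype=bool)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError("images must be (H, W, 3) RGB")
        if m.shape != img.shape[:2]:
            raise ValueError("mask shape must match its image")
        positives.append(img[m])
    colors = np.concatenate(positives)
    if len(colors) < config.min_positive_pixels:
        raise ValueError(
            f"too few positive training pixels: {len(colors)} < {config.min_positive_pixels}"
        )
    idx = (colors.astype(np.int64) * config.bins) // 256
    hist = np.zeros((config.bins,) * 3, dtype=float)
    np.add.at(hist, (idx[:, 0], idx[:, 1], idx[:, 2]), 1.0)
    if config.smoothing_sigma > 0:
        hist = gaussian_filter(hist, sigma=config.smoothing_sigma, mode="constant")
    hist /= hist.sum()
    return ColorLikelihoodModel(
        lesion_type=lesion_type,
        config=config,
        histogram=hist,
        n_training_pixels=len(colors),
    )


def likelihood_map(
    model: ColorLikelihoodModel,
    image: np.ndarray,
    image_id: str = "",
    fov_mask: np.ndarray | None = None,
) -> scoring.LikelihoodImage:
    """Per-pixel density evaluation of an RGB image."""
    values = model.evaluate(np.asarray(image))
    return scoring.LikelihoodImage(
        image_id=image_id,
        lesion_type=model.lesion_type,
        values=values,
        fov_mask=fov_mask,
    )


def strawman_image_score(model: ColorLikelihoodModel, image: np.ndarray) -> float:
    """Image score: summax-1% of the likelihood map."""
    return scoring.summax(likelihood_map(model, image), 1.0)


@dataclass(frozen=True)
class BenchmarkResult:
    """Min/max/avg image-wise EER over train/test iterations, per lesion type,
    plus pooled pixel-wise summaries."""

    lesion_types: tuple[str, ...]
    image_eer: Mapping[str, tuple[float, ...]]  # per-iteration EERs
    pixel_auc: Mapping[str, tuple[float, ...]]
    pixel_eer: Mapping[str, tuple[float, ...]]
    n_iterations: int
    skipped: tuple[tuple[str, int, str], ...] = ()  # (lesion, iteration, reason)

    def eer_stats(self, lesion_type: str) -> dict[str, float]:
        values = self.image_eer[lesion_type]
        return {
            "min": float(np.min(values)),
            "max": float(np.max(values)),
            "avg": float(np.mean(values)),
        }

    def overall_avg_eer(self) -> float:
        """Mean over lesion types of the per-type average image EER."""
        return float(
            np.mean([np.mean(self.image_eer[lt]) for lt in self.lesion_types])
        )

    def to_json_dict(self) -> dict:
        return {
            "n_iterations": self.n_iterations,
            "per_lesion": {
                lt: {
                    "image_eer": self.eer_stats(lt),
                    "pixel_auc_avg": float(np.mean(self.pixel_auc[lt])),
                    "pixel_eer_avg": float(np.mean(self.pixel_eer[lt])),
                }
                for lt in self.lesion_types
            },
            "overall_avg_image_eer": self.overall_avg_eer(),
            "skipped": [list(s) for s in self.skipped],
        }


def run_benchmark(
    images: Sequence[np.ndarray],
    masks_by_type: Mapping[str, Sequence[np.ndarray]],
    *,
    n_iterations: int = 5,
    test_fraction: float = 0.5,
    sampling_step: int = 25,
    seed: int = 0,
    config: ColorModelConfig | None = None,
) -> BenchmarkResult:
    """Train/test the baseline over random splits and summarize ROC results.

    For each iteration the images are split at random; per lesion type a
    colour model is trained on the training images' masks, the test images
    are scored (summax-1%) for the image-wise ROC/EER, and the test pixels
    are pooled for the pixel-wise ROC (thinned with ``sampling_step``).
    Iterations where a lesion type is untrainable (no positive training
    pixels) or unevaluable (single-class test labels) are skipped and
    recorded.
    """
    # distinct stream from any generator seeded with the bare integer, so a
    # scene and its benchmark may share a seed without correlated draws
    rng = np.random.default_rng([seed, 0x5B])
    n = len(images)
    if n < 4:
        raise ValueError("benchmark needs at least 4 images")
    n_test = max(2, int(round(test_fraction * n)))
    lesion_types = tuple(masks_by_type)
    image_eer: dict[str, list[float]] = {lt: [] for lt in lesion_types}
    pixel_auc: dict[str, list[float]] = {lt: [] for lt in lesion_types}
    pixel_eer: dict[str, list[float]] = {lt: [] for lt in lesion_types}
    skipped: list[tuple[str, int, str]] = []

    for it in range(n_iterations):
        order = rng.permutation(n)
        test_idx = order[:n_test]
        train_idx = order[n_test:]
        for lt in lesion_types:
            masks = masks_by_type[lt]
            try:
                model = train_color_model(
                    [images[i] for i in train_idx],
                    [masks[i] for i in train_idx],
                    lesion_type=lt,
                    config=config,
                )
            except ValueError as exc:
                skipped.append((lt, it, f"training: {exc}"))
                continue
            maps = [
                likelihood_map(model, images[i], image_id=str(i)) for i in test_idx
            ]
            scores = np.array([scoring.summax(m, 1.0) for m in maps])
            labels = np.array([np.asarray(masks[i], bool).any() for i in test_idx])
            try:
                curve = evaluation.roc_from_scores(
                    evaluation.ScoredSet(scores=scores, abnormal=labels)
                )
            except evaluation.SingleClassError as exc:
                skipped.append((lt, it, f"image ROC: {exc}"))
                continue
            image_eer[lt].append(evaluation.eer(curve))
            try:
                pcurve = evaluation.pixel_roc(
                    maps,
                    [np.asarray(masks[i], bool) for i in test_idx],
                    sampling_step=sampling_step,
                )
            except evaluation.SingleClassError as exc:
                skipped.append((lt, it, f"pixel ROC: {exc}"))
                continue
            pixel_auc[lt].append(evaluation.auc(pcurve))
            pixel_eer[lt].append(evaluation.eer(pcurve))

    kept = tuple(lt for lt in lesion_types if image_eer[lt])
    return BenchmarkResult(
        lesion_types=kept,
        image_eer={lt: tuple(image_eer[lt]) for lt in kept},
        pixel_auc={lt: tuple(pixel_auc[lt]) for lt in kept},
        pixel_eer={lt: tuple(pixel_eer[lt]) for lt in kept},
        n_iterations=n_iterations,
        skipped=tuple(skipped),
    )
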
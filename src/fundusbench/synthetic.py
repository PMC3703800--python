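"""Synthetic fundus-like scenes with simulated expert annotators.

The generator plants elliptical lesions of several types on a noisy
reddish-brown background and simulates N experts who outline each lesion
with a jittered polygon, occasionally miss a lesion, occasionally add a
spurious marking, and assign a three-level confidence from the lesion's
salience (its effective radius). Every draw funnels through one seeded
generator, so a scene is bit-reproducible from its config.

True lesions are realized as 16-vertex polygon discretizations of the
sampled ellipses — the same discretization the experts jitter — so in the
noiseless limit (zero jitter, zero miss and false-marking rates) an
expert's rasterized support equals the true mask exactly.

``planted_tau_scenario`` constructs a scene with a known consensus level k
out of n experts, arranged so the mutual-agreement threshold search must
recover tau* = k/n; it is the ground-truth recovery probe for the fusion
module.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from shapely.geometry import Polygon as ShapelyPolygon

from .annotations import (
    ConfidenceLevel,
    ExpertAnnotationSet,
    Geometry,
    Marking,
    RepresentativePoint,
    write_annotation_xml,
)
from .rasterize import rasterize_geometry

__all__ = ["SceneConfig", "SyntheticScene", "generate", "planted_tau_scenario"]

#: Colour offsets (added to the background) emulating the photometric
#: appearance of the four exercised lesion types: exudates are bright
#: yellowish deposits, microaneurysms and haemorrhages are dark red.
DEFAULT_LESION_OFFSETS: Mapping[str, tuple[int, int, int]] = {
    "hard_exudates": (90, 90, -20),
    "soft_exudates": (70, 70, 40),
    "microaneurysms": (-50, -35, -15),
    "haemorrhages": (-70, -45, -25),
}

_N_BOUNDARY_SAMPLES = 16


@dataclass(frozen=True)
class SceneConfig:
    """Generator configuration; the defaults define the study conditions.

    Images are 64x64 RGB with background (120, 70, 40) and Gaussian channel
    noise sigma = 8, so the default lesion colour offsets are several noise
    standard deviations away from the background. Four experts outline each
    lesion with 1-pixel boundary jitter, miss it with probability 0.05 and
    add a spurious low-confidence marking to an image with probability 0.02.
    Confidence is assigned from the lesion's effective radius
    sqrt(rx * ry): high above 7 px, moderate above 5.5 px, low below.
    """

    image_size: tuple[int, int] = (64, 64)
    n_images: int = 48
    prevalence: float = 0.5
    lesions_per_image: tuple[int, int] = (1, 3)
    lesion_radius_range: tuple[float, float] = (4.0, 9.0)
    background_color: tuple[int, int, int] = (120, 70, 40)
    channel_noise_sigma: float = 8.0
    lesion_color_offsets: Mapping[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_LESION_OFFSETS)
    )
    n_experts: int = 4
    boundary_jitter_sigma: float = 1.0
    miss_probability: float = 0.05
    false_marking_rate: float = 0.02
    confidence_radius_thresholds: tuple[float, float] = (5.5, 7.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.prevalence, self.miss_probability, self.false_marking_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        lo, hi = self.lesion_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("lesion radius range must be positive and ordered")
        if self.n_experts < 1 or self.n_images < 2:
            raise ValueError("need >=1 expert and >=2 images")
        if self.prevalence > 0 and self.lesions_per_image[1] < 1:
            raise ValueError("abnormal images require a positive lesion count")


@dataclass(frozen=True)
class SyntheticScene:
    """Generated images, hidden truth, and the simulated expert annotations."""

    config: SceneConfig
    image_ids: tuple[str, ...]
    images: tuple[np.ndarray, ...]
    true_masks: Mapping[str, tuple[np.ndarray, ...]]
    annotation_sets: tuple[ExpertAnnotationSet, ...]
    log: tuple[dict, ...]

    @property
    def lesion_types(self) -> tuple[str, ...]:
        return tuple(self.true_masks)

    def abnormal_flags(self, lesion_type: str) -> np.ndarray:
        return np.array([m.any() for m in self.true_masks[lesion_type]])

    def write_to(self, root: str | Path) -> Path:
        """Materialize the scene on disk: PNG images, XML annotations,
        1-bit true-mask PNGs and the config as JSON."""
        from PIL import Image

        root = Path(root)
        (root / "images").mkdir(parents=True, exist_ok=True)
        (root / "annotations").mkdir(exist_ok=True)
        (root / "truth").mkdir(exist_ok=True)
        for image_id, img in zip(self.image_ids, self.images):
            Image.fromarray(img).save(root / "images" / f"{image_id}.png")
        for aset in self.annotation_sets:
            path = root / "annotations" / f"{aset.image_id}_{aset.expert_id}.xml"
            path.write_text(write_annotation_xml(aset), encoding="utf-8")
        for lesion_type, masks in self.true_masks.items():
            for image_id, mask in zip(self.image_ids, masks):
                Image.fromarray(mask.astype(np.uint8) * 255).convert("1").save(
                    root / "truth" / f"{image_id}_{lesion_type}.png"
                )
        cfg = {
            k: (dict(v) if isinstance(v, Mapping) else v)
            for k, v in vars(self.config).items()
        }
        (root / "config.json").write_text(json.dumps(cfg, indent=2), encoding="utf-8")
        return root


def _round6(value: float) -> float:
    return round(float(value), 6)


def _ellipse_polygon_vertices(
    center: tuple[float, float], radii: tuple[float, float], orientation: float
) -> tuple[tuple[float, float], ...]:
    """16 boundary samples of the ellipse, coordinates quantized to 6 dp."""
    cx, cy = center
    rx, ry = radii
    cos_t, sin_t = math.cos(orientation), math.sin(orientation)
    verts = []
    for i in range(_N_BOUNDARY_SAMPLES):
        a = 2.0 * math.pi * i / _N_BOUNDARY_SAMPLES
        u, v = rx * math.cos(a), ry * math.sin(a)
        verts.append(
            (_round6(cx + u * cos_t - v * sin_t), _round6(cy + u * sin_t + v * cos_t))
        )
    return tuple(verts)


def _jitter_polygon(
    vertices: Sequence[tuple[float, float]], sigma: float, rng: np.random.Generator
) -> tuple[tuple[float, float], ...]:
    """Add Gaussian vertex jitter; repair self-intersections by convex hull."""
    if sigma == 0:
        return tuple(vertices)
    arr = np.asarray(vertices, dtype=float) + rng.normal(0.0, sigma, (len(vertices), 2))
    poly = ShapelyPolygon(arr)
    if not poly.is_valid:
        hull = poly.convex_hull
        arr = np.asarray(hull.exterior.coords)[:-1]
    return tuple((_round6(x), _round6(y)) for x, y in arr)


def _confidence_for_radius(r_eff: float, thresholds: tuple[float, float]) -> ConfidenceLevel:
    low_up, high_low = thresholds
    if r_eff >= high_low:
        return ConfidenceLevel.HIGH
    if r_eff >= low_up:
        return ConfidenceLevel.MODERATE
    return ConfidenceLevel.LOW


@dataclass(frozen=True)
class _TrueLesion:
    lesion_type: str
    center: tuple[float, float]
    radii: tuple[float, float]
    orientation: float
    vertices: tuple[tuple[float, float], ...]

    @property
    def effective_radius(self) -> float:
        return math.sqrt(self.radii[0] * self.radii[1])


def _place_lesions(
    cfg: SceneConfig, rng: np.random.Generator
) -> list[_TrueLesion]:
    h, w = cfg.image_size
    lo_n, hi_n = cfg.lesions_per_image
    n_lesions = int(rng.integers(lo_n, hi_n + 1))
    types = tuple(cfg.lesion_color_offsets)
    placed: list[_TrueLesion] = []
    for _ in range(n_lesions):
        for _attempt in range(20):
            rx = float(rng.uniform(*cfg.lesion_radius_range))
            ry = float(rng.uniform(*cfg.lesion_radius_range))
            r_max = max(rx, ry)
            margin = r_max + 2.0
            if 2 * margin >= min(h, w):
                continue
            cx = float(rng.uniform(margin, w - margin))
            cy = float(rng.uniform(margin, h - margin))
            if all(
                math.hypot(cx - p.center[0], cy - p.center[1])
                > r_max + max(p.radii) + 2.0
                for p in placed
            ):
                orientation = float(rng.uniform(0.0, math.pi))
                lesion_type = str(types[rng.integers(len(types))])
                placed.append(
                    _TrueLesion(
                        lesion_type=lesion_type,
                        center=(_round6(cx), _round6(cy)),
                        radii=(_round6(rx), _round6(ry)),
                        orientation=_round6(orientation),
                        vertices=_ellipse_polygon_vertices((cx, cy), (rx, ry), orientation),
                    )
                )
                break
    return placed


def generate(config: SceneConfig | None = None) -> SyntheticScene:
    """Generate a scene: images, hidden true masks, expert annotation sets.

    Deterministic for a fixed config (including its seed). The first
    ``round(prevalence * n_images)`` positions of a seeded permutation are
    abnormal; each abnormal image receives non-overlapping elliptical
    lesions painted as a uniform colour offset over the noisy background.
    """
    cfg = config or SceneConfig()
    n_abnormal = int(round(cfg.prevalence * cfg.n_images))
    if cfg.prevalence > 0 and n_abnormal == 0:
        raise ValueError("infeasible config: positive prevalence but zero abnormal images")
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_size
    types = tuple(cfg.lesion_color_offsets)

    abnormal_positions = set(rng.permutation(cfg.n_images)[:n_abnormal].tolist())
    image_ids = tuple(f"image{i:03d}" for i in range(cfg.n_images))
    images: list[np.ndarray] = []
    true_masks: dict[str, list[np.ndarray]] = {t: [] for t in types}
    lesions_per_image: list[list[_TrueLesion]] = []
    log: list[dict] = []

    for i, image_id in enumerate(image_ids):
        lesions = _place_lesions(cfg, rng) if i in abnormal_positions else []
        if i in abnormal_positions and not lesions:
            raise ValueError("infeasible config: could not place any lesion")
        lesions_per_image.append(lesions)
        base = np.asarray(cfg.background_color, dtype=float)
        img = np.broadcast_to(base, (h, w, 3)).copy()
        img += rng.normal(0.0, cfg.channel_noise_sigma, (h, w, 3))
        masks_here = {t: np.zeros((h, w), dtype=bool) for t in types}
        for lesion in lesions:
            mask = rasterize_geometry(Geometry.polygon(lesion.vertices), cfg.image_size)
            masks_here[lesion.lesion_type] |= mask
            img[mask] += np.asarray(cfg.lesion_color_offsets[lesion.lesion_type], float)
            log.append(
                {
                    "event": "lesion",
                    "image_id": image_id,
                    "lesion_type": lesion.lesion_type,
                    "center": lesion.center,
                    "radii": lesion.radii,
                }
            )
        for t in types:
            true_masks[t].append(masks_here[t])
        images.append(np.clip(img, 0, 255).astype(np.uint8))

    expert_ids = tuple(f"expert{chr(ord('A') + n)}" for n in range(cfg.n_experts))
    annotation_sets: list[ExpertAnnotationSet] = []
    for n, expert_id in enumerate(expert_ids):
        for i, image_id in enumerate(image_ids):
            markings: list[Marking] = []
            for lesion in lesions_per_image[i]:
                if cfg.miss_probability > 0 and rng.random() < cfg.miss_probability:
                    log.append(
                        {
                            "event": "miss",
                            "image_id": image_id,
                            "expert_id": expert_id,
                            "lesion_type": lesion.lesion_type,
                        }
                    )
                    continue
                vertices = _jitter_polygon(
                    lesion.vertices, cfg.boundary_jitter_sigma, rng
                )
                markings.append(
                    Marking(
                        lesion_type=lesion.lesion_type,
                        region=Geometry.polygon(vertices),
                        rep_points=(
                            RepresentativePoint(center=lesion.center, radius=1.0),
                        ),
                        confidence=_confidence_for_radius(
                            lesion.effective_radius, cfg.confidence_radius_thresholds
                        ),
                    )
                )
            if cfg.false_marking_rate > 0 and rng.random() < cfg.false_marking_rate:
                fx = _round6(float(rng.uniform(4, w - 4)))
                fy = _round6(float(rng.uniform(4, h - 4)))
                f_type = str(types[rng.integers(len(types))])
                markings.append(
                    Marking(
                        lesion_type=f_type,
                        region=Geometry.circle((fx, fy), 2.5),
                        rep_points=(RepresentativePoint(center=(fx, fy), radius=1.0),),
                        confidence=ConfidenceLevel.LOW,
                    )
                )
                log.append(
                    {
                        "event": "false_marking",
                        "image_id": image_id,
                        "expert_id": expert_id,
                        "lesion_type": f_type,
                        "center": (fx, fy),
                    }
                )
            annotation_sets.append(
                ExpertAnnotationSet(
                    image_id=image_id,
                    expert_id=expert_id,
                    image_size=cfg.image_size,
                    markings=tuple(markings),
                )
            )

    return SyntheticScene(
        config=cfg,
        image_ids=image_ids,
        images=tuple(images),
        true_masks={t: tuple(m) for t, m in true_masks.items()},
        annotation_sets=tuple(annotation_sets),
        log=tuple(log),
    )


def planted_tau_scenario(
    n_experts: int,
    agreement_level: int,
    *,
    n_true: int = 3,
    n_spurious: int = 3,
    n_blank: int = 2,
    image_size: tuple[int, int] = (64, 64),
    seed: int = 0,
) -> SyntheticScene:
    """A scene whose mutual-agreement optimum is the consensus level k/n.

    ``n_true`` images carry a lesion region marked by exactly k =
    ``agreement_level`` experts at high confidence (so its average
    confidence is k/n); the remaining experts mark a small disjoint
    low-confidence cue on those images, keeping their image scores
    informative. ``n_spurious`` images carry a spurious region marked by
    k - 1 experts at moderate confidence (average 2(k-1)/(3n) < k/n), and
    ``n_blank`` images are unmarked. Every expert's summax scores then
    separate exactly the labeling induced by tau = k/n, and no labeling
    induced by a smaller attained threshold, so the recoverable optimum
    satisfies tau* = k/n.
    """
    n = n_experts
    k = agreement_level
    if not 1 <= k <= n:
        raise ValueError("agreement level must satisfy 1 <= k <= n_experts")
    rng = np.random.default_rng(seed)
    h, w = image_size
    lesion_type = "planted"
    big_r = 6.0
    small_r = 3.0

    expert_ids = tuple(f"expert{chr(ord('A') + i)}" for i in range(n))
    image_ids = tuple(
        [f"true{i:02d}" for i in range(n_true)]
        + [f"spur{i:02d}" for i in range(n_spurious)]
        + [f"blank{i:02d}" for i in range(n_blank)]
    )

    def jittered_center(base_xy: tuple[float, float]) -> tuple[float, float]:
        return (
            _round6(base_xy[0] + rng.uniform(-3, 3)),
            _round6(base_xy[1] + rng.uniform(-3, 3)),
        )

    images: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    markings_by: dict[tuple[str, str], list[Marking]] = {
        (img, e): [] for img in image_ids for e in expert_ids
    }
    log: list[dict] = []

    background = np.full((h, w, 3), (120, 70, 40), dtype=np.uint8)
    # disjoint cue spots for the non-consensus experts, along the top edge
    for image_id in image_ids:
        img = background.copy()
        mask = np.zeros((h, w), dtype=bool)
        if image_id.startswith("true"):
            center = jittered_center((w / 2.0, h / 2.0))
            region = Geometry.circle(center, big_r)
            mask = rasterize_geometry(region, image_size)
            img[mask] = (200, 180, 60)
            rep = (RepresentativePoint(center=center, radius=1.0),)
            for e in expert_ids[:k]:
                markings_by[(image_id, e)].append(
                    Marking(lesion_type, region, rep, ConfidenceLevel.HIGH)
                )
            for idx, e in enumerate(expert_ids[k:]):
                cue_center = jittered_center((8.0 + 10.0 * idx, 8.0))
                cue = Geometry.circle(cue_center, small_r)
                markings_by[(image_id, e)].append(
                    Marking(
                        lesion_type,
                        cue,
                        (RepresentativePoint(center=cue_center, radius=1.0),),
                        ConfidenceLevel.LOW,
                    )
                )
            log.append({"event": "true_region", "image_id": image_id, "center": center})
        elif image_id.startswith("spur") and k >= 2:
            center = jittered_center((w / 2.0, h / 2.0))
            region = Geometry.circle(center, big_r)
            rep = (RepresentativePoint(center=center, radius=1.0),)
            for e in expert_ids[: k - 1]:
                markings_by[(image_id, e)].append(
                    Marking(lesion_type, region, rep, ConfidenceLevel.MODERATE)
                )
            log.append({"event": "spurious_region", "image_id": image_id, "center": center})
        images.append(img)
        masks.append(mask)

    annotation_sets = tuple(
        ExpertAnnotationSet(
            image_id=image_id,
            expert_id=e,
            image_size=image_size,
            markings=tuple(markings_by[(image_id, e)]),
        )
        for image_id in image_ids
        for e in expert_ids
    )
    cfg = SceneConfig(
        image_size=image_size,
        n_images=len(image_ids),
        prevalence=n_true / len(image_ids),
        n_experts=n,
        boundary_jitter_sigma=0.0,
        miss_probability=0.0,
        false_marking_rate=0.0,
        lesion_color_offsets={lesion_type: (80, 110, 20)},
        seed=seed,
    )
    return SyntheticScene(
        config=cfg,
        image_ids=image_ids,
        images=tuple(images),
        true_masks={lesion_type: tuple(masks)},
        annotation_sets=annotation_sets,
        log=tuple(log),
    )
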
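from __future__ import annotations

import numpy as np
import pytest

from fundusbench.annotations import (
    ConfidenceLevel,
    ExpertAnnotationSet,
    Geometry,
    Marking,
    RepresentativePoint,
)
from fundusbench.fusion import FusionDataset

CONFIDENCE_VALUES = (0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0)


def coord(rng: np.random.Generator, lo: float = 0.0, hi: float = 60.0) -> float:
    """A coordinate exactly representable with 6 decimal places."""
    return round(float(rng.uniform(lo, hi)), 6)


def random_marking(rng: np.random.Generator) -> Marking:
    variant = rng.integers(3)
    if variant == 0:
        n = int(rng.integers(3, 8))
        region = Geometry.polygon([(coord(rng), coord(rng)) for _ in range(n)])
    elif variant == 1:
        region = Geometry.circle((coord(rng), coord(rng)), coord(rng, 0.5, 10))
    else:
        region = Geometry.ellipse(
            (coord(rng), coord(rng)),
            (coord(rng, 0.5, 10), coord(rng, 0.5, 10)),
            coord(rng, 0, 3.14),
        )
    lesions = ("hard_exudates", "soft_exudates", "microaneurysms", "haemorrhages")
    return Marking(
        lesion_type=str(lesions[rng.integers(len(lesions))]),
        region=region,
        rep_points=tuple(
            RepresentativePoint((coord(rng), coord(rng)), coord(rng, 0, 2))
            for _ in range(int(rng.integers(1, 3)))
        ),
        confidence=list(ConfidenceLevel)[rng.integers(3)],
    )


def random_annotation_set(rng: np.random.Generator, max_markings: int = 5) -> ExpertAnnotationSet:
    return ExpertAnnotationSet(
        image_id=f"image{int(rng.integers(1000)):03d}",
        expert_id=f"expert{int(rng.integers(10))}",
        image_size=(int(rng.integers(16, 96)), int(rng.integers(16, 96))),
        markings=tuple(random_marking(rng) for _ in range(int(rng.integers(0, max_markings + 1)))),
    )


def random_fusion_dataset(
    rng: np.random.Generator,
    n_images: int | None = None,
    n_experts: int | None = None,
    max_size: int = 16,
) -> FusionDataset:
    """A small random stack dataset with attainable confidence values."""
    n_images = n_images or int(rng.integers(3, 9))
    n_experts = n_experts or int(rng.integers(1, 4))
    h = int(rng.integers(4, max_size + 1))
    w = int(rng.integers(4, max_size + 1))
    stacks = []
    for _ in range(n_images):
        stack = rng.choice(CONFIDENCE_VALUES, size=(n_experts, h, w), p=(0.7, 0.1, 0.1, 0.1))
        stacks.append(np.asarray(stack, dtype=float))
    return FusionDataset(
        lesion_type="hard_exudates",
        image_ids=tuple(f"img{i:02d}" for i in range(n_images)),
        expert_ids=tuple(f"e{i}" for i in range(n_experts)),
        stacks=tuple(stacks),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
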
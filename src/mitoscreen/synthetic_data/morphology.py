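"""Labelled morphology-phenotype image sets for classifier training."""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np

from .field import (FieldImage, GroundTruth, MORPHOLOGY_CLASSES, SceneConfig,
                    generate_field, with_seed)

__all__ = ["generate_morphology_set"]


def generate_morphology_set(
    n_per_class: int,
    classes: Sequence[str],
    seed: int,
    base_config: SceneConfig | None = None,
) -> List[Tuple[FieldImage, GroundTruth]]:
    """Generate ``n_per_class`` fields per morphology class.

    Every cell in a field shares the field's class; the label is stored both
    in ``FieldImage.metadata['morphology']`` and in the per-cell truth table.
    Mitolysosome planting is disabled so the sets isolate network shape.
    """
    classes = list(classes)
    for c in classes:
        if c not in MORPHOLOGY_CLASSES:
            raise ValueError(
                f"unknown morphology class {c!r}; choose from {MORPHOLOGY_CLASSES}")
    if base_config is None:
        base_config = SceneConfig()
    ss = np.random.SeedSequence(seed)
    out: List[Tuple[FieldImage, GroundTruth]] = []
    for ci, cls in enumerate(classes):
        child = ss.spawn(1)[0]
        seeds = child.generate_state(n_per_class)
        for j in range(n_per_class):
            cfg = with_seed(base_config, int(seeds[j] % (2**31)),
                            mito_morphology=cls, mitolysosomes_per_cell=0.0)
            field, truth = generate_field(cfg)
            out.append((field, truth))
    return out
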
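"""Self-contained end-to-end benchmarks run on generated data.

Each function regenerates its inputs from a seed, runs the relevant part of
the package, and returns measured quantities.  They back both the
acceptance test suite and the standalone acceptance report script.
"""

from __future__ import annotations

from typing import Dict

import numpy as np
import pandas as pd
from scipy import stats

from .image_core import LabelMaps, SegmentationConfig
from .morphology import extract_features, train_classifier
from .pipeline import calibrate_from_fields, score_field, score_fields
from .ratiometric import RatioConfig
from .screen import (dunnett_null_maxt, dunnett_test, normalize_to_controls,
                     summarize_wells)
from .synthetic_data import (FieldImage, SceneConfig, generate_field,
                             generate_morphology_set, iter_plate_fields,
                             make_plate_design)

DEFAULT_SEG = SegmentationConfig(background_method="constant")
DEFAULT_RATIO = RatioConfig()


def morphology_holdout_benchmark(seed: int = 0, n_fields_per_class: int = 34,
                                 holdout_fraction: float = 0.25) -> Dict:
    """Train the fragmented-vs-tubular classifier on generated cells and
    report per-class holdout accuracy.

    With the default 6 cells per field, 34 fields per class yields ~200
    cells per class.
    """
    rows = []
    for field, truth in generate_morphology_set(
            n_fields_per_class, ["tubular", "fragmented"], seed):
        maps = LabelMaps(nuclei=truth.nuclei_mask, cells=truth.cell_mask,
                         mito=truth.mito_mask)
        df = extract_features(maps)
        df["label"] = field.metadata["morphology"]
        rows.append(df)
    features = pd.concat(rows, ignore_index=True)
    clf = train_classifier(features, holdout_fraction=holdout_fraction,
                           seed=seed)
    counts = features["label"].value_counts().to_dict()
    return {"per_class_accuracy": clf.per_class_holdout_accuracy,
            "min_accuracy": min(clf.per_class_holdout_accuracy.values()),
            "n_cells_per_class": counts,
            "n_cells": int(len(features))}


def plate_recovery_benchmark(seed: int = 0, n_fields: int = 10) -> Dict:
    """Simulate a screen plate, score it end to end, and compare per-well
    estimates against planted ground truth.

    Returns the Pearson correlation of estimated vs true per-well mean
    red-only counts, and the recovered centered effect of a planted 80%
    mitophagy suppression (true value -0.8).
    """
    scene = SceneConfig(mitolysosomes_per_cell=1.2, rng_seed=seed)
    design = make_plate_design(
        ["KD80", "KD50", "UP50", "NULL1", "NULL2"], n_fields=n_fields,
        effects={"KD80": 0.2, "KD50": 0.5, "UP50": 1.5,
                 "NULL1": 1.0, "NULL2": 0.8},
        n_sint_wells=3, dfp_induction=5.0)
    fields = list(iter_plate_fields(design, scene, seed=seed))

    controls = [img for _, _, img, _ in fields
                if img.metadata["treatment"] == "control"]
    weight = calibrate_from_fields(controls, DEFAULT_SEG, DEFAULT_RATIO)
    cells, _ = score_fields(((w, i, img) for w, i, img, _ in fields),
                            weight, DEFAULT_SEG, DEFAULT_RATIO)
    wells = summarize_wells(cells, design.wells, qc_min_cells=0)

    truth_rows = [{"well_id": w,
                   "truth_count": truth.per_cell_truth["n_mitolysosomes"].mean()}
                  for w, _, _, truth in fields]
    truth = pd.DataFrame(truth_rows).groupby("well_id").mean()
    merged = wells.set_index("well_id").join(truth)
    pearson = float(stats.pearsonr(merged["mean_red_only_count_per_cell"],
                                   merged["truth_count"])[0])
    effects = normalize_to_controls(wells)
    kd80 = float(effects.loc[effects["target_gene"] == "KD80",
                             "centered_effect"].mean())
    return {"pearson_counts": pearson, "kd80_centered_effect": kd80,
            "n_wells": int(len(wells)), "weight": weight.w}


def gain_invariance_benchmark(seed: int = 0) -> Dict:
    """Rescale the red channel by g in {0.5, 1, 2}, recalibrate, and
    measure the relative change in total red-only area per cell."""
    field, _ = generate_field(SceneConfig(rng_seed=seed, psf_sigma=0.8,
                                          mitolysosomes_per_cell=4.0))
    areas = {}
    for gain in (0.5, 1.0, 2.0):
        scaled = FieldImage(
            nuclei=field.nuclei, green=field.green,
            red=field.red.astype(np.float64) * gain, metadata=field.metadata)
        w = calibrate_from_fields([scaled], DEFAULT_SEG, DEFAULT_RATIO)
        cells, _, _ = score_field(scaled, w, DEFAULT_SEG, DEFAULT_RATIO)
        areas[gain] = sum(c.red_only_area_px for c in cells)
    base = areas[1.0]
    rel = max(abs(areas[g] - base) / base for g in (0.5, 2.0))
    return {"areas": areas, "max_rel_change": float(rel)}


def dunnett_calibration_benchmark(seed: int = 0, n_reps: int = 10_000,
                                  n_groups: int = 3, group_size: int = 5,
                                  alpha: float = 0.05,
                                  n_resamples: int = 200_000) -> Dict:
    """Familywise type-I error of the many-to-one test under the global
    null, plus the k=1 agreement with the two-sample t-test.

    The null max-|t| distribution depends only on the design, so it is
    computed once and shared across replicates.
    """
    rng = np.random.default_rng(seed)
    null = dunnett_null_maxt([group_size] * n_groups, group_size,
                             n_resamples=n_resamples, seed=seed)
    rejections = 0
    for _ in range(n_reps):
        ctrl = rng.normal(0, 1, group_size)
        groups = {f"g{i}": rng.normal(0, 1, group_size)
                  for i in range(n_groups)}
        res = dunnett_test(groups, ctrl, alpha=alpha, null_maxt=null)
        if min(res.p_adjusted.values()) < alpha:
            rejections += 1
    fwer = rejections / n_reps

    ctrl = rng.normal(0, 1, 8)
    grp = rng.normal(0.5, 1, 8)
    res1 = dunnett_test({"g": grp}, ctrl)
    t_p = float(stats.ttest_ind(grp, ctrl).pvalue)
    return {"fwer": float(fwer), "alpha": alpha, "n_reps": n_reps,
            "k1_p": res1.p_adjusted["g"], "k1_t_test_p": t_p,
            "k1_abs_diff": abs(res1.p_adjusted["g"] - t_p)}
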
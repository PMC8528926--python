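"""Per-cell mitochondrial shape features and the two-bin phenotype
classifier (fragmented vs tubular), trained on labelled control sets and
applied population-wide."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from skimage import measure, morphology as skmorph

from .image_core import LabelMaps

__all__ = ["FEATURE_NAMES", "extract_cell_features", "extract_features",
           "TrainedClassifier", "train_classifier", "PopulationPhenotype",
           "classify_population"]

FEATURE_NAMES = [
    "n_components",
    "mean_component_area",
    "median_component_area",
    "total_area",
    "form_factor",
    "eccentricity",
    "solidity",
    "skeleton_length_per_area",
    "largest_component_fraction",
    "network_compactness",
]


def extract_cell_features(mito_mask: np.ndarray) -> Dict[str, float]:
    """Shape features of one cell's mitochondrial mask.

    form_factor is mean 4*pi*area/perimeter^2 per component (1 for a disc,
    ->0 for elongated shapes); network_compactness is mask area over the
    convex-hull area of the whole network.  An empty mask yields all zeros
    plus ``empty=1``.
    """
    mask = np.asarray(mito_mask, dtype=bool)
    if not mask.any():
        feats = {name: 0.0 for name in FEATURE_NAMES}
        feats["empty"] = 1.0
        return feats
    labels = measure.label(mask, connectivity=2)
    regions = measure.regionprops(labels)
    areas = np.array([r.area for r in regions], dtype=np.float64)
    ffs, eccs, sols = [], [], []
    for r in regions:
        perim = r.perimeter_crofton if r.perimeter_crofton > 0 else r.perimeter
        if perim <= 0:  # single-pixel component
            ffs.append(1.0)
        else:
            ffs.append(min(1.0, 4.0 * np.pi * r.area / perim**2))
        eccs.append(r.eccentricity)
        sols.append(r.solidity)
    total = float(areas.sum())
    skeleton = skmorph.skeletonize(mask)
    hull_area = float(skmorph.convex_hull_image(mask).sum())
    return {
        "n_components": float(len(regions)),
        "mean_component_area": float(areas.mean()),
        "median_component_area": float(np.median(areas)),
        "total_area": total,
        "form_factor": float(np.mean(ffs)),
        "eccentricity": float(np.mean(eccs)),
        "solidity": float(np.mean(sols)),
        "skeleton_length_per_area": float(skeleton.sum()) / total,
        "largest_component_fraction": float(areas.max()) / total,
        "network_compactness": total / hull_area if hull_area > 0 else 0.0,
        "empty": 0.0,
    }


def extract_features(labelmaps: LabelMaps) -> pd.DataFrame:
    """Per-cell feature table (one row per cell label) from the
    mitochondrial mask restricted to each cell."""
    mito = np.asarray(labelmaps.mito, dtype=bool)
    rows = []
    for cid in np.unique(labelmaps.cells):
        if cid == 0:
            continue
        feats = extract_cell_features(mito & (labelmaps.cells == cid))
        feats["cell_id"] = int(cid)
        rows.append(feats)
    cols = ["cell_id"] + FEATURE_NAMES + ["empty"]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class TrainedClassifier:
    model: RandomForestClassifier
    feature_names: List[str]
    class_labels: List[str]
    per_class_holdout_accuracy: Dict[str, float]
    training_seed: int
    feature_importances: Dict[str, float] = dc_field(default_factory=dict)


def train_classifier(features: pd.DataFrame, holdout_fraction: float = 0.25,
                     seed: int = 0, label_col: str = "label",
                     n_estimators: int = 200) -> TrainedClassifier:
    """Fit a class-balanced random forest with a stratified holdout.

    ``features`` needs one column per entry of FEATURE_NAMES plus a label
    column.  Per-class holdout accuracy (the diagonal of the normalized
    confusion matrix) is recorded for every class.
    """
    missing = [f for f in FEATURE_NAMES if f not in features.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    if label_col not in features.columns:
        raise ValueError(f"no label column {label_col!r}")
    y = features[label_col].to_numpy()
    classes = sorted(pd.unique(y))
    if len(classes) < 2:
        raise ValueError("need at least two classes to train")
    X = features[FEATURE_NAMES].to_numpy(dtype=np.float64)
    constant = [f for f, v in zip(FEATURE_NAMES, X.std(axis=0)) if v == 0]
    if constant:
        warnings.warn(f"degenerate constant features: {constant}")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=holdout_fraction, stratify=y, random_state=seed)
    model = RandomForestClassifier(
        n_estimators=n_estimators, class_weight="balanced", random_state=seed,
        n_jobs=1)
    model.fit(X_tr, y_tr)
    pred = model.predict(X_te)
    acc = {c: float(np.mean(pred[y_te == c] == c)) for c in classes}
    importances = dict(zip(FEATURE_NAMES, model.feature_importances_.tolist()))
    return TrainedClassifier(model=model, feature_names=list(FEATURE_NAMES),
                             class_labels=[str(c) for c in classes],
                             per_class_holdout_accuracy=acc,
                             training_seed=seed,
                             feature_importances=importances)


@dataclass
class PopulationPhenotype:
    sample_id: str
    percentages: Dict[str, float]  # class -> % of population
    n_cells: int

    @property
    def pct_fragmented(self) -> float:
        return self.percentages.get("fragmented", 0.0)

    @property
    def pct_tubular(self) -> float:
        return self.percentages.get("tubular", 0.0)


def classify_population(clf: TrainedClassifier, features: pd.DataFrame,
                        sample_id: str = "") -> PopulationPhenotype:
    """Apply a trained classifier to a per-cell feature table and report the
    class percentages of the population."""
    missing = [f for f in clf.feature_names if f not in features.columns]
    if missing:
        raise ValueError(f"missing features: {missing}")
    if len(features) == 0:
        raise ValueError("empty cell set: nothing to classify")
    X = features[clf.feature_names].to_numpy(dtype=np.float64)
    pred = clf.model.predict(X)
    n = len(pred)
    pct = {c: float(100.0 * np.sum(pred == c) / n) for c in clf.class_labels}
    return PopulationPhenotype(sample_id=sample_id, percentages=pct, n_cells=n)
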
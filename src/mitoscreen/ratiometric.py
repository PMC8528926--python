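"""Ratiometric mitophagy scoring.

The scoring chain is: weight the red channel so that the green/red ratio of
healthy (``yellow``) mitochondria in non-mitophagy controls sits at 1, map
each pixel to green/(w*red), and call connected regions below 0.5 red-only —
i.e. regions at least twice as bright in red as in green — then aggregate
per cell.  Object-integrated variants cover section- and puncta-style data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats
from skimage import measure

from .image_core import LabelMaps

__all__ = [
    "RatioConfig", "ChannelWeight", "RatioMap", "StructureRecord",
    "CellMeasurement", "calibrate_channel_weight", "compute_ratio_map",
    "detect_red_only_structures", "quantify_per_cell",
    "classify_objects_by_integrated_ratio", "grid_quantify",
    "puncta_mitophagy_frequency", "channel_intensity_ratio",
]


@dataclass(frozen=True)
class RatioConfig:
    red_only_threshold: float = 0.5
    yellow_reference: float = 1.0
    min_structure_area: int = 4
    pixel_mode: str = "per_pixel"  # per_pixel | per_object_integrated
    weight_estimator: str = "median_ratio"  # median_ratio | robust_regression
    intensity_floor_frac: float = 0.01  # of the weighted-red 99th percentile
    puncta_overlap_cutoff: float = 0.25

    def validate(self) -> None:
        if not 0 < self.red_only_threshold < self.yellow_reference:
            raise ValueError(
                "need 0 < red_only_threshold < yellow_reference, got "
                f"{self.red_only_threshold} vs {self.yellow_reference}")
        if self.min_structure_area < 1:
            raise ValueError("min_structure_area must be >= 1")
        if self.weight_estimator not in ("median_ratio", "robust_regression"):
            raise ValueError(f"unknown weight_estimator {self.weight_estimator!r}")


@dataclass
class ChannelWeight:
    """Multiplier applied to the red channel before taking ratios."""

    w: float
    n_calibration_pixels: int
    calibration_wells: List[str] = dc_field(default_factory=list)

    def __post_init__(self):
        if not self.w > 0:
            raise ValueError(f"channel weight must be > 0, got {self.w}")


@dataclass
class RatioMap:
    """Per-pixel green/(w*red) ratios plus the channels they came from."""

    ratio: np.ndarray          # NaN where invalid
    valid: np.ndarray          # bool: weighted red above the intensity floor
    green: np.ndarray
    red_weighted: np.ndarray
    floor: float


@dataclass
class StructureRecord:
    structure_id: int
    cell_id: int
    area_px: int
    mean_ratio: float
    integrated_green: float
    integrated_red: float
    centroid: Tuple[float, float]


@dataclass
class CellMeasurement:
    cell_id: int
    red_only_area_px: int
    n_red_only_structures: int
    mito_area_px: int
    field_id: str = ""
    well_id: str = ""


def calibrate_channel_weight(
    control_fields: Sequence[Tuple[np.ndarray, np.ndarray, np.ndarray]],
    cfg: RatioConfig,
    calibration_wells: Sequence[str] = (),
) -> ChannelWeight:
    """Estimate the red-channel weight from non-mitophagy control fields.

    ``control_fields`` holds (green, red, mito_mask) triples of
    background-corrected channels.  After weighting, the central tendency of
    green/(w*red) over control mito pixels equals ``yellow_reference``.
    """
    cfg.validate()
    if not control_fields:
        raise ValueError("need at least one control field for calibration")
    greens, reds = [], []
    for green, red, mask in control_fields:
        mask = np.asarray(mask, dtype=bool)
        g = np.asarray(green, dtype=np.float64)[mask]
        r = np.asarray(red, dtype=np.float64)[mask]
        keep = r > 0
        greens.append(g[keep])
        reds.append(r[keep])
    g = np.concatenate(greens)
    r = np.concatenate(reds)
    if g.size == 0:
        raise ValueError("empty calibration mask: no mito pixels in controls")
    ratios = g / r
    if cfg.weight_estimator == "median_ratio":
        w = float(np.median(ratios)) / cfg.yellow_reference
    else:
        slope, _, _, _ = stats.theilslopes(g, r)
        w = float(slope) / cfg.yellow_reference
    if w <= 0:
        raise ValueError("calibration produced a non-positive weight")
    # crude bimodality screen: a heavy low-ratio tail suggests mitophagy in
    # the calibration wells
    low = np.mean(ratios < 0.5 * np.median(ratios))
    if low > 0.15:
        warnings.warn(
            f"calibration ratio distribution looks bimodal ({low:.0%} of "
            "pixels far below the median); possible mitophagy in controls")
    return ChannelWeight(w=w, n_calibration_pixels=int(g.size),
                         calibration_wells=list(calibration_wells))


def compute_ratio_map(green: np.ndarray, red: np.ndarray,
                      weight: ChannelWeight, cfg: RatioConfig) -> RatioMap:
    """Per-pixel green/(w*red); pixels with weighted red below the intensity
    floor are masked out (NaN) rather than divided."""
    cfg.validate()
    g = np.asarray(green, dtype=np.float64)
    r = np.asarray(red, dtype=np.float64) * weight.w
    if g.shape != r.shape:
        raise ValueError("channel shapes differ")
    p99 = np.percentile(r, 99)
    floor = cfg.intensity_floor_frac * p99 if p99 > 0 else 0.0
    valid = r > max(floor, 0.0)
    ratio = np.full(g.shape, np.nan)
    np.divide(g, r, out=ratio, where=valid)
    return RatioMap(ratio=ratio, valid=valid, green=g, red_weighted=r,
                    floor=float(floor))


def detect_red_only_structures(ratio_map: RatioMap, labelmaps: LabelMaps,
                               cfg: RatioConfig) -> List[StructureRecord]:
    """Connected components of {ratio < threshold}, assigned to cells.

    Components smaller than ``min_structure_area`` are dropped; a component
    is assigned to the cell owning the majority of its pixels (cell 0 means
    unassigned and is handled downstream).
    """
    cfg.validate()
    candidate = ratio_map.valid & (ratio_map.ratio < cfg.red_only_threshold)
    labels = measure.label(candidate, connectivity=2)
    records: List[StructureRecord] = []
    sid = 0
    for region in measure.regionprops(labels):
        if region.area < cfg.min_structure_area:
            continue
        coords = tuple(region.coords.T)
        cells = labelmaps.cells[coords]
        owners, counts = np.unique(cells, return_counts=True)
        cell_id = int(owners[np.argmax(counts)])
        sid += 1
        records.append(StructureRecord(
            structure_id=sid,
            cell_id=cell_id,
            area_px=int(region.area),
            mean_ratio=float(np.nanmean(ratio_map.ratio[coords])),
            integrated_green=float(ratio_map.green[coords].sum()),
            integrated_red=float(ratio_map.red_weighted[coords].sum()),
            centroid=tuple(region.centroid),
        ))
    return records


def quantify_per_cell(structures: Sequence[StructureRecord],
                      labelmaps: LabelMaps,
                      field_id: str = "", well_id: str = "",
                      ) -> Tuple[List[CellMeasurement], int]:
    """Aggregate red-only structures per cell.

    Every segmented cell gets a record (zeros when nothing was detected).
    Structures falling outside any cell are excluded; their count is
    returned as the second element for QC.
    """
    cell_ids = [int(c) for c in np.unique(labelmaps.cells) if c > 0]
    area: Dict[int, int] = {c: 0 for c in cell_ids}
    count: Dict[int, int] = {c: 0 for c in cell_ids}
    n_unassigned = 0
    for s in structures:
        if s.cell_id in area:
            area[s.cell_id] += s.area_px
            count[s.cell_id] += 1
        else:
            n_unassigned += 1
    if n_unassigned:
        warnings.warn(f"{n_unassigned} red-only structures outside any cell "
                      "were excluded")
    mito = np.asarray(labelmaps.mito, dtype=bool)
    out = []
    for c in cell_ids:
        out.append(CellMeasurement(
            cell_id=c, red_only_area_px=area[c], n_red_only_structures=count[c],
            mito_area_px=int(mito[labelmaps.cells == c].sum()),
            field_id=field_id, well_id=well_id))
    return out, n_unassigned


def classify_objects_by_integrated_ratio(
    green: np.ndarray, red: np.ndarray, object_labels: np.ndarray,
    weight: ChannelWeight, cfg: RatioConfig,
) -> pd.DataFrame:
    """Per-object call from integrated intensities.

    The object ratio is sum(green)/(w*sum(red)) over its pixels; objects
    below ``red_only_threshold`` are called red_only, others yellow.
    Objects with zero red integral are flagged and left uncalled.
    """
    cfg.validate()
    g = np.asarray(green, dtype=np.float64)
    r = np.asarray(red, dtype=np.float64)
    labels = np.asarray(object_labels)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    sum_g = ndi.sum_labels(g, labels, index=ids)
    sum_r = ndi.sum_labels(r, labels, index=ids) * weight.w
    rows = []
    for oid, sg, sr in zip(ids, sum_g, sum_r):
        if sr <= 0:
            rows.append({"object_id": int(oid), "ratio": np.nan,
                         "call": "flagged", "flagged": True})
            continue
        ratio = sg / sr
        rows.append({"object_id": int(oid), "ratio": float(ratio),
                     "call": "red_only" if ratio < cfg.red_only_threshold
                     else "yellow",
                     "flagged": False})
    df = pd.DataFrame(rows, columns=["object_id", "ratio", "call", "flagged"])
    if df["flagged"].any():
        warnings.warn(f"{int(df['flagged'].sum())} objects had zero red "
                      "integral and were flagged")
    return df


class RegionTooSmallError(ValueError):
    """Region cannot host the requested number of grid windows."""

    def __init__(self, requested: int, feasible: int, grid_size: int):
        self.max_feasible = feasible
        super().__init__(
            f"region supports at most {feasible} non-overlapping "
            f"{grid_size}x{grid_size} windows, {requested} requested")


def grid_quantify(red_only_labels: np.ndarray, region_mask: np.ndarray,
                  grid_size: int = 250, n_grids: int = 4,
                  seed: int = 0) -> Tuple[float, List[Tuple[int, int]]]:
    """Mean red-only object count over randomly placed square windows.

    Windows are uniform-random, non-overlapping, and lie entirely inside
    the region mask.  Objects are counted by centroid membership.  Returns
    (mean count, list of window top-left corners).
    """
    region = np.asarray(region_mask, dtype=bool)
    labels = np.asarray(red_only_labels)
    h, w = region.shape
    if grid_size > min(h, w):
        raise RegionTooSmallError(n_grids, 0, grid_size)
    # valid top-left corners: the whole window inside the region
    integral = np.pad(region.astype(np.int64), ((1, 0), (1, 0))).cumsum(0).cumsum(1)
    hh, ww = h - grid_size + 1, w - grid_size + 1
    win = (integral[grid_size:grid_size + hh, grid_size:grid_size + ww]
           - integral[:hh, grid_size:grid_size + ww]
           - integral[grid_size:grid_size + hh, :ww]
           + integral[:hh, :ww])
    feasible = np.argwhere(win == grid_size * grid_size)
    # conservative feasibility bound: how many disjoint windows can tile it
    max_disjoint = len({(y // grid_size, x // grid_size) for y, x in feasible})
    if len(feasible) == 0 or max_disjoint < n_grids:
        raise RegionTooSmallError(n_grids, max_disjoint, grid_size)
    rng = np.random.default_rng(seed)
    corners: List[Tuple[int, int]] = []
    best = 0
    for _ in range(200):  # random restarts: greedy placement can dead-end
        corners = []
        order = rng.permutation(len(feasible))
        for idx in order:
            y, x = feasible[idx]
            if all(abs(y - cy) >= grid_size or abs(x - cx) >= grid_size
                   for cy, cx in corners):
                corners.append((int(y), int(x)))
                if len(corners) == n_grids:
                    break
        best = max(best, len(corners))
        if len(corners) == n_grids:
            break
    if len(corners) < n_grids:
        raise RegionTooSmallError(n_grids, best, grid_size)
    centroids = ndi.center_of_mass(labels > 0, labels,
                                   index=np.unique(labels[labels > 0]))
    counts = []
    for y, x in corners:
        n = sum(1 for cy, cx in centroids
                if y <= cy < y + grid_size and x <= cx < x + grid_size)
        counts.append(n)
    return float(np.mean(counts)), corners


def puncta_mitophagy_frequency(puncta_labels: np.ndarray,
                               green_mask: np.ndarray,
                               overlap_cutoff: float = 0.25) -> float:
    """Percentage of puncta lacking green co-localisation.

    A punctum counts as quenched (mitophagic) when less than
    ``overlap_cutoff`` of its area overlaps the green mask.  Returns NaN
    with a warning when there are no puncta.
    """
    labels = np.asarray(puncta_labels)
    gmask = np.asarray(green_mask, dtype=bool)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if len(ids) == 0:
        warnings.warn("puncta_mitophagy_frequency undefined: zero puncta")
        return float("nan")
    areas = ndi.sum_labels(np.ones_like(labels, dtype=np.float64), labels, ids)
    overlaps = ndi.sum_labels(gmask.astype(np.float64), labels, ids)
    quenched = (overlaps / areas) < overlap_cutoff
    return float(100.0 * quenched.sum() / len(ids))


def channel_intensity_ratio(green: np.ndarray, red: np.ndarray,
                            mask: np.ndarray) -> float:
    """Integrated green over integrated red within a mask."""
    g = np.asarray(green, dtype=np.float64)
    r = np.asarray(red, dtype=np.float64)
    m = np.asarray(mask, dtype=bool)
    if g.shape != r.shape or g.shape != m.shape:
        raise ValueError("rasters must share a shape")
    if not m.any():
        raise ValueError("mask is empty")
    denom = r[m].sum()
    if denom <= 0:
        warnings.warn("channel_intensity_ratio undefined: zero red integral")
        return float("nan")
    return float(g[m].sum() / denom)
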
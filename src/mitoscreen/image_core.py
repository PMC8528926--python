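"""Shared image operations: background correction, segmentation,
colocalization.

All operations are deterministic given their configuration; there is no
hidden randomness anywhere in this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import feature, filters, morphology, restoration, segmentation

__all__ = ["SegmentationConfig", "LabelMaps", "subtract_background",
           "segment_nuclei", "segment_cells", "segment_mito",
           "manders_coefficient"]


@dataclass(frozen=True)
class SegmentationConfig:
    nuclei_min_area: int = 40
    nuclei_smoothing_sigma: float = 2.0
    mito_threshold_method: str = "otsu"   # otsu | fixed
    mito_fixed_threshold: float = 0.0
    mito_min_area: int = 2
    cell_assignment: str = "watershed_on_distance"  # or nearest_nucleus
    background_method: str = "rolling_ball"  # rolling_ball | median | constant
    background_radius: int = 25

    def validate(self) -> None:
        if self.nuclei_min_area <= 0 or self.background_radius <= 0:
            raise ValueError("areas and radii must be positive")
        if self.background_method not in ("rolling_ball", "median", "constant"):
            raise ValueError(f"unknown background_method {self.background_method!r}")
        if self.cell_assignment not in ("nearest_nucleus", "watershed_on_distance"):
            raise ValueError(f"unknown cell_assignment {self.cell_assignment!r}")
        if self.mito_threshold_method not in ("otsu", "fixed"):
            raise ValueError(
                f"unknown mito_threshold_method {self.mito_threshold_method!r}")


@dataclass
class LabelMaps:
    """Nuclei/cell label rasters plus the binary mitochondrial mask.

    0 is background everywhere; nucleus label i lies inside cell label i.
    """

    nuclei: np.ndarray
    cells: np.ndarray
    mito: np.ndarray

    def validate(self) -> None:
        for lab in np.unique(self.nuclei):
            if lab == 0:
                continue
            owners = np.unique(self.cells[self.nuclei == lab])
            owners = owners[owners > 0]
            if len(owners) != 1:
                raise AssertionError(f"nucleus {lab} spans cells {owners}")


def _remove_small(mask, min_area: int):
    """remove_small_objects across the skimage 0.26 min_size->max_size
    rename; drops objects with area < min_area."""
    try:
        return morphology.remove_small_objects(mask, max_size=min_area - 1)
    except TypeError:  # older scikit-image
        return morphology.remove_small_objects(mask, min_size=min_area)


def subtract_background(image: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """Estimate and remove the background of a single channel.

    ``constant`` subtracts the global median (exact for flat backgrounds),
    ``median`` a local median surface, ``rolling_ball`` the morphological
    rolling-ball surface. Output is clipped to be nonnegative.
    """
    cfg.validate()
    img = np.asarray(image, dtype=np.float64)
    if np.any(img < 0):
        raise ValueError("expected a nonnegative raster")
    if cfg.background_radius >= min(img.shape):
        raise ValueError(
            f"background_radius {cfg.background_radius} >= image size {img.shape}")
    if cfg.background_method == "constant":
        bg = np.median(img)
    elif cfg.background_method == "median":
        size = 2 * cfg.background_radius + 1
        bg = ndi.median_filter(img, size=size)
    else:
        bg = restoration.rolling_ball(img, radius=cfg.background_radius)
    return np.clip(img - bg, 0, None)


def segment_nuclei(nuclei_channel: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """Threshold + distance-transform watershed nuclei segmentation."""
    cfg.validate()
    img = np.asarray(nuclei_channel, dtype=np.float64)
    smoothed = ndi.gaussian_filter(img, cfg.nuclei_smoothing_sigma)
    if smoothed.max() <= smoothed.min():
        return np.zeros(img.shape, dtype=np.int32)
    mask = smoothed > filters.threshold_otsu(smoothed)
    mask = ndi.binary_fill_holes(mask)
    mask = _remove_small(mask, cfg.nuclei_min_area)
    if not mask.any():
        return np.zeros(img.shape, dtype=np.int32)
    distance = ndi.distance_transform_edt(mask)
    min_dist = max(3, int(round(np.sqrt(cfg.nuclei_min_area / np.pi))))
    peaks = feature.peak_local_max(distance, min_distance=min_dist,
                                   labels=mask, exclude_border=False)
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    labels = segmentation.watershed(-distance, markers, mask=mask)
    labels = _remove_small(labels, cfg.nuclei_min_area)
    return _relabel_sequential(labels)


def _relabel_sequential(labels: np.ndarray) -> np.ndarray:
    out, _, _ = segmentation.relabel_sequential(labels)
    return out.astype(np.int32)


def segment_cells(nuclei_labels: np.ndarray, cytoplasm_proxy: np.ndarray,
                  cfg: SegmentationConfig) -> np.ndarray:
    """Propagate nucleus labels over the above-background foreground.

    Every foreground pixel ends up in exactly one cell and the cell count
    equals the nucleus count. With zero nuclei the map is empty.
    """
    cfg.validate()
    nuclei_labels = np.asarray(nuclei_labels)
    if nuclei_labels.max() == 0:
        return np.zeros(nuclei_labels.shape, dtype=np.int32)
    proxy = ndi.gaussian_filter(np.asarray(cytoplasm_proxy, dtype=np.float64), 2.0)
    if proxy.max() > proxy.min():
        fg = proxy > filters.threshold_otsu(proxy)
    else:
        fg = np.zeros(proxy.shape, dtype=bool)
    fg |= nuclei_labels > 0

    if cfg.cell_assignment == "nearest_nucleus":
        _, (iy, ix) = ndi.distance_transform_edt(nuclei_labels == 0,
                                                 return_indices=True)
        cells = np.where(fg, nuclei_labels[iy, ix], 0)
    else:
        dist_to_nuc = ndi.distance_transform_edt(nuclei_labels == 0)
        cells = segmentation.watershed(dist_to_nuc, nuclei_labels, mask=fg)
        leftover = fg & (cells == 0)
        if leftover.any():  # foreground disconnected from every seed
            _, (iy, ix) = ndi.distance_transform_edt(nuclei_labels == 0,
                                                     return_indices=True)
            cells = np.where(leftover, nuclei_labels[iy, ix], cells)
    return cells.astype(np.int32)


def segment_mito(red_channel: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """Binary mitochondrial mask from a background-corrected channel."""
    cfg.validate()
    img = np.asarray(red_channel, dtype=np.float64)
    if cfg.mito_threshold_method == "fixed":
        mask = img > cfg.mito_fixed_threshold
    else:
        if img.max() <= img.min():
            warnings.warn("segment_mito: flat image with otsu -> empty mask")
            return np.zeros(img.shape, dtype=bool)
        mask = img > filters.threshold_otsu(img)
    if cfg.mito_min_area > 1:
        mask = _remove_small(mask, cfg.mito_min_area)
    return mask


def manders_coefficient(channel_a: np.ndarray, mask_b: np.ndarray,
                        mask_a: np.ndarray) -> float:
    """Fraction of channel A intensity (within mask A) lying inside mask B.

    Returns NaN with a warning when mask A carries no intensity.
    """
    a = np.asarray(channel_a, dtype=np.float64)
    mb = np.asarray(mask_b, dtype=bool)
    ma = np.asarray(mask_a, dtype=bool)
    if a.shape != mb.shape or a.shape != ma.shape:
        raise ValueError("rasters must share a shape")
    denom = a[ma].sum()
    if denom <= 0:
        warnings.warn("manders_coefficient undefined: no intensity in mask_a")
        return float("nan")
    return float(a[ma & mb].sum() / denom)
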
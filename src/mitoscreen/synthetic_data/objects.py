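"""In-vivo-style object fields: tissue sections with scattered mitochondrial
structures, and puncta fields with a planted quenched fraction."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import draw as skdraw

__all__ = ["ObjectFieldTruth", "generate_object_field", "generate_puncta_field"]


@dataclass
class ObjectFieldTruth:
    region_mask: np.ndarray
    object_labels: np.ndarray
    per_object: pd.DataFrame  # object_id, is_red_only, area_px


def generate_object_field(
    image_size: Tuple[int, int] = (600, 600),
    n_objects: int = 120,
    red_only_fraction: float = 0.3,
    redonly_ratio: float = 0.2,
    channel_gain: float = 1.5,
    amplitude: float = 1500.0,
    background_level: float = 80.0,
    psf_sigma: float = 0.8,
    noise_sd: float = 4.0,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray, ObjectFieldTruth]:
    """Section-like field: an elliptical tissue region scattered with
    elongated mitochondrial structures, a planted fraction of them red-only.

    Returns (green, red, truth); channels are float rasters.
    """
    rng = np.random.default_rng(seed)
    h, w = image_size
    region = np.zeros((h, w), dtype=bool)
    rr, cc = skdraw.ellipse(h / 2, w / 2, h * 0.45, w * 0.45, shape=(h, w))
    region[rr, cc] = True

    labels = np.zeros((h, w), dtype=np.int32)
    coords = np.argwhere(ndi.binary_erosion(region, iterations=6))
    rows = []
    placed = 0
    tries = 0
    occupied = np.zeros((h, w), dtype=bool)
    while placed < n_objects and tries < 40 * n_objects:
        tries += 1
        cy, cx = coords[rng.integers(len(coords))]
        obj_rr, obj_cc = skdraw.ellipse(
            cy, cx, rng.uniform(2.0, 4.5), rng.uniform(1.2, 2.5),
            shape=(h, w), rotation=rng.uniform(0, np.pi))
        obj = np.zeros((h, w), dtype=bool)
        obj[obj_rr, obj_cc] = True
        obj &= region
        if obj.sum() < 3 or (ndi.binary_dilation(obj, iterations=3) & occupied).any():
            continue
        placed += 1
        labels[obj] = placed
        occupied |= obj
        rows.append({"object_id": placed,
                     "is_red_only": bool(rng.random() < red_only_fraction),
                     "area_px": int(obj.sum())})
    truth = ObjectFieldTruth(region_mask=region, object_labels=labels,
                             per_object=pd.DataFrame(
                                 rows, columns=["object_id", "is_red_only",
                                                "area_px"]))

    green = np.zeros((h, w), dtype=np.float64)
    red_pre = np.zeros((h, w), dtype=np.float64)
    for row in rows:
        obj = labels == row["object_id"]
        amp = amplitude * rng.uniform(0.8, 1.2)
        red_pre[obj] += amp
        green[obj] += amp * (redonly_ratio if row["is_red_only"] else 1.0)
    red = channel_gain * red_pre
    out = []
    for img in (green, red):
        img = img + background_level
        if psf_sigma > 0:
            img = ndi.gaussian_filter(img, psf_sigma)
        img = img + rng.normal(0, noise_sd, size=img.shape)
        out.append(np.clip(img, 0, None))
    return out[0], out[1], truth


def generate_puncta_field(
    image_size: Tuple[int, int] = (300, 300),
    n_puncta: int = 40,
    quenched_fraction: float = 0.25,
    seed: int = 0,
    punctum_radius: float = 2.5,
) -> Tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Red puncta labels plus a green mask covering the non-quenched ones.

    Returns (puncta_labels, green_mask, per_punctum truth table).
    """
    rng = np.random.default_rng(seed)
    h, w = image_size
    labels = np.zeros((h, w), dtype=np.int32)
    green_mask = np.zeros((h, w), dtype=bool)
    margin = int(punctum_radius) + 3
    rows = []
    occupied = np.zeros((h, w), dtype=bool)
    placed = 0
    tries = 0
    while placed < n_puncta and tries < 60 * n_puncta:
        tries += 1
        cy = rng.integers(margin, h - margin)
        cx = rng.integers(margin, w - margin)
        rr, cc = skdraw.disk((cy, cx), punctum_radius, shape=(h, w))
        punc = np.zeros((h, w), dtype=bool)
        punc[rr, cc] = True
        if (ndi.binary_dilation(punc, iterations=3) & occupied).any():
            continue
        placed += 1
        labels[punc] = placed
        occupied |= punc
        quenched = bool(rng.random() < quenched_fraction)
        if not quenched:
            green_mask |= ndi.binary_dilation(punc, iterations=1)
        rows.append({"punctum_id": placed, "quenched": quenched})
    return labels, green_mask, pd.DataFrame(
        rows, columns=["punctum_id", "quenched"])
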
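"""Two-channel tandem-tag reporter scene generator with ground truth.

Scenes contain nuclei, per-cell mitochondrial networks rendered identically
in both channels (``yellow``), and mitolysosome puncta rendered with a
quenched green channel (``red-only``).  A channel gain multiplier, constant
background, Gaussian blur and shot/read noise are applied on top, so every
downstream correction step has something real to correct.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import draw as skdraw
from skimage.morphology import dilation, disk

__all__ = [
    "SceneConfig",
    "FieldImage",
    "GroundTruth",
    "SceneSizeError",
    "generate_field",
]

MORPHOLOGY_CLASSES = ("tubular", "fragmented", "clumped")
NOISE_MODELS = ("poisson", "gaussian", "both", "none")


class SceneSizeError(ValueError):
    """Raised when the requested cells cannot be placed in the image."""


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one simulated field.

    Structure size and brightness are free parameters (not pinned down by
    any published measurement) and are exposed here with sensible defaults.
    """

    image_size: Tuple[int, int] = (256, 256)
    n_cells: int = 6
    mitolysosomes_per_cell: float = 3.0
    mito_morphology: str = "tubular"
    network_density: float = 0.12
    redonly_ratio: float = 0.2
    channel_gain: float = 1.5
    background_level: float = 100.0
    psf_sigma: float = 1.0
    noise_model: str = "both"
    rng_seed: int = 0
    # geometry / photometry knobs
    cell_radius: float = 36.0
    nucleus_radius: float = 10.0
    mito_amplitude: float = 2000.0
    nuclei_amplitude: float = 1500.0
    cytoplasm_level: float = 150.0
    lysosome_radius: float = 2.5
    read_noise_sd: float = 4.0

    def validate(self) -> None:
        h, w = self.image_size
        if h < 64 or w < 64:
            raise ValueError(f"image_size must be >= 64x64, got {self.image_size}")
        if not 0.0 <= self.network_density <= 1.0:
            raise ValueError("network_density must be in [0, 1]")
        if self.redonly_ratio < 0:
            raise ValueError("redonly_ratio must be >= 0")
        if self.channel_gain <= 0:
            raise ValueError("channel_gain must be > 0")
        if self.mitolysosomes_per_cell < 0:
            raise ValueError("mitolysosomes_per_cell must be >= 0")
        if self.mito_morphology not in MORPHOLOGY_CLASSES:
            raise ValueError(
                f"unknown morphology {self.mito_morphology!r}; "
                f"choose from {MORPHOLOGY_CLASSES}"
            )
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")


@dataclass
class FieldImage:
    """One imaged field: three 16-bit channel rasters plus metadata."""

    nuclei: np.ndarray
    green: np.ndarray
    red: np.ndarray
    metadata: Dict = dc_field(default_factory=dict)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.green.shape


@dataclass
class GroundTruth:
    """Planted labels for one field.

    ``per_cell_truth`` columns: cell_id, n_mitolysosomes, red_only_area_px,
    morphology_class.  Mitolysosome labels never intersect the yellow
    network mask and each lies inside exactly one cell.
    """

    nuclei_mask: np.ndarray
    cell_mask: np.ndarray
    mito_mask: np.ndarray
    mitolysosome_mask: np.ndarray
    per_cell_truth: pd.DataFrame

    def validate(self) -> None:
        if np.any(self.mito_mask & (self.mitolysosome_mask > 0)):
            raise AssertionError("mitolysosome mask intersects mito mask")
        for lab in np.unique(self.mitolysosome_mask):
            if lab == 0:
                continue
            cells = np.unique(self.cell_mask[self.mitolysosome_mask == lab])
            cells = cells[cells > 0]
            if len(cells) != 1:
                raise AssertionError(f"mitolysosome {lab} spans cells {cells}")


def _place_cell_centers(rng: np.random.Generator, shape, n_cells, radius,
                        max_tries: int = 4000):
    h, w = shape
    margin = 0.75 * radius
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise SceneSizeError(
            f"image {shape} too small for cells of radius {radius}")
    min_sep2 = (1.65 * radius) ** 2
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n_cells:
        if tries >= max_tries:
            raise SceneSizeError(
                f"could not place {n_cells} cells of radius {radius} in "
                f"image {shape} (placed {len(centers)})")
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        if all((cy - y) ** 2 + (cx - x) ** 2 >= min_sep2 for y, x in centers):
            centers.append((cy, cx))
        tries += 1
    return centers


def _ellipse_mask(shape, center, r_major, r_minor, theta) -> np.ndarray:
    rr, cc = skdraw.ellipse(center[0], center[1], r_major, r_minor,
                            shape=shape, rotation=theta)
    m = np.zeros(shape, dtype=bool)
    m[rr, cc] = True
    return m


def _tubular_network(rng, cytoplasm, center, target_area) -> np.ndarray:
    """Persistent random walks from near the nucleus, dilated to ~3 px."""
    h, w = cytoplasm.shape
    path = np.zeros((h, w), dtype=bool)
    walks = 0
    while path.sum() * 5 < target_area and walks < 60:  # disk(1) dilation ~x5
        ang = rng.uniform(0, 2 * math.pi)
        r0 = rng.uniform(8, 14)
        y = center[0] + r0 * math.sin(ang)
        x = center[1] + r0 * math.cos(ang)
        direction = ang + rng.normal(0, 0.4)
        for _ in range(rng.integers(40, 90)):
            y += 1.4 * math.sin(direction)
            x += 1.4 * math.cos(direction)
            iy, ix = int(round(y)), int(round(x))
            if not (0 <= iy < h and 0 <= ix < w) or not cytoplasm[iy, ix]:
                break
            path[iy, ix] = True
            direction += rng.normal(0, 0.28)
        walks += 1
    return dilation(path, disk(1)) & cytoplasm


def _fragmented_network(rng, cytoplasm, target_area) -> np.ndarray:
    mask = np.zeros_like(cytoplasm)
    coords = np.argwhere(cytoplasm)
    if len(coords) == 0:
        return mask
    tries = 0
    while mask.sum() < target_area and tries < 400:
        cy, cx = coords[rng.integers(len(coords))]
        frag = _ellipse_mask(cytoplasm.shape, (cy, cx),
                             rng.uniform(1.6, 3.2), rng.uniform(1.0, 2.0),
                             rng.uniform(0, math.pi))
        mask |= frag & cytoplasm
        tries += 1
    return mask


def _clumped_network(rng, cytoplasm, center, target_area) -> np.ndarray:
    mask = np.zeros_like(cytoplasm)
    coords = np.argwhere(cytoplasm)
    if len(coords) == 0:
        return mask
    hub = coords[rng.integers(len(coords))]
    tries = 0
    while mask.sum() < target_area and tries < 400:
        cy = hub[0] + rng.normal(0, 5.0)
        cx = hub[1] + rng.normal(0, 5.0)
        blob = _ellipse_mask(cytoplasm.shape, (cy, cx),
                             rng.uniform(2.5, 5.0), rng.uniform(2.0, 4.0),
                             rng.uniform(0, math.pi))
        mask |= blob & cytoplasm
        tries += 1
    return mask


def _place_mitolysosomes(rng, cell_region, mito_mask, n_wanted, radius):
    """Non-overlapping puncta inside one cell, clear of the network."""
    shape = cell_region.shape
    forbidden = dilation(mito_mask, disk(2))
    allowed = cell_region & ~forbidden
    # keep puncta well inside the cell: segmentation boundaries between
    # neighbouring cells jitter by a few pixels, so a generous margin keeps
    # the true owner unambiguous
    allowed &= ndi.binary_erosion(cell_region, disk(int(math.ceil(radius)) + 4))
    coords = np.argwhere(allowed)
    placed = []
    occupied = np.zeros(shape, dtype=bool)
    tries = 0
    while len(placed) < n_wanted and tries < 80 * max(n_wanted, 1) and len(coords):
        cy, cx = coords[rng.integers(len(coords))]
        rr, cc = skdraw.disk((cy, cx), radius, shape=shape)
        punc = np.zeros(shape, dtype=bool)
        punc[rr, cc] = True
        punc &= cell_region
        grown = dilation(punc, disk(3))
        if not (grown & (occupied | forbidden)).any():
            placed.append(punc)
            occupied |= punc
        tries += 1
    return placed


def generate_field(config: SceneConfig) -> Tuple[FieldImage, GroundTruth]:
    """Render one field and its ground truth.

    Pre-noise photometry: yellow network pixels have green/red equal to
    ``1/channel_gain``; mitolysosome pixels have green/red equal to
    ``redonly_ratio/channel_gain``.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    h, w = config.image_size
    shape = (h, w)

    centers = _place_cell_centers(rng, shape, config.n_cells, config.cell_radius)

    cell_mask = np.zeros(shape, dtype=np.int32)
    nuclei_mask = np.zeros(shape, dtype=np.int32)
    mito_mask = np.zeros(shape, dtype=bool)
    lys_mask = np.zeros(shape, dtype=np.int32)

    if centers:
        yy, xx = np.mgrid[0:h, 0:w]
        d2 = np.stack([(yy - cy) ** 2 + (xx - cx) ** 2 for cy, cx in centers])
        nearest = np.argmin(d2, axis=0)
        radii = config.cell_radius * rng.uniform(0.88, 1.05, size=len(centers))
        for i in range(len(centers)):
            cell_mask[(nearest == i) & (d2[i] <= radii[i] ** 2)] = i + 1

    rows = []
    lys_label = 0
    cell_amp = np.ones(len(centers))
    for i, (cy, cx) in enumerate(centers):
        cid = i + 1
        region = cell_mask == cid
        nuc = _ellipse_mask(shape, (cy, cx),
                            config.nucleus_radius * rng.uniform(0.85, 1.15),
                            config.nucleus_radius * rng.uniform(0.7, 1.0),
                            rng.uniform(0, math.pi)) & region
        nuclei_mask[nuc] = cid
        cytoplasm = region & ~dilation(nuc, disk(2))
        target = config.network_density * cytoplasm.sum()
        if config.mito_morphology == "tubular":
            net = _tubular_network(rng, cytoplasm, (cy, cx), target)
        elif config.mito_morphology == "fragmented":
            net = _fragmented_network(rng, cytoplasm, target)
        else:
            net = _clumped_network(rng, cytoplasm, (cy, cx), target)
        mito_mask |= net

        n_lys = int(rng.poisson(config.mitolysosomes_per_cell))
        puncta = _place_mitolysosomes(rng, cytoplasm, net, n_lys,
                                      config.lysosome_radius)
        area = 0
        for punc in puncta:
            lys_label += 1
            lys_mask[punc] = lys_label
            area += int(punc.sum())
        cell_amp[i] = rng.uniform(0.85, 1.15)
        rows.append({"cell_id": cid, "n_mitolysosomes": len(puncta),
                     "red_only_area_px": area,
                     "morphology_class": config.mito_morphology})

    truth = GroundTruth(
        nuclei_mask=nuclei_mask, cell_mask=cell_mask, mito_mask=mito_mask,
        mitolysosome_mask=lys_mask,
        per_cell_truth=pd.DataFrame(
            rows, columns=["cell_id", "n_mitolysosomes", "red_only_area_px",
                           "morphology_class"]),
    )

    # --- photometry ---------------------------------------------------
    amp_map = np.zeros(shape, dtype=np.float64)
    for i in range(len(centers)):
        amp_map[cell_mask == i + 1] = config.mito_amplitude * cell_amp[i]

    haze = np.where(cell_mask > 0, config.cytoplasm_level, 0.0)
    # inside a mitolysosome the whole green signal (reporter + cytoplasmic
    # haze) is quenched, so green/red there is exactly redonly_ratio/gain
    green = np.where(lys_mask > 0,
                     config.redonly_ratio * (haze + amp_map),
                     haze + np.where(mito_mask, amp_map, 0.0))
    red_pre = haze + np.where(mito_mask | (lys_mask > 0), amp_map, 0.0)
    red = config.channel_gain * red_pre
    nuc_ch = np.where(nuclei_mask > 0, config.nuclei_amplitude, 0.0)

    channels = []
    for img in (nuc_ch, green, red):
        img = img + config.background_level
        if config.psf_sigma > 0:
            img = ndi.gaussian_filter(img, config.psf_sigma)
        if config.noise_model in ("poisson", "both"):
            img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
        if config.noise_model in ("gaussian", "both"):
            img = img + rng.normal(0, config.read_noise_sd, size=shape)
        channels.append(np.clip(np.round(img), 0, 65535).astype(np.uint16))

    field = FieldImage(nuclei=channels[0], green=channels[1], red=channels[2],
                       metadata={"config": config, "seed": config.rng_seed,
                                 "morphology": config.mito_morphology})
    return field, truth


def with_seed(config: SceneConfig, seed: int, **overrides) -> SceneConfig:
    """Copy ``config`` with a new seed (and optional field overrides)."""
    return replace(config, rng_seed=int(seed), **overrides)
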
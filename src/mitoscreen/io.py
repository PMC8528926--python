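"""File I/O: per-channel 16-bit TIFFs, label TIFFs, CSV tables."""

from __future__ import annotations

import os
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import pandas as pd
import tifffile

from .synthetic_data import FieldImage, GroundTruth

CHANNELS = ("nuclei", "green", "red")


def write_field(outdir, name: str, field: FieldImage,
                truth: GroundTruth | None = None) -> None:
    """Write one field as three channel TIFFs (plus ground-truth label
    TIFFs and a per-cell CSV when truth is given)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ch in CHANNELS:
        tifffile.imwrite(outdir / f"{name}_{ch}.tif", getattr(field, ch))
    if truth is not None:
        tifffile.imwrite(outdir / f"{name}_gt_cells.tif",
                         truth.cell_mask.astype(np.uint16))
        tifffile.imwrite(outdir / f"{name}_gt_nuclei.tif",
                         truth.nuclei_mask.astype(np.uint16))
        tifffile.imwrite(outdir / f"{name}_gt_mito.tif",
                         truth.mito_mask.astype(np.uint8))
        tifffile.imwrite(outdir / f"{name}_gt_mitolysosomes.tif",
                         truth.mitolysosome_mask.astype(np.uint16))
        truth.per_cell_truth.to_csv(outdir / f"{name}_gt_cells.csv", index=False)


def read_field(directory, name: str) -> FieldImage:
    directory = Path(directory)
    arrays = {ch: tifffile.imread(directory / f"{name}_{ch}.tif")
              for ch in CHANNELS}
    return FieldImage(nuclei=arrays["nuclei"], green=arrays["green"],
                      red=arrays["red"], metadata={"name": name})


def list_fields(directory) -> Dict[str, Tuple[str, int]]:
    """Map field name -> (well_id, field_index) from files named
    ``<well>_f<i>_green.tif``."""
    out = {}
    for fn in sorted(os.listdir(directory)):
        if fn.endswith("_green.tif"):
            name = fn[:-len("_green.tif")]
            well, _, fidx = name.rpartition("_f")
            out[name] = (well or name, int(fidx) if fidx.isdigit() else 0)
    return out


def write_layout(path, design_wells: pd.DataFrame) -> None:
    design_wells.to_csv(path, index=False)


def read_layout(path) -> pd.DataFrame:
    return pd.read_csv(path)
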
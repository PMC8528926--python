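"""End-to-end scoring: background correction -> segmentation -> channel
calibration -> ratio mapping -> red-only detection -> per-cell/per-well
tables.  This is the glue used by the CLI and by screen simulations."""

from __future__ import annotations

from dataclasses import asdict
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .image_core import (LabelMaps, SegmentationConfig, segment_cells,
                         segment_mito, segment_nuclei, subtract_background)
from .ratiometric import (CellMeasurement, ChannelWeight, RatioConfig,
                          StructureRecord, calibrate_channel_weight,
                          compute_ratio_map, detect_red_only_structures,
                          quantify_per_cell)
from .synthetic_data import FieldImage

__all__ = ["segment_field", "calibrate_from_fields", "score_field",
           "score_fields", "cells_to_frame", "structures_to_frame",
           "match_cells_to_truth"]


def match_cells_to_truth(seg_cells: np.ndarray,
                         truth_nuclei: np.ndarray) -> Dict[int, int]:
    """Map ground-truth cell id -> segmented cell label via majority overlap
    of the true nucleus. Unmatched truth cells map to 0."""
    mapping: Dict[int, int] = {}
    for tc in np.unique(truth_nuclei):
        if tc == 0:
            continue
        ids, counts = np.unique(seg_cells[truth_nuclei == tc],
                                return_counts=True)
        mapping[int(tc)] = int(ids[np.argmax(counts)])
    return mapping


def segment_field(field: FieldImage, seg_cfg: SegmentationConfig,
                  ) -> Tuple[LabelMaps, np.ndarray, np.ndarray]:
    """Segment one field; returns (labelmaps, corrected green, corrected red)."""
    green = subtract_background(field.green, seg_cfg)
    red = subtract_background(field.red, seg_cfg)
    nuclei = segment_nuclei(field.nuclei, seg_cfg)
    cells = segment_cells(nuclei, field.red, seg_cfg)
    mito = segment_mito(red, seg_cfg)
    return LabelMaps(nuclei=nuclei, cells=cells, mito=mito), green, red


def calibrate_from_fields(control_fields: Sequence[FieldImage],
                          seg_cfg: SegmentationConfig,
                          ratio_cfg: RatioConfig) -> ChannelWeight:
    """Segment control fields and calibrate the red-channel weight on their
    mitochondrial pixels."""
    triples = []
    wells = []
    for f in control_fields:
        maps, green, red = segment_field(f, seg_cfg)
        triples.append((green, red, maps.mito))
        wells.append(str(f.metadata.get("well_id", "")))
    return calibrate_channel_weight(triples, ratio_cfg,
                                    calibration_wells=sorted(set(wells)))


def score_field(field: FieldImage, weight: ChannelWeight,
                seg_cfg: SegmentationConfig, ratio_cfg: RatioConfig,
                field_id: str = "", well_id: str = "",
                ) -> Tuple[List[CellMeasurement], List[StructureRecord], LabelMaps]:
    maps, green, red = segment_field(field, seg_cfg)
    rmap = compute_ratio_map(green, red, weight, ratio_cfg)
    structures = detect_red_only_structures(rmap, maps, ratio_cfg)
    cells, _ = quantify_per_cell(structures, maps, field_id=field_id,
                                 well_id=well_id)
    return cells, structures, maps


def score_fields(fields: Iterable[Tuple[str, int, FieldImage]],
                 weight: ChannelWeight, seg_cfg: SegmentationConfig,
                 ratio_cfg: RatioConfig,
                 ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Score (well_id, field_index, image) triples into cell and structure
    tables."""
    all_cells: List[CellMeasurement] = []
    all_structures: List[Dict] = []
    for well_id, idx, field in fields:
        fid = f"{well_id}_f{idx}"
        cells, structures, _ = score_field(field, weight, seg_cfg, ratio_cfg,
                                           field_id=fid, well_id=well_id)
        all_cells.extend(cells)
        for s in structures:
            row = asdict(s)
            row.update(field_id=fid, well_id=well_id)
            all_structures.append(row)
    return cells_to_frame(all_cells), pd.DataFrame(all_structures)


def cells_to_frame(cells: Sequence[CellMeasurement]) -> pd.DataFrame:
    return pd.DataFrame([asdict(c) for c in cells],
                        columns=["cell_id", "red_only_area_px",
                                 "n_red_only_structures", "mito_area_px",
                                 "field_id", "well_id"])


def structures_to_frame(structures: Sequence[StructureRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in structures])
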
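"""Screen-plate simulation: layouts with planted effects, rendered fields."""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, Iterator, Sequence, Tuple

import numpy as np
import pandas as pd

from .field import FieldImage, GroundTruth, SceneConfig, generate_field, with_seed

__all__ = ["PlateDesign", "PlateConfigError", "make_plate_design",
           "generate_plate", "iter_plate_fields"]

CONTROL_TARGET = "siNT"
TREATMENTS = ("control", "DFP")


class PlateConfigError(ValueError):
    """Raised for invalid plate layouts (e.g. missing siNT controls)."""


@dataclass
class PlateDesign:
    """Well table for a simulated plate.

    Columns of ``wells``: well_id, treatment (control|DFP), target_gene,
    oligo_id, planted_effect (multiplicative change in mitolysosome rate),
    n_fields.
    """

    wells: pd.DataFrame
    dfp_induction: float = 6.0
    metadata: Dict = dc_field(default_factory=dict)

    def validate(self) -> None:
        required = {"well_id", "treatment", "target_gene", "oligo_id",
                    "planted_effect", "n_fields"}
        missing = required - set(self.wells.columns)
        if missing:
            raise PlateConfigError(f"wells table missing columns {sorted(missing)}")
        if (self.wells["planted_effect"] <= 0).any():
            raise PlateConfigError("planted_effect must be > 0 for every well")
        bad = set(self.wells["treatment"]) - set(TREATMENTS)
        if bad:
            raise PlateConfigError(f"unknown treatments {sorted(bad)}")
        for arm in self.wells["treatment"].unique():
            sub = self.wells[self.wells["treatment"] == arm]
            if not (sub["target_gene"] == CONTROL_TARGET).any():
                raise PlateConfigError(f"no {CONTROL_TARGET} well in {arm} arm")

    @property
    def control_wells(self) -> list:
        sel = self.wells["target_gene"] == CONTROL_TARGET
        return list(self.wells.loc[sel, "well_id"])


def make_plate_design(
    targets: Sequence[str],
    n_fields: int = 10,
    effects: Dict[str, float] | None = None,
    n_sint_wells: int = 3,
    treatment: str = "DFP",
    include_control_arm: bool = True,
    oligos_per_target: int = 1,
    dfp_induction: float = 6.0,
) -> PlateDesign:
    """Convenience constructor: one well per target (or per oligo), plus
    siNT control wells in each treatment arm."""
    effects = effects or {}
    rows = []
    idx = 0

    def add(treat, target, oligo, eff):
        nonlocal idx
        idx += 1
        rows.append({"well_id": f"W{idx:03d}", "treatment": treat,
                     "target_gene": target, "oligo_id": oligo,
                     "planted_effect": float(eff), "n_fields": int(n_fields)})

    for i in range(n_sint_wells):
        add(treatment, CONTROL_TARGET, f"{CONTROL_TARGET}_pool", 1.0)
    if include_control_arm:
        for i in range(max(1, n_sint_wells // 2)):
            add("control", CONTROL_TARGET, f"{CONTROL_TARGET}_pool", 1.0)
    for t in targets:
        if oligos_per_target == 1:
            add(treatment, t, f"{t}_pool", effects.get(t, 1.0))
        else:
            for k in range(1, oligos_per_target + 1):
                oid = f"{t}_o{k}"
                eff = effects.get(oid, effects.get(t, 1.0))
                add(treatment, t, oid, eff)
    return PlateDesign(wells=pd.DataFrame(rows), dfp_induction=dfp_induction)


def _well_rate(design: PlateDesign, base_rate: float, row) -> float:
    factor = design.dfp_induction if row["treatment"] == "DFP" else 1.0
    return base_rate * factor * row["planted_effect"]


def iter_plate_fields(
    design: PlateDesign, base_config: SceneConfig, seed: int | None = None,
) -> Iterator[Tuple[str, int, FieldImage, GroundTruth]]:
    """Yield (well_id, field_index, image, truth) lazily.

    The per-well mitolysosome rate is ``base rate x treatment factor x
    planted_effect``; field seeds derive deterministically from the plate
    seed and the well/field indices.
    """
    design.validate()
    plate_seed = base_config.rng_seed if seed is None else seed
    for wi, (_, row) in enumerate(design.wells.iterrows()):
        rate = _well_rate(design, base_config.mitolysosomes_per_cell, row)
        for fi in range(int(row["n_fields"])):
            ss = np.random.SeedSequence(entropy=(plate_seed, wi, fi))
            cfg = with_seed(base_config, int(ss.generate_state(1)[0] % (2**31)),
                            mitolysosomes_per_cell=rate)
            img, truth = generate_field(cfg)
            img.metadata.update(well_id=row["well_id"], field_index=fi,
                                treatment=row["treatment"],
                                target_gene=row["target_gene"],
                                oligo_id=row["oligo_id"])
            yield row["well_id"], fi, img, truth


def generate_plate(
    design: PlateDesign, base_config: SceneConfig, seed: int | None = None,
) -> Dict[Tuple[str, int], Tuple[FieldImage, GroundTruth]]:
    """Materialize all fields of a plate keyed by (well_id, field_index)."""
    return {(w, i): (img, truth)
            for w, i, img, truth in iter_plate_fields(design, base_config, seed)}
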
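"""Plate-level normalization, Dunnett many-to-one testing and multi-tier
hit calling.

Normalization follows the screen convention: each well's statistic is
divided by the mean of the non-targeting (siNT) control wells of the same
plate and treatment arm, and shifted so that the control sits at 0.  Hit
confirmation in the deconvolution tier requires at least 2 of 3 individual
oligos to be significant with concordant direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["summarize_wells", "normalize_to_controls", "DunnettResult",
           "dunnett_null_maxt", "dunnett_test", "call_hits",
           "CONTROL_LABEL"]

CONTROL_LABEL = "siNT"


def summarize_wells(cells: pd.DataFrame, layout: pd.DataFrame,
                    qc_min_cells: int = 1000) -> pd.DataFrame:
    """Aggregate per-cell measurements to per-well summaries.

    ``cells`` needs columns well_id and red_only_area_px (plus optionally
    n_red_only_structures); ``layout`` needs well_id, treatment,
    target_gene, oligo_id.  Wells with fewer than ``qc_min_cells`` cells are
    flagged (``qc_pass`` False) and should be excluded from statistics.
    """
    unknown = set(cells["well_id"]) - set(layout["well_id"])
    if unknown:
        raise KeyError(f"wells present in data but not in layout: "
                       f"{sorted(unknown)}")
    rows = []
    for well_id, grp in cells.groupby("well_id", sort=True):
        row = {"well_id": well_id, "n_cells": int(len(grp)),
               "mean_red_only_area_per_cell":
                   float(grp["red_only_area_px"].mean()),
               "n_fields_used": int(grp["field_id"].nunique())
               if "field_id" in grp else 1}
        if "n_red_only_structures" in grp:
            row["mean_red_only_count_per_cell"] = \
                float(grp["n_red_only_structures"].mean())
        row["qc_pass"] = row["n_cells"] >= qc_min_cells
        rows.append(row)
    wells = pd.DataFrame(rows)
    return wells.merge(
        layout[[c for c in ("well_id", "treatment", "target_gene", "oligo_id",
                            "plate_id") if c in layout.columns]],
        on="well_id", how="left")


def normalize_to_controls(wells: pd.DataFrame,
                          control_label: str = CONTROL_LABEL,
                          value_col: str = "mean_red_only_area_per_cell",
                          ) -> pd.DataFrame:
    """Fold change vs same-plate, same-treatment siNT mean; centered effect
    is fold change minus 1, so the control arm sits at 0 by construction."""
    wells = wells.copy()
    if "plate_id" not in wells.columns:
        wells["plate_id"] = "plate1"
    if "qc_pass" not in wells.columns:
        wells["qc_pass"] = True
    out = []
    for (plate, treat), grp in wells.groupby(["plate_id", "treatment"], sort=False):
        ctrl = grp[(grp["target_gene"] == control_label) & grp["qc_pass"]]
        if len(ctrl) == 0:
            raise ValueError(f"no usable {control_label} control wells for "
                             f"plate {plate!r} / treatment {treat!r}")
        ctrl_mean = float(ctrl[value_col].mean())
        if ctrl_mean == 0:
            raise ValueError(f"zero {control_label} control mean for plate "
                             f"{plate!r} / treatment {treat!r}")
        g = grp.copy()
        g["fold_change_vs_siNT"] = g[value_col] / ctrl_mean
        g["centered_effect"] = g["fold_change_vs_siNT"] - 1.0
        out.append(g)
    res = pd.concat(out, ignore_index=True)
    res["direction"] = np.select(
        [res["centered_effect"] > 0, res["centered_effect"] < 0],
        ["up", "down"], default="none")
    return res


@dataclass
class DunnettResult:
    t_stats: Dict[str, float]
    p_adjusted: Dict[str, float]
    df: int
    n_resamples: int


def dunnett_null_maxt(group_sizes: Sequence[int], n_control: int,
                      n_resamples: int = 100_000,
                      seed: int = 0) -> np.ndarray:
    """Monte Carlo sample of the null max-|t| statistic for many-to-one
    comparisons with a pooled variance estimate.

    Returned sorted ascending, ready for ``searchsorted``.  Depends only on
    the group sizes, so one sample can serve many datasets of equal design.
    """
    rng = np.random.default_rng(seed)
    sizes = np.asarray(list(group_sizes), dtype=np.int64)
    k = len(sizes)
    n_total = int(sizes.sum()) + int(n_control)
    df = n_total - (k + 1)
    means = rng.standard_normal((n_resamples, k)) / np.sqrt(sizes)
    mean_c = rng.standard_normal(n_resamples) / np.sqrt(n_control)
    s2 = rng.chisquare(df, size=n_resamples) / df
    se = np.sqrt(s2[:, None] * (1.0 / sizes + 1.0 / n_control))
    t = (means - mean_c[:, None]) / se
    return np.sort(np.abs(t).max(axis=1))


def dunnett_test(groups: Mapping[str, Sequence[float]],
                 control: Sequence[float], alpha: float = 0.05,
                 n_resamples: int = 100_000, seed: int = 0,
                 null_maxt: np.ndarray | None = None) -> DunnettResult:
    """Many-to-one comparisons against a shared control with familywise
    adjustment on the max-|t| statistic.

    With a single treatment group the adjusted p equals the two-sample
    pooled t-test p exactly (computed analytically).  For k > 1 the
    adjustment is Monte Carlo: p_i = P(max_j |T_j| >= |t_i|) under the
    global null, estimated from ``n_resamples`` draws (or from a
    precomputed ``null_maxt`` sample for repeated equal designs).
    """
    names = list(groups)
    ctrl = np.asarray(control, dtype=np.float64)
    if len(names) == 0:
        raise ValueError("no treatment groups")
    arrays = {g: np.asarray(groups[g], dtype=np.float64) for g in names}
    for g, a in arrays.items():
        if len(a) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")
    if len(ctrl) < 2:
        raise ValueError("control has fewer than 2 replicates")

    k = len(names)
    n_total = sum(len(a) for a in arrays.values()) + len(ctrl)
    df = n_total - (k + 1)
    ss = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    ss += ((ctrl - ctrl.mean()) ** 2).sum()
    if ss == 0:
        warnings.warn("zero pooled variance; p-values undefined")
        return DunnettResult(t_stats={g: np.nan for g in names},
                             p_adjusted={g: np.nan for g in names},
                             df=df, n_resamples=0)
    s2 = ss / df
    t_stats = {}
    for g, a in arrays.items():
        se = np.sqrt(s2 * (1.0 / len(a) + 1.0 / len(ctrl)))
        t_stats[g] = float((a.mean() - ctrl.mean()) / se)

    if k == 1:
        g = names[0]
        p = {g: float(2.0 * stats.t.sf(abs(t_stats[g]), df))}
        return DunnettResult(t_stats=t_stats, p_adjusted=p, df=df,
                             n_resamples=0)

    if null_maxt is None:
        null_maxt = dunnett_null_maxt([len(arrays[g]) for g in names],
                                      len(ctrl), n_resamples, seed)
    m = len(null_maxt)
    p_adj = {}
    for g in names:
        n_ge = m - np.searchsorted(null_maxt, abs(t_stats[g]), side="left")
        p_adj[g] = float((n_ge + 1) / (m + 1))
    return DunnettResult(t_stats=t_stats, p_adjusted=p_adj, df=df,
                         n_resamples=m)


def call_hits(effects: pd.DataFrame, alpha: float = 0.05,
              tier: str = "primary",
              min_supporting_oligos: int = 2) -> pd.DataFrame:
    """Hit calls from per-target (primary) or per-oligo (deconvolution)
    normalized effects.

    ``effects`` needs columns target, centered_effect, p_adjusted and, for
    the deconvolution tier, oligo.  A deconvolution hit requires at least
    ``min_supporting_oligos`` significant oligos sharing one direction.
    """
    required = {"target", "centered_effect", "p_adjusted"}
    missing = required - set(effects.columns)
    if missing:
        raise ValueError(f"effects table missing columns {sorted(missing)}")
    rows = []
    if tier == "primary":
        for target, grp in effects.groupby("target", sort=True):
            sig = grp["p_adjusted"] < alpha
            eff = grp["centered_effect"]
            is_hit = bool(sig.any())
            rows.append({"target": target, "tier": "primary",
                         "is_hit": is_hit, "supporting_oligos": int(sig.sum()),
                         "partial": False,
                         "rule": f"pooled p_adj < {alpha}",
                         "direction": _sign_label(eff[sig].mean())
                         if is_hit else "none"})
    elif tier == "deconvolution":
        if "oligo" not in effects.columns:
            raise ValueError("deconvolution tier requires an 'oligo' column")
        for target, grp in effects.groupby("target", sort=True):
            partial = grp["oligo"].nunique() < 3
            if partial:
                warnings.warn(f"target {target!r} has fewer than 3 oligos; "
                              "deconvolution call is partial")
            sig = grp[grp["p_adjusted"] < alpha]
            n_up = int((sig["centered_effect"] > 0).sum())
            n_down = int((sig["centered_effect"] < 0).sum())
            support = max(n_up, n_down)
            is_hit = support >= min_supporting_oligos
            rows.append({
                "target": target, "tier": "deconvolution", "is_hit": is_hit,
                "supporting_oligos": support, "partial": partial,
                "rule": f">={min_supporting_oligos} of 3 oligos significant, "
                        "concordant direction",
                "direction": ("up" if n_up > n_down else "down")
                if is_hit else "none"})
    else:
        raise ValueError(f"unknown tier {tier!r}")
    return pd.DataFrame(rows, columns=["target", "tier", "is_hit",
                                       "supporting_oligos", "partial",
                                       "rule", "direction"])


def _sign_label(x: float) -> str:
    if np.isnan(x) or x == 0:
        return "none"
    return "up" if x > 0 else "down"
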
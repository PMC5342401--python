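"""Wet-lab assay quantifications.

Implements the defined measurement transforms for four bench assays —
relative qPCR expression by the Livak 2^-ddCt method, wound-healing
(scratch) closure ratio, acridine orange / ethidium bromide live/apoptotic/
necrotic fractions, and an agarose-gel DNA-fragmentation index — each of
which consumes tabulated measurements (Ct values, pixel areas, cell counts,
lane intensities), never images.  Group comparison runs through the shared
statistics core (:func:`leadnet.stats.group_stats`).
"""

from __future__ import annotations

import logging
import math
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .network import normalize_symbol
from .stats import GroupStats, group_stats

logger = logging.getLogger("leadnet")

CT_COLUMNS = ["sample", "group", "gene", "ct"]


def _validate_ct_table(ct: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValidationError(f"Ct table missing columns {missing}")
    ct = ct.copy()
    ct["gene"] = ct["gene"].map(normalize_symbol)
    vals = pd.to_numeric(ct["ct"], errors="coerce")
    if vals.isna().any() or not np.isfinite(vals).all() or (vals <= 0).any():
        raise ValidationError("Ct values must be finite and positive")
    ct["ct"] = vals
    return ct


def delta_delta_ct(ct: pd.DataFrame, target: str, reference: str,
                   calibrator_group: str, per_sample: bool = False) -> pd.DataFrame:
    """Relative expression by the Livak 2^-ddCt method.

    Technical replicates (repeated (sample, gene) rows) are averaged before
    dCt.  Per sample, dCt = mean Ct(target) - mean Ct(reference); ddCt =
    dCt(sample) - mean dCt over the calibrator group; fold = 2^-ddCt.

    Parameters
    ----------
    ct : DataFrame with columns sample, group, gene, ct
    target, reference : str
        Target gene and endogenous-control gene (e.g. ACTB).
    calibrator_group : str
        Group whose mean dCt anchors ddCt (e.g. untreated control, or normal
        mucosa for patient tissue).
    per_sample : bool
        When True return the per-sample table (sample, group, delta_ct,
        delta_delta_ct, fold_change) instead of the group summary.

    Returns
    -------
    pandas.DataFrame
        Group summary with columns group, gene, n, fold_change (geometric
        mean of sample folds), delta_delta_ct (mean), dispersion (SD of log2
        folds, back-transformed: 2^sd).
    """
    ct = _validate_ct_table(ct)
    target, reference = normalize_symbol(target), normalize_symbol(reference)
    mean_ct = (ct.groupby(["sample", "group", "gene"], sort=False)["ct"]
                 .mean().reset_index())
    wide = mean_ct.pivot_table(index=["sample", "group"], columns="gene",
                               values="ct", aggfunc="mean")
    if target not in wide.columns:
        raise ValidationError(f"target gene {target!r} absent from Ct table")
    if reference not in wide.columns:
        raise ValidationError(f"reference gene {reference!r} absent from Ct table")
    no_ref = wide[wide[reference].isna()].index.get_level_values("sample").tolist()
    if no_ref:
        raise ValidationError(
            f"sample(s) missing the reference gene {reference}: {no_ref[:5]}"
        )
    wide = wide.dropna(subset=[target])
    per = wide.reset_index()
    per["delta_ct"] = per[target] - per[reference]
    cal = per.loc[per["group"] == calibrator_group, "delta_ct"]
    if cal.empty:
        raise ValidationError(f"calibrator group {calibrator_group!r} is empty")
    per["delta_delta_ct"] = per["delta_ct"] - cal.mean()
    per["fold_change"] = 2.0 ** (-per["delta_delta_ct"])
    per = per[["sample", "group", "delta_ct", "delta_delta_ct", "fold_change"]]
    if per_sample:
        return per.reset_index(drop=True)

    rows = []
    for group, sub in per.groupby("group", sort=False):
        log2f = np.log2(sub["fold_change"].to_numpy())
        sd = float(log2f.std(ddof=1)) if log2f.size > 1 else 0.0
        rows.append({"group": group, "gene": target, "n": int(log2f.size),
                     "fold_change": float(2.0 ** log2f.mean()),
                     "delta_delta_ct": float(sub["delta_delta_ct"].mean()),
                     "dispersion": float(2.0 ** sd)})
    return pd.DataFrame(rows)


class WoundRatio(NamedTuple):
    """Wound-closure ratio; ``closed`` marks a fully healed (zero-area) wound."""

    ratio: float
    closed: bool


def wound_ratio(initial_area_px: float, final_area_px: float) -> WoundRatio:
    """Initial cell-free area divided by final cell-free area (pixels).

    A ratio above 1 means cells migrated into the wound.  A fully closed
    wound (final area 0) returns an infinite ratio flagged ``closed`` so
    downstream statistics can exclude it rather than ingest an infinity.
    """
    if not (initial_area_px > 0):
        raise ValidationError("initial wound area must be positive")
    if final_area_px < 0:
        raise ValidationError("final wound area must be non-negative")
    if final_area_px == 0:
        return WoundRatio(math.inf, True)
    return WoundRatio(float(initial_area_px) / float(final_area_px), False)


def wound_table(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorised wound ratios: adds ``ratio`` and ``closed`` columns."""
    out = df.copy()
    ratios = [wound_ratio(i, f) for i, f in
              zip(out["initial_area_px"], out["final_area_px"])]
    out["ratio"] = [r.ratio for r in ratios]
    out["closed"] = [r.closed for r in ratios]
    n_closed = int(out["closed"].sum())
    if n_closed:
        logger.warning("%d fully closed wound(s) flagged; exclude from stats",
                       n_closed)
    return out


def aoeb_fractions(live: int, apoptotic: int, necrotic: int) -> tuple[float, float, float]:
    """Live/apoptotic/necrotic cell fractions from AO/EB dual-stain counts."""
    for name, v in (("live", live), ("apoptotic", apoptotic), ("necrotic", necrotic)):
        if v < 0:
            raise ValidationError(f"{name} count must be >= 0")
    total = live + apoptotic + necrotic
    if total <= 0:
        raise ValidationError("AO/EB counts sum to zero")
    return (live / total, apoptotic / total, necrotic / total)


def aoeb_table(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorised AO/EB fractions: adds live_frac/apoptotic_frac/necrotic_frac."""
    out = df.copy()
    fracs = [aoeb_fractions(l, a, n) for l, a, n in
             zip(out["live"], out["apoptotic"], out["necrotic"])]
    out["live_frac"] = [f[0] for f in fracs]
    out["apoptotic_frac"] = [f[1] for f in fracs]
    out["necrotic_frac"] = [f[2] for f in fracs]
    return out


def fragmentation_index(intact_band: float, total_lane: float) -> float:
    """DNA-fragmentation index 1 - intact/total from gel lane intensities.

    0 means a fully intact genomic band, 1 a fully degraded lane; apoptotic
    laddering raises the index.
    """
    if not (total_lane > 0):
        raise ValidationError("total lane intensity must be positive")
    if intact_band < 0 or intact_band > total_lane:
        raise ValidationError("intact band intensity must lie in [0, total_lane]")
    return 1.0 - float(intact_band) / float(total_lane)


def lane_table(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorised fragmentation indices: adds a ``frag_index`` column."""
    out = df.copy()
    out["frag_index"] = [fragmentation_index(i, t) for i, t in
                         zip(out["intact_band"], out["total_lane"])]
    return out


def assay_group_stats(df: pd.DataFrame, value_col: str, group_col: str = "group",
                      alpha: float = 0.05, check_normality: bool = True) -> GroupStats:
    """ANOVA + Tukey of an assay readout across treatment arms.

    Non-finite values (e.g. closed-wound infinities) are dropped with a
    logged warning before testing.
    """
    sub = df[[group_col, value_col]].copy()
    finite = np.isfinite(sub[value_col].astype(float))
    if not finite.all():
        logger.warning("dropping %d non-finite %s value(s) before statistics",
                       int((~finite).sum()), value_col)
        sub = sub[finite]
    grouped = {g: v[value_col].to_numpy(dtype=float)
               for g, v in sub.groupby(group_col, sort=False)}
    return group_stats(grouped, alpha=alpha, check_normality=check_normality)
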
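"""I-DIRT SILAC ratio computation and in-vivo interaction classification.

In an I-DIRT experiment, isotopically heavy wild-type cells and light
bait-tagged cells are lysed while frozen and mixed 1:1 before purification.
A prey bound to the bait in vivo is drawn only from the light culture
(light fraction near 1); a prey that exchanges onto the bait after lysis
samples both cultures equally (light fraction near 0.5).  Peptide-level
light/heavy precursor elution areas are converted to ratios, aggregated per
protein, and classified with the strict log2(light/heavy) > 0 rule.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = ["compute_peptide_ratios", "aggregate_protein_ratios", "summarize_in_vivo"]

logger = logging.getLogger(__name__)


def compute_peptide_ratios(peptides: pd.DataFrame, pseudocount: float = 0.0) -> pd.DataFrame:
    """Light fraction and log2 ratio per quantifiable peptide.

    ``light_fraction = A_L / (A_L + A_H)``;
    ``log2_ratio = log2((A_L + eps) / (A_H + eps))``.

    With the default ``pseudocount=0`` any peptide with a zero area in either
    channel is excluded (logged), since its ratio is undefined; a positive
    pseudocount keeps such peptides with a finite ratio.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    req = {"peptide_id", "protein_id", "light_area", "heavy_area"}
    missing = req - set(peptides.columns)
    if missing:
        raise ValueError(f"peptide table missing columns: {sorted(missing)}")
    if (peptides["light_area"] < 0).any() or (peptides["heavy_area"] < 0).any():
        raise ValueError("negative precursor areas")
    out = peptides.copy()
    total = out["light_area"] + out["heavy_area"]
    n_zero = int((total == 0).sum())
    if n_zero:
        logger.info("excluding %d unquantifiable peptides (both areas zero)", n_zero)
        out = out[total > 0].copy()
        total = total[total > 0]
    if pseudocount == 0.0:
        bad = (out["light_area"] == 0) | (out["heavy_area"] == 0)
        if bad.any():
            logger.info(
                "excluding %d peptides with a zero-area channel (pseudocount=0)",
                int(bad.sum()),
            )
            out = out[~bad].copy()
            total = out["light_area"] + out["heavy_area"]
    out["light_fraction"] = out["light_area"] / total
    out["log2_ratio"] = np.log2(
        (out["light_area"] + pseudocount) / (out["heavy_area"] + pseudocount)
    )
    return out.reset_index(drop=True)


def aggregate_protein_ratios(peptide_ratios: pd.DataFrame, method: str = "median") -> pd.DataFrame:
    """Protein-level SILAC ratio from peptide ratios.

    ``method="median"`` (default, robust to outlier peptides) or
    ``"weighted_mean"`` (weights are total precursor areas).  The protein
    light fraction is derived from the aggregated log2 ratio so the two
    fields stay algebraically consistent; ``in_vivo`` is the strict
    log2 ratio > 0 rule (a 50:50 peptide pool is NOT called in vivo).
    """
    if method not in ("median", "weighted_mean"):
        raise ValueError(f"unknown aggregation method {method!r}")
    if peptide_ratios.empty:
        return pd.DataFrame(
            columns=["protein_id", "log2_ratio", "light_fraction", "n_peptides", "in_vivo"]
        )
    rows = []
    for pid, g in peptide_ratios.groupby("protein_id"):
        if method == "median":
            lr = float(g["log2_ratio"].median())
        else:
            w = (g["light_area"] + g["heavy_area"]).astype(float)
            lr = float(np.average(g["log2_ratio"], weights=w))
        lf = 2.0**lr / (1.0 + 2.0**lr)
        rows.append(
            {
                "protein_id": pid,
                "log2_ratio": lr,
                "light_fraction": lf,
                "n_peptides": len(g),
                "in_vivo": lr > 0.0,
            }
        )
    return pd.DataFrame(rows)


def summarize_in_vivo(protein_ratios: pd.DataFrame) -> str:
    """One-line summary of how many proteins pass the in-vivo rule."""
    n = len(protein_ratios)
    k = int(protein_ratios["in_vivo"].sum()) if n else 0
    return f"{k} of {n} proteins have light:heavy log2 ratio > 0 (in vivo)"
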
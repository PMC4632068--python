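"""APEX-style spectral-count quantitation for AP-MS runs.

Spectral counts are a label-free abundance proxy, but the number of spectra a
protein yields depends on its length and peptide detectability.  The APEX
correction divides each count by the protein's expected peptide observability
``O_i`` and renormalizes within the run, giving relative abundances that are
comparable across proteins.  For bait-centric comparisons, scores are further
divided by the bait's own score in the same run, and paired runs from two
growth conditions are compared with a pooled two-sample Z test on count
fractions.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MissingObservabilityError",
    "BaitMissingError",
    "apex_normalize",
    "bait_normalize",
    "two_sample_z",
    "condition_ratio",
    "condition_trends",
]

COUNT_COLUMNS = ["protein_id", "run_id", "condition", "spectral_count", "unique_peptides"]


class MissingObservabilityError(ValueError):
    """A counted protein has no (or a nonpositive) observability score."""


class BaitMissingError(ValueError):
    """The bait protein is absent, or has zero score, in an analyzed run."""


def _check_counts(counts: pd.DataFrame) -> None:
    missing = [c for c in ("protein_id", "run_id", "spectral_count") if c not in counts.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    if (counts["spectral_count"] < 0).any():
        raise ValueError("negative spectral counts")


def apex_normalize(
    counts: pd.DataFrame,
    obs: pd.DataFrame,
    scale: float = 1.0,
    per_run: bool = True,
) -> pd.DataFrame:
    """Observability-corrected, run-normalized abundance scores.

    For protein i in run r with spectral count ``n_ir`` and observability
    ``O_i``::

        apex_ir = scale * (n_ir / O_i) / sum_k (n_kr / O_k)

    where the sum runs over the same run (``per_run=True``, default) or the
    whole table.  A zero count maps to a zero score.

    Parameters
    ----------
    counts
        Tidy table with ``protein_id``, ``run_id``, ``spectral_count`` (and
        any passenger columns, which are preserved).
    obs
        Table with ``protein_id`` and strictly positive ``observability``.
    scale
        The per-run normalization constant C; 1 gives relative abundances,
        passing the run total gives corrected pseudo-counts.

    Raises
    ------
    MissingObservabilityError
        If a protein with a nonzero count lacks a positive observability.
    """
    _check_counts(counts)
    if scale <= 0:
        raise ValueError("scale must be positive")
    omap = obs.set_index("protein_id")["observability"]
    out = counts.copy()
    o = out["protein_id"].map(omap)
    bad = out.loc[(out["spectral_count"] > 0) & (~(o > 0)), "protein_id"]
    if len(bad):
        raise MissingObservabilityError(
            "missing or nonpositive observability for: " + ", ".join(sorted(set(bad.astype(str))))
        )
    weighted = out["spectral_count"] / o
    weighted = weighted.where(out["spectral_count"] > 0, 0.0)
    if per_run:
        denom = weighted.groupby(out["run_id"]).transform("sum")
    else:
        denom = weighted.sum()
    if np.any(denom <= 0):
        raise ValueError("a run has zero total weighted count")
    out["apex"] = scale * weighted / denom
    return out


def bait_normalize(scores: pd.DataFrame, bait_id: str) -> pd.DataFrame:
    """Divide every APEX score by the bait's score from the same run.

    The bait itself maps to exactly 1.0 in every run, making prey abundances
    stoichiometries relative to the purified complex.
    """
    if "apex" not in scores.columns:
        raise ValueError("scores must carry an 'apex' column (run apex_normalize first)")
    out = scores.copy()
    bait = out.loc[out["protein_id"] == bait_id].set_index("run_id")["apex"]
    for run in out["run_id"].unique():
        if run not in bait.index or not bait[run] > 0:
            raise BaitMissingError(f"bait {bait_id!r} absent or zero in run {run!r}")
    out["bait_normalized"] = out["apex"] / out["run_id"].map(bait)
    # exact 1.0 for the bait, immune to floating-point division
    out.loc[out["protein_id"] == bait_id, "bait_normalized"] = 1.0
    return out


def two_sample_z(n1: float, total1: float, n2: float, total2: float) -> float:
    """Pooled-proportion Z statistic comparing one protein's count fraction.

    ``p_j = n_j / N_j``; the statistic is ``(p1 - p2) / sqrt(pbar (1 - pbar)
    (1/N1 + 1/N2))`` with ``pbar`` the pooled fraction.  Positive means a
    higher fraction in the first run.  Returns NaN (a null result, not an
    error) when the pooled fraction is 0 or 1, where the test is undefined.
    """
    if total1 <= 0 or total2 <= 0:
        raise ValueError("run totals must be positive")
    p1 = n1 / total1
    p2 = n2 / total2
    pbar = (n1 + n2) / (total1 + total2)
    if pbar <= 0.0 or pbar >= 1.0:
        return float("nan")
    se = math.sqrt(pbar * (1.0 - pbar) * (1.0 / total1 + 1.0 / total2))
    return (p1 - p2) / se


def condition_ratio(
    scores: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    counts: pd.DataFrame | None = None,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Per-pair bait-normalized abundance ratios (minus / plus glucose).

    Parameters
    ----------
    scores
        Output of :func:`bait_normalize`.
    pairs
        ``(minus_run, plus_run)`` run-id pairs; each pair was acquired
        back-to-back on the same instrument.
    counts
        Optional raw count table; when given, a two-sample Z statistic on
        count fractions is reported per pair.
    pseudocount
        Replacement for zero scores so ratios stay finite.  Default: half the
        smallest nonzero bait-normalized score within the pair.

    Returns a tidy frame with one row per (protein, pair): ``ratio_minus_over_plus``
    and ``z`` (NaN when counts are not supplied or the test is undefined).
    """
    if len(pairs) == 0:
        raise ValueError("empty pair list")
    if "bait_normalized" not in scores.columns:
        raise ValueError("scores must carry 'bait_normalized' (run bait_normalize first)")
    by_run = {r: g.set_index("protein_id")["bait_normalized"] for r, g in scores.groupby("run_id")}
    count_by_run: dict[str, pd.Series] = {}
    totals: dict[str, float] = {}
    if counts is not None:
        for r, g in counts.groupby("run_id"):
            count_by_run[r] = g.set_index("protein_id")["spectral_count"]
            totals[r] = float(count_by_run[r].sum())
    rows = []
    for idx, (minus_run, plus_run) in enumerate(pairs):
        if minus_run not in by_run or plus_run not in by_run:
            raise ValueError(f"pair ({minus_run!r}, {plus_run!r}) references an unknown run")
        sm, sp = by_run[minus_run], by_run[plus_run]
        proteins = sm.index.union(sp.index)
        a = sm.reindex(proteins, fill_value=0.0)
        b = sp.reindex(proteins, fill_value=0.0)
        if pseudocount is None:
            nonzero = pd.concat([a[a > 0], b[b > 0]])
            eps = 0.5 * float(nonzero.min()) if len(nonzero) else 1.0
        else:
            eps = float(pseudocount)
        a_adj = a.where(a > 0, eps)
        b_adj = b.where(b > 0, eps)
        ratio = a_adj / b_adj
        for pid in proteins:
            z = float("nan")
            if counts is not None and minus_run in totals and plus_run in totals:
                n1 = float(count_by_run[minus_run].get(pid, 0))
                n2 = float(count_by_run[plus_run].get(pid, 0))
                z = two_sample_z(n1, totals[minus_run], n2, totals[plus_run])
            rows.append(
                {
                    "protein_id": pid,
                    "pair": idx,
                    "minus_run": minus_run,
                    "plus_run": plus_run,
                    "ratio_minus_over_plus": float(ratio[pid]),
                    "z": z,
                }
            )
    return pd.DataFrame(rows)


def condition_trends(per_pair: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-pair ratios into a per-protein trend.

    ``minus`` requires every evaluated pair ratio > 1 (reproducibly more
    abundant in the PB-induced, glucose-depleted condition), ``plus``
    requires every ratio < 1; anything else — including a ratio of exactly
    1 — is ``inconsistent``.
    """
    def trend(r: pd.Series) -> str:
        if (r > 1).all():
            return "minus"
        if (r < 1).all():
            return "plus"
        return "inconsistent"

    g = per_pair.groupby("protein_id")["ratio_minus_over_plus"]
    out = g.agg([("n_pairs", "size"), ("trend", trend)]).reset_index()
    return out
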
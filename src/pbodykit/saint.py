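"""SAINT-style prey specificity scoring against control purifications.

Negative-control affinity purifications (CRAPome-style) define, per prey, the
spectral-count level expected from nonspecific bead binding.  Each prey in
each bait replicate is scored with a two-component Poisson posterior: the
"contaminant" component has rate lambda0 estimated from depth-scaled control
counts (floored at ``lambda_min``), the "true interaction" component has rate
lambda1 set to the prey's mean bait count in that condition, forced to at
least twice lambda0.  The condition score is the mean posterior over that
condition's replicates, so a single spurious replicate cannot carry a prey.

This is a transparent re-design with the same interface and [0, 1] semantics
as SAINT scores, not a reimplementation of SAINTexpress.
"""

from __future__ import annotations


import numpy as np
import pandas as pd
from scipy.stats import poisson

__all__ = [
    "EmptyControlsError",
    "score_specificity",
    "apply_filter_cascade",
    "classify_condition_specific",
]

BAIT_CONDITIONS = ("minus_glucose", "plus_glucose")


class EmptyControlsError(ValueError):
    """No control runs supplied; pass ``allow_empty_controls=True`` to score
    against the ``lambda_min`` null only."""


def score_specificity(
    counts: pd.DataFrame,
    controls: pd.DataFrame,
    prior: float = 0.1,
    lambda_min: float = 0.1,
    allow_empty_controls: bool = False,
    return_posteriors: bool = False,
):
    """Score every (prey, condition) for bait-specific co-purification.

    Parameters
    ----------
    counts
        Bait-run count table (``protein_id``, ``run_id``, ``condition``,
        ``spectral_count``); conditions other than the two bait conditions
        are ignored.
    controls
        Control count table (``protein_id``, ``control_run_id``, ``count``).
        Proteins absent from a control run count as zero there.
    prior
        Prior probability pi that a prey is a genuine interactor.
    lambda_min
        Floor on the contaminant rate, so preys never seen in controls still
        have a proper null.
    return_posteriors
        Also return the per-replicate posterior table.

    Returns
    -------
    DataFrame with ``protein_id``, ``condition``, ``score`` (and optionally a
    second frame with per-replicate posteriors).
    """
    if not 0 < prior < 1:
        raise ValueError("prior must be in (0, 1)")
    if lambda_min <= 0:
        raise ValueError("lambda_min must be positive")
    bait = counts[counts["condition"].isin(BAIT_CONDITIONS)]
    if bait.empty:
        raise ValueError("no bait-condition runs in count table")
    run_totals = bait.groupby("run_id")["spectral_count"].sum()
    if (run_totals <= 0).any():
        raise ValueError("a bait run has zero total counts")

    n_controls = 0 if controls is None else controls["control_run_id"].nunique()
    if n_controls == 0 and not allow_empty_controls:
        raise EmptyControlsError(
            "no control runs supplied; to score against the lambda_min-only "
            "null, pass allow_empty_controls=True"
        )

    proteins = pd.Index(sorted(bait["protein_id"].unique()))
    runs = bait[["run_id", "condition"]].drop_duplicates().set_index("run_id")["condition"]

    # mean control count per unit depth; zero-filled over all control runs
    if n_controls > 0:
        ctl_totals = controls.groupby("control_run_id")["count"].sum()
        if (ctl_totals <= 0).any():
            raise ValueError("a control run has zero total counts")
        wide = (
            controls.pivot_table(
                index="protein_id", columns="control_run_id", values="count",
                aggfunc="sum", fill_value=0,
            )
            .reindex(proteins, fill_value=0)
        )
        per_depth = (wide / ctl_totals).mean(axis=1)  # m_i: expected fraction
    else:
        per_depth = pd.Series(0.0, index=proteins)

    grid = bait.pivot_table(
        index="protein_id", columns="run_id", values="spectral_count",
        aggfunc="sum", fill_value=0,
    ).reindex(proteins, fill_value=0)

    cond_mean = {
        c: grid[[r for r in grid.columns if runs[r] == c]].mean(axis=1)
        for c in BAIT_CONDITIONS
        if any(runs[r] == c for r in grid.columns)
    }

    post_rows = []
    for run in grid.columns:
        cond = runs[run]
        lam0 = np.maximum(per_depth.values * run_totals[run], lambda_min)
        lam1 = np.maximum(cond_mean[cond].values, 2.0 * lam0)
        x = grid[run].values
        logf1 = poisson.logpmf(x, lam1)
        logf0 = poisson.logpmf(x, lam0)
        # posterior on log scale for numerical safety at extreme counts
        log_odds = np.log(prior) - np.log1p(-prior) + logf1 - logf0
        p = 1.0 / (1.0 + np.exp(-log_odds))
        post_rows.append(
            pd.DataFrame(
                {
                    "protein_id": proteins,
                    "run_id": run,
                    "condition": cond,
                    "count": x,
                    "posterior": p,
                }
            )
        )
    posteriors = pd.concat(post_rows, ignore_index=True)
    scores = (
        posteriors.groupby(["protein_id", "condition"])["posterior"]
        .mean()
        .rename("score")
        .reset_index()
    )
    if return_posteriors:
        return scores, posteriors
    return scores


def apply_filter_cascade(
    counts: pd.DataFrame,
    scores: pd.DataFrame,
    min_unique: int = 2,
    min_experiments: int = 2,
    saint_threshold: float = 0.5,
) -> pd.DataFrame:
    """Three-criterion final-list filter.

    A prey enters the final list iff (1) some bait run identified it with at
    least ``min_unique`` unique peptides, (2) it was identified (count > 0)
    in at least ``min_experiments`` bait runs across both conditions, and
    (3) its specificity score exceeds ``saint_threshold`` (strictly) in at
    least one condition.
    """
    bait = counts[counts["condition"].isin(BAIT_CONDITIONS)]
    if bait.empty:
        return pd.DataFrame(
            columns=[
                "protein_id", "passes_peptides", "passes_replication",
                "passes_specificity", "in_final_list",
            ]
        )
    g = bait.groupby("protein_id")
    max_unique = g["unique_peptides"].max()
    n_identified = g["spectral_count"].apply(lambda s: int((s > 0).sum()))
    max_score = (
        scores.groupby("protein_id")["score"].max()
        if len(scores)
        else pd.Series(dtype=float)
    )
    out = pd.DataFrame({"protein_id": max_unique.index})
    out["passes_peptides"] = (max_unique >= min_unique).values
    out["passes_replication"] = (n_identified.reindex(max_unique.index) >= min_experiments).values
    out["passes_specificity"] = (
        max_score.reindex(max_unique.index).fillna(0.0) > saint_threshold
    ).values
    out["in_final_list"] = (
        out["passes_peptides"] & out["passes_replication"] & out["passes_specificity"]
    )
    return out.reset_index(drop=True)


def classify_condition_specific(
    trends: pd.DataFrame,
    scores: pd.DataFrame,
    hi: float = 0.6,
    lo: float = 0.4,
) -> pd.DataFrame:
    """Label preys that associate with the bait in only one growth condition.

    ``minus_specific`` requires a unanimous minus trend AND score > ``hi`` in
    minus-glucose AND score < ``lo`` in plus-glucose (both strict);
    symmetrically for ``plus_specific``.  Everything else is ``shared``.
    """
    wide = scores.pivot_table(index="protein_id", columns="condition", values="score")
    for c in BAIT_CONDITIONS:
        if c not in wide.columns:
            wide[c] = np.nan
    t = trends.set_index("protein_id")["trend"]
    rows = []
    for pid in t.index:
        s_minus = wide["minus_glucose"].get(pid, np.nan)
        s_plus = wide["plus_glucose"].get(pid, np.nan)
        label = "shared"
        if pd.notna(s_minus) and pd.notna(s_plus):
            if t[pid] == "minus" and s_minus > hi and s_plus < lo:
                label = "minus_specific"
            elif t[pid] == "plus" and s_plus > hi and s_minus < lo:
                label = "plus_specific"
        rows.append(
            {
                "protein_id": pid,
                "trend": t[pid],
                "score_minus": s_minus,
                "score_plus": s_plus,
                "condition_class": label,
            }
        )
    return pd.DataFrame(rows)
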
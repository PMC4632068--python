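"""Hypergeometric set-overlap tests with Benjamini-Hochberg correction.

Shared by the LC/prion overlap analysis and flat GO-style term enrichment:
given a universe of N genes, an annotation set of K, and a query of n with k
in the overlap, the upper-tail hypergeometric probability P(X >= k) measures
enrichment.  The universe is always an explicit parameter — results depend
strongly on it and no default background is assumed.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["hypergeom_upper", "bh_adjust", "enrich"]

logger = logging.getLogger(__name__)


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) drawing n from N with K successes, without replacement.

    Summed in log space over the upper tail so extreme-tail probabilities
    (e.g. 1e-44-scale overlaps) do not underflow intermediate terms.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    support = np.arange(k, min(K, n) + 1)
    if len(support) == 0:
        return 0.0
    logp = hypergeom.logpmf(support, N, K, n)
    return float(np.exp(logsumexp(logp)))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    universe: Iterable[str],
    query: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Upper-tail enrichment of the query in every annotation term.

    Query and annotation members outside the universe are clipped (and
    logged) rather than silently counted; BH correction is applied across
    all tested terms.  Returns a frame sorted by adjusted p-value.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query)
    dropped = q - uni
    if dropped:
        logger.warning("clipping %d query ids outside the universe", len(dropped))
    q &= uni
    if not q or not annotations:
        raise ValueError("query and annotations must be nonempty")
    N, n = len(uni), len(q)
    rows = []
    for term, members in annotations.items():
        m = set(members)
        extra = m - uni
        if extra:
            logger.warning("term %s: clipping %d ids outside the universe", term, len(extra))
        m &= uni
        K = len(m)
        k = len(q & m)
        rows.append(
            {"term": term, "N": N, "K": K, "n": n, "k": k,
             "p_upper": hypergeom_upper(N, K, n, k)}
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bh_adjust(out["p_upper"].to_numpy())
    return out.sort_values("p_adjusted", kind="mergesort").reset_index(drop=True)
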
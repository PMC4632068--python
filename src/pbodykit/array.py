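"""RNA co-enrichment calling from paired IP/total probe arrays.

Each immunopurification contributes a pair of arrays — total RNA from the
input lysate and RNA recovered in the IP — hybridized to the same probe set.
The pipeline: subtract the median signal of negative-control probes, floor
and log2-transform, normalize the pair by (two-array cyclic) loess on the
MA representation, average a transcript's probes, drop low-signal /
high-variability / saturated transcripts, regress IP signal on total signal,
and call a transcript enriched when it lies above the upper limit of the
regression band.  Consensus requires enrichment in more than one biological
replicate and no enrichment in the mock (tag-only) IP.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "subtract_background",
    "loess_normalize_pair",
    "average_probes",
    "filter_transcripts",
    "fit_regression_band",
    "call_enrichment",
    "consensus_calls",
    "analyze_replicate",
    "run_array_pipeline",
    "RegressionFit",
]

logger = logging.getLogger(__name__)

PROBE_COLUMNS = ["probe_id", "transcript_id", "is_negative_control", "raw_total", "raw_ip"]


def subtract_background(probes: pd.DataFrame, floor: float = 1.0) -> pd.DataFrame:
    """Median negative-control background subtraction, floor, log2.

    The per-channel median over negative-control probes is subtracted from
    every probe; values below ``floor`` are set to ``floor`` before the log
    transform so the log is always defined.
    """
    neg = probes[probes["is_negative_control"]]
    if neg.empty:
        raise ValueError("no negative-control probes; background is undefined")
    out = probes.copy()
    for ch in ("total", "ip"):
        med = float(neg[f"raw_{ch}"].median())
        sub = (out[f"raw_{ch}"] - med).clip(lower=floor)
        out[f"bg_sub_{ch}"] = sub
        out[f"log_{ch}"] = np.log2(sub)
    return out


def loess_normalize_pair(
    log_total: np.ndarray,
    log_ip: np.ndarray,
    span: float = 0.4,
    iterations: int = 2,
    min_points: int = 30,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-array cyclic loess normalization.

    For a single array pair, cyclic loess reduces to one MA correction: fit a
    loess trend of M = log_ip - log_total against A = (log_ip + log_total)/2
    and split the fitted trend evenly between the channels, leaving A
    untouched.  Fewer than ``min_points`` points: returned unchanged with a
    warning (the smoother would be unstable).
    """
    lt = np.asarray(log_total, dtype=float)
    li = np.asarray(log_ip, dtype=float)
    if lt.shape != li.shape:
        raise ValueError("paired vectors must have equal length")
    if lt.size < min_points:
        warnings.warn(
            f"only {lt.size} points (< {min_points}); loess pass-through", stacklevel=2
        )
        return lt.copy(), li.copy()
    a = (li + lt) / 2.0
    m = li - lt
    fitted = lowess(m, a, frac=span, it=iterations, return_sorted=False)
    return lt + fitted / 2.0, li - fitted / 2.0


def average_probes(probes: pd.DataFrame) -> pd.DataFrame:
    """Per-transcript mean log signals over that transcript's probes.

    Negative controls and probes without a transcript annotation are
    excluded.  Carries the probe-level coefficients of variation of the
    background-subtracted signal in both channels and the max raw total
    intensity, for the downstream quality filter.
    """
    use = probes[(~probes["is_negative_control"]) & probes["transcript_id"].notna()]
    if use.empty:
        raise ValueError("no annotated, non-control probes")
    g = use.groupby("transcript_id")

    def cv(x: pd.Series) -> float:
        mu = x.mean()
        if len(x) < 2 or mu == 0:
            return 0.0
        return float(x.std(ddof=1) / mu)

    out = pd.DataFrame(
        {
            "mean_log_total": g["log_total"].mean(),
            "mean_log_ip": g["log_ip"].mean(),
            "n_probes_used": g["log_total"].size(),
            "probe_cv_total": g["bg_sub_total"].apply(cv),
            "probe_cv_ip": g["bg_sub_ip"].apply(cv),
            "max_raw_total": g["raw_total"].max(),
        }
    ).reset_index()
    return out


def filter_transcripts(
    signals: pd.DataFrame,
    neg_control_log_total: np.ndarray,
    low_quantile: float = 0.95,
    saturation_value: float = 2**16 - 1,
    cv_max: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop low-abundance, high-variability, or saturated transcripts.

    A transcript is removed when its mean log total signal falls below the
    ``low_quantile`` quantile of the negative-control log signal (it is not
    distinguishable from background), when its probe CV in either channel
    exceeds ``cv_max`` (the enrichment statistic uses both channels, so
    variability in either corrupts it), or when any of its total-channel
    probes reached ``saturation_value``.
    """
    bg = float(np.quantile(np.asarray(neg_control_log_total, dtype=float), low_quantile))
    low = signals["mean_log_total"] < bg
    cv = signals["probe_cv_total"]
    if "probe_cv_ip" in signals.columns:
        cv = np.maximum(cv, signals["probe_cv_ip"])
    noisy = cv > cv_max
    saturated = signals["max_raw_total"] >= saturation_value
    keep = ~(low | noisy | saturated)
    report = {
        "n_input": int(len(signals)),
        "n_low_abundance": int(low.sum()),
        "n_high_cv": int(noisy.sum()),
        "n_saturated": int(saturated.sum()),
        "n_kept": int(keep.sum()),
        "background_log_threshold": bg,
    }
    logger.info("transcript filter: %s", report)
    return signals[keep].reset_index(drop=True), report


@dataclass
class RegressionFit:
    """OLS fit of mean IP log signal on mean total log signal, with band."""

    slope: float
    intercept: float
    residual_sd: float
    n: int
    x_mean: float
    sxx: float
    level: float
    band_kind: str  # "prediction" or "mean_ci"

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def upper(self, x):
        """Upper limit of the band at the two-sided ``level``."""
        x = np.asarray(x, dtype=float)
        t = stats.t.ppf((1.0 + self.level) / 2.0, self.n - 2)
        leverage = 1.0 / self.n + (x - self.x_mean) ** 2 / self.sxx
        extra = 1.0 if self.band_kind == "prediction" else 0.0
        half = t * self.residual_sd * np.sqrt(extra + leverage)
        return self.predict(x) + half


def fit_regression_band(
    signals: pd.DataFrame,
    level: float = 0.95,
    band_kind: str = "prediction",
) -> RegressionFit:
    """Least-squares line through (total, IP) with its upper band.

    ``band_kind="prediction"`` (default) bounds a new single observation and
    is the operative definition of "outside the regression band" here;
    ``"mean_ci"`` bounds the mean line itself and is far narrower at large n.
    The upper-tail nominal false-call rate of the two-sided band is
    (1 - level)/2.
    """
    if band_kind not in ("prediction", "mean_ci"):
        raise ValueError(f"unknown band_kind {band_kind!r}")
    x = signals["mean_log_total"].to_numpy(dtype=float)
    y = signals["mean_log_ip"].to_numpy(dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError(f"need >= 10 transcripts to fit, got {n}")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("degenerate regressor: zero variance in total signal")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    residual_sd = float(np.sqrt(np.sum(resid**2) / (n - 2)))
    return RegressionFit(slope, intercept, residual_sd, n, float(x.mean()), sxx, level, band_kind)


def call_enrichment(fit: RegressionFit, signals: pd.DataFrame) -> pd.DataFrame:
    """Per-transcript enrichment call: strictly above the upper band."""
    x = signals["mean_log_total"].to_numpy(dtype=float)
    y = signals["mean_log_ip"].to_numpy(dtype=float)
    return pd.DataFrame(
        {"transcript_id": signals["transcript_id"], "enriched": y > fit.upper(x)}
    )


def consensus_calls(
    replicate_calls: dict[str, pd.DataFrame],
    mock_calls: pd.DataFrame | None,
    min_replicates: int = 2,
) -> pd.DataFrame:
    """Cross-replicate consensus excluding mock-enriched transcripts.

    A transcript reaches consensus iff it is enriched in at least
    ``min_replicates`` biological replicates AND is not enriched in the mock
    IP.  A transcript filtered out of a replicate simply contributes no call
    there.  Without a mock the mock condition is vacuously false (warned).
    """
    if len(replicate_calls) < 2:
        raise ValueError("need at least two biological replicates")
    if mock_calls is None:
        warnings.warn("no mock IP supplied; mock exclusion is vacuous", stacklevel=2)
    all_ids: set[str] = set()
    for calls in replicate_calls.values():
        all_ids |= set(calls["transcript_id"])
    if mock_calls is not None:
        all_ids |= set(mock_calls["transcript_id"])
    idx = sorted(all_ids)
    out = pd.DataFrame({"transcript_id": idx})
    n_enr = pd.Series(0, index=idx)
    for name, calls in replicate_calls.items():
        e = calls.set_index("transcript_id")["enriched"].reindex(idx, fill_value=False)
        out[f"enriched_{name}"] = e.to_numpy()
        n_enr += e.astype(int)
    out["n_replicates_enriched"] = n_enr.to_numpy()
    if mock_calls is not None:
        mock = (
            mock_calls.set_index("transcript_id")["enriched"].reindex(idx, fill_value=False)
        )
    else:
        mock = pd.Series(False, index=idx)
    out["enriched_in_mock"] = mock.to_numpy()
    out["consensus"] = (out["n_replicates_enriched"] >= min_replicates) & (
        ~out["enriched_in_mock"]
    )
    return out


def analyze_replicate(
    probes: pd.DataFrame,
    floor: float = 1.0,
    span: float = 0.4,
    level: float = 0.95,
    band_kind: str = "prediction",
    low_quantile: float = 0.95,
    saturation_value: float = 2**16 - 1,
    cv_max: float = 0.5,
):
    """Full single-replicate pipeline: background -> loess -> average ->
    filter -> regression band -> calls.

    Returns ``(calls, fit, filter_report)``.
    """
    bg = subtract_background(probes, floor=floor)
    lt, li = loess_normalize_pair(
        bg["log_total"].to_numpy(), bg["log_ip"].to_numpy(), span=span
    )
    bg = bg.assign(log_total=lt, log_ip=li)
    signals = average_probes(bg)
    neg_log = bg.loc[bg["is_negative_control"], "log_total"].to_numpy()
    kept, report = filter_transcripts(
        signals, neg_log, low_quantile=low_quantile,
        saturation_value=saturation_value, cv_max=cv_max,
    )
    fit = fit_regression_band(kept, level=level, band_kind=band_kind)
    calls = call_enrichment(fit, kept)
    return calls, fit, report


def run_array_pipeline(
    replicates: dict[str, pd.DataFrame],
    mock: pd.DataFrame | None = None,
    min_replicates: int = 2,
    **kwargs,
):
    """Call consensus enrichment over biological replicates plus a mock IP.

    Returns ``(consensus, per_replicate_calls, qc)`` where qc maps replicate
    name to its filter report and band parameters.
    """
    per_calls: dict[str, pd.DataFrame] = {}
    qc: dict[str, dict] = {}
    for name, probes in replicates.items():
        calls, fit, report = analyze_replicate(probes, **kwargs)
        per_calls[name] = calls
        qc[name] = {
            **report,
            "slope": fit.slope,
            "intercept": fit.intercept,
            "residual_sd": fit.residual_sd,
            "band_kind": fit.band_kind,
            "level": fit.level,
        }
    mock_calls = None
    if mock is not None:
        mock_calls, mock_fit, mock_report = analyze_replicate(mock, **kwargs)
        qc["mock"] = {
            **mock_report,
            "slope": mock_fit.slope,
            "intercept": mock_fit.intercept,
            "residual_sd": mock_fit.residual_sd,
            "band_kind": mock_fit.band_kind,
            "level": mock_fit.level,
        }
    consensus = consensus_calls(per_calls, mock_calls, min_replicates=min_replicates)
    return consensus, per_calls, qc
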
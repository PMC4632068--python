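"""Windowed-entropy low-complexity segment detection (SEG-style).

A sliding window of W residues is scored by the Shannon entropy of its
residue composition.  Windows at or below a trigger threshold K1 seed a
candidate segment, which extends over contiguous windows at or below an
extension threshold K2; overlapping or adjacent candidates merge, and merged
segments shorter than ``min_length`` residues are discarded.  This is the
trigger/extend/merge core of the SEG algorithm; the final minimal-probability
subsequence refinement is deliberately omitted, which can shift reported
boundaries by up to W - 1 residues.

A separate Q/N-richness scan flags prion-like candidate regions; it is a
compositional proxy, not a prion-propensity model, and an externally supplied
prediction list is the preferred source of prion-domain calls.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass

__all__ = [
    "AMINO_ACIDS",
    "ComplexitySegment",
    "QnScanResult",
    "window_entropy",
    "seg_scan",
    "qn_scan",
    "domain_calls",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ComplexitySegment:
    """A low-complexity interval, 1-based inclusive coordinates."""

    protein_id: str
    start: int
    end: int
    min_window_entropy: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class QnScanResult:
    is_qn_rich: bool
    best_start: int  # 1-based
    best_fraction: float


def window_entropy(window: str) -> float:
    """Shannon entropy (bits) of a window's residue composition.

    Only the 20 standard amino acids enter the count; 'X' and other letters
    are skipped and the denominator is the number of counted residues, so an
    unknown-rich window is not spuriously scored as low complexity.
    """
    if not window:
        raise ValueError("empty window")
    counts = Counter(c for c in window.upper() if c in AMINO_ACIDS)
    total = sum(counts.values())
    if total == 0:
        return 0.0
    h = 0.0
    for c in counts.values():
        p = c / total
        h -= p * math.log2(p)
    return h


def _window_entropies(seq: str, window: int) -> list[float]:
    return [window_entropy(seq[i : i + window]) for i in range(len(seq) - window + 1)]


def seg_scan(
    protein_id: str,
    seq: str,
    window: int = 12,
    trigger: float = 2.2,
    extend: float = 2.5,
    min_length: int = 35,
) -> list[ComplexitySegment]:
    """Call low-complexity segments of at least ``min_length`` residues.

    Parameters use SEG's canonical defaults: window W=12, trigger complexity
    K1=2.2 bits, extension complexity K2=2.5 bits.  Sequences shorter than
    the window yield an empty result with a warning.
    """
    seq = seq.upper()
    n = len(seq)
    if n < window:
        warnings.warn(
            f"{protein_id}: sequence shorter than window ({n} < {window}); no scan",
            stacklevel=2,
        )
        return []
    ent = _window_entropies(seq, window)
    low = [h <= extend for h in ent]
    trig = [h <= trigger for h in ent]

    # maximal runs of extension-level windows that contain >= 1 trigger window
    spans: list[tuple[int, int]] = []  # 0-based residue spans [a, b]
    i = 0
    while i < len(ent):
        if low[i]:
            j = i
            while j + 1 < len(ent) and low[j + 1]:
                j += 1
            if any(trig[k] for k in range(i, j + 1)):
                spans.append((i, j + window - 1))
            i = j + 1
        else:
            i += 1

    # merge overlapping/adjacent residue spans
    merged: list[list[int]] = []
    for a, b in spans:
        if merged and a <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])

    out = []
    for a, b in merged:
        if b - a + 1 < min_length:
            continue
        h_min = min(
            ent[k] for k in range(len(ent)) if k >= a and k + window - 1 <= b and low[k]
        )
        out.append(ComplexitySegment(protein_id, a + 1, b + 1, h_min))
    return out


def qn_scan(seq: str, window: int = 80, threshold: float = 0.3) -> QnScanResult:
    """Flag Q/N-rich (prion-like candidate) sequences.

    True iff some window of ``window`` residues has a Q+N fraction of at
    least ``threshold`` (boundary inclusive).  Sequences shorter than the
    window are scanned as a single full-length window.
    """
    seq = seq.upper()
    w = min(window, len(seq))
    if w == 0:
        raise ValueError("empty sequence")
    is_qn = [1 if c in "QN" else 0 for c in seq]
    run = sum(is_qn[:w])
    best, best_start = run, 0
    for i in range(1, len(seq) - w + 1):
        run += is_qn[i + w - 1] - is_qn[i - 1]
        if run > best:
            best, best_start = run, i
    frac = best / w
    return QnScanResult(frac >= threshold, best_start + 1, frac)


def domain_calls(
    sequences: dict[str, str],
    prion_ids: set[str] | None = None,
    min_length: int = 35,
    use_qn_proxy: bool = False,
    **seg_kwargs,
) -> "pd.DataFrame":
    """Per-protein LC>=min_length and prion flags.

    ``has_lc`` is true iff :func:`seg_scan` reports a merged segment of at
    least ``min_length`` residues.  ``has_prion`` comes from the supplied id
    list (the preferred, externally predicted source); with
    ``use_qn_proxy=True`` the Q/N scan is used instead.
    """
    import pandas as pd  # local: keeps the scanner importable without pandas

    rows = []
    for pid, seq in sequences.items():
        segs = seg_scan(pid, seq, min_length=min_length, **seg_kwargs)
        if use_qn_proxy:
            prion = qn_scan(seq).is_qn_rich
        else:
            prion = pid in (prion_ids or set())
        rows.append({"protein_id": pid, "has_lc": bool(segs), "has_prion": prion})
    return pd.DataFrame(rows)
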
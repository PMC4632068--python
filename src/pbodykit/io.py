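"""Readers and writers for the exchanged plain-text formats.

All tabular files are UTF-8 TSV with a header row; '.' and 'NA' are accepted
as missing values.  Sequence-segment coordinates are 1-based inclusive.
FASTA goes through Biopython.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_counts",
    "read_controls",
    "read_observability",
    "read_peptides",
    "read_probes",
    "read_id_list",
    "read_annotations",
    "read_tsv",
    "write_tsv",
    "write_manifest",
]

NA_VALUES = [".", "NA", ""]


def read_fasta(path) -> dict[str, str]:
    """Parse a FASTA file to an id -> uppercase-sequence dict.

    Wrapped and unwrapped records are equivalent; duplicate ids are an error.
    """
    seqs: dict[str, str] = {}
    dups = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            dups.append(rec.id)
        seqs[rec.id] = str(rec.seq).upper()
    if dups:
        raise ValueError(f"duplicate FASTA ids: {sorted(set(dups))}")
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return seqs


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in sequences.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=NA_VALUES, keep_default_na=True, **kwargs)


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def _check_nonneg_int(df: pd.DataFrame, col: str, path) -> None:
    bad = df.index[df[col].isna() | (df[col] < 0)]
    if len(bad):
        # +2: one for the header row, one for 1-based numbering
        raise ValueError(f"{path}: invalid {col} at line {int(bad[0]) + 2}")


def read_counts(path) -> pd.DataFrame:
    """Spectral-count table: protein_id, run_id, condition, spectral_count,
    unique_peptides."""
    df = read_tsv(path)
    _require_columns(
        df, ["protein_id", "run_id", "condition", "spectral_count", "unique_peptides"], path
    )
    _check_nonneg_int(df, "spectral_count", path)
    _check_nonneg_int(df, "unique_peptides", path)
    dup = df.duplicated(["protein_id", "run_id"])
    if dup.any():
        ids = df.loc[dup, "protein_id"].unique().tolist()
        raise ValueError(f"{path}: duplicate (protein, run) rows for {ids}")
    return df


def read_controls(path) -> pd.DataFrame:
    df = read_tsv(path)
    _require_columns(df, ["protein_id", "control_run_id", "count"], path)
    _check_nonneg_int(df, "count", path)
    return df


def read_observability(path) -> pd.DataFrame:
    df = read_tsv(path)
    _require_columns(df, ["protein_id", "observability"], path)
    dup = df["protein_id"][df["protein_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate protein ids {sorted(set(dup))}")
    return df


def read_peptides(path) -> pd.DataFrame:
    df = read_tsv(path)
    _require_columns(df, ["peptide_id", "protein_id", "light_area", "heavy_area"], path)
    for col in ("light_area", "heavy_area"):
        bad = df.index[df[col].isna() | (df[col] < 0)]
        if len(bad):
            raise ValueError(f"{path}: invalid {col} at line {int(bad[0]) + 2}")
    return df


def read_probes(path) -> pd.DataFrame:
    df = read_tsv(path)
    _require_columns(
        df, ["probe_id", "transcript_id", "is_negative_control", "raw_total", "raw_ip"], path
    )
    if df["is_negative_control"].dtype != bool:
        df["is_negative_control"] = (
            df["is_negative_control"].astype(str).str.lower().isin(["true", "1", "yes"])
        )
    for col in ("raw_total", "raw_ip"):
        bad = df.index[df[col].isna() | (df[col] < 0)]
        if len(bad):
            raise ValueError(f"{path}: invalid {col} at line {int(bad[0]) + 2}")
    dup = df["probe_id"][df["probe_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate probe ids {sorted(set(dup))[:5]}")
    return df


def read_id_list(path) -> list[str]:
    """One id per line; '#' comment lines and blanks skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if s and not s.startswith("#"):
            out.append(s.split("\t")[0])
    return out


def read_annotations(path) -> dict[str, set[str]]:
    """Two-column TSV (term_id <tab> gene_id) -> term -> gene-set map."""
    ann: dict[str, set[str]] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}: line {i}: expected 'term<TAB>gene'")
        ann.setdefault(parts[0], set()).add(parts[1])
    if not ann:
        raise ValueError(f"{path}: no annotations")
    return ann


def write_tsv(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, params: dict, inputs: list | None = None) -> None:
    """Record every effective parameter and input checksum for a run."""
    manifest = {
        "parameters": params,
        "inputs": {str(p): _sha256(p) for p in (inputs or []) if Path(p).exists()},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
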
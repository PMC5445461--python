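"""Readers and writers for the plain-text formats the pipeline exchanges.

Count matrices are tab-separated with a header row of sample IDs and gene
IDs in the first column; gzip is accepted transparently by file extension.
Ground-truth tables and score/profile/result tables are plain TSV.  Gene
sets use the GMT convention: set name, description, then member gene IDs,
tab-separated, one set per line.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simdata import CountMatrix

__all__ = [
    "read_counts_tsv",
    "write_counts_tsv",
    "read_group_tsv",
    "read_truth_tsv",
    "write_truth_tsv",
    "read_gmt",
    "write_gmt",
    "write_manifest",
    "read_config",
]


def read_counts_tsv(path, group=None) -> CountMatrix:
    """Read a gene x sample count matrix; rejects ragged rows, non-integer
    cells and duplicate gene identifiers with row/column context."""
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed TSV ({exc})") from exc
    if frame.isna().any().any():
        bad = frame.index[frame.isna().any(axis=1)][0]
        raise ValueError(f"{path}: missing/ragged values at gene {bad!r}")
    vals = frame.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        col = frame.columns[[not np.issubdtype(d, np.number) for d in frame.dtypes]][0]
        raise ValueError(f"{path}: non-numeric counts in column {col!r}")
    if not np.allclose(vals, np.round(vals)):
        i, j = np.argwhere(~np.isclose(vals, np.round(vals)))[0]
        raise ValueError(
            f"{path}: non-integer count at gene {frame.index[i]!r}, "
            f"sample {frame.columns[j]!r}"
        )
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene identifier {dup!r}")
    frame.index = frame.index.astype(str)
    return CountMatrix(frame.astype(np.int64), group)


def write_counts_tsv(cm: CountMatrix, path) -> None:
    frame = cm.counts.copy()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t")


def read_group_tsv(path) -> pd.Series:
    """Two-column TSV (sample_id, group) -> Series indexed by sample."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "group"], dtype=str)
    if df["group"].isna().any():
        raise ValueError(f"{path}: expected two tab-separated columns (sample, group)")
    return pd.Series(df["group"].to_numpy(), index=df["sample_id"].to_numpy(), name="group")


def write_truth_tsv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT lines need name, description "
                    "and at least one gene"
                )
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = [g for g in parts[2:] if g]
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def write_gmt(sets: dict, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *map(str, members)]) + "\n")


def write_manifest(outdir, subcommand: str, params: dict) -> Path:
    """Record all parameters (and the seed) of a run for reproducibility."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "manifest.json"
    payload = {"subcommand": subcommand, "params": params}
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return path


def read_config(path) -> dict[str, str]:
    """Plain-text ``key = value`` configuration (one pair per line, # comments)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected 'key = value'")
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out
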
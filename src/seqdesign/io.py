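"""TSV / JSON / config readers and writers shared by the CLI subcommands.

Conventions: counts files are tab-separated, one transcript per record
(id, count[, length bp]), UTF-8, LF endings, optional header; genomic
interval output is BED-like 0-based half-open; JSON reports carry a
versioned "schema" field; config files are flat YAML key-value documents
mirroring the CLI flags (unknown keys rejected).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .tx import TranscriptCounts

__all__ = [
    "read_counts_tsv",
    "write_counts_tsv",
    "write_table_tsv",
    "write_json_report",
    "write_planted_bed",
    "load_config",
]

SCHEMA_VERSION = 1


def read_counts_tsv(path, total_reads: int | None = None) -> TranscriptCounts:
    """Read a counts TSV (id<TAB>count[<TAB>length]); header row optional."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty counts file") from exc
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least 2 tab-separated columns")
    start = 0
    first = pd.to_numeric(df.iloc[0, 1], errors="coerce")
    if pd.isna(first):
        start = 1  # header row
        if len(df) == 1:
            raise ValueError(f"{path}: no data rows")
    body = df.iloc[start:]
    values = pd.to_numeric(body.iloc[:, 1], errors="coerce")
    bad = values.isna()
    if bad.any():
        lineno = int(body.index[bad.to_numpy()][0]) + 1
        raise ValueError(f"{path}: line {lineno}: cannot parse read count "
                         f"{body.iloc[:, 1][bad].iloc[0]!r}")
    counts = {str(t): int(v) for t, v in zip(body.iloc[:, 0], values)}
    lengths = None
    if df.shape[1] >= 3:
        lens = pd.to_numeric(body.iloc[:, 2], errors="coerce")
        lengths = {
            str(t): float(v)
            for t, v in zip(body.iloc[:, 0], lens)
            if not pd.isna(v)
        }
    return TranscriptCounts(counts=counts, total_reads=total_reads, lengths=lengths)


def write_counts_tsv(counts: TranscriptCounts, path, truth: dict | None = None) -> None:
    """Write a counts TSV; `truth` optionally appends a true-nu column."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        if truth is None:
            fh.write("transcript_id\tcount\n")
            for t, a in counts.counts.items():
                fh.write(f"{t}\t{a}\n")
        else:
            fh.write("transcript_id\tcount\ttrue_nu\n")
            for t, a in counts.counts.items():
                fh.write(f"{t}\t{a}\t{truth.get(t, float('nan')):.10g}\n")


def write_table_tsv(df: pd.DataFrame, path) -> None:
    """Write a result table as TSV (UTF-8, LF)."""
    df.to_csv(Path(path), sep="\t", index=False, lineterminator="\n")


def write_json_report(payload: dict, path, kind: str) -> None:
    """Write a machine-readable report with a versioned schema tag."""
    doc = {"schema": f"seqdesign/{kind}/{SCHEMA_VERSION}", **_jsonable(payload)}
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=False) + "\n", encoding="utf-8")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def write_planted_bed(testbed: pd.DataFrame, path, chrom: str = "synthetic") -> None:
    """BED-like TSV (0-based half-open) of planted SV intervals."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for _, row in testbed.iterrows():
            start = int(row["position"])
            end = int(row["position"] + row["sv_length"])
            fh.write(f"{chrom}\t{start}\t{end}\t{row['sv_id']}\n")


def load_config(path, allowed_keys) -> dict:
    """Load a flat YAML config; reject unknown keys so typos fail loudly."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if raw is None:
        return {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat key-value document")
    unknown = set(raw) - set(allowed_keys)
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {', '.join(sorted(unknown))}")
    # YAML 1.1 leaves "1e9"-style scalars as strings; coerce numeric lookalikes
    for key, value in raw.items():
        if isinstance(value, str):
            try:
                raw[key] = float(value)
            except ValueError:
                pass
    return raw
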
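"""Readers and writers for the plain-text formats the pipeline consumes.

All genomic intervals are 0-based half-open ([start, end)), matching BED.
Positions in allelic site tables are 1-based, matching the usual convention
for per-site variant records; conversion happens at the point of overlap
queries, never in storage.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd


class SchemaError(ValueError):
    """A required column is missing or malformed in a tabular input."""


class BedParseError(ValueError):
    """A BED-like file contains a malformed line (reported with its number)."""


#: canonical column sets
READ_COLUMNS = ["sample_id", "chrom", "pos", "allele", "NM", "MQ"]
SITE_COLUMNS = ["sample_id", "chrom", "pos", "gene_id", "major_count", "total_count"]
ANNOTATION_COLUMNS = ["gene_id", "chrom", "start", "end", "tss", "strand"]
DE_COLUMNS = ["gene_id", "log2fc", "p"]


def require_columns(df: pd.DataFrame, columns: Sequence[str], what: str = "table") -> None:
    """Raise :class:`SchemaError` naming the first missing column."""
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{what} is missing required column {col!r}")


def read_table(path: str | Path, columns: Sequence[str] | None = None,
               what: str | None = None) -> pd.DataFrame:
    """Read a tab-separated table with a header row."""
    df = pd.read_csv(path, sep="\t")
    if columns is not None:
        require_columns(df, columns, what or Path(path).name)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_bed(path: str | Path, extra_names: Sequence[str] = ()) -> pd.DataFrame:
    """Read a BED-like file (chrom, start, end[, extras]); 0-based half-open.

    Malformed lines raise :class:`BedParseError` with the 1-based line number.
    Lines starting with ``#`` or ``track`` are skipped.
    """
    names = ["chrom", "start", "end", *extra_names]
    rows = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < len(names):
                raise BedParseError(
                    f"{path}:{lineno}: expected at least {len(names)} fields, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if not 0 <= start < end:
                raise BedParseError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})")
            rows.append([fields[0], start, end, *fields[3:len(names)]])
    return pd.DataFrame(rows, columns=names)


def write_bed(df: pd.DataFrame, path: str | Path,
              extra_columns: Sequence[str] = ()) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cols = ["chrom", "start", "end", *extra_columns]
    df[cols].to_csv(path, sep="\t", index=False, header=False)


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list, one identifier per line."""
    with open(path) as handle:
        return [line.strip() for line in handle if line.strip()]


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as handle:
        for gene in genes:
            handle.write(f"{gene}\n")


def sha256_of(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()
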
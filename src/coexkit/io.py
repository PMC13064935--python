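"""Readers and writers for the plain-text interchange formats.

Formats
-------
Expression TSV
    First column gene id, remaining columns sample ids; header row
    required; tab-separated.
GMT
    One gene set per line: name, description, then members, tab-separated.
Alteration TSV
    Columns ``sample_id``, ``gene``, ``event_code`` where the code is
    ``MUT`` or a discrete copy-number code in {-2, -1, 0, 1, 2}.
Annotation TSV
    ``sample_id`` plus arbitrary scalar columns (e.g. a splice-variant
    SRPM).
Gene-length TSV
    Columns ``gene_id``, ``length_bp``.
Allowlist
    One gene id per line (e.g. protein-coding genes).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .containers import ExpressionMatrix, GeneSet, Unit

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
    "read_alterations_tsv",
    "write_alterations_tsv",
    "read_annotations_tsv",
    "write_annotations_tsv",
    "read_gene_lengths_tsv",
    "read_allowlist",
]

ALTERATION_COLUMNS = ["sample_id", "gene", "event_code"]


def read_expression_tsv(path: str | Path, unit: Unit | str) -> ExpressionMatrix:
    """Read a gene x sample expression TSV into an :class:`ExpressionMatrix`."""
    df = pd.read_csv(path, sep="\t", header=0, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene"
    return ExpressionMatrix(data=df.astype(float), unit=Unit(unit))


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> Path:
    path = Path(path)
    out = matrix.data.copy()
    out.index.name = "gene"
    # %.17g guarantees exact float round-trip through text
    out.to_csv(path, sep="\t", float_format="%.17g")
    return path


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file into a list of :class:`GeneSet`."""
    sets: list[GeneSet] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description and >=1 member")
        name, description, *members = fields
        members = [m for m in members if m]
        sets.append(GeneSet(name=name, members=members, description=description))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> Path:
    path = Path(path)
    lines = ["\t".join([s.name, s.description or "na", *s.members]) for s in sets]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_alterations_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ALTERATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"alteration table {path} lacks columns {missing}")
    return df[ALTERATION_COLUMNS]


def write_alterations_tsv(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table[ALTERATION_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_annotations_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError(f"annotation table {path} lacks a sample_id column")
    return df.set_index("sample_id")


def write_annotations_tsv(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    out = table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.17g")
    return path


def read_gene_lengths_tsv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "length_bp"}.issubset(df.columns):
        raise ValueError(f"gene-length table {path} needs columns gene_id, length_bp")
    lengths = df.set_index("gene_id")["length_bp"].astype(float)
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0].tolist()
        raise ValueError(f"nonpositive gene lengths for: {bad}")
    return lengths


def read_allowlist(path: str | Path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
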
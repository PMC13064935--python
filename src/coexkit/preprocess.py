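"""Expression preprocessing: unit conversion to TPM, gene filtering,
duplicate-name uniquification, and the natural-log transform.

TPM (transcripts per million) is a within-sample normalization: every
sample column sums to 1e6 after conversion. Two conversion paths are
supported — from FPKM (column renormalization) and from raw counts plus
gene lengths (length-rate normalization). TPM values are then natural
log-transformed with a +1 pseudocount for downstream correlation
analyses; since ln(x + 1) is strictly increasing, all rank-based
statistics are unchanged by the transform.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, Unit

__all__ = [
    "fpkm_to_tpm",
    "counts_to_tpm",
    "drop_zero_genes",
    "dedupe_gene_names",
    "log_transform",
    "subset_to_allowlist",
]

TPM_TOTAL = 1e6


def fpkm_to_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Convert FPKM to TPM: ``tpm_ij = fpkm_ij / sum_i fpkm_ij * 1e6``.

    Idempotent on already-normalized columns. Raises on an all-zero
    sample column (the per-sample total is the denominator).
    """
    matrix.require_unit(Unit.FPKM, Unit.TPM)
    totals = matrix.data.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"all-zero sample column(s): {zero}")
    return ExpressionMatrix(matrix.data.div(totals, axis=1) * TPM_TOTAL, Unit.TPM)


def counts_to_tpm(matrix: ExpressionMatrix, lengths: pd.Series) -> ExpressionMatrix:
    """Convert raw counts to TPM using per-gene lengths in base pairs.

    ``rate_ij = count_ij / length_i``; rates are renormalized per sample
    to sum to 1e6.
    """
    matrix.require_unit(Unit.COUNTS)
    missing = matrix.genes.difference(lengths.index).tolist()
    if missing:
        raise ValueError(f"missing gene lengths for: {missing}")
    lens = lengths.reindex(matrix.genes).astype(float)
    if (lens <= 0).any():
        raise ValueError("gene lengths must be positive")
    rates = matrix.data.div(lens, axis=0)
    totals = rates.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"zero-rate sample column(s): {zero}")
    return ExpressionMatrix(rates.div(totals, axis=1) * TPM_TOTAL, Unit.TPM)


def drop_zero_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Remove genes with zero expression across *all* samples.

    Genes that are zero in only some samples are retained; survivor
    order is preserved.
    """
    keep = (matrix.data != 0).any(axis=1)
    return matrix.with_data(matrix.data.loc[keep])


def dedupe_gene_names(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Make duplicate gene names unique.

    The first occurrence keeps its name; the k-th duplicate is suffixed
    ``.k`` (``TP53, TP53 -> TP53, TP53.1``), matching the make-unique
    convention common in expression toolchains.
    """
    counts: dict[str, int] = {}
    new_index = []
    for name in matrix.genes:
        k = counts.get(name, 0)
        counts[name] = k + 1
        new_index.append(name if k == 0 else f"{name}.{k}")
    data = matrix.data.copy()
    data.index = pd.Index(new_index, name=matrix.data.index.name)
    return matrix.with_data(data)


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Natural-log transform TPM values with a +1 pseudocount.

    ``x -> ln(x + 1)`` elementwise; the resulting unit is ``LOG_TPM``.
    The map is strictly increasing, so Spearman correlations computed
    before and after are identical.
    """
    matrix.require_unit(Unit.TPM)
    if matrix.data.size and matrix.data.to_numpy().min() < 0:
        raise ValueError("negative TPM values")
    return ExpressionMatrix(np.log1p(matrix.data), Unit.LOG_TPM)


def subset_to_allowlist(matrix: ExpressionMatrix, allowlist: list[str]) -> ExpressionMatrix:
    """Keep only genes present in a user-supplied allowlist (e.g. the
    protein-coding genes), preserving matrix order."""
    allowed = set(allowlist)
    keep = [g for g in matrix.genes if g in allowed]
    return matrix.with_data(matrix.data.loc[keep])
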
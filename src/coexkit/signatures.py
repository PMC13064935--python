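"""Single-sample gene-set activity scoring and genome-wide correlation
rankings ("snake plots").

The activity score of a gene set in a sample is the mean z-score, across
the set's member genes, of log-TPM expression (each gene standardized
across samples). Every detectable gene is then ranked by its Spearman
correlation with the activity score; the sorted rank-vs-rho table is the
snake plot, and the percentile position of highlighted genes (e.g. a
candidate regulator against a basal signature) is the headline readout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _stats
from .containers import ExpressionMatrix, GeneSet, Unit

__all__ = [
    "ActivityScore",
    "score_signature",
    "correlate_genes_to_score",
    "snake_ranking",
    "activity_gene_heatmap",
]

logger = logging.getLogger(__name__)


@dataclass
class ActivityScore:
    """Per-sample activity of one signature (mean member z-score)."""

    name: str
    values: pd.Series  # indexed by sample id
    members_used: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError(f"activity score {self.name!r} has non-finite values")


def score_signature(matrix: ExpressionMatrix, gene_set: GeneSet) -> ActivityScore:
    """Mean z-score activity of ``gene_set`` per sample.

    Member genes absent from the matrix are skipped; members with zero
    variance across samples carry no ranking information and are
    excluded with a logged warning. At least one usable member is
    required.
    """
    matrix.require_unit(Unit.LOG_TPM, Unit.TPM)
    present = gene_set.present_in(matrix.genes)
    if not present:
        raise ValueError(f"no members of gene set {gene_set.name!r} present in matrix")
    sub = matrix.data.loc[present]
    sd = sub.std(axis=1, ddof=1)
    usable = sd.index[sd > 0].tolist()
    dropped = sd.index[sd == 0].tolist()
    if dropped:
        logger.warning("gene set %s: excluded %d zero-variance member(s): %s",
                       gene_set.name, len(dropped), dropped)
    if not usable:
        raise ValueError(f"all present members of {gene_set.name!r} have zero variance")
    z = sub.loc[usable].sub(sub.loc[usable].mean(axis=1), axis=0).div(sd.loc[usable], axis=0)
    return ActivityScore(name=gene_set.name, values=z.mean(axis=0), members_used=tuple(usable))


def correlate_genes_to_score(matrix: ExpressionMatrix, score: ActivityScore) -> pd.DataFrame:
    """Spearman-correlate every gene with an activity score and rank.

    Returns a DataFrame indexed by gene with columns ``rho``, ``p``,
    ``q`` (BH-adjusted across all genes tested) and ``rank`` (1 = most
    positively correlated; ties broken by gene label). Genes belonging
    to the scored signature are not excluded; flag them downstream via
    :func:`snake_ranking` if needed.
    """
    if not score.values.index.equals(matrix.samples):
        if set(score.values.index) != set(matrix.samples):
            raise ValueError("activity score samples do not match matrix samples")
        score = ActivityScore(score.name, score.values.reindex(matrix.samples),
                              score.members_used)
    values = matrix.data.to_numpy()
    vec = score.values.to_numpy()
    rho = _stats.spearman_rows_vs_vector(values, vec)
    n = matrix.n_samples
    tie_free = None
    if n <= _stats.EXACT_MAX_N and not _stats.has_ties(vec):
        tie_free = np.array([not _stats.has_ties(row) for row in values])
    p = _stats.spearman_pvalues(rho, n, tie_free)
    out = pd.DataFrame({"rho": rho, "p": p}, index=matrix.genes)
    finite = out["p"].notna()
    q = np.full(len(out), np.nan)
    q[finite.to_numpy()] = _stats.bh_adjust(out.loc[finite, "p"].to_numpy())
    out["q"] = q
    # deterministic ordering: rho descending, ties broken by gene label
    out = out.iloc[np.lexsort((out.index.to_numpy(), -out["rho"].to_numpy()))]
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def snake_ranking(ranking: pd.DataFrame, highlight: list[str] | None = None) -> pd.DataFrame:
    """Plot-ready snake table: (rank, gene, rho, highlight, percentile).

    ``percentile`` is the gene's position from the top of the ranking on
    a 0-100 scale (rank 1 -> 100). Highlight genes missing from the
    ranking are reported with a warning, not fatal.
    """
    highlight = list(highlight or [])
    missing = [g for g in highlight if g not in ranking.index]
    if missing:
        logger.warning("highlight gene(s) not in ranking: %s", missing)
    table = ranking.reset_index().rename(columns={ranking.index.name or "index": "gene"})
    table = table[["rank", "gene", "rho"]].sort_values("rank").reset_index(drop=True)
    g = len(table)
    table["highlight"] = table["gene"].isin(highlight)
    table["percentile"] = 100.0 * (g - (table["rank"] - 1)) / g
    return table


def activity_gene_heatmap(matrix: ExpressionMatrix, scores: list[ActivityScore],
                          genes: list[str]) -> pd.DataFrame:
    """Spearman rho between each activity score (rows) and each listed
    gene's expression (columns); plot-ready association matrix.

    Absent genes are omitted with a warning; constant genes give an
    undefined correlation reported as NaN.
    """
    present = [g for g in genes if g in matrix.genes]
    absent = [g for g in genes if g not in matrix.genes]
    if absent:
        logger.warning("heatmap gene(s) absent from matrix, omitted: %s", absent)
    if not present:
        raise ValueError("no requested genes present in matrix")
    values = matrix.data.loc[present].to_numpy()
    rows = {}
    for score in scores:
        vec = score.values.reindex(matrix.samples).to_numpy()
        rows[score.name] = _stats.spearman_rows_vs_vector(values, vec)
    return pd.DataFrame(rows, index=present).T
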
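"""ALAN — the Algorithm for Linking Activity Networks.

Rather than comparing two genes by their direct pairwise correlation,
ALAN compares the *behavior* of genes: each gene's genome-wide vector of
Spearman correlations to every other gene (its row of the behavior
matrix). Two genes with similar behavior vectors sit in the same
transcriptional network even if their direct correlation is modest. The
ALAN score of a gene pair is the Pearson correlation of their behavior
vectors (self-entries excluded), bounded in [-1, 1]; with G genes the
behavior matrix encodes G^2 potential interactions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import _stats
from .containers import ExpressionMatrix, GeneSet, Unit

__all__ = [
    "BehaviorMatrix",
    "ALANProfile",
    "build_behavior_matrix",
    "alan_score",
    "geneset_alan_heatmap",
    "compare_profiles_r2",
    "count_potential_interactions",
]

DEFAULT_BLOCK_SIZE = 512


@dataclass
class BehaviorMatrix:
    """Gene x gene Spearman correlation matrix; rows are behavior vectors."""

    data: pd.DataFrame

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    def profile(self, gene: str) -> "ALANProfile":
        if gene not in self.data.index:
            raise KeyError(f"gene {gene!r} not in behavior matrix")
        return ALANProfile(focal=gene, values=self.data.loc[gene].copy())


@dataclass
class ALANProfile:
    """One gene's behavior vector over the whole gene universe."""

    focal: str
    values: pd.Series


def build_behavior_matrix(matrix: ExpressionMatrix,
                          block_size: int = DEFAULT_BLOCK_SIZE) -> BehaviorMatrix:
    """All-pairs Spearman correlation of log-expression across samples.

    Genes are rank-transformed across samples once, then correlations
    are accumulated blockwise so the working set stays bounded for large
    gene panels; the result is symmetric with a unit diagonal. Constant
    genes have undefined correlations and must be removed first (an
    error lists the offenders); at least 3 samples are required.
    """
    matrix.require_unit(Unit.LOG_TPM, Unit.TPM)
    if matrix.n_samples < 3:
        raise ValueError(f"need >= 3 samples, got {matrix.n_samples}")
    values = matrix.data.to_numpy(dtype=float)
    constant = matrix.genes[np.ptp(values, axis=1) == 0].tolist()
    if constant:
        raise ValueError(f"constant gene(s) must be removed first: {constant}")
    ranked = _stats.standardize_rows(_stats.rank_rows(values))
    g = ranked.shape[0]
    out = np.empty((g, g), dtype=float)
    for start in range(0, g, block_size):
        stop = min(start + block_size, g)
        out[start:stop] = ranked[start:stop] @ ranked.T
    np.clip(out, -1.0, 1.0, out=out)
    out = (out + out.T) / 2.0
    np.fill_diagonal(out, 1.0)
    return BehaviorMatrix(pd.DataFrame(out, index=matrix.genes, columns=matrix.genes))


def alan_score(behavior: BehaviorMatrix, a: str, b: str) -> float:
    """Pearson correlation of two genes' behavior vectors.

    The self-entries of both genes (always 1) are excluded before
    correlating so identical-by-construction positions do not inflate
    the score. Symmetric in its arguments; ``alan_score(g, g) = 1``.
    """
    for gene in (a, b):
        if gene not in behavior.data.index:
            raise KeyError(f"gene {gene!r} not in behavior matrix")
    if a == b:
        return 1.0
    a, b = sorted((a, b))  # canonical order makes the score exactly symmetric
    keep = ~behavior.data.columns.isin([a, b])
    va = behavior.data.loc[a].to_numpy()[keep]
    vb = behavior.data.loc[b].to_numpy()[keep]
    if va.size < 2 or np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError(f"behavior vectors of {a!r}/{b!r} are degenerate")
    r = float(np.corrcoef(va, vb)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def geneset_alan_heatmap(behavior: BehaviorMatrix, focal_genes: list[str],
                         panel: GeneSet) -> pd.DataFrame:
    """ALAN scores of each focal gene (rows) against each panel member
    (columns), e.g. candidate regulators vs a 25-transcription-factor
    subtype panel. Absent panel members are dropped with a warning."""
    import logging

    present = panel.present_in(behavior.genes)
    absent = [m for m in panel.members if m not in set(present)]
    if absent:
        logging.getLogger(__name__).warning(
            "panel %s: dropped absent member(s): %s", panel.name, absent)
    if not present:
        raise ValueError(f"no members of panel {panel.name!r} present in behavior matrix")
    for gene in focal_genes:
        if gene not in behavior.data.index:
            raise KeyError(f"focal gene {gene!r} not in behavior matrix")
    out = pd.DataFrame(index=focal_genes, columns=present, dtype=float)
    for f in focal_genes:
        for m in present:
            out.loc[f, m] = alan_score(behavior, f, m)
    return out


def compare_profiles_r2(p1: ALANProfile, p2: ALANProfile) -> tuple[float, float, float]:
    """Ordinary least-squares of profile 2 on profile 1: (R^2, slope, intercept).

    Profiles are aligned on their common gene universe; the self-entries
    of both focal genes are removed first. Used to quantify how
    concordant one gene's network is across two cohorts, or two genes'
    networks within one cohort.
    """
    common = p1.values.index.intersection(p2.values.index)
    common = common.difference([p1.focal, p2.focal])
    if len(common) < 3:
        raise ValueError(f"profile intersection too small ({len(common)} genes)")
    x = p1.values.reindex(common).to_numpy()
    y = p2.values.reindex(common).to_numpy()
    res = stats.linregress(x, y)
    return float(res.rvalue**2), float(res.slope), float(res.intercept)


def count_potential_interactions(n_genes: int) -> int:
    """Number of potential gene-gene interactions ALAN can score: G^2."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    return int(n_genes) ** 2
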
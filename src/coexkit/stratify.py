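"""Expression-quartile stratification and alteration-frequency testing.

A cohort is split into High and Low groups — the top and bottom 25%
quartiles of one gene's expression (floor(n/4) samples each, ties broken
by sample id for determinism). Group differences are then tested with
Mann-Whitney U (expression or scalar annotations such as a splice-variant
SRPM) and Fisher's exact test (mutation / discrete copy-number
alteration frequencies), with Benjamini-Hochberg FDR control and the
conventional star annotation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _stats
from .containers import ExpressionMatrix

__all__ = [
    "QuartileSplit",
    "ContingencyResult",
    "CNA_CATEGORY",
    "ALTERATION_CATEGORIES",
    "quartile_split",
    "compare_groups_numeric",
    "categorize_alterations",
    "fisher_alteration_test",
    "bh_adjust",
    "significance_stars",
]

logger = logging.getLogger(__name__)

# discrete copy-number codes (cBioPortal/GISTIC convention)
CNA_CATEGORY = {"-2": "HOMODEL", "-1": "HETERODEL", "0": "NEUTRAL", "1": "GAIN", "2": "AMP"}
ALTERATION_CATEGORIES = ["MUT_ONLY", "HOMODEL", "HETERODEL", "NEUTRAL", "GAIN", "AMP",
                         "MULTIPLE"]
UNALTERED = {"NEUTRAL"}


@dataclass
class QuartileSplit:
    """Top/bottom expression-quartile partition on one gene."""

    gene: str
    high: tuple[str, ...]
    low: tuple[str, ...]
    cutoff_low: float   # highest expression admitted to the low group
    cutoff_high: float  # lowest expression admitted to the high group
    n_cohort: int       # full cohort size (retained n is len(high)+len(low))

    @property
    def n_retained(self) -> int:
        return len(self.high) + len(self.low)


def quartile_split(matrix: ExpressionMatrix, gene: str) -> QuartileSplit:
    """Split samples into top/bottom floor(n/4) by one gene's expression.

    Samples are sorted by (expression, sample id); the deterministic tie
    break makes group sizes invariant under any strictly increasing
    transform of the gene's expression.
    """
    if gene not in matrix.genes:
        raise KeyError(f"gene {gene!r} not in matrix")
    n = matrix.n_samples
    if n < 4:
        raise ValueError(f"need >= 4 samples to form quartiles, got {n}")
    expr = matrix.data.loc[gene]
    if isinstance(expr, pd.DataFrame):  # duplicated gene label
        raise ValueError(f"gene label {gene!r} is duplicated; dedupe first")
    order = sorted(matrix.samples, key=lambda s: (expr[s], s))
    k = n // 4
    low, high = order[:k], order[-k:]
    return QuartileSplit(gene=gene, high=tuple(high), low=tuple(low),
                         cutoff_low=float(expr[low[-1]]),
                         cutoff_high=float(expr[high[0]]), n_cohort=n)


def compare_groups_numeric(values: pd.Series, split: QuartileSplit) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of a numeric feature between the
    High and Low groups.

    Missing values are dropped (count logged). The exact null is used
    when both groups have <= 8 observations and the pooled values are
    tie-free; otherwise the tie-corrected normal approximation.
    Returns (U statistic for the High group, two-sided p).
    """
    hi = values.reindex(list(split.high)).dropna()
    lo = values.reindex(list(split.low)).dropna()
    n_missing = (len(split.high) - len(hi)) + (len(split.low) - len(lo))
    if n_missing:
        logger.info("compare_groups_numeric: dropped %d sample(s) with missing values",
                    n_missing)
    if len(hi) == 0 or len(lo) == 0:
        raise ValueError("a group is empty after missing-value removal")
    pooled = np.concatenate([hi.to_numpy(), lo.to_numpy()])
    if np.ptp(pooled) == 0:
        return float(len(hi) * len(lo) / 2.0), 1.0
    tie_free = np.unique(pooled).size == pooled.size
    if len(hi) <= 8 and len(lo) <= 8 and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(hi, lo, alternative="two-sided", method=method,
                             use_continuity=False)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def _collapse(has_mut: bool, cna_code: str | None) -> str:
    if cna_code is None:
        cna_cat = "NEUTRAL"
    else:
        if cna_code not in CNA_CATEGORY:
            raise ValueError(f"unknown CNA code {cna_code!r}")
        cna_cat = CNA_CATEGORY[cna_code]
    if has_mut:
        return "MULTIPLE" if cna_cat != "NEUTRAL" else "MUT_ONLY"
    return cna_cat


def categorize_alterations(alterations: pd.DataFrame, gene: str,
                           profiled_samples: list[str] | None = None) -> pd.Series:
    """Collapse mutation and discrete CNA records into one category per sample.

    Codes -2/-1/0/1/2 map to HOMODEL/HETERODEL/NEUTRAL/GAIN/AMP; a
    mutation together with a non-NEUTRAL CNA becomes MULTIPLE, a
    mutation alone MUT_ONLY. When ``profiled_samples`` is given, listed
    samples without records are NEUTRAL (profiled, no event); samples
    outside the profiled set are NA and excluded. Without it, only
    samples with records for ``gene`` appear (absent samples are NA).
    """
    sub = alterations[alterations["gene"].astype(str) == gene]
    calls: dict[str, str] = {}
    grouped: dict[str, tuple[bool, str | None]] = {}
    for sample_id, grp in sub.groupby("sample_id"):
        codes = [str(c) for c in grp["event_code"]]
        has_mut = "MUT" in codes
        cna_codes = sorted({c for c in codes if c != "MUT"})
        for c in cna_codes:
            if c not in CNA_CATEGORY:
                raise ValueError(f"unknown event code {c!r} for sample {sample_id}")
        if len(cna_codes) > 1:
            raise ValueError(f"conflicting CNA codes {cna_codes} for sample "
                             f"{sample_id}, gene {gene}")
        grouped[str(sample_id)] = (has_mut, cna_codes[0] if cna_codes else None)
    for sample_id, (has_mut, cna) in grouped.items():
        calls[sample_id] = _collapse(has_mut, cna)
    if profiled_samples is not None:
        profiled = [str(s) for s in profiled_samples]
        calls = {s: calls.get(s, "NEUTRAL") for s in profiled}
    return pd.Series(calls, name=gene, dtype=object)


@dataclass
class ContingencyResult:
    """Fisher's exact test of alteration frequency between split groups."""

    gene: str
    table: np.ndarray                 # 2x2 [[high_alt, high_unalt], [low_alt, low_unalt]]
    category_counts: pd.DataFrame     # group x category descriptive counts
    p: float
    q: float | None = None
    stars: str | None = None
    degenerate: bool = False
    n_na: int = 0


def fisher_alteration_test(calls: pd.Series, split: QuartileSplit,
                           gene: str | None = None) -> ContingencyResult:
    """Collapsed altered/not-altered 2x2 Fisher's exact test between the
    High and Low groups.

    "Altered" is any category except NEUTRAL; samples without a call
    (NA) are removed and counted. A table with a zero margin is
    degenerate and reported with p = 1 and a flag. Per-category counts
    are attached for stacked-bar style descriptive output.
    """
    gene = gene or str(calls.name)
    rows = {}
    tables = []
    n_na = 0
    for label, group in (("high", split.high), ("low", split.low)):
        present = [s for s in group if s in calls.index]
        n_na += len(group) - len(present)
        if not present:
            raise ValueError(f"no alteration calls for any sample in the {label} group")
        cats = calls.reindex(present)
        altered = int((~cats.isin(UNALTERED)).sum())
        tables.append([altered, len(present) - altered])
        rows[label] = cats.value_counts().reindex(ALTERATION_CATEGORIES, fill_value=0)
    table = np.array(tables, dtype=int)
    degenerate = bool((table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any())
    if degenerate:
        p = 1.0
    else:
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return ContingencyResult(gene=gene, table=table,
                             category_counts=pd.DataFrame(rows).T, p=p,
                             degenerate=degenerate, n_na=n_na)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; q >= p, monotone in p."""
    return _stats.bh_adjust(np.asarray(list(p_values), dtype=float))


def significance_stars(q: float) -> str:
    """Star label for a BH-adjusted p-value (4-tier convention)."""
    if not (0.0 <= q <= 1.0) or math.isnan(q):
        raise ValueError(f"q must be in [0, 1], got {q}")
    if q > 0.05:
        return "ns"
    if q > 0.01:
        return "*"
    if q > 0.001:
        return "**"
    if q > 0.0001:
        return "***"
    return "****"
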
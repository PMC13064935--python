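"""Shared rank-statistics machinery.

Spearman correlations are computed vectorized (rank rows once, then
Pearson on the rank matrix) so genome-wide rankings and the gene x gene
behavior matrix stay fast. p-values use the t approximation except for
tiny tie-free cohorts (n < 10 samples), where the exact permutation null
is enumerated once per n and cached.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

EXACT_MAX_N = 9  # full permutation enumeration up to 9! labelings


def rank_rows(values: np.ndarray) -> np.ndarray:
    """Average-rank each row of a 2-D array."""
    return stats.rankdata(values, axis=1)


def standardize_rows(values: np.ndarray) -> np.ndarray:
    """Center and scale rows to unit norm; raises on constant rows."""
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("constant rows cannot be standardized")
    return centered / norms


def spearman_rows_vs_vector(values: np.ndarray, vector: np.ndarray) -> np.ndarray:
    """Spearman rho of each row of ``values`` against ``vector``.

    Constant rows yield NaN (undefined correlation) rather than raising.
    """
    ranked = rank_rows(values)
    rv = stats.rankdata(vector)
    rv = rv - rv.mean()
    rv_norm = np.linalg.norm(rv)
    if rv_norm == 0:
        return np.full(values.shape[0], np.nan)
    centered = ranked - ranked.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = centered @ rv / (norms * rv_norm)
    rho[norms == 0] = np.nan
    return np.clip(rho, -1.0, 1.0, out=rho)


@lru_cache(maxsize=8)
def _exact_null_abs_rho(n: int) -> np.ndarray:
    """Sorted |rho| values over all n! tie-free rank permutations."""
    base = np.arange(1, n + 1, dtype=float)
    denom = n * (n * n - 1)
    rhos = np.array(
        [1.0 - 6.0 * np.sum((base - np.asarray(p, dtype=float)) ** 2) / denom
         for p in permutations(range(1, n + 1))]
    )
    return np.sort(np.abs(rhos))


def spearman_pvalues(rho: np.ndarray, n: int, tie_free: np.ndarray | None = None) -> np.ndarray:
    """Two-sided p-values for Spearman rho at sample size ``n``.

    ``tie_free`` marks rows eligible for the exact null (no ties in the
    row nor in the reference vector); others use the t approximation.
    """
    rho = np.asarray(rho, dtype=float)
    p = np.full(rho.shape, np.nan)
    ok = np.isfinite(rho)
    if n > 2:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * np.sqrt((n - 2) / np.clip(1.0 - rho**2, 1e-300, None))
        p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=n - 2)
        np.clip(p, 0.0, 1.0, out=p)
    if 2 < n <= EXACT_MAX_N:
        null_abs = _exact_null_abs_rho(n)
        total = null_abs.size
        use = ok if tie_free is None else (ok & tie_free)
        idx = np.searchsorted(null_abs, np.abs(rho[use]) - 1e-12, side="left")
        p[use] = (total - idx) / total
    return p


def has_ties(row: np.ndarray) -> bool:
    return np.unique(row).size < row.size


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
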
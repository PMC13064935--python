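"""Independent brute-force oracles used to pin down expected values.

These deliberately avoid the code paths they check: Spearman is
rank-then-Pearson by hand, Fisher's exact test is full hypergeometric
enumeration with binomial coefficients, and BH is the literal step-up
definition.
"""

from math import comb

import numpy as np


def spearman_bruteforce(x, y):
    """Spearman rho as Pearson correlation of average ranks."""
    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sorted_v[j] == sorted_v[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2.0  # average of ranks i+1..j
            i = j
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def fisher_exact_enumeration(table):
    """Two-sided Fisher p by summing hypergeometric probabilities of all
    tables with the observed margins that are no more probable."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(k):
        if k < 0 or k > r1 or c1 - k < 0 or c1 - k > r2:
            return 0.0
        return comb(r1, k) * comb(r2, c1 - k) / denom

    p_obs = prob(a)
    return sum(p for k in range(0, min(r1, c1) + 1)
               if (p := prob(k)) <= p_obs * (1 + 1e-9))


def bh_stepup(p_values):
    """BH q-values straight from the step-up definition."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * m / rank_from_top)
        q[idx] = running_min
    return q
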
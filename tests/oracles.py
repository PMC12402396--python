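"""Independent brute-force oracles for the rank and distribution statistics.

These are deliberately naive O(n^2) / enumeration implementations, kept free
of scipy so the library's statistics can be checked against a second route.
"""

from __future__ import annotations

import numpy as np


def midranks(pooled: np.ndarray) -> np.ndarray:
    """Midranks (ties averaged), 1-based, by direct comparison counting."""
    pooled = np.asarray(pooled, dtype=float)
    n = pooled.size
    ranks = np.empty(n)
    for i in range(n):
        less = np.sum(pooled < pooled[i])
        equal = np.sum(pooled == pooled[i])
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def bf_kruskal_h(a: np.ndarray, b: np.ndarray) -> float:
    """Two-group Kruskal-Wallis H with tie correction, from the definition."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n = pooled.size
    ranks = midranks(pooled)
    r_a = ranks[: a.size]
    r_b = ranks[a.size :]
    h = (12.0 / (n * (n + 1))) * (
        a.size * (r_a.mean() - (n + 1) / 2.0) ** 2
        + b.size * (r_b.mean() - (n + 1) / 2.0) ** 2
    )
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    denom = 1.0 - tie_term / (n**3 - n)
    if denom == 0:
        return 0.0
    return float(h / denom)


def bf_u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of A over B by exhaustive pair counting (ties = 1/2)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def bf_rank_biserial(a: np.ndarray, b: np.ndarray) -> float:
    """(wins - losses) / (n_A n_B) over all cross-group pairs."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    wins = sum(1 for x in a for y in b if x > y)
    losses = sum(1 for x in a for y in b if x < y)
    return (wins - losses) / (a.size * b.size)


def bf_ks_d(a: np.ndarray, b: np.ndarray) -> float:
    """sup |ECDF_A - ECDF_B| scanned over every pooled point."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    d = 0.0
    for x in np.concatenate([a, b]):
        ecdf_a = np.sum(a <= x) / a.size
        ecdf_b = np.sum(b <= x) / b.size
        d = max(d, abs(ecdf_a - ecdf_b))
    return float(d)


def bf_chi2(table: np.ndarray) -> float:
    """Pearson chi-square from observed/expected, no continuity correction."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    return float(np.sum((table - expected) ** 2 / expected))
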
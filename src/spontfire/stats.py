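"""Group statistics: per-timepoint rank tests with effect sizes, gated
parametric/nonparametric group comparisons, and ISI distribution tests.

The per-timepoint scan compares the two groups' instantaneous rates at a
1-s grid with the Kruskal-Wallis test (rank-based, chi-square approximation
with tie correction; for two groups it is the Mann-Whitney test in
disguise) and attaches the rank-biserial correlation as a nonparametric
effect size, tiered as low (< 0.2), medium ([0.2, 0.5)) or high (>= 0.5)
wherever p < 0.05.  Group-mean comparisons run a normality test per group
(Lilliefors-corrected KS by default, Shapiro-Wilk optionally) and route to
t-tests or their rank-based counterparts accordingly.  ISI distributions
are compared with the two-sample KS test and the 2x2 short-vs-long ISI
table with Pearson's chi-square (no continuity correction: the expected
counts in this application are large).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .core import RateSeries

__all__ = [
    "kruskal_wallis",
    "rank_biserial",
    "classify_effect",
    "timepoint_scan",
    "GroupComparison",
    "compare_group_means",
    "ks_two_sample",
    "chi2_short_isi",
    "paired_spike_count_test",
]

EFFECT_TIERS = ("ns", "low", "medium", "high")


def kruskal_wallis(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float]:
    """Two-group Kruskal-Wallis H and its chi-square (df = 1) p-value.

    Identical pooled values give (H, p) = (0, 1) rather than an error.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(a, b)
    return float(h), float(p)


def rank_biserial(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """Rank-biserial correlation, ``2 U_A / (n_A n_B) - 1`` with midrank ties.

    Positive values mean group A is stochastically larger; the range is
    [-1, 1] with +/-1 at complete separation.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    u_a = float(sps.mannwhitneyu(a, b, alternative="two-sided").statistic)
    return 2.0 * u_a / (a.size * b.size) - 1.0


def classify_effect(r: float, p: float, alpha: float = 0.05) -> str:
    """Effect tier: ns unless p < alpha, else low / medium / high by |r|."""
    if not -1.0 - 1e-12 <= r <= 1.0 + 1e-12:
        raise ValueError("rank-biserial r must be in [-1, 1]")
    if p >= alpha:
        return "ns"
    if abs(r) < 0.2:
        return "low"
    if abs(r) < 0.5:
        return "medium"
    return "high"


def timepoint_scan(
    series_a: list[RateSeries],
    series_b: list[RateSeries],
    step: float = 1.0,
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Kruskal-Wallis + rank-biserial at a grid of timepoints.

    Grid points sit at window centres ``step/2, 3*step/2, ...`` so adjacent
    tests share no boxcar content at the default 1-s window and step.
    Columns: ``t_s, H, p, rank_biserial, effect_tier`` (plus ``p_adj`` when
    ``fdr`` is set, with the tier then gated on the adjusted p).
    """
    if len(series_a) < 2 or len(series_b) < 2:
        raise ValueError("each group needs at least 2 animals")
    all_series = series_a + series_b
    n = all_series[0].rate.size
    fs = all_series[0].fs
    for s in all_series[1:]:
        if s.rate.size != n or s.fs != fs:
            raise ValueError("all rate series must share length and rate")
    centers = np.arange(step / 2.0, n / fs, step)
    idx = np.round(centers * fs).astype(int)
    idx = idx[idx < n]
    mat_a = np.stack([s.rate[idx] for s in series_a])
    mat_b = np.stack([s.rate[idx] for s in series_b])
    rows = []
    for j, i in enumerate(idx):
        h, p = kruskal_wallis(mat_a[:, j], mat_b[:, j])
        r = rank_biserial(mat_a[:, j], mat_b[:, j])
        rows.append((i / fs, h, p, r))
    df = pd.DataFrame(rows, columns=["t_s", "H", "p", "rank_biserial"])
    p_for_tier = df["p"].to_numpy()
    if fdr:
        df["p_adj"] = multipletests(p_for_tier, method="fdr_bh")[1]
        p_for_tier = df["p_adj"].to_numpy()
    df["effect_tier"] = [
        classify_effect(r, p, alpha)
        for r, p in zip(df["rank_biserial"], p_for_tier)
    ]
    return df


@dataclass(frozen=True)
class GroupComparison:
    """Result of a normality-gated two-sample (or paired) comparison."""

    label: str
    test_used: str  # unpaired t / paired t / mann-whitney / wilcoxon
    statistic: float
    p: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    normality_p_a: float
    normality_p_b: float
    paired: bool


def _normality_p(x: np.ndarray, method: str) -> float:
    if np.ptp(x) == 0:
        return 0.0  # degenerate: constant sample, treat as non-normal
    if method == "lilliefors":
        if x.size < 4:  # Lilliefors table starts at n = 4
            return float(sps.shapiro(x).pvalue)
        return float(lilliefors(x, dist="norm")[1])
    if method == "shapiro":
        return float(sps.shapiro(x).pvalue)
    raise ValueError("normality method must be lilliefors or shapiro")


def compare_group_means(
    values_a: np.ndarray,
    values_b: np.ndarray,
    paired: bool = False,
    normality: str = "lilliefors",
    alpha: float = 0.05,
    label: str = "",
) -> GroupComparison:
    """Two-tailed comparison of per-animal means with a normality gate.

    Both groups passing the normality test at ``alpha`` routes to a t-test
    (paired or unpaired); otherwise to the Wilcoxon signed-rank (paired) or
    Mann-Whitney U (unpaired) test.  Zero-variance ties degrade gracefully
    to (statistic 0, p 1) with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 observations per group")
    if paired and a.size != b.size:
        raise ValueError("paired comparison requires equal-length groups")
    p_norm_a = _normality_p(a, normality)
    p_norm_b = _normality_p(b, normality)
    both_normal = p_norm_a >= alpha and p_norm_b >= alpha

    if paired and np.all(a == b):
        warnings.warn("paired samples are identical; degenerate tie", stacklevel=2)
        test = "paired t" if both_normal else "wilcoxon"
        stat, p = 0.0, 1.0
    elif both_normal:
        if paired:
            test = "paired t"
            res = sps.ttest_rel(a, b)
        else:
            test = "unpaired t"
            res = sps.ttest_ind(a, b)
        stat, p = float(res.statistic), float(res.pvalue)
        if np.isnan(stat):  # zero-variance degenerate case
            warnings.warn("degenerate variance in t-test", stacklevel=2)
            stat, p = 0.0, 1.0
    else:
        if paired:
            test = "wilcoxon"
            res = sps.wilcoxon(a, b)
        else:
            test = "mann-whitney"
            res = sps.mannwhitneyu(a, b, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        label=label,
        test_used=test,
        statistic=stat,
        p=p,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        normality_p_a=p_norm_a,
        normality_p_b=p_norm_b,
        paired=paired,
    )


def ks_two_sample(isis_a: np.ndarray, isis_b: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov D and asymptotic p-value."""
    a = np.asarray(isis_a, dtype=float)
    b = np.asarray(isis_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def chi2_short_isi(
    counts_a: tuple[int, int], counts_b: tuple[int, int]
) -> tuple[float, float]:
    """Pearson chi-square (df = 1, no continuity correction) on the 2x2
    short/non-short ISI table; rows are groups, columns (short, non-short)."""
    table = np.array([counts_a, counts_b], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=1) == 0):
        raise ValueError("each group needs a positive ISI total")
    if table.sum(axis=0).min() == 0:
        return 0.0, 1.0  # a column is empty: proportions identical (0 or 1)
    chi2, p, _, expected = sps.chi2_contingency(table, correction=False)
    if expected.min() < 5:
        warnings.warn(
            "expected cell count below 5; consider an exact test", stacklevel=2
        )
    return float(chi2), float(p)


def paired_spike_count_test(
    counts_before: np.ndarray, counts_after: np.ndarray
) -> GroupComparison:
    """Two-tailed paired t-test on per-animal total spike counts."""
    before = np.asarray(counts_before, dtype=float)
    after = np.asarray(counts_after, dtype=float)
    if before.size != after.size:
        raise ValueError("before/after must be the same animals")
    if before.size < 2:
        raise ValueError("need at least 2 animals")
    diff = before - after
    if np.ptp(diff) == 0:
        if diff[0] == 0:
            stat, p = 0.0, 1.0
        else:
            warnings.warn("degenerate zero-variance difference", stacklevel=2)
            stat, p = float(np.sign(diff[0]) * np.inf), 0.0
    else:
        res = sps.ttest_rel(before, after)
        stat, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        label="total spike count before vs after",
        test_used="paired t",
        statistic=stat,
        p=p,
        mean_a=float(before.mean()),
        sd_a=float(before.std(ddof=1)) if before.size > 1 else 0.0,
        mean_b=float(after.mean()),
        sd_b=float(after.std(ddof=1)) if after.size > 1 else 0.0,
        normality_p_a=float("nan"),
        normality_p_b=float("nan"),
        paired=True,
    )
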
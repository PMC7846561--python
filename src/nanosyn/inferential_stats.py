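"""Nonparametric test battery for the spatial analyses.

Thin, convention-pinning wrappers around scipy.stats: one-sample Wilcoxon
signed-rank against a theoretical median (exact null enumeration at small n),
Mann-Whitney U, two-sample Kolmogorov-Smirnov D, Kruskal-Wallis with Dunn's
multiple-comparisons post hoc, Bonferroni correction, and the
D'Agostino-Pearson omnibus normality test.  Statistics are reported in the
field's conventional form (W+ = sum of positive ranks; U1 for the first
sample) so printed tables read like standard software output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "wilcoxon_one_sample",
    "mann_whitney",
    "ks_two_sample",
    "kruskal_dunn",
    "bonferroni",
    "dagostino_pearson",
    "results_table",
]

#: largest n at which the Wilcoxon null is enumerated exactly (no ties/zeros)
WILCOXON_EXACT_N = 25
#: largest min(n, m) at which the Mann-Whitney null is enumerated exactly
MW_EXACT_N = 8


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: tuple[int, ...]
    method: str
    correction: str = "none"
    note: str = ""

    def corrected(self, m: int, how: str = "bonferroni") -> "TestResult":
        return TestResult(
            self.statistic,
            min(1.0, m * self.p_value),
            self.n,
            self.method,
            correction=how,
            note=self.note,
        )


def wilcoxon_one_sample(
    xs, mu0: float = 0.5, alternative: str = "two-sided"
) -> TestResult:
    """One-sample Wilcoxon signed-rank test against a theoretical median.

    Zero differences are dropped (Wilcoxon's convention).  The statistic is
    W+, the sum of ranks of positive differences.  The null is enumerated
    exactly for n <= 25 when no |difference| ties exist; otherwise the normal
    approximation with continuity and tie correction is used.
    """
    d = np.asarray(xs, dtype=float) - mu0
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return TestResult(0.0, 1.0, (0,), "wilcoxon", note="all values equal mu0")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    has_ties = np.unique(np.abs(d)).size < n
    method = "exact" if (n <= WILCOXON_EXACT_N and not has_ties) else "approx"
    res = sps.wilcoxon(
        d, alternative=alternative, correction=(method == "approx"), method=method
    )
    return TestResult(w_plus, float(res.pvalue), (n,), f"wilcoxon[{method}]")


def mann_whitney(xs, ys, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U test (exact for min(n, m) <= 8 without ties)."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([xs, ys])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(xs.size, ys.size) <= MW_EXACT_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(xs, ys, alternative=alternative, method=method)
    return TestResult(
        float(res.statistic), float(res.pvalue), (xs.size, ys.size),
        f"mann_whitney[{method}]",
    )


def ks_two_sample(xs, ys) -> TestResult:
    """Two-sample Kolmogorov-Smirnov D with the asymptotic p-value."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.ks_2samp(xs, ys, method="asymp")
    return TestResult(
        float(res.statistic), float(res.pvalue), (xs.size, ys.size), "ks_2samp[asymp]"
    )


def kruskal_dunn(
    groups: dict[str, np.ndarray] | list, alpha: float = 0.05
) -> tuple[TestResult, list[tuple[str, str, TestResult]]]:
    """Kruskal-Wallis H followed by Dunn's pairwise z tests.

    Dunn's z statistics are computed on the pooled mid-ranks with tie
    correction; pairwise p-values are Bonferroni-scaled by the number of
    comparisons.  Pairwise results are returned regardless of the omnibus
    outcome so tables can show them, but should be read only when the
    omnibus rejects.
    """
    if isinstance(groups, dict):
        names = list(groups)
        samples = [np.asarray(groups[k], dtype=float) for k in names]
    else:
        names = [f"group{i}" for i in range(len(groups))]
        samples = [np.asarray(g, dtype=float) for g in groups]
    if len(samples) < 3:
        raise ValueError("need >= 3 groups; use mann_whitney for two")
    if any(s.size == 0 for s in samples):
        raise ValueError("all groups must be nonempty")
    h, p = sps.kruskal(*samples)
    omnibus = TestResult(float(h), float(p), tuple(s.size for s in samples),
                         "kruskal_wallis")
    pooled = np.concatenate(samples)
    ranks = sps.rankdata(pooled)
    N = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (N - 1))
    sizes = [s.size for s in samples]
    mean_ranks = []
    start = 0
    for m in sizes:
        mean_ranks.append(ranks[start:start + m].mean())
        start += m
    pairs = list(itertools.combinations(range(len(samples)), 2))
    m_comp = len(pairs)
    out = []
    for i, j in pairs:
        se = np.sqrt((N * (N + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        praw = 2.0 * sps.norm.sf(abs(z))
        res = TestResult(float(z), min(1.0, m_comp * praw),
                         (sizes[i], sizes[j]), "dunn", correction="dunn")
        out.append((names[i], names[j], res))
    return omnibus, out


def bonferroni(pvals, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p) elementwise."""
    p = np.asarray(pvals, dtype=float)
    m = p.size if m is None else m
    if m < p.size:
        raise ValueError("m must be >= number of p-values")
    return np.minimum(1.0, m * p)


def dagostino_pearson(xs) -> TestResult:
    """D'Agostino-Pearson K^2 omnibus normality test (requires n >= 20)."""
    xs = np.asarray(xs, dtype=float)
    if xs.size < 20:
        raise ValueError("D'Agostino-Pearson approximation invalid for n < 20")
    if np.ptp(xs) == 0:
        raise ValueError("constant sample has no defined skewness/kurtosis")
    k2, p = sps.normaltest(xs)
    return TestResult(float(k2), float(p), (xs.size,), "dagostino_pearson")


def results_table(rows: list[dict]) -> pd.DataFrame:
    """Tidy comparisons table (comparison, n, statistic, p, corrected p)."""
    return pd.DataFrame(
        rows, columns=["comparison", "n", "statistic", "p", "p_corrected", "method"]
    )
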
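"""Shared nonparametric-test wrappers used across analysis stages."""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust", "signed_rank_test", "mann_whitney"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment (q-values)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def signed_rank_test(values, *, exact_max_n: int = 25) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test of symmetry about zero.

    Zeros are discarded before ranking.  The exact null distribution is used
    for n <= ``exact_max_n`` when the |values| are tie-free; otherwise the
    normal approximation with continuity correction.  Returns (W, p).
    """
    x = np.asarray(values, dtype=float)
    x = x[x != 0]
    if x.size == 0:
        raise ValueError("all values are zero: signed-rank test degenerate")
    has_ties = len(np.unique(np.abs(x))) < len(x)
    if x.size <= exact_max_n and not has_ties:
        res = stats.wilcoxon(x, zero_method="wilcox", method="exact")
    else:
        res = stats.wilcoxon(
            x, zero_method="wilcox", method="approx", correction=True
        )
    return float(res.statistic), float(res.pvalue)


def mann_whitney(x, y, *, exact_max_n: int = 25) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; exact for small tie-free samples.

    Returns (U of the first sample, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if max(x.size, y.size) <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
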
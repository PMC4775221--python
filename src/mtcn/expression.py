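"""Gene-expression association with mtDNA copy number.

Per-gene Spearman correlation against copy number (with a low-expression
filter and a p-value zeroing rule to suppress spurious correlations),
followed by a mean-rank gene-set enrichment test: gene sets whose member
statistics rank systematically higher (or lower) than the remaining genes
are called enriched for positive (negative) correlation with mtDNA content.

The mean-rank test is the two-sample Wilcoxon rank-sum normal approximation
of the set against its complement, computed on midranks of the (thresholded)
correlation statistics with a tie-variance correction — massive ties at zero
produced by the thresholding rule are expected and handled by midranks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust

__all__ = [
    "GeneCorrelation",
    "EnrichmentResult",
    "read_gmt",
    "filter_genes",
    "gene_correlations",
    "mean_rank_gene_set_test",
    "gene_set_scan",
    "single_gene_report",
]

logger = logging.getLogger(__name__)

#: Genes whose mean read count falls below this are dropped before
#: correlation (low-expression noise floor).
MEAN_COUNT_FLOOR = 16.0

#: Per-gene correlations with uncorrected p above this are set to zero
#: before ranking (spurious-correlation suppression).
ZEROING_P = 0.05

#: Minimum overlapping RNA samples for the correlation stage.
MIN_SAMPLES = 20


@dataclass
class GeneCorrelation:
    """Spearman correlation of one gene's expression with copy number.

    ``rho_thresholded`` is rho when p <= the zeroing threshold, else 0; the
    thresholded value is what enters the gene-set ranking.
    """

    gene_id: str
    rho: float
    p: float
    rho_thresholded: float
    constant: bool = False  # gene had zero variance; rho recorded as 0


@dataclass
class EnrichmentResult:
    """Directional mean-rank enrichment of one gene set.

    ``enrichment_score`` = −log10(q) signed by direction (+ for enrichment
    of positive correlations, − for negative).
    """

    gene_set_name: str
    n_genes_in_universe: int
    direction: str  # up | down
    p: float
    q: float = math.nan
    enrichment_score: float = math.nan


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file (name <tab> description <tab> genes...).

    Duplicate set names get a numeric suffix, preserving both entries.
    """
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT rows need name, description "
                    "and at least one gene"
                )
            name = parts[0]
            genes = [g for g in parts[2:] if g]
            if name in sets:
                k = 2
                while f"{name}.{k}" in sets:
                    k += 1
                logger.warning(
                    "%s: duplicate gene-set name %r renamed to %r",
                    path, name, f"{name}.{k}",
                )
                name = f"{name}.{k}"
            sets[name] = genes
    return sets


def filter_genes(
    expr: pd.DataFrame, *, mean_floor: float = MEAN_COUNT_FLOOR
) -> pd.DataFrame:
    """Drop genes (rows) with mean expression strictly below ``mean_floor``."""
    if (expr.to_numpy() < 0).any():
        raise ValueError("expression matrix must be non-negative")
    kept = expr[expr.mean(axis=1) >= mean_floor]
    if kept.empty:
        raise ValueError(
            f"no genes left after mean-expression filter (< {mean_floor})"
        )
    return kept


def _spearman_matrix(mat: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Spearman rho and t-distribution p against a vector.

    Matches scipy.stats.spearmanr's p-value (t approximation, n−2 df).
    Constant rows yield rho = nan.
    """
    n = mat.shape[1]
    rv = stats.rankdata(v)
    rm = np.apply_along_axis(stats.rankdata, 1, mat)
    rv_c = rv - rv.mean()
    rm_c = rm - rm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rm_c**2).sum(axis=1) * (rv_c**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rm_c @ rv_c) / denom
        rho = np.clip(rho, -1.0, 1.0)
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(rho), 1.0)] = 0.0
    return rho, p


def gene_correlations(
    expr: pd.DataFrame,
    copy_number: Mapping[str, float],
    *,
    min_samples: int = MIN_SAMPLES,
    zeroing_p: float = ZEROING_P,
) -> list[GeneCorrelation]:
    """Spearman correlation of each gene with copy number.

    ``expr`` is a filtered genes × samples matrix; ``copy_number`` maps
    sample id → (corrected) copy number.  Refuses to run below
    ``min_samples`` overlapping samples.  Correlations with p above
    ``zeroing_p`` are zeroed in ``rho_thresholded``.
    """
    shared = [s for s in expr.columns if s in copy_number]
    if len(shared) < min_samples:
        raise ValueError(
            f"only {len(shared)} samples with both expression and copy "
            f"number; need >= {min_samples}"
        )
    sub = expr[shared]
    cn = np.array([copy_number[s] for s in shared], dtype=float)
    rho, p = _spearman_matrix(sub.to_numpy(dtype=float), cn)

    out: list[GeneCorrelation] = []
    for gene, r_, p_ in zip(sub.index, rho, p):
        if np.isnan(r_):
            out.append(
                GeneCorrelation(
                    gene_id=str(gene), rho=0.0, p=1.0, rho_thresholded=0.0,
                    constant=True,
                )
            )
        else:
            out.append(
                GeneCorrelation(
                    gene_id=str(gene),
                    rho=float(r_),
                    p=float(p_),
                    rho_thresholded=float(r_) if p_ <= zeroing_p else 0.0,
                )
            )
    return out


def mean_rank_gene_set_test(
    statistics: Mapping[str, float],
    gene_set: Iterable[str],
    alternative: str = "up",
) -> float:
    """Mean-rank gene-set test: does the set rank high (or low) in the universe?

    Midranks of all statistics are computed; the set's rank-sum is compared
    with its null expectation under random assignment via the tie-corrected
    normal approximation of the two-sample Wilcoxon rank-sum test (set vs
    complement).  ``alternative="up"`` asks for enrichment of large
    statistics, ``"down"`` for small ones.  One-sided p in (0, 1).
    """
    if alternative not in ("up", "down"):
        raise ValueError("alternative must be 'up' or 'down'")
    genes = list(statistics)
    gs = set(gene_set)
    values = np.array([statistics[g] for g in genes], dtype=float)
    in_set = np.array([g in gs for g in genes])
    n1 = int(in_set.sum())
    N = len(genes)
    if n1 == 0:
        raise ValueError("gene set has no overlap with the statistic universe")
    if n1 == N:
        raise ValueError("gene set covers the entire universe; test undefined")
    n2 = N - n1
    ranks = stats.rankdata(values)
    W = float(ranks[in_set].sum())
    mean_W = n1 * (N + 1) / 2.0
    # Tie-corrected variance of the rank-sum.
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_W = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var_W <= 0:
        return 1.0  # all statistics identical; no information
    z = (W - mean_W) / math.sqrt(var_W)
    if alternative == "up":
        p = stats.norm.sf(z)
    else:
        p = stats.norm.cdf(z)
    return float(min(max(p, np.nextafter(0, 1)), 1.0))


def gene_set_scan(
    correlations: Sequence[GeneCorrelation],
    gene_sets: Mapping[str, Sequence[str]],
    tissue_label: str = "tumor",
) -> list[EnrichmentResult]:
    """Directional enrichment scan over a gene-set collection.

    Ranks the thresholded correlations (zeros included), tests each set in
    both directions, BH-adjusts across all (set, direction) tests of the
    run, and reports the signed −log10(q) enrichment score.  Sets without
    overlap are skipped with a log message.  Results are per tissue run
    (``tissue_label`` is carried through to output only).
    """
    statistics = {c.gene_id: c.rho_thresholded for c in correlations}
    universe = set(statistics)
    results: list[EnrichmentResult] = []
    for name in gene_sets:
        members = set(gene_sets[name]) & universe
        if not members:
            logger.info("gene set %r: no overlap with universe; skipped", name)
            continue
        if members == universe:
            logger.info("gene set %r covers the whole universe; skipped", name)
            continue
        for direction in ("up", "down"):
            p = mean_rank_gene_set_test(statistics, members, direction)
            results.append(
                EnrichmentResult(
                    gene_set_name=name,
                    n_genes_in_universe=len(members),
                    direction=direction,
                    p=p,
                )
            )
    if results:
        qs = bh_adjust([r.p for r in results])
        for r, q in zip(results, qs):
            r.q = float(q)
            score = -math.log10(max(r.q, 1e-300))
            r.enrichment_score = score if r.direction == "up" else -score
    return results


def single_gene_report(
    correlations: Sequence[GeneCorrelation], gene_id: str
) -> tuple[float, float] | None:
    """Unthresholded (rho, p) for one gene, or None if it was filtered out."""
    for c in correlations:
        if c.gene_id == gene_id:
            return c.rho, c.p
    return None
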
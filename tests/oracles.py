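"""Independent oracles used by the test suite.

Each function recomputes a quantity by brute force (enumeration, raw flag
arithmetic, permutation) without going through the library code paths it
checks.
"""

from __future__ import annotations

import itertools
import re

import numpy as np
import pysam
from scipy.stats import rankdata

FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAP = 0x4
FLAG_SECONDARY = 0x100
FLAG_QCFAIL = 0x200
FLAG_DUP = 0x400
FLAG_SUPP = 0x800


def brute_force_bam_counts(
    path,
    mapq_threshold=30,
    mt_names=("MT", "chrM", "chrMT", "M"),
    nonprimary_regex=r"^(GL\d|NC_|hs37d5|chrUn|HLA-|EBV)|_(random|alt|decoy|fix|hap\d*)$",
):
    """Record-by-record filter using raw SAM flag bits only."""
    nonprimary = re.compile(nonprimary_regex)
    counts = {}
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for read in bam.fetch(until_eof=True):
            f = read.flag
            if f & (FLAG_UNMAP | FLAG_SECONDARY | FLAG_SUPP | FLAG_QCFAIL | FLAG_DUP):
                continue
            if not f & FLAG_PROPER:
                continue
            if read.mapping_quality <= mapq_threshold:
                continue
            name = read.reference_name
            if nonprimary.search(name):
                continue
            counts[name] = counts.get(name, 0) + 1
    rm = sum(v for k, v in counts.items() if k in set(mt_names))
    rn = sum(v for k, v in counts.items() if k not in set(mt_names))
    return counts, rm, rn


def exact_mannwhitney_p(x, y):
    """Two-sided Mann-Whitney p by full enumeration (group sizes <= 12)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1, N = len(x), len(pooled)
    ranks = rankdata(pooled)
    obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = np.array(
        [
            ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
            for comb in itertools.combinations(range(N), n1)
        ]
    )
    return min(1.0, 2 * min((us <= obs).mean(), (us >= obs).mean()))


def exact_signed_rank_p(r):
    """Two-sided Wilcoxon signed-rank p by sign enumeration (n <= 14)."""
    r = np.asarray(r, float)
    r = r[r != 0]
    n = len(r)
    ranks = rankdata(np.abs(r))
    obs = ranks[r > 0].sum()
    ws = np.array(
        [
            sum(rk for rk, s in zip(ranks, signs) if s)
            for signs in itertools.product([0, 1], repeat=n)
        ]
    )
    return min(1.0, 2 * min((ws <= obs).mean(), (ws >= obs).mean()))


def permutation_mean_rank_p(statistics, gene_set, alternative, n_perm, seed):
    """Monte-Carlo permutation estimate of the mean-rank gene-set null.

    Draws random same-size sets from the universe and compares their
    rank-sum with the observed one; add-one estimator.
    """
    genes = list(statistics)
    values = np.array([statistics[g] for g in genes], float)
    ranks = rankdata(values)
    gs = set(gene_set)
    idx = np.array([g in gs for g in genes])
    n1 = int(idx.sum())
    obs = ranks[idx].sum()
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.choice(len(genes), size=n1, replace=False)
        w = ranks[perm].sum()
        if alternative == "up" and w >= obs:
            count += 1
        elif alternative == "down" and w <= obs:
            count += 1
    return (count + 1) / (n_perm + 1)


def two_group_lsq_delta(y1, y2):
    """Closed-form two-group least squares: difference of group means."""
    return float(np.mean(y2) - np.mean(y1))
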
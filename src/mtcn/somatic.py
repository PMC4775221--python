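"""Association of somatic alterations with tumor mtDNA copy number.

Carriers of a lesion (a recurrently mutated gene, a focal/arm-level copy
number alteration, a subtype label, or an mtDNA variant class) are compared
with non-carriers by a two-sided Mann-Whitney U test on corrected tumor
copy number, with Benjamini-Hochberg adjustment within each alteration
family and post-hoc direction from the carrier/non-carrier median
difference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._stats import bh_adjust, mann_whitney

__all__ = [
    "AlterationCall",
    "AssociationResult",
    "CODING_CLASSES",
    "build_mutation_calls",
    "read_cna_calls",
    "association_scan",
    "group_compare",
]

logger = logging.getLogger(__name__)

#: MAF variant classes counted as nonsynonymous coding mutations.
CODING_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
    }
)

#: Recognized non-coding / silent classes; anything else is logged once and
#: treated as non-coding.
KNOWN_NONCODING = frozenset(
    {
        "Silent",
        "3'UTR",
        "5'UTR",
        "3'Flank",
        "5'Flank",
        "Intron",
        "IGR",
        "RNA",
        "Nonstop_Mutation",
        "Translation_Start_Site",
        "lincRNA",
    }
)


@dataclass
class AlterationCall:
    """One testable lesion and the set of samples carrying it."""

    alteration_id: str
    kind: str  # mutation | cna | subtype_label | mtdna_variant_class
    carriers: frozenset[str]
    untestable: bool = False


@dataclass
class AssociationResult:
    """Mann-Whitney carrier vs non-carrier comparison for one alteration."""

    alteration_id: str
    kind: str
    n_carriers: int
    n_noncarriers: int
    u_statistic: float
    p: float
    q: float = math.nan
    direction: str = "none"  # increases | decreases | none
    untestable: bool = False


def build_mutation_calls(
    maf: pd.DataFrame,
    *,
    hypermutator_cutoff: int = 600,
    min_freq: float = 0.04,
) -> list[AlterationCall]:
    """Derive per-gene mutation carrier sets from a MAF-like table.

    Only nonsynonymous coding classes count (missense, nonsense, frameshift,
    in-frame indel, splice site).  Samples with more than
    ``hypermutator_cutoff`` nonsynonymous coding mutations are removed before
    any counting; genes mutated in at most ``min_freq`` of the remaining
    patients are dropped (strictly-greater-than retention).  The frequency
    denominator is the number of patients with any mutation data after the
    hypermutator exclusion.
    """
    required = {"Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"}
    missing = required - set(maf.columns)
    if missing:
        raise ValueError(f"MAF table missing column(s) {sorted(missing)}")

    unknown = (
        set(maf["Variant_Classification"].unique())
        - CODING_CLASSES
        - KNOWN_NONCODING
    )
    if unknown:
        logger.warning(
            "unknown Variant_Classification value(s) treated as non-coding: %s",
            sorted(unknown),
        )

    coding = maf[maf["Variant_Classification"].isin(CODING_CLASSES)]
    per_sample = coding.groupby("Tumor_Sample_Barcode").size()
    hypermutators = set(per_sample[per_sample > hypermutator_cutoff].index)
    if hypermutators:
        logger.info(
            "excluding %d hypermutated sample(s) (> %d coding mutations)",
            len(hypermutators),
            hypermutator_cutoff,
        )

    kept_samples = set(maf["Tumor_Sample_Barcode"].unique()) - hypermutators
    denominator = len(kept_samples)
    if denominator == 0:
        return []
    coding = coding[~coding["Tumor_Sample_Barcode"].isin(hypermutators)]

    calls: list[AlterationCall] = []
    for gene, grp in coding.groupby("Hugo_Symbol", sort=True):
        carriers = frozenset(grp["Tumor_Sample_Barcode"].unique())
        if len(carriers) / denominator > min_freq:
            calls.append(
                AlterationCall(
                    alteration_id=f"{gene}_mutation",
                    kind="mutation",
                    carriers=carriers,
                )
            )
    return calls


def read_cna_calls(matrix: pd.DataFrame) -> list[AlterationCall]:
    """Binary alteration × sample matrix (index = alteration_id) → calls.

    Entries must be exactly 0 or 1; an empty carrier row is kept but flagged
    untestable.
    """
    vals = matrix.to_numpy()
    bad = ~np.isin(vals, [0, 1])
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"CNA matrix entry at alteration {matrix.index[i]!r}, sample "
            f"{matrix.columns[j]!r} is {vals[i, j]!r}; must be 0 or 1"
        )
    if matrix.index.duplicated().any():
        raise ValueError("duplicate alteration_id rows in CNA matrix")
    calls = []
    for alt_id, row in matrix.iterrows():
        carriers = frozenset(matrix.columns[row.astype(bool)])
        calls.append(
            AlterationCall(
                alteration_id=str(alt_id),
                kind="cna",
                carriers=carriers,
                untestable=len(carriers) == 0,
            )
        )
    return calls


def association_scan(
    calls: Sequence[AlterationCall],
    copy_number: Mapping[str, float],
    *,
    strata: Mapping[str, str] | None = None,
    alpha: float = 0.05,
) -> list[AssociationResult]:
    """Mann-Whitney U scan of alterations against tumor copy number.

    ``copy_number`` maps tumor sample id → corrected copy number.  When
    ``strata`` is given (sample → stratum label), testing is restricted to
    within-stratum comparisons by subtracting each stratum's median before
    pooling — a guard against subtype confounding.  BH runs across all
    testable calls in this scan; callers wanting separate families (e.g.
    mutations vs CNAs) scan each family separately.
    """
    values = dict(copy_number)
    if strata:
        df = pd.DataFrame(
            {"v": list(values.values())},
            index=list(values.keys()),
        )
        df["stratum"] = [strata.get(s, "_unstratified") for s in df.index]
        centered = df.groupby("stratum")["v"].transform(lambda s: s - s.median())
        values = dict(zip(df.index, centered))

    results: list[AssociationResult] = []
    for call in calls:
        carriers = [values[s] for s in call.carriers if s in values]
        noncarr = [values[s] for s in values if s not in call.carriers]
        res = AssociationResult(
            alteration_id=call.alteration_id,
            kind=call.kind,
            n_carriers=len(carriers),
            n_noncarriers=len(noncarr),
            u_statistic=math.nan,
            p=math.nan,
        )
        if call.untestable or not carriers or not noncarr:
            res.untestable = True
        else:
            res.u_statistic, res.p = mann_whitney(carriers, noncarr)
        results.append(res)

    tested = [r for r in results if not r.untestable]
    if tested:
        qs = bh_adjust([r.p for r in tested])
        lookup = {
            r.alteration_id: call
            for r, call in zip(results, calls)
        }
        for r, q in zip(tested, qs):
            r.q = float(q)
            call = lookup[r.alteration_id]
            med_c = float(np.median([values[s] for s in call.carriers if s in values]))
            med_n = float(
                np.median([values[s] for s in values if s not in call.carriers])
            )
            if r.q < alpha:
                r.direction = "increases" if med_c > med_n else "decreases"
    return results


def group_compare(
    copy_number: Mapping[str, float],
    group_labels: Mapping[str, str],
    group_a: str,
    group_b: str,
) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney comparison of copy number between two labelled
    groups (e.g. a subtype vs the rest, or mtDNA-indel vs unmutated samples).

    Returns (U, p, direction) where direction says whether ``group_a`` has
    higher or lower median copy number than ``group_b``.
    """
    a = [v for s, v in copy_number.items() if group_labels.get(s) == group_a]
    b = [v for s, v in copy_number.items() if group_labels.get(s) == group_b]
    if not a or not b:
        raise ValueError(
            f"both groups must be non-empty (got {len(a)} vs {len(b)})"
        )
    u, p = mann_whitney(a, b)
    direction = "higher" if np.median(a) > np.median(b) else "lower"
    return u, p, direction
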
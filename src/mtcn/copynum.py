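"""Relative mtDNA copy number from read-count ratios.

The estimator is the ratio of mitochondrial to nuclear read counts scaled by
an "effective ploidy" correction:

    m = rm / rn × R,      R_tumor = (purity·ploidy + (1 − purity)·2) / 2

For normal tissue and blood the nuclear genome is assumed diploid and R = 1.
A tumor sample is a purity-weighted mixture of tumor cells (average nuclear
copy number = ploidy) and normal infiltrate (diploid); dividing the nuclear
read count by the mixture's average nuclear copy number relative to diploid
removes the depression/inflation of rn caused by aneuploidy and impurity.

m is a *relative*, platform-dependent quantity (exome capture picks up mtDNA
incidentally, whole-genome sequencing uniformly); it is never converted to
copies per cell and raw values are never compared across platforms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .io import PurityPloidy, ReadCountRecord, SampleMeta

__all__ = [
    "CopyNumberEstimate",
    "compute_correction_factor",
    "estimate_copy_number",
    "estimate_cohort",
]

logger = logging.getLogger(__name__)


@dataclass
class CopyNumberEstimate:
    """Raw and (optionally) batch-corrected relative mtDNA copy number.

    ``flagged`` marks degenerate records (rm == 0, capture failure) that are
    excluded from every log-scale analysis.  ``log10_m_corrected`` is filled
    by the batch-effect module.
    """

    sample_id: str
    rm: int
    rn: int
    R: float
    m_raw: float
    m: float
    log10_m: float  # nan when flagged
    log10_m_corrected: float | None = None
    flagged: bool = False

    @property
    def log10_m_best(self) -> float:
        """Corrected value when available, raw otherwise."""
        if self.log10_m_corrected is not None:
            return self.log10_m_corrected
        return self.log10_m


def compute_correction_factor(
    sample_type: str,
    purity: float | None = None,
    ploidy: float | None = None,
    *,
    missing_policy: str = "error",
) -> float:
    """Effective-ploidy correction factor R.

    Tumor samples: R = (purity·ploidy + (1 − purity)·2) / 2, so a sample of
    pure normal tissue (purity 0) gives R = 1 regardless of ploidy.
    Normal tissue and blood: R = 1 (diploid assumption).

    ``missing_policy`` governs tumor samples without purity/ploidy estimates:
    ``"error"`` raises, ``"fallback"`` returns R = 1 with a logged warning.
    """
    if sample_type in ("normal_tissue", "blood"):
        return 1.0
    if sample_type != "tumor":
        raise ValueError(f"unknown sample_type {sample_type!r}")
    if purity is None or ploidy is None:
        if missing_policy == "fallback":
            logger.warning(
                "tumor sample without purity/ploidy: falling back to R=1"
            )
            return 1.0
        raise ValueError(
            "tumor sample requires purity and ploidy "
            "(or missing_policy='fallback')"
        )
    if not 0.0 <= purity <= 1.0:
        raise ValueError(f"purity must be in [0, 1], got {purity}")
    if ploidy <= 0:
        raise ValueError(f"ploidy must be positive, got {ploidy}")
    return (purity * ploidy + (1.0 - purity) * 2.0) / 2.0


def estimate_copy_number(rec: ReadCountRecord, R: float) -> CopyNumberEstimate:
    """Relative copy number m = (rm/rn)·R for one sample.

    rn must be positive.  rm == 0 yields m = 0 with the record flagged
    (capture failure, not biology) and log10_m = nan.
    """
    if rec.rn <= 0:
        raise ValueError(f"sample {rec.sample_id!r}: rn must be positive")
    if R <= 0:
        raise ValueError(f"sample {rec.sample_id!r}: R must be positive")
    m_raw = rec.rm / rec.rn
    m = m_raw * R
    flagged = rec.rm == 0
    log10_m = math.log10(m) if not flagged else math.nan
    return CopyNumberEstimate(
        sample_id=rec.sample_id,
        rm=rec.rm,
        rn=rec.rn,
        R=R,
        m_raw=m_raw,
        m=m,
        log10_m=log10_m,
        flagged=flagged,
    )


def estimate_cohort(
    records: Iterable[ReadCountRecord],
    meta: Iterable[SampleMeta],
    purity: Iterable[PurityPloidy] = (),
    *,
    missing_policy: str = "error",
) -> list[CopyNumberEstimate]:
    """Estimate copy number for every sample with metadata.

    Tumor samples take their correction factor from the purity/ploidy table;
    samples without metadata are skipped with a warning.
    """
    meta_map: Mapping[str, SampleMeta] = {m.sample_id: m for m in meta}
    pp_map: Mapping[str, PurityPloidy] = {p.sample_id: p for p in purity}
    out: list[CopyNumberEstimate] = []
    for rec in records:
        sm = meta_map.get(rec.sample_id)
        if sm is None:
            logger.warning("no metadata for sample %s; skipped", rec.sample_id)
            continue
        pp = pp_map.get(rec.sample_id)
        R = compute_correction_factor(
            sm.sample_type,
            purity=pp.purity if pp else None,
            ploidy=pp.ploidy if pp else None,
            missing_policy=missing_policy,
        )
        out.append(estimate_copy_number(rec, R))
    return out
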
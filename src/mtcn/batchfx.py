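"""Plate batch-effect model for log10 mtDNA copy number.

Sequencing batches (plates) shift the observed mtDNA read fraction
multiplicatively — additively on the log10 scale.  Per cancer type we fit the
two-factor fixed-effects model

    M_ijk = mu + alpha_i + beta_j + eps_ijk

where M is log10 copy number, i indexes the plate, j the tissue class
(tissue-derived = tumor or adjacent normal, vs blood) and k the sample.  The
model is over-parameterized; we identify it with sample-size-weighted
sum-to-zero constraints on alpha and beta so that subtracting alpha leaves
the cohort mean unchanged.  Any full-rank coding yields identical corrected
*differences* between samples.

Correction subtracts the fitted plate effect from each exome (WXS) sample's
log10 copy number; the tissue effect is biology and is never subtracted.
Whole-genome (WGS) samples pass through uncorrected: the batch effect there
is small and exome capture is the dominant source of plate-level variation
in mitochondrial yield.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .copynum import CopyNumberEstimate
from .io import SampleMeta

__all__ = [
    "BatchModelFit",
    "PlateDiagnostics",
    "tissue_class",
    "fit_batch_model",
    "correct_copy_number",
    "batch_correct",
    "batch_diagnostics",
]

logger = logging.getLogger(__name__)


def tissue_class(sample_type: str) -> str:
    """Collapse sample types into the model's two tissue classes."""
    return "blood" if sample_type == "blood" else "tissue"


@dataclass
class BatchModelFit:
    """Least-squares fit of the plate/tissue model for one cancer type.

    alpha and beta are reported under the sample-size-weighted sum-to-zero
    constraint.  ``low_confidence_plates`` lists plates estimated from a
    single sample; ``beta_dropped`` is set when plate and tissue are
    perfectly confounded and the tissue term had to be removed.
    """

    cancer_type: str
    mu: float
    alpha: dict[str, float]
    beta: dict[str, float]
    residuals: dict[str, float]
    constraint: str = "weighted-sum-to-zero"
    low_confidence_plates: list[str] = field(default_factory=list)
    beta_dropped: bool = False
    n_samples: int = 0


def _usable(estimates: Iterable[CopyNumberEstimate]) -> list[CopyNumberEstimate]:
    return [e for e in estimates if not e.flagged and math.isfinite(e.log10_m)]


def fit_batch_model(
    estimates: Sequence[CopyNumberEstimate],
    meta: Sequence[SampleMeta],
    *,
    cancer_type: str | None = None,
) -> BatchModelFit:
    """Fit mu + plate + tissue effects to log10 copy number by least squares.

    Flagged (rm == 0) estimates are excluded.  With a single plate the plate
    effect is identically zero and mu reduces to the (tissue-adjusted) mean.
    Perfect plate/tissue confounding drops the tissue term with a warning.
    """
    meta_map = {m.sample_id: m for m in meta}
    usable = [e for e in _usable(estimates) if e.sample_id in meta_map]
    if not usable:
        raise ValueError("no usable (unflagged, with-metadata) estimates to fit")
    if cancer_type is None:
        cts = {meta_map[e.sample_id].cancer_type for e in usable}
        if len(cts) > 1:
            raise ValueError(
                "estimates span multiple cancer types; fit each separately "
                f"(got {sorted(cts)})"
            )
        cancer_type = cts.pop()

    y = np.array([e.log10_m for e in usable])
    plates = pd.Categorical([meta_map[e.sample_id].plate_id for e in usable])
    tissues = pd.Categorical(
        [tissue_class(meta_map[e.sample_id].sample_type) for e in usable]
    )
    n = len(y)

    plate_levels = list(plates.categories)
    tissue_levels = list(tissues.categories)

    # Treatment-coded design (first level is reference); refit without the
    # tissue block if it makes the design rank-deficient (confounding).
    def design(include_tissue: bool) -> np.ndarray:
        cols = [np.ones(n)]
        for lv in plate_levels[1:]:
            cols.append((plates == lv).astype(float))
        if include_tissue:
            for lv in tissue_levels[1:]:
                cols.append((tissues == lv).astype(float))
        return np.column_stack(cols)

    beta_dropped = False
    X = design(include_tissue=len(tissue_levels) > 1)
    if len(tissue_levels) > 1 and np.linalg.matrix_rank(X) < X.shape[1]:
        logger.warning(
            "%s: plate and tissue perfectly confounded; dropping tissue term",
            cancer_type,
        )
        beta_dropped = True
        X = design(include_tissue=False)

    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    resid = y - fitted

    # Treatment-coded effects -> weighted sum-to-zero parameterization.
    a_raw = {plate_levels[0]: 0.0}
    for j, lv in enumerate(plate_levels[1:], start=1):
        a_raw[lv] = float(coef[j])
    plate_n = pd.Series(plates).value_counts()
    a_bar = sum(a_raw[lv] * plate_n[lv] for lv in plate_levels) / n
    alpha = {lv: a_raw[lv] - a_bar for lv in plate_levels}

    if beta_dropped or len(tissue_levels) <= 1:
        beta = {lv: 0.0 for lv in tissue_levels}
        b_bar = 0.0
    else:
        b_raw = {tissue_levels[0]: 0.0}
        off = len(plate_levels)  # 1 intercept + P-1 plate columns
        for j, lv in enumerate(tissue_levels[1:]):
            b_raw[lv] = float(coef[off + j])
        tissue_n = pd.Series(tissues).value_counts()
        b_bar = sum(b_raw[lv] * tissue_n[lv] for lv in tissue_levels) / n
        beta = {lv: b_raw[lv] - b_bar for lv in tissue_levels}

    mu = float(coef[0] + a_bar + b_bar)
    low_conf = [lv for lv in plate_levels if plate_n[lv] == 1]
    if low_conf:
        logger.warning(
            "%s: plate effect(s) estimated from a single sample: %s",
            cancer_type,
            low_conf,
        )

    return BatchModelFit(
        cancer_type=cancer_type,
        mu=mu,
        alpha=alpha,
        beta=beta,
        residuals={e.sample_id: float(r) for e, r in zip(usable, resid)},
        low_confidence_plates=low_conf,
        beta_dropped=beta_dropped,
        n_samples=n,
    )


def correct_copy_number(
    fit: BatchModelFit,
    estimates: Sequence[CopyNumberEstimate],
    meta: Sequence[SampleMeta],
) -> list[CopyNumberEstimate]:
    """Fill ``log10_m_corrected`` = log10_m − alpha(plate) for WXS samples.

    WGS samples pass through with corrected == raw.  The tissue effect is not
    subtracted.  Estimates are modified in place and returned.
    """
    meta_map = {m.sample_id: m for m in meta}
    for e in estimates:
        sm = meta_map.get(e.sample_id)
        if sm is None:
            raise ValueError(f"no metadata for sample {e.sample_id!r}")
        if e.flagged:
            e.log10_m_corrected = None
            continue
        if sm.platform == "WGS":
            e.log10_m_corrected = e.log10_m
            continue
        if sm.plate_id not in fit.alpha:
            raise ValueError(
                f"sample {e.sample_id!r}: plate {sm.plate_id!r} absent from fit"
            )
        e.log10_m_corrected = e.log10_m - fit.alpha[sm.plate_id]
    return list(estimates)


def batch_correct(
    estimates: Sequence[CopyNumberEstimate],
    meta: Sequence[SampleMeta],
) -> tuple[list[CopyNumberEstimate], dict[str, BatchModelFit]]:
    """Per-cancer-type fit on WXS samples, then plate correction.

    Returns the corrected estimates and the per-cancer-type fits.  Cancer
    types with no usable WXS samples are passed through uncorrected.
    """
    meta_map = {m.sample_id: m for m in meta}
    by_ct: dict[str, list[CopyNumberEstimate]] = {}
    for e in estimates:
        sm = meta_map.get(e.sample_id)
        if sm is None:
            continue
        by_ct.setdefault(sm.cancer_type, []).append(e)

    fits: dict[str, BatchModelFit] = {}
    for ct, ests in sorted(by_ct.items()):
        wxs = [
            e
            for e in _usable(ests)
            if meta_map[e.sample_id].platform == "WXS"
        ]
        if not wxs:
            for e in ests:
                e.log10_m_corrected = None if e.flagged else e.log10_m
            continue
        fit = fit_batch_model(wxs, meta, cancer_type=ct)
        fits[ct] = fit
        correct_copy_number(fit, ests, meta)
    return list(estimates), fits


@dataclass
class PlateDiagnostics:
    """Batch-effect diagnostics for one cancer type.

    Kruskal-Wallis tests ask whether plates differ in median log10 copy
    number (blood and tissue-derived samples separately); the Pearson
    correlation between per-plate blood and tissue means detects a shared
    plate-level contribution.  Fields are None when the data do not meet the
    minimum plate/sample counts.
    """

    cancer_type: str
    kw_p_blood: float | None
    kw_p_tissue: float | None
    plate_mean_r: float | None
    plate_mean_p: float | None
    n_plates_tested: int
    notes: list[str] = field(default_factory=list)


def batch_diagnostics(
    estimates: Sequence[CopyNumberEstimate],
    meta: Sequence[SampleMeta],
    *,
    min_plates: int = 3,
    min_per_plate: int = 3,
    use_corrected: bool = False,
) -> list[PlateDiagnostics]:
    """Plate-level batch diagnostics per cancer type.

    The plate-mean correlation uses only plates with at least
    ``min_per_plate`` blood and ``min_per_plate`` tissue samples and requires
    at least ``min_plates`` such plates.
    """
    meta_map = {m.sample_id: m for m in meta}
    rows = []
    for e in _usable(estimates):
        sm = meta_map.get(e.sample_id)
        if sm is None:
            continue
        value = e.log10_m_best if use_corrected else e.log10_m
        if value is None or not math.isfinite(value):
            continue
        rows.append(
            {
                "cancer_type": sm.cancer_type,
                "plate": sm.plate_id,
                "tclass": tissue_class(sm.sample_type),
                "value": value,
            }
        )
    df = pd.DataFrame(rows)
    out: list[PlateDiagnostics] = []
    if df.empty:
        return out

    for ct, g in df.groupby("cancer_type", sort=True):
        notes: list[str] = []

        def kw_p(sub: pd.DataFrame) -> float | None:
            groups = [
                grp["value"].to_numpy()
                for _, grp in sub.groupby("plate")
                if len(grp) > 0
            ]
            groups = [x for x in groups if len(x) > 0]
            if len(groups) < 2:
                return None
            if np.ptp(np.concatenate(groups)) == 0:
                return None  # all values identical; test degenerate
            return float(stats.kruskal(*groups).pvalue)

        kw_blood = kw_p(g[g.tclass == "blood"])
        kw_tissue = kw_p(g[g.tclass == "tissue"])
        if kw_blood is None:
            notes.append("Kruskal-Wallis (blood) not applicable: <2 plates")
        if kw_tissue is None:
            notes.append("Kruskal-Wallis (tissue) not applicable: <2 plates")

        piv = g.pivot_table(
            index="plate",
            columns="tclass",
            values="value",
            aggfunc=["mean", "count"],
        )
        r = p = None
        n_plates = 0
        if ("mean", "blood") in piv.columns and ("mean", "tissue") in piv.columns:
            ok = (piv[("count", "blood")] >= min_per_plate) & (
                piv[("count", "tissue")] >= min_per_plate
            )
            sub = piv[ok]
            n_plates = len(sub)
            if n_plates >= min_plates:
                mb = sub[("mean", "blood")].to_numpy()
                mt = sub[("mean", "tissue")].to_numpy()
                if np.ptp(mb) > 0 and np.ptp(mt) > 0:
                    r_, p_ = stats.pearsonr(mb, mt)
                    r, p = float(r_), float(p_)
                else:
                    notes.append("plate-mean correlation undefined: constant means")
            else:
                notes.append(
                    f"plate-mean correlation skipped: {n_plates} qualifying "
                    f"plate(s) < {min_plates}"
                )
        else:
            notes.append("plate-mean correlation skipped: missing tissue class")

        out.append(
            PlateDiagnostics(
                cancer_type=str(ct),
                kw_p_blood=kw_blood,
                kw_p_tissue=kw_tissue,
                plate_mean_r=r,
                plate_mean_p=p,
                n_plates_tested=n_plates,
                notes=notes,
            )
        )
    return out
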
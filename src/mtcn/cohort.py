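"""Cohort-level statistics on mtDNA copy number.

Paired tumor/adjacent-normal depletion testing, cross-platform concordance,
covariate correlation, and univariate Cox survival association.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from ._stats import bh_adjust, signed_rank_test
from .copynum import CopyNumberEstimate
from .io import SampleMeta

__all__ = [
    "PairedRatio",
    "DepletionTestResult",
    "ConcordanceResult",
    "SurvivalResult",
    "build_pairs",
    "depletion_test",
    "platform_concordance",
    "correlate_covariate",
    "cox_survival",
    "read_survival_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairedRatio:
    """Tumor vs matched adjacent-normal copy number for one patient.

    r = log2(mT / mN); negative r means the tumor holds less mtDNA than the
    matched normal tissue.
    """

    patient_id: str
    cancer_type: str
    tumor_sample_id: str
    normal_sample_id: str
    mT: float
    mN: float
    r: float


@dataclass
class DepletionTestResult:
    """Signed-rank test of paired log2 ratios against zero for one cancer type."""

    cancer_type: str
    n_pairs: int
    statistic: float
    p: float
    q: float = math.nan
    direction: str = "none"  # depleted | accumulated | none
    median_r: float = math.nan
    frac_depleted: float = math.nan
    untestable: bool = False


@dataclass
class ConcordanceResult:
    """Spearman concordance of copy-number estimates across two platforms."""

    cancer_type: str
    n: int
    rho: float
    p: float


@dataclass
class SurvivalResult:
    """Univariate Cox PH association of log10 copy number with overall survival."""

    cancer_type: str
    n: int
    n_events: int
    coefficient: float
    hazard_ratio: float
    wald_p: float
    unestimable: bool = False
    # Median-split summary, for plotting only; inference uses the
    # continuous covariate.
    median_split: dict = field(default_factory=dict)


def _best_m(e: CopyNumberEstimate) -> float | None:
    """Copy number on the linear scale, batch-corrected when available."""
    if e.flagged:
        return None
    v = e.log10_m_best
    if v is None or not math.isfinite(v):
        return None
    return 10.0 ** v


def build_pairs(
    estimates: Sequence[CopyNumberEstimate],
    meta: Sequence[SampleMeta],
) -> list[PairedRatio]:
    """Pair each patient's tumor with adjacent normal tissue.

    Pair members must share patient, sequencing center and plate; blood is
    never used as the normal member.  When several (tumor, normal) candidate
    pairs exist for a patient, the lexicographically smallest
    (tumor_sample_id, normal_sample_id) pair is taken deterministically.
    """
    meta_map = {m.sample_id: m for m in meta}
    by_patient: dict[tuple[str, str], dict[str, list]] = {}
    for e in estimates:
        sm = meta_map.get(e.sample_id)
        if sm is None or sm.sample_type not in ("tumor", "normal_tissue"):
            continue
        m = _best_m(e)
        if m is None or m <= 0:
            continue
        key = (sm.patient_id, sm.cancer_type)
        slot = by_patient.setdefault(key, {"tumor": [], "normal_tissue": []})
        slot[sm.sample_type].append((e.sample_id, m, sm))

    pairs: list[PairedRatio] = []
    for (patient, ct), slot in sorted(by_patient.items()):
        candidates = []
        for tid, mt, smt in slot["tumor"]:
            for nid, mn, smn in slot["normal_tissue"]:
                if smt.center == smn.center and smt.plate_id == smn.plate_id:
                    candidates.append((tid, nid, mt, mn))
        if not candidates:
            continue
        if len(candidates) > 1:
            logger.info(
                "patient %s: %d candidate tumor/normal pairs; using "
                "lexicographically smallest",
                patient,
                len(candidates),
            )
        tid, nid, mt, mn = min(candidates, key=lambda c: (c[0], c[1]))
        pairs.append(
            PairedRatio(
                patient_id=patient,
                cancer_type=ct,
                tumor_sample_id=tid,
                normal_sample_id=nid,
                mT=mt,
                mN=mn,
                r=math.log2(mt / mn),
            )
        )
    return pairs


def depletion_test(
    pairs: Sequence[PairedRatio],
    *,
    min_pairs: int = 10,
    alpha: float = 0.05,
) -> list[DepletionTestResult]:
    """Per-cancer-type Wilcoxon signed-rank test of log2 tumor/normal ratios.

    Cancer types with fewer than ``min_pairs`` pairs are omitted.  BH
    adjustment runs across the tested cancer types; direction is called from
    the median ratio only when q < ``alpha``.
    """
    by_ct: dict[str, list[PairedRatio]] = {}
    for p in pairs:
        by_ct.setdefault(p.cancer_type, []).append(p)

    results: list[DepletionTestResult] = []
    for ct in sorted(by_ct):
        grp = by_ct[ct]
        if len(grp) < min_pairs:
            logger.info(
                "%s: %d pairs < %d required; skipped", ct, len(grp), min_pairs
            )
            continue
        r = np.array([p.r for p in grp])
        res = DepletionTestResult(
            cancer_type=ct,
            n_pairs=len(grp),
            statistic=math.nan,
            p=math.nan,
            median_r=float(np.median(r)),
            frac_depleted=float(np.mean(r < 0)),
        )
        if np.all(r == 0):
            res.untestable = True
        else:
            res.statistic, res.p = signed_rank_test(r)
        results.append(res)

    tested = [res for res in results if not res.untestable]
    if tested:
        qs = bh_adjust([res.p for res in tested])
        for res, q in zip(tested, qs):
            res.q = float(q)
            if res.q < alpha:
                res.direction = "depleted" if res.median_r < 0 else "accumulated"
    return results


def platform_concordance(
    estimates_wxs: Sequence[CopyNumberEstimate],
    estimates_wgs: Sequence[CopyNumberEstimate],
    meta: Sequence[SampleMeta],
    *,
    min_samples: int = 3,
) -> list[ConcordanceResult]:
    """Spearman correlation of WXS vs WGS copy number per cancer type.

    Estimates from the two platforms are matched on (patient_id,
    sample_type).  Cancer types with fewer than ``min_samples`` matched
    samples are skipped.
    """
    meta_map = {m.sample_id: m for m in meta}

    def keyed(ests: Sequence[CopyNumberEstimate]) -> dict:
        out = {}
        for e in ests:
            sm = meta_map.get(e.sample_id)
            m = _best_m(e)
            if sm is None or m is None:
                continue
            out[(sm.cancer_type, sm.patient_id, sm.sample_type)] = m
        return out

    wxs = keyed(estimates_wxs)
    wgs = keyed(estimates_wgs)
    shared = sorted(set(wxs) & set(wgs))
    by_ct: dict[str, list[tuple[float, float]]] = {}
    for key in shared:
        by_ct.setdefault(key[0], []).append((wxs[key], wgs[key]))

    results = []
    for ct in sorted(by_ct):
        vals = by_ct[ct]
        if len(vals) < min_samples:
            logger.info("%s: %d overlapping samples < %d; skipped", ct, len(vals), min_samples)
            continue
        x, y = zip(*vals)
        rho, p = stats.spearmanr(x, y)
        results.append(
            ConcordanceResult(cancer_type=ct, n=len(vals), rho=float(rho), p=float(p))
        )
    return results


def correlate_covariate(
    values: Mapping[str, float],
    covariate: Mapping[str, float],
    *,
    min_samples: int = 3,
) -> tuple[float, float, int]:
    """Spearman correlation between copy number (or paired log ratios) and a
    per-sample covariate.

    Returns (rho, uncorrected p, n overlapping samples).  The covariate must
    not be constant over the overlap.
    """
    shared = sorted(set(values) & set(covariate))
    if len(shared) < min_samples:
        raise ValueError(
            f"only {len(shared)} overlapping samples; need >= {min_samples}"
        )
    x = np.array([values[s] for s in shared], dtype=float)
    y = np.array([covariate[s] for s in shared], dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("covariate is constant: correlation undefined")
    if np.ptp(x) == 0:
        raise ValueError("copy-number values are constant: correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p), len(shared)


def read_survival_table(path) -> pd.DataFrame:
    """Read the survival TSV (patient_id, time_days, event)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("patient_id", "time_days", "event"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if (df["time_days"] < 0).any():
        raise ValueError(f"{path}: negative survival times")
    if not df["event"].isin([0, 1]).all():
        raise ValueError(f"{path}: event must be 0/1")
    return df


def cox_survival(
    estimates: Sequence[CopyNumberEstimate],
    survival: pd.DataFrame,
    meta: Sequence[SampleMeta],
    *,
    min_events: int = 2,
) -> list[SurvivalResult]:
    """Univariate Cox proportional-hazards fit per cancer type.

    The predictor is the log10 (batch-corrected) tumor copy number; p-values
    come from the Wald test on its coefficient.  A median-split two-group
    summary is attached for plotting; it plays no role in inference.
    """
    meta_map = {m.sample_id: m for m in meta}
    surv = survival.set_index("patient_id")

    rows = []
    for e in estimates:
        sm = meta_map.get(e.sample_id)
        if sm is None or sm.sample_type != "tumor":
            continue
        if e.flagged or not math.isfinite(e.log10_m_best):
            continue
        if sm.patient_id not in surv.index:
            continue
        srow = surv.loc[sm.patient_id]
        rows.append(
            {
                "cancer_type": sm.cancer_type,
                "patient_id": sm.patient_id,
                "log10_m": e.log10_m_best,
                "time": float(srow["time_days"]),
                "event": int(srow["event"]),
            }
        )
    df = pd.DataFrame(rows)
    results: list[SurvivalResult] = []
    if df.empty:
        return results
    # One tumor sample per patient (deterministic: keep first by sample order).
    df = df.drop_duplicates(subset=["cancer_type", "patient_id"], keep="first")

    for ct, g in df.groupby("cancer_type", sort=True):
        n_events = int(g["event"].sum())
        res = SurvivalResult(
            cancer_type=str(ct),
            n=len(g),
            n_events=n_events,
            coefficient=math.nan,
            hazard_ratio=math.nan,
            wald_p=math.nan,
        )
        if n_events < min_events or np.ptp(g["log10_m"].to_numpy()) == 0:
            res.unestimable = True
            results.append(res)
            continue
        cph = CoxPHFitter()
        try:
            cph.fit(
                g[["log10_m", "time", "event"]],
                duration_col="time",
                event_col="event",
            )
        except Exception as exc:
            logger.warning("%s: Cox fit failed: %s", ct, exc)
            res.unestimable = True
            results.append(res)
            continue
        summ = cph.summary.loc["log10_m"]
        res.coefficient = float(summ["coef"])
        res.hazard_ratio = float(math.exp(res.coefficient))
        res.wald_p = float(summ["p"])

        med = float(g["log10_m"].median())
        hi = g[g["log10_m"] > med]
        lo = g[g["log10_m"] <= med]
        res.median_split = {
            "median_log10_m": med,
            "n_high": len(hi),
            "n_low": len(lo),
            "events_high": int(hi["event"].sum()),
            "events_low": int(lo["event"].sum()),
        }
        results.append(res)
    return results
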
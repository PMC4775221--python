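"""Paired depletion, concordance, covariate and survival statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from mtcn import (
    CopyNumberEstimate,
    PairedRatio,
    SampleMeta,
    SimulationConfig,
    build_pairs,
    correlate_covariate,
    cox_survival,
    depletion_test,
    estimate_cohort,
    generate_cohort,
    null_config,
    platform_concordance,
)

from oracles import exact_signed_rank_p


def _est(sid, log10m, flagged=False):
    m = 10.0 ** log10m
    return CopyNumberEstimate(
        sample_id=sid,
        rm=0 if flagged else 1000,
        rn=1_000_000,
        R=1.0,
        m_raw=m,
        m=0.0 if flagged else m,
        log10_m=math.nan if flagged else log10m,
        flagged=flagged,
    )


def _meta(sid, patient, stype, plate="p1", center="C", platform="WXS", ct="CT"):
    return SampleMeta(
        sample_id=sid,
        patient_id=patient,
        sample_type=stype,
        platform=platform,
        center=center,
        plate_id=plate,
        cancer_type=ct,
    )


class TestBuildPairs:
    def test_valid_pair_log2_ratio(self):
        ests = [_est("t1", math.log10(50)), _est("n1", math.log10(100))]
        meta = [_meta("t1", "P1", "tumor"), _meta("n1", "P1", "normal_tissue")]
        (pair,) = build_pairs(ests, meta)
        assert pair.r == pytest.approx(-1.0)

    def test_different_plate_not_paired(self):
        ests = [_est("t1", 2.0), _est("n1", 2.0)]
        meta = [
            _meta("t1", "P1", "tumor", plate="pA"),
            _meta("n1", "P1", "normal_tissue", plate="pB"),
        ]
        assert build_pairs(ests, meta) == []

    def test_blood_never_used_as_normal(self):
        ests = [_est("t1", 2.0), _est("b1", 2.0)]
        meta = [_meta("t1", "P1", "tumor"), _meta("b1", "P1", "blood")]
        assert build_pairs(ests, meta) == []

    def test_multiple_candidates_resolved_lexicographically(self):
        ests = [_est("t2", 2.1), _est("t1", 2.0), _est("n1", 2.0)]
        meta = [
            _meta("t2", "P1", "tumor"),
            _meta("t1", "P1", "tumor"),
            _meta("n1", "P1", "normal_tissue"),
        ]
        (pair,) = build_pairs(ests, meta)
        assert pair.tumor_sample_id == "t1"

    def test_antisymmetry_of_ratio(self, rng):
        mt, mn = 10 ** rng.normal(2.5, 0.3, 2)
        fwd = math.log2(mt / mn)
        rev = math.log2(mn / mt)
        assert fwd == pytest.approx(-rev)


def _pairs(rs, ct="CT"):
    return [
        PairedRatio(
            patient_id=f"P{i}",
            cancer_type=ct,
            tumor_sample_id=f"t{i}",
            normal_sample_id=f"n{i}",
            mT=2 ** r,
            mN=1.0,
            r=float(r),
        )
        for i, r in enumerate(rs)
    ]


class TestDepletionTest:
    def test_all_negative_ratios_give_minimal_p_and_depleted(self, rng):
        rs = -np.abs(rng.normal(1, 0.2, 20))
        (res,) = depletion_test(_pairs(rs))
        # minimal attainable exact p for n=20: 2 / 2^20
        assert res.p == pytest.approx(2 / 2**20)
        assert res.direction == "depleted"
        assert res.frac_depleted == 1.0

    def test_small_groups_skipped(self, rng):
        rs = rng.normal(0, 1, 9)
        assert depletion_test(_pairs(rs)) == []

    def test_sign_flip_flips_direction(self, rng):
        rs = np.abs(rng.normal(1, 0.2, 15))
        (up,) = depletion_test(_pairs(rs))
        (down,) = depletion_test(_pairs(-rs))
        assert up.p == pytest.approx(down.p)
        assert up.direction == "accumulated" and down.direction == "depleted"

    def test_matches_exact_enumeration_oracle(self, rng):
        rs = rng.normal(-0.3, 1.0, 12)
        (res,) = depletion_test(_pairs(rs), min_pairs=5)
        assert res.p == pytest.approx(exact_signed_rank_p(rs))

    def test_bh_q_monotone_and_geq_p(self, rng):
        pairs = []
        for k, shift in enumerate([-1.0, -0.3, 0.0, 0.5]):
            pairs += _pairs(rng.normal(shift, 1, 15), ct=f"CT{k}")
        results = depletion_test(pairs)
        results = sorted(results, key=lambda r: r.p)
        qs = [r.q for r in results]
        ps = [r.p for r in results]
        assert all(q >= p for q, p in zip(qs, ps))
        assert qs == sorted(qs)

    def test_rank_invariance_under_monotone_transform(self, rng):
        """Signed-rank p depends only on signs and |r| ranks."""
        rs = rng.normal(-0.4, 1.0, 18)
        (a,) = depletion_test(_pairs(rs))
        # odd monotone transform preserving sign and abs-ordering
        rs2 = np.sign(rs) * np.expm1(np.abs(rs))
        (b,) = depletion_test(_pairs(rs2))
        assert a.p == pytest.approx(b.p)

    def test_all_zero_ratios_untestable(self):
        (res,) = depletion_test(_pairs(np.zeros(12)))
        assert res.untestable

    def test_planted_depletion_detected_with_high_power(self):
        """Median log2 ratio -0.5 at sigma(r)=0.5, n=30 pairs: >90% power."""
        sigma_sample = 0.5 * math.log10(2) / math.sqrt(2)
        cfg = SimulationConfig(
            n_patients=30,
            frac_adjacent_normal=1.0,
            frac_blood=0.0,
            tumor_log2_ratio=-0.5,
            sigma_log10=sigma_sample,
            alteration_shift_log10=0.0,
            n_genes=5,
            planted_set_size=2,
            n_decoy_sets=1,
        )
        hits = 0
        n_rep = 25
        for rep in range(n_rep):
            cohort = generate_cohort(cfg, seed=1000 + rep)
            meta = cohort.meta_records()
            ests = estimate_cohort(
                cohort.read_count_records(), meta, cohort.purity_records()
            )
            results = depletion_test(build_pairs(ests, meta))
            if results and results[0].q < 0.05 and results[0].direction == "depleted":
                hits += 1
        assert hits / n_rep > 0.9


class TestConcordance:
    def test_monotone_transform_gives_rho_one(self):
        ests_wxs = [_est(f"P{i}-x", 2.0 + 0.05 * i) for i in range(6)]
        ests_wgs = [_est(f"P{i}-g", 1.0 + 0.2 * i) for i in range(6)]
        meta = [
            m
            for i in range(6)
            for m in (
                _meta(f"P{i}-x", f"P{i}", "tumor", platform="WXS"),
                _meta(f"P{i}-g", f"P{i}", "tumor", platform="WGS"),
            )
        ]
        (res,) = platform_concordance(ests_wxs, ests_wgs, meta)
        assert res.rho == pytest.approx(1.0)

    def test_insufficient_overlap_skipped(self):
        ests_wxs = [_est("P0-x", 2.0)]
        ests_wgs = [_est("P0-g", 2.0)]
        meta = [
            _meta("P0-x", "P0", "tumor", platform="WXS"),
            _meta("P0-g", "P0", "tumor", platform="WGS"),
        ]
        assert platform_concordance(ests_wxs, ests_wgs, meta) == []

    def test_shared_truth_gives_significant_positive_rho(self, demo_pipeline):
        cohort, ests, meta, _ = demo_pipeline
        plat = {m.sample_id: m.platform for m in meta}
        res = platform_concordance(
            [e for e in ests if plat[e.sample_id] == "WXS"],
            [e for e in ests if plat[e.sample_id] == "WGS"],
            meta,
        )
        assert res and res[0].rho > 0.5 and res[0].p < 0.01


class TestCovariate:
    def test_perfect_anticorrelation(self, rng):
        vals = {f"s{i}": float(v) for i, v in enumerate(rng.normal(2.5, 0.3, 10))}
        cov = {k: -v for k, v in vals.items()}
        rho, p, n = correlate_covariate(vals, cov)
        assert rho == pytest.approx(-1.0)
        assert n == 10

    def test_constant_covariate_errors(self, rng):
        vals = {f"s{i}": float(v) for i, v in enumerate(rng.normal(2.5, 0.3, 10))}
        with pytest.raises(ValueError, match="constant"):
            correlate_covariate(vals, {k: 1.0 for k in vals})

    def test_permuted_covariate_p_uniform(self, rng):
        ps = []
        for _ in range(400):
            vals = {f"s{i}": float(v) for i, v in enumerate(rng.normal(0, 1, 15))}
            cov = {f"s{i}": float(v) for i, v in enumerate(rng.normal(0, 1, 15))}
            _, p, _ = correlate_covariate(vals, cov)
            ps.append(p)
        ps = np.array(ps)
        rate = (ps < 0.05).mean()
        margin = 1.96 * math.sqrt(0.05 * 0.95 / 400)
        assert 0.05 - margin <= rate <= 0.05 + margin


class TestCoxSurvival:
    def _cohort_results(self, gamma, n, seed, **kw):
        cfg = SimulationConfig(
            n_patients=n,
            survival_gamma=gamma,
            frac_adjacent_normal=0.0,
            frac_blood=0.0,
            n_genes=5,
            planted_set_size=2,
            n_decoy_sets=1,
            alteration_shift_log10=0.0,
            **kw,
        )
        cohort = generate_cohort(cfg, seed=seed)
        meta = cohort.meta_records()
        ests = estimate_cohort(
            cohort.read_count_records(), meta, cohort.purity_records()
        )
        return cox_survival(ests, cohort.survival, meta)

    def test_recovers_planted_log_hazard_coefficient(self):
        """gamma = 1 at n=300: estimate within Monte-Carlo tolerance.

        Plate effects are off and depth is high so the covariate is measured
        essentially without error; regression dilution from measurement noise
        is a property of the estimator's input, not of the Cox stage.
        """
        coefs = [
            self._cohort_results(
                1.0, 300, seed=500 + r, plate_sigma=0.0, depth_wxs=2e7
            )[0].coefficient
            for r in range(8)
        ]
        mean = float(np.mean(coefs))
        sem = float(np.std(coefs, ddof=1) / math.sqrt(len(coefs)))
        assert abs(mean - 1.0) < max(3 * sem, 0.15)

    def test_constant_copy_number_unestimable(self):
        ests = [_est(f"P{i}-T", 2.5) for i in range(10)]
        meta = [_meta(f"P{i}-T", f"P{i}", "tumor") for i in range(10)]
        surv = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(10)],
                "time_days": np.arange(10) + 1.0,
                "event": [1] * 10,
            }
        )
        (res,) = cox_survival(ests, surv, meta)
        assert res.unestimable

    def test_median_split_summary_counts(self):
        res = self._cohort_results(1.0, 40, seed=9)[0]
        ms = res.median_split
        assert ms["n_high"] + ms["n_low"] == res.n
        assert ms["events_high"] + ms["events_low"] == res.n_events
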
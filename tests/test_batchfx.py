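"""Plate/tissue linear model: fitting, correction, diagnostics."""

import math

import numpy as np
import pytest

from mtcn import (
    CopyNumberEstimate,
    SampleMeta,
    SimulationConfig,
    batch_correct,
    batch_diagnostics,
    correct_copy_number,
    estimate_cohort,
    fit_batch_model,
    generate_cohort,
)
from scipy.stats import spearmanr

from oracles import two_group_lsq_delta


def _est(sid, log10m):
    m = 10.0 ** log10m
    return CopyNumberEstimate(
        sample_id=sid, rm=1000, rn=1_000_000, R=1.0, m_raw=m, m=m, log10_m=log10m
    )


def _meta(sid, plate, stype="tumor", platform="WXS", patient=None):
    return SampleMeta(
        sample_id=sid,
        patient_id=patient or sid,
        sample_type=stype,
        platform=platform,
        center="C",
        plate_id=plate,
    )


class TestFit:
    def test_single_plate_single_tissue_reduces_to_mean(self, rng):
        vals = rng.normal(2.5, 0.2, 12)
        ests = [_est(f"s{i}", v) for i, v in enumerate(vals)]
        meta = [_meta(f"s{i}", "p1") for i in range(12)]
        fit = fit_batch_model(ests, meta)
        assert fit.alpha == {"p1": 0.0}
        assert fit.mu == pytest.approx(vals.mean())
        assert sum(fit.residuals.values()) == pytest.approx(0.0, abs=1e-9)

    def test_two_plates_recover_known_offset(self, rng):
        base = rng.normal(2.5, 0.1, 10)
        ests = [_est(f"a{i}", v) for i, v in enumerate(base)]
        ests += [_est(f"b{i}", v + 0.3) for i, v in enumerate(base)]
        meta = [_meta(f"a{i}", "p1") for i in range(10)]
        meta += [_meta(f"b{i}", "p2") for i in range(10)]
        fit = fit_batch_model(ests, meta)
        delta = fit.alpha["p2"] - fit.alpha["p1"]
        oracle = two_group_lsq_delta(base, base + 0.3)
        assert delta == pytest.approx(oracle) == pytest.approx(0.3)
        # weighted sum-to-zero constraint
        assert fit.alpha["p1"] + fit.alpha["p2"] == pytest.approx(0.0, abs=1e-12)

    def test_plate_effect_recovery_error_within_3se(self):
        """Monte-Carlo recovery: 6 plates, alpha ~ N(0, 0.15^2), n=40/plate."""
        rng = np.random.default_rng(77)
        errs, ses = [], []
        for rep in range(25):
            alpha = rng.normal(0, 0.15, 6)
            alpha -= alpha.mean()
            sigma = 0.2
            ests, meta = [], []
            for p in range(6):
                for i in range(40):
                    sid = f"r{rep}p{p}s{i}"
                    ests.append(_est(sid, float(rng.normal(2.5 + alpha[p], sigma))))
                    meta.append(_meta(sid, f"plate{p}"))
            fit = fit_batch_model(ests, meta)
            est_alpha = np.array([fit.alpha[f"plate{p}"] for p in range(6)])
            errs.append(np.mean(np.abs(est_alpha - alpha)))
            # SE of a weighted-contrast plate mean, n=40 per plate
            ses.append(sigma / math.sqrt(40))
        assert np.mean(errs) < 3 * np.mean(ses)

    def test_translation_equivariance(self, rng):
        vals = rng.normal(2.5, 0.2, 30)
        plates = [f"p{i % 3}" for i in range(30)]
        stypes = ["tumor" if i % 2 else "blood" for i in range(30)]
        ests = [_est(f"s{i}", v) for i, v in enumerate(vals)]
        meta = [_meta(f"s{i}", plates[i], stype=stypes[i]) for i in range(30)]
        fit0 = fit_batch_model(ests, meta)
        ests1 = [_est(f"s{i}", v + 1.7) for i, v in enumerate(vals)]
        fit1 = fit_batch_model(ests1, meta)
        assert fit1.mu == pytest.approx(fit0.mu + 1.7)
        for p in fit0.alpha:
            assert fit1.alpha[p] == pytest.approx(fit0.alpha[p], abs=1e-9)
        for t in fit0.beta:
            assert fit1.beta[t] == pytest.approx(fit0.beta[t], abs=1e-9)

    def test_perfect_confounding_drops_tissue(self, rng):
        # plate p1 all blood, plate p2 all tumor -> confounded
        ests = [_est(f"s{i}", float(rng.normal(2.5, 0.1))) for i in range(20)]
        meta = [
            _meta(f"s{i}", "p1" if i < 10 else "p2", stype="blood" if i < 10 else "tumor")
            for i in range(20)
        ]
        fit = fit_batch_model(ests, meta)
        assert fit.beta_dropped
        assert set(fit.beta.values()) == {0.0}

    def test_singleton_plate_flagged(self, rng):
        ests = [_est(f"s{i}", float(rng.normal(2.5, 0.1))) for i in range(11)]
        meta = [_meta(f"s{i}", "p1" if i < 10 else "lonely") for i in range(11)]
        fit = fit_batch_model(ests, meta)
        assert fit.low_confidence_plates == ["lonely"]

    def test_corrected_contrasts_invariant_to_coding(self, rng):
        """Between-sample corrected differences don't depend on the constraint."""
        vals = rng.normal(2.5, 0.3, 24)
        plates = [f"p{i % 4}" for i in range(24)]
        ests = [_est(f"s{i}", v) for i, v in enumerate(vals)]
        meta = [_meta(f"s{i}", plates[i]) for i in range(24)]
        fit = fit_batch_model(ests, meta)
        correct_copy_number(fit, ests, meta)
        corr = {e.sample_id: e.log10_m_corrected for e in ests}
        # reference-coded correction: subtract (alpha_p - alpha_p0) instead
        ref = {
            e.sample_id: e.log10_m - (fit.alpha[plates[i]] - fit.alpha["p0"])
            for i, e in enumerate(ests)
        }
        for i in range(24):
            for j in range(24):
                a = corr[f"s{i}"] - corr[f"s{j}"]
                b = ref[f"s{i}"] - ref[f"s{j}"]
                assert a == pytest.approx(b, abs=1e-12)


class TestCorrection:
    def test_subtracts_fitted_plate_effect(self, rng):
        ests = [_est("a", 2.3), _est("b", 2.3)]
        meta = [_meta("a", "p1"), _meta("b", "p2")]
        fit = fit_batch_model(
            [_est(f"x{i}", 2.0 + (0.3 if i >= 10 else 0)) for i in range(20)],
            [_meta(f"x{i}", "p1" if i < 10 else "p2") for i in range(20)],
        )
        correct_copy_number(fit, ests, meta)
        assert ests[0].log10_m_corrected == pytest.approx(2.3 - fit.alpha["p1"])
        assert ests[1].log10_m_corrected == pytest.approx(2.3 - fit.alpha["p2"])
        assert ests[1].log10_m_corrected == pytest.approx(2.3 - 0.15)

    def test_unknown_plate_errors(self):
        fit = fit_batch_model(
            [_est("x", 2.0)], [_meta("x", "p1")], cancer_type="ALL"
        )
        with pytest.raises(ValueError, match="plate"):
            correct_copy_number(fit, [_est("y", 2.0)], [_meta("y", "p9")])

    def test_wgs_passes_through(self):
        fit = fit_batch_model([_est("x", 2.0)], [_meta("x", "p1")])
        e = _est("w", 2.5)
        correct_copy_number(fit, [e], [_meta("w", "p9", platform="WGS")])
        assert e.log10_m_corrected == 2.5

    def test_correction_is_idempotent(self, rng):
        cohort = generate_cohort(SimulationConfig(n_patients=50), seed=21)
        meta = cohort.meta_records()
        ests = estimate_cohort(
            cohort.read_count_records(), meta, cohort.purity_records()
        )
        ests, fits = batch_correct(ests, meta)
        # refit on the corrected values: plate effects should vanish
        refit_input = [
            CopyNumberEstimate(
                sample_id=e.sample_id,
                rm=e.rm,
                rn=e.rn,
                R=e.R,
                m_raw=e.m_raw,
                m=10 ** e.log10_m_corrected,
                log10_m=e.log10_m_corrected,
            )
            for e in ests
            if e.log10_m_corrected is not None and math.isfinite(e.log10_m_corrected)
        ]
        refit = fit_batch_model(refit_input, meta, cancer_type="SYNTH")
        assert max(abs(a) for a in refit.alpha.values()) < 1e-9

    def test_correction_improves_rank_agreement_with_truth(self):
        cfg = SimulationConfig(n_patients=60, plate_sigma=0.3, sigma_log10=0.15)
        cohort = generate_cohort(cfg, seed=31)
        meta = cohort.meta_records()
        ests = estimate_cohort(
            cohort.read_count_records(), meta, cohort.purity_records()
        )
        ests, _ = batch_correct(ests, meta)
        usable = [
            e
            for e in ests
            if not e.flagged and e.log10_m_corrected is not None
        ]
        truth = [cohort.truth.m_true[e.sample_id] for e in usable]
        rho_raw = spearmanr([e.log10_m for e in usable], truth).statistic
        rho_corr = spearmanr(
            [e.log10_m_corrected for e in usable], truth
        ).statistic
        assert rho_corr > rho_raw


class TestDiagnostics:
    def test_single_plate_marked_not_applicable(self, rng):
        ests = [_est(f"s{i}", float(rng.normal(2.5, 0.1))) for i in range(6)]
        meta = [_meta(f"s{i}", "p1") for i in range(6)]
        (diag,) = batch_diagnostics(ests, meta)
        assert diag.kw_p_tissue is None
        assert any("not applicable" in n for n in diag.notes)

    def test_shared_plate_effect_gives_positive_plate_mean_correlation(self):
        rng = np.random.default_rng(42)
        ests, meta = [], []
        alphas = rng.normal(0, 0.4, 6)
        for p in range(6):
            for i in range(4):
                sid_b = f"b{p}_{i}"
                sid_t = f"t{p}_{i}"
                ests.append(_est(sid_b, float(rng.normal(2.2 + alphas[p], 0.05))))
                meta.append(_meta(sid_b, f"p{p}", stype="blood"))
                ests.append(_est(sid_t, float(rng.normal(2.6 + alphas[p], 0.05))))
                meta.append(_meta(sid_t, f"p{p}", stype="tumor"))
        (diag,) = batch_diagnostics(ests, meta)
        assert diag.plate_mean_r is not None and diag.plate_mean_r > 0.8
        assert diag.kw_p_blood < 0.05 and diag.kw_p_tissue < 0.05

    def test_null_plates_give_uniform_kw_p(self):
        """Kruskal-Wallis p roughly uniform when plates share a distribution."""
        rng = np.random.default_rng(7)
        ps = []
        for rep in range(200):
            ests, meta = [], []
            for p in range(4):
                for i in range(8):
                    sid = f"r{rep}p{p}i{i}"
                    ests.append(_est(sid, float(rng.normal(2.5, 0.2))))
                    meta.append(_meta(sid, f"p{p}"))
            (diag,) = batch_diagnostics(ests, meta)
            ps.append(diag.kw_p_tissue)
        ps = np.array(ps)
        # rejection rate at 0.05 within binomial 95% CI for 200 draws
        rate = (ps < 0.05).mean()
        margin = 1.96 * math.sqrt(0.05 * 0.95 / 200)
        assert 0.05 - margin <= rate <= 0.05 + margin
        assert (ps < 0.5).mean() == pytest.approx(0.5, abs=0.12)
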
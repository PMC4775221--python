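"""Somatic-alteration association and Cox survival analysis.

Carriers of a lesion are compared with non-carriers by Mann-Whitney U on
corrected tumor copy number; overall survival is modelled by univariate
Cox regression on log10 copy number (Wald test).
"""

from mtcn import (
    SimulationConfig,
    association_scan,
    batch_correct,
    build_mutation_calls,
    cox_survival,
    estimate_cohort,
    generate_cohort,
    read_cna_calls,
)

cfg = SimulationConfig(n_patients=100, carrier_fraction=0.3, survival_gamma=1.0)
cohort = generate_cohort(cfg, seed=4)
meta = cohort.meta_records()
estimates = estimate_cohort(
    cohort.read_count_records(), meta, cohort.purity_records()
)
estimates, _ = batch_correct(estimates, meta)
stype = {m.sample_id: m.sample_type for m in meta}
cn = {
    e.sample_id: e.log10_m_corrected
    for e in estimates
    if not e.flagged and stype[e.sample_id] == "tumor"
    and e.log10_m_corrected is not None
}

print("mutation associations (BH within the mutation family):")
for r in association_scan(build_mutation_calls(cohort.maf), cn)[:4]:
    print(
        f"  {r.alteration_id:<16} carriers={r.n_carriers:<3}"
        f" p={r.p:.2e} q={r.q:.2e} {r.direction}"
    )

print("\nCNA associations (separate BH family):")
for r in association_scan(read_cna_calls(cohort.cna), cn)[:3]:
    print(
        f"  {r.alteration_id:<16} carriers={r.n_carriers:<3}"
        f" p={r.p:.2e} q={r.q:.2e} {r.direction}"
    )

(surv,) = cox_survival(estimates, cohort.survival, meta)
print(
    f"\nsurvival: coef={surv.coefficient:.2f} per log10 copy number,"
    f" HR={surv.hazard_ratio:.2f}, Wald p={surv.wald_p:.2e}"
    f" (n={surv.n}, events={surv.n_events})"
)
print(
    "\nMUTG00 and CNA00 carry the planted +0.3 log10 shift; the survival"
    " model recovers the planted positive log-hazard coefficient."
)
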
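"""Paired tumor vs adjacent-normal depletion test.

Pairs each patient's tumor with its adjacent normal (same plate and
center), forms r = log2(mT/mN) and runs a Wilcoxon signed-rank test per
cancer type with BH correction.  Negative median r = tumors hold less
mtDNA than matched normal tissue.
"""

from mtcn import (
    SimulationConfig,
    batch_correct,
    build_pairs,
    depletion_test,
    estimate_cohort,
    generate_cohort,
)

cfg = SimulationConfig(
    n_patients=40, frac_adjacent_normal=1.0, tumor_log2_ratio=-0.5,
    sigma_log10=0.12, alteration_shift_log10=0.0,
)
cohort = generate_cohort(cfg, seed=3)
meta = cohort.meta_records()
estimates = estimate_cohort(
    cohort.read_count_records(), meta, cohort.purity_records()
)
estimates, _ = batch_correct(estimates, meta)
pairs = build_pairs(estimates, meta)
(result,) = depletion_test(pairs)

print(f"pairs: {result.n_pairs}")
print(f"median log2(mT/mN): {result.median_r:.3f}")
print(f"fraction of pairs depleted: {result.frac_depleted:.2f}")
print(f"Wilcoxon signed-rank p = {result.p:.2e}, BH q = {result.q:.2e}")
print(f"call: {result.direction}")
print(
    "\nThe generator planted a median tumor/normal log2 ratio of -0.5;"
    " the test recovers significant mtDNA depletion."
)
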
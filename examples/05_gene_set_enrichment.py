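"""Gene-set association of expression with mtDNA copy number.

Per-gene Spearman correlations (filtered, thresholded at p <= 0.05) are
ranked; the mean-rank test asks whether a set's genes sit unusually high
or low in that ranking.  The enrichment score is -log10(BH q), signed by
direction.
"""

from mtcn import (
    SimulationConfig,
    batch_correct,
    estimate_cohort,
    filter_genes,
    gene_correlations,
    gene_set_scan,
    generate_cohort,
)

cohort = generate_cohort(SimulationConfig(n_patients=80, n_decoy_sets=10), seed=5)
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

expr = filter_genes(cohort.expression)
correlations = gene_correlations(expr, cn)
results = gene_set_scan(correlations, cohort.gene_sets)
top = sorted(results, key=lambda r: -abs(r.enrichment_score))[:5]

print(f"{'gene set':<14} {'dir':<5} {'p':>9} {'q':>9} {'score':>7}")
for r in top:
    print(
        f"{r.gene_set_name:<14} {r.direction:<5} {r.p:>9.2e} {r.q:>9.2e}"
        f" {r.enrichment_score:>7.2f}"
    )
print(
    "\nThe planted set (whose genes track copy number) dominates the"
    " ranking; decoy sets stay near score 0."
)
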
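# Methods

## Copy-number estimation

The estimator is a read-depth ratio.  For each sample we count alignments
that are mapped, primary (not secondary/supplementary), QC-pass,
non-duplicate, properly paired, and have Phred-scaled mapping quality
strictly greater than 30 (an aligner-reported 99.9% correct-placement
probability; together with the pairing requirement this suppresses reads
attracted by nuclear-encoded mitochondrial homologs).  `rm` is the count on
the mitochondrial contig (accepted aliases: MT, chrM, chrMT, M), `rn` the
sum over primary nuclear contigs.  Decoy/alt/unplaced contigs are excluded
from both, under a configurable regex; whether such reads belong in the
nuclear denominator is ambiguous, and excluding them keeps `rn` tied to the
well-defined diploid reference.  The MAPQ threshold is a parameter
(`mapq_threshold`, default 30); prior literature finds 20 already adequate,
so results should be insensitive to it.  Files containing only single-end
reads are refused outright: the properly-paired filter would silently
discard every read, which is a configuration problem, not an answer.

Relative copy number is `m = (rm/rn) × R`.  For normal tissue and blood the
nuclear genome is assumed diploid, R = 1.  For tumors, the sample is a
mixture of tumor cells at average ploidy `ploidy` (fraction `purity`) and
diploid infiltrate, so the nuclear denominator is inflated or depressed by
the factor `(purity·ploidy + (1−purity)·2)/2`; multiplying by R undoes
this.  Purity/ploidy are inputs (e.g. from allele-specific copy-number
callers); tumors lacking them either raise an error or fall back to R = 1
with a warning, under a caller-chosen policy.  Samples with `rm = 0` get
`m = 0` and a flag; zeros indicate capture failure rather than an absence
of mitochondria, so flagged samples are excluded from all log-scale
analyses instead of being pseudocounted.

All copy-number logarithms are base 10; only the paired tumor/normal ratio
uses base 2.

## Plate batch model

Observed log10 copy number is modelled per cancer type as
`M_ijk = μ + α_i + β_j + ε_ijk` over plates i and two tissue classes j
(tissue-derived = tumor or adjacent normal, vs blood).  The design is
over-parameterized; we identify it with *sample-size-weighted sum-to-zero*
constraints on α and β, so subtracting α̂ preserves the cohort mean.  Any
full-rank coding yields identical corrected between-sample differences,
which the test suite asserts explicitly.  The fit is ordinary least squares
on a treatment-coded design; effects are re-centred afterwards.  Plates
observed in a single sample are estimated but flagged low-confidence;
perfect plate/tissue confounding drops β with a warning.  Correction
subtracts only α̂ (the tissue effect is biology); whole-genome samples pass
through uncorrected because plate variation there is much smaller —
exome-capture efficiency is the dominant source of plate-level variation in
mitochondrial yield.  Both raw and corrected values are always carried.

Diagnostics per cancer type: Kruskal-Wallis tests of plate differences in
log10 copy number (blood and tissue-derived samples separately) and the
Pearson correlation between per-plate blood means and tissue means
(computed over plates with at least 3 samples of each class, requiring at
least 3 such plates) — a shared plate-level contribution shows up as a
positive correlation even when blood and tissue of the same patients sit on
different plates.

## Cohort statistics

*Pairing.* Tumor and adjacent-normal samples are paired within patient,
sequencing center and plate (so multiplicative plate effects cancel in the
ratio); blood is never a pair member.  Ambiguous candidates resolve
deterministically to the lexicographically smallest sample-id pair.

*Depletion.* Per cancer type with ≥ 10 pairs, a two-sided Wilcoxon
signed-rank test of r = log2(mT/mN) against 0; zeros discarded; exact null
for n ≤ 25 without ties, otherwise normal approximation with continuity
correction.  BH adjustment across the cancer types of one run; direction
called from the median only at q < 0.05.

*Concordance and covariates.* Spearman correlations: WXS vs WGS estimates
matched on (patient, sample type), and copy number (or paired log ratio)
against arbitrary per-sample covariates such as immune/stromal infiltration
scores; covariate p-values are reported uncorrected.

*Survival.* Univariate Cox proportional hazards with log10 corrected tumor
copy number as the (continuous) predictor; p-values from the Wald test.  A
median-split two-group summary is emitted for plotting only.

*Expression.* Genes with mean expression < 16 are dropped; runs require
≥ 20 samples with both expression and copy number.  Per-gene Spearman ρ and
p are computed against copy number; correlations with p > 0.05 are set to 0
(spurious-correlation suppression — the uncorrected 0.05 gate is
deliberate and configurable).  The gene-set statistic ranks these
thresholded values, zeros included, with midranks across the massive tie at
0.  Each set is tested in both directions by the tie-corrected normal
approximation of the Wilcoxon rank-sum test of set vs complement ("mean
rank" test); BH runs across all (set, direction) tests of one
(study, tissue) run; the reported enrichment score is −log10(q) signed by
direction.  Ranking signed correlations with a down-tail alternative (not
|ρ|) is the implemented reading of "negative enrichment".

*Somatic alterations.* Mutation carriers are derived from MAF tables using
the nonsynonymous coding classes (missense, nonsense, frameshift, in-frame
indel, splice site); samples with > 600 such mutations are removed *before*
any counting, and genes mutated in > 4% of the remaining patients are kept
(the frequency denominator is patients with any mutation data after that
exclusion; both choices are recorded because the order is consequential).
Copy-number alterations arrive as a pre-selected binary matrix.  Each
lesion is tested two-sided by Mann-Whitney U against corrected tumor copy
number, with post-hoc direction from the carrier/non-carrier median
difference; mutations and CNAs form separate BH families by default.  An
optional stratification label (e.g. an expression subtype) re-centres
copy number within strata before testing, as a guard against subtype
confounding.  `group_compare` covers two-group label comparisons (subtypes,
mtDNA variant classes) directly.

Exact null distributions are used for the rank tests whenever samples are
small (≤ 25) and tie-free; otherwise the standard normal approximations
with the usual corrections.  All BH families are per analysis stage within
one run — never pooled across stages.

## Synthetic cohorts

The generator emulates the data-generating process the pipeline assumes:
true log10 copy number is normal per tissue with means near log10(500)
(soft tissue; blood 0.3 lower), biological spread σ = 0.25; the tumor mean
is offset by a configurable median log2 tumor/normal ratio (−0.5 by
default); plate effects are N(0, 0.15²) in log10, applied to exome plates
only; tumor purity is Beta(5, 2) and ploidy ∈ {2, 3, 4}; nuclear reads are
Poisson at configurable depth and mitochondrial reads Poisson with mean
`rn · m* · c_platform · 10^α / R` times a per-copy read fraction (WGS
capture 1.0, WXS 0.05 — exome capture sees mtDNA only off-target; an
overdispersion knob mixes in a gamma multiplier for negative-binomial-like
counts).  A planted gene set has log2 expression linear in log10 m* (slope
1) among independent noise genes plus deliberately low-expressed genes to
exercise the filter; one mutation gene and one CNA shift carriers' log10 m*
by +0.3; survival is exponential with log hazard γ·log10 m* (γ = 1) under
uniform censoring.  One master seed spawns a fixed, append-only list of
per-output substreams, so every artifact is a deterministic function of
(config, seed) and adding outputs never perturbs existing ones.  BAM
fixtures are written with exactly specified read blocks (contig, MAPQ, flag
combinations) on a two-contig miniature reference implied by the header.

What the generator does *not* emulate: real genome sequence content (no
NUMT homology — the MAPQ/pairing filters are exercised structurally, not
against true mismapping), GC or target-capture bias along the genome,
correlated gene-gene expression structure, subclonality, or informative
censoring.  Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness to every
artifact of real cohorts.

## Numerical and design choices

- Problem sizes in the test suite (cohorts of 25–300 patients, 200–1000
  Monte-Carlo replicates, 10,000 permutations) were chosen so the whole
  suite completes in a few minutes while leaving Monte-Carlo error well
  below the asserted margins.
- The normal-approximation mean-rank p agrees with permutation estimates
  to within a few percent at moderate p; in extreme tails (p ≲ 10⁻³) the
  normal approximation is coarser and permutation estimates themselves
  carry a 1/(N+1) floor, so tail checks assert agreement at the resolution
  both can support.
- Cox fits with fewer than 2 events or a constant predictor are reported
  as unestimable rather than attempted.
- Degenerate inputs (all-zero ratios, constant covariates, empty carrier
  groups, whole-universe gene sets) raise or flag explicitly; nothing is
  silently dropped.
- Regression dilution: copy number enters downstream tests as an estimate;
  at low mitochondrial read counts the measurement noise attenuates
  continuous-covariate effects (visibly in Cox coefficients).  Recovery
  tests therefore run at depths where the covariate is essentially
  noise-free; the attenuation itself is a property of the input, not of
  the analysis stages.

## Limitations

- m is never calibrated to copies per cell; only within-platform,
  within-run comparisons are meaningful.
- The batch model is plain least squares with no shrinkage; plates with
  very few samples get noisy effects (flagged, not shrunk).
- Survival modelling is strictly univariate; no adjustment for stage,
  grade or other clinical covariates.
- The somatic scan tests marginal associations; the stratification option
  mitigates but does not resolve confounding between co-occurring lesions.
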
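"""Synthetic cohorts with known ground truth for every pipeline stage.

The generator emulates the statistical structure the estimator and the
downstream tests assume in real tumor-sequencing cohorts:

* per-sample true relative mtDNA copy number (hundreds to ~2000 copies per
  cell, log-normal across samples, tissue-dependent means, optional tumor
  depletion);
* multiplicative plate batch effects (additive in log10) shared by all
  samples on a plate, applied to exome (WXS) plates;
* per-tumor purity (Beta) and ploidy (2/3/4), entering the read model
  through the effective-ploidy factor so that the estimator's correction is
  exercised;
* platform-dependent mitochondrial capture efficiency (whole-genome reads
  capture mtDNA uniformly; exome capture only incidentally);
* Poisson read counts at configurable depth (an overdispersion knob mixes a
  gamma multiplier in, giving negative-binomial-like counts);
* genes whose expression is monotone in copy number (a planted gene set)
  among unrelated noise genes;
* somatic alterations that shift carriers' log10 copy number;
* survival times whose log hazard is linear in log10 copy number.

Everything observable is a deterministic function of (config, master seed);
one master seed spawns an independent sub-stream per output so adding a new
output never perturbs existing ones.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticCohort",
    "generate_cohort",
    "null_config",
    "BamReadSpec",
    "generate_bam_fixture",
]

# Sub-stream indices under the master SeedSequence.  Append only.
_STREAMS = (
    "assign",      # plate/purity/ploidy/carrier assignment
    "truth",       # true copy numbers
    "reads",       # read-count noise
    "expression",  # expression matrix
    "mutations",   # decoy mutation placement
    "cna",         # decoy CNA placement
    "survival",    # event times and censoring
)

LOG10_2 = math.log10(2.0)


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Copy-number scale: typical soft tissues carry roughly 500–2000 mtDNA
    copies per cell, so true log10 copy number is centred near 2.7 (≈500)
    for normal tissue with biological spread ``sigma_log10`` ≈ 0.25.  The
    default tumor effect is a median log2 tumor/normal ratio of −0.5
    (depletion), switchable off for null cohorts.
    """

    n_patients: int = 100
    cancer_type: str = "SYNTH"
    center: str = "C1"

    # Cohort composition
    frac_adjacent_normal: float = 0.7   # patients contributing a normal-tissue sample
    frac_blood: float = 0.5             # patients contributing a blood sample
    frac_wgs: float = 0.0               # patients additionally profiled by WGS (tumor+normal)

    # True copy number (log10 scale)
    mean_log10_m_normal: float = math.log10(500.0)
    blood_offset_log10: float = -0.3    # blood carries fewer mtDNA copies than soft tissue
    tumor_log2_ratio: float = -0.5      # median log2(mT/mN); 0 for null cohorts
    sigma_log10: float = 0.25

    # Plates / batch effects (WXS plates only; WGS plates carry no effect)
    n_plates: int = 6
    plate_sigma: float = 0.15

    # Purity / ploidy
    purity_beta: tuple[float, float] = (5.0, 2.0)
    ploidy_choices: tuple[float, ...] = (2.0, 3.0, 4.0)
    ploidy_probs: tuple[float, ...] = (0.6, 0.25, 0.15)

    # Read model
    depth_wxs: float = 2e6              # expected nuclear reads per WXS sample
    depth_wgs: float = 2e6              # expected nuclear reads per WGS sample
    read_fraction_per_copy: float = 1e-6  # nuclear-read fraction contributed per mtDNA copy
    capture_wxs: float = 0.05           # incidental (off-target) mtDNA capture in exomes
    capture_wgs: float = 1.0
    overdispersion: float = 0.0         # gamma CV^2; 0 = pure Poisson
    n_nuclear_contigs: int = 22

    # Expression
    n_genes: int = 300
    planted_set_size: int = 30
    expression_slope: float = 1.0       # log2 expression units per log10 copy number
    expression_sigma: float = 0.5
    n_lowexpr_genes: int = 10           # genes below the mean-count floor, to exercise filtering
    n_decoy_sets: int = 50
    decoy_set_size: int = 20

    # Somatic alterations
    n_mutation_genes: int = 10
    n_cna: int = 8
    carrier_fraction: float = 0.2
    alteration_shift_log10: float = 0.3  # planted shift for the first mutation gene and first CNA
    planted_alterations: int = 1         # how many of each family carry the shift

    # Survival
    survival_gamma: float = 1.0          # log-hazard per unit log10 copy number
    baseline_hazard: float = 1.0 / 1000  # per day
    censor_horizon_days: float = 2000.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown simulation config key(s): {sorted(unknown)}")
        for key in ("purity_beta", "ploidy_choices", "ploidy_probs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.n_plates < 1:
            raise ValueError("n_plates must be >= 1")
        if not 0 <= self.frac_adjacent_normal <= 1:
            raise ValueError("frac_adjacent_normal must be in [0, 1]")
        if not 0 <= self.frac_blood <= 1:
            raise ValueError("frac_blood must be in [0, 1]")
        if not 0 <= self.frac_wgs <= 1:
            raise ValueError("frac_wgs must be in [0, 1]")
        if self.depth_wxs <= 0 or self.depth_wgs <= 0:
            raise ValueError("sequencing depth must be positive")
        if not math.isclose(sum(self.ploidy_probs), 1.0, abs_tol=1e-9):
            raise ValueError("ploidy_probs must sum to 1")
        if self.planted_set_size > self.n_genes:
            raise ValueError("planted_set_size exceeds n_genes")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth needed to score recovery of every pipeline stage."""

    master_seed: int
    config: dict
    m_true: dict[str, float]            # sample_id -> true copy number (linear)
    plate_effects: dict[str, float]     # plate_id -> alpha* (log10)
    tissue_means: dict[str, float]      # tissue class -> mean log10 m*
    capture: dict[str, float]           # platform -> capture efficiency
    planted_gene_set: list[str]
    expression_slope: float
    planted_alterations: dict[str, float]  # alteration_id -> delta* (log10)
    survival_gamma: float

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


@dataclass
class SyntheticCohort:
    """All generated tables plus the ground truth."""

    counts: pd.DataFrame     # sample_id, contig, read_count (long format)
    meta: pd.DataFrame
    purity: pd.DataFrame
    expression: pd.DataFrame  # genes x tumor samples
    gene_sets: dict[str, list[str]]
    maf: pd.DataFrame
    cna: pd.DataFrame        # alteration_id x sample binary
    survival: pd.DataFrame
    truth: SyntheticTruth

    def read_count_records(self):
        """Counts table as ReadCountRecord objects (no file round-trip)."""
        from .io import ReadCountRecord

        records = []
        for sid, grp in self.counts.groupby("sample_id", sort=True):
            cc = dict(zip(grp["contig"], grp["read_count"].astype(int)))
            rm = cc.get("MT", 0)
            rn = sum(v for c, v in cc.items() if c != "MT")
            records.append(
                ReadCountRecord(sample_id=str(sid), contig_counts=cc, rm=rm, rn=rn)
            )
        return records

    def meta_records(self):
        """Metadata table as SampleMeta objects."""
        from .io import SampleMeta

        return [SampleMeta(**row) for row in self.meta.to_dict("records")]

    def purity_records(self):
        """Purity table as PurityPloidy objects."""
        from .io import PurityPloidy

        return [PurityPloidy(**row) for row in self.purity.to_dict("records")]

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(out / "counts.tsv", sep="\t", index=False)
        self.meta.to_csv(out / "meta.tsv", sep="\t", index=False)
        self.purity.to_csv(out / "purity.tsv", sep="\t", index=False)
        self.expression.to_csv(out / "expr.tsv", sep="\t", index_label="gene_id")
        self.maf.to_csv(out / "muts.maf", sep="\t", index=False)
        self.cna.to_csv(out / "cna.tsv", sep="\t", index_label="alteration_id")
        self.survival.to_csv(out / "survival.tsv", sep="\t", index=False)
        with open(out / "gene_sets.gmt", "w", encoding="utf-8") as fh:
            for name, genes in self.gene_sets.items():
                fh.write("\t".join([name, "synthetic"] + list(genes)) + "\n")
        self.truth.to_json(out / "truth.json")


def null_config(**overrides) -> SimulationConfig:
    """A global-null cohort: every effect of scientific interest is zero.

    Tumor/normal ratio, planted expression slope, alteration shifts and the
    survival log-hazard coefficient are all 0; plate batch effects (a
    nuisance, not a signal) are kept unless overridden.  Keyword overrides
    are applied on top.
    """
    base = dict(
        tumor_log2_ratio=0.0,
        expression_slope=0.0,
        alteration_shift_log10=0.0,
        survival_gamma=0.0,
        blood_offset_log10=0.0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def generate_cohort(
    config: SimulationConfig | None = None, seed: int = 0
) -> SyntheticCohort:
    """Generate one synthetic cohort under ``config`` with the given seed."""
    cfg = config or SimulationConfig()
    cfg.validate()
    rngs = _streams(seed)

    n = cfg.n_patients
    patients = [f"P{i:04d}" for i in range(n)]
    rng_a = rngs["assign"]

    plates = [f"plate{j + 1}" for j in range(cfg.n_plates)]
    plate_of_patient = rng_a.choice(plates, size=n)
    has_normal = rng_a.random(n) < cfg.frac_adjacent_normal
    has_blood = rng_a.random(n) < cfg.frac_blood
    has_wgs = rng_a.random(n) < cfg.frac_wgs
    purity = rng_a.beta(*cfg.purity_beta, size=n)
    ploidy = rng_a.choice(cfg.ploidy_choices, size=n, p=cfg.ploidy_probs)

    plate_alpha = {
        p: float(a)
        for p, a in zip(plates, rngs["truth"].normal(0.0, cfg.plate_sigma, cfg.n_plates))
    }
    wgs_plate = "plateWGS"

    # Alteration carrier sets (tumor samples), fixed before copy numbers so
    # planted shifts can enter m*.
    mut_genes = [f"MUTG{k:02d}" for k in range(cfg.n_mutation_genes)]
    cna_ids = [f"CNA{k:02d}" for k in range(cfg.n_cna)]
    carrier_mask = {}
    for alt in mut_genes + cna_ids:
        carrier_mask[alt] = rng_a.random(n) < cfg.carrier_fraction
    planted: dict[str, float] = {}
    for fam in (mut_genes, cna_ids):
        for alt in fam[: cfg.planted_alterations]:
            planted[alt] = cfg.alteration_shift_log10

    # --- true copy numbers -------------------------------------------------
    rng_t = rngs["truth"]
    mean_normal = cfg.mean_log10_m_normal
    mean_tumor = mean_normal + cfg.tumor_log2_ratio * LOG10_2
    mean_blood = mean_normal + cfg.blood_offset_log10
    tissue_means = {
        "normal_tissue": mean_normal,
        "tumor": mean_tumor,
        "blood": mean_blood,
    }

    log10_m_tumor = rng_t.normal(mean_tumor, cfg.sigma_log10, n)
    for alt, delta in planted.items():
        log10_m_tumor = log10_m_tumor + delta * carrier_mask[alt]
    log10_m_normal = rng_t.normal(mean_normal, cfg.sigma_log10, n)
    log10_m_blood = rng_t.normal(mean_blood, cfg.sigma_log10, n)

    # --- samples -----------------------------------------------------------
    meta_rows = []
    m_true: dict[str, float] = {}
    sample_specs = []  # (sample_id, patient_idx, sample_type, platform, plate)

    def add_sample(pi: int, stype: str, platform: str, plate: str, tag: str, log10m: float):
        sid = f"{patients[pi]}-{tag}"
        meta_rows.append(
            {
                "sample_id": sid,
                "patient_id": patients[pi],
                "sample_type": stype,
                "platform": platform,
                "center": cfg.center,
                "plate_id": plate,
                "cancer_type": cfg.cancer_type,
            }
        )
        m_true[sid] = 10.0 ** log10m
        sample_specs.append((sid, pi, stype, platform, plate))

    for i in range(n):
        plate = str(plate_of_patient[i])
        add_sample(i, "tumor", "WXS", plate, "T", float(log10_m_tumor[i]))
        if has_normal[i]:
            add_sample(i, "normal_tissue", "WXS", plate, "N", float(log10_m_normal[i]))
        if has_blood[i]:
            add_sample(i, "blood", "WXS", plate, "B", float(log10_m_blood[i]))
        if has_wgs[i]:
            add_sample(i, "tumor", "WGS", wgs_plate, "T.WGS", float(log10_m_tumor[i]))
            if has_normal[i]:
                add_sample(
                    i, "normal_tissue", "WGS", wgs_plate, "N.WGS", float(log10_m_normal[i])
                )

    meta = pd.DataFrame(meta_rows)

    purity_rows = [
        {"sample_id": sid, "purity": float(purity[pi]), "ploidy": float(ploidy[pi])}
        for sid, pi, stype, _, _ in sample_specs
        if stype == "tumor"
    ]
    purity_df = pd.DataFrame(purity_rows)

    # --- read counts -------------------------------------------------------
    rng_r = rngs["reads"]
    contigs = [f"chr{c}" for c in range(1, cfg.n_nuclear_contigs + 1)]
    count_rows = []
    for sid, pi, stype, platform, plate in sample_specs:
        depth = cfg.depth_wxs if platform == "WXS" else cfg.depth_wgs
        capture = cfg.capture_wxs if platform == "WXS" else cfg.capture_wgs
        if stype == "tumor":
            R = (purity[pi] * ploidy[pi] + (1 - purity[pi]) * 2.0) / 2.0
        else:
            R = 1.0
        alpha = plate_alpha.get(plate, 0.0) if platform == "WXS" else 0.0
        disp = 1.0
        if cfg.overdispersion > 0:
            shape = 1.0 / cfg.overdispersion
            disp = rng_r.gamma(shape, 1.0 / shape)
        nuclear = rng_r.poisson(depth / cfg.n_nuclear_contigs, cfg.n_nuclear_contigs)
        rn = int(nuclear.sum())
        mt_mean = (
            rn
            * m_true[sid]
            * cfg.read_fraction_per_copy
            * capture
            * (10.0 ** alpha)
            / R
            * disp
        )
        rm = int(rng_r.poisson(mt_mean))
        for c, v in zip(contigs, nuclear):
            count_rows.append({"sample_id": sid, "contig": c, "read_count": int(v)})
        count_rows.append({"sample_id": sid, "contig": "MT", "read_count": rm})
    counts = pd.DataFrame(count_rows)

    # --- expression (tumor samples, WXS) -----------------------------------
    rng_e = rngs["expression"]
    tumor_wxs = [
        sid for sid, _, stype, platform, _ in sample_specs
        if stype == "tumor" and platform == "WXS"
    ]
    genes = [f"G{g:04d}" for g in range(cfg.n_genes)]
    planted_set = genes[: cfg.planted_set_size]
    base = rng_e.normal(math.log2(200.0), 1.0, cfg.n_genes)
    x = np.array([math.log10(m_true[s]) for s in tumor_wxs])
    xc = x - x.mean()
    log2expr = (
        base[:, None]
        + rng_e.normal(0.0, cfg.expression_sigma, (cfg.n_genes, len(tumor_wxs)))
    )
    log2expr[: cfg.planted_set_size] += cfg.expression_slope * xc[None, :]
    expr = np.power(2.0, log2expr)
    # Low-expression genes to exercise the mean-count floor.
    low = rng_e.uniform(0.5, 8.0, (cfg.n_lowexpr_genes, len(tumor_wxs)))
    low_genes = [f"LOW{g:02d}" for g in range(cfg.n_lowexpr_genes)]
    expression = pd.DataFrame(
        np.vstack([expr, low]), index=genes + low_genes, columns=tumor_wxs
    )

    gene_sets = {"PLANTED_SET": list(planted_set)}
    other = genes[cfg.planted_set_size:]
    for k in range(cfg.n_decoy_sets):
        pick = rng_e.choice(len(other), size=min(cfg.decoy_set_size, len(other)), replace=False)
        gene_sets[f"DECOY{k:02d}"] = [other[int(i)] for i in sorted(pick)]

    # --- mutations (MAF) ---------------------------------------------------
    rng_m = rngs["mutations"]
    tumor_sid = {pi: f"{patients[pi]}-T" for pi in range(n)}
    maf_rows = []
    classes = ["Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del", "Splice_Site"]
    for gene in mut_genes:
        for pi in np.flatnonzero(carrier_mask[gene]):
            maf_rows.append(
                {
                    "Hugo_Symbol": gene,
                    "Tumor_Sample_Barcode": tumor_sid[int(pi)],
                    "Variant_Classification": classes[int(rng_m.integers(len(classes)))],
                }
            )
    # A sprinkling of silent mutations that must not create carriers.
    for pi in rng_m.choice(n, size=max(1, n // 10), replace=False):
        maf_rows.append(
            {
                "Hugo_Symbol": "SILENTG",
                "Tumor_Sample_Barcode": tumor_sid[int(pi)],
                "Variant_Classification": "Silent",
            }
        )
    maf = pd.DataFrame(maf_rows, columns=["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"])

    cna = pd.DataFrame(
        {tumor_sid[pi]: [int(carrier_mask[a][pi]) for a in cna_ids] for pi in range(n)},
        index=cna_ids,
    )

    # --- survival ----------------------------------------------------------
    rng_s = rngs["survival"]
    xs = np.array([math.log10(m_true[tumor_sid[pi]]) for pi in range(n)])
    hazard = cfg.baseline_hazard * np.exp(cfg.survival_gamma * (xs - xs.mean()))
    event_time = rng_s.exponential(1.0 / hazard)
    censor_time = rng_s.uniform(0.0, cfg.censor_horizon_days, n)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    survival = pd.DataFrame(
        {
            "patient_id": patients,
            "time_days": np.round(time, 3),
            "event": event,
        }
    )

    truth = SyntheticTruth(
        master_seed=seed,
        # JSON-canonical form (tuples become lists) so that a round-trip
        # through truth.json compares equal.
        config=json.loads(json.dumps(dataclasses.asdict(cfg))),
        m_true={k: float(v) for k, v in m_true.items()},
        plate_effects={**plate_alpha, wgs_plate: 0.0},
        tissue_means=tissue_means,
        capture={"WXS": cfg.capture_wxs, "WGS": cfg.capture_wgs},
        planted_gene_set=list(planted_set),
        expression_slope=cfg.expression_slope,
        planted_alterations={
            (f"{a}_mutation" if a in mut_genes else a): d for a, d in planted.items()
        },
        survival_gamma=cfg.survival_gamma,
    )

    return SyntheticCohort(
        counts=counts,
        meta=meta,
        purity=purity_df,
        expression=expression,
        gene_sets=gene_sets,
        maf=maf,
        cna=cna,
        survival=survival,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# BAM fixtures


@dataclass(frozen=True)
class BamReadSpec:
    """A homogeneous block of synthetic paired reads to place on one contig."""

    contig: str
    count: int
    mapq: int = 60
    proper_pair: bool = True
    duplicate: bool = False
    qcfail: bool = False
    secondary: bool = False
    supplementary: bool = False
    paired: bool = True


def generate_bam_fixture(
    specs: Sequence[BamReadSpec],
    path: str | Path,
    *,
    seed: int = 0,
    nuclear_contig_length: int = 1_000_000,
    mt_contig_length: int = 16_569,
    mt_names: Sequence[str] = ("MT",),
    read_length: int = 50,
) -> Path:
    """Write a coordinate-sorted, indexed BAM containing exactly the
    specified synthetic read blocks on a miniature reference.

    The reference is implied by the header only (no FASTA needed): every
    contig mentioned in the specs is declared, mitochondrial-like contigs at
    16,569 bp and nuclear-like contigs at 1 Mbp.  Reads carry placeholder
    sequence; flags, MAPQ and contig placement follow the specs exactly.
    """
    import pysam

    path = Path(path)
    contigs = sorted({s.contig for s in specs}) or ["MT", "chr1"]
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {
                "SN": c,
                "LN": mt_contig_length if c in set(mt_names) else nuclear_contig_length,
            }
            for c in contigs
        ],
    }
    rng = np.random.default_rng(seed)
    tid = {c: i for i, c in enumerate(contigs)}
    lengths = {c: sq["LN"] for c, sq in zip(contigs, header["SQ"])}

    unsorted = path.with_suffix(".unsorted.bam")
    with pysam.AlignmentFile(str(unsorted), "wb", header=header) as out:
        serial = 0
        for spec in specs:
            if spec.contig not in tid:
                raise ValueError(f"spec contig {spec.contig!r} missing from header")
            max_pos = lengths[spec.contig] - 3 * read_length
            for _ in range(spec.count):
                pos = int(rng.integers(0, max(1, max_pos)))
                a = pysam.AlignedSegment()
                a.query_name = f"read{serial:07d}"
                serial += 1
                a.query_sequence = "A" * read_length
                a.query_qualities = pysam.qualitystring_to_array("I" * read_length)
                a.reference_id = tid[spec.contig]
                a.reference_start = pos
                a.mapping_quality = spec.mapq
                a.cigarstring = f"{read_length}M"
                flag = 0
                if spec.paired:
                    flag |= 0x1 | 0x40 | 0x20  # paired, first-in-pair, mate reverse
                    if spec.proper_pair:
                        flag |= 0x2
                    a.next_reference_id = tid[spec.contig]
                    a.next_reference_start = pos + read_length
                    a.template_length = 2 * read_length
                if spec.duplicate:
                    flag |= 0x400
                if spec.qcfail:
                    flag |= 0x200
                if spec.secondary:
                    flag |= 0x100
                if spec.supplementary:
                    flag |= 0x800
                a.flag = flag
                out.write(a)

    pysam.sort("-o", str(path), str(unsorted))
    unsorted.unlink()
    pysam.index(str(path))
    return path
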
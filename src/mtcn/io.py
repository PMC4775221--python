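"""Read counting from alignments and validated tabular cohort inputs.

The copy-number estimator upstream of everything else in this package is a
read-depth ratio: the number of sequencing reads mapping to the mitochondrial
contig versus the nuclear genome.  This module produces those counts from a
coordinate-sorted, indexed BAM under the filter set used for depth-ratio
mtDNA quantification (QC-pass, non-duplicate, properly paired, MAPQ strictly
greater than a Phred threshold, primary alignments only), and parses/validates
the tab-separated cohort tables (per-contig counts, sample metadata,
purity/ploidy) that the rest of the pipeline consumes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

__all__ = [
    "DEFAULT_MT_NAMES",
    "DEFAULT_MAPQ_THRESHOLD",
    "DEFAULT_NONPRIMARY_REGEX",
    "ReadCountRecord",
    "SampleMeta",
    "PurityPloidy",
    "ConfigurationError",
    "ParseError",
    "mapq_alignment_accuracy",
    "count_filtered_reads",
    "read_counts_table",
    "write_counts_table",
    "read_metadata",
    "read_purity_ploidy",
]

#: Mitochondrial contig aliases accepted by default (GRCh37 "MT", UCSC "chrM").
DEFAULT_MT_NAMES: tuple[str, ...] = ("MT", "chrM", "chrMT", "M")

#: Phred-scaled mapping-quality threshold; reads with MAPQ <= threshold are
#: dropped (strict "> 30").  30 corresponds to a 99.9% correct-alignment
#: probability and suppresses reads attracted by nuclear mtDNA homologs (NUMTs).
DEFAULT_MAPQ_THRESHOLD: int = 30

#: Contigs matching this pattern are treated as non-primary (decoys, alts,
#: unplaced scaffolds) and excluded from the nuclear denominator.
DEFAULT_NONPRIMARY_REGEX: str = (
    r"^(GL\d|NC_|hs37d5|chrUn|HLA-|EBV)|_(random|alt|decoy|fix|hap\d*)$"
)

SAMPLE_TYPES = frozenset({"tumor", "normal_tissue", "blood"})
PLATFORMS = frozenset({"WXS", "WGS"})


class ConfigurationError(ValueError):
    """Raised when inputs are inconsistent with the requested configuration."""


class ParseError(ValueError):
    """Raised when a tabular input violates its schema."""


@dataclass
class ReadCountRecord:
    """Filtered per-contig read counts for one sample.

    ``rm`` is the mitochondrial read count and ``rn`` the total count over all
    primary nuclear contigs (autosomes + sex chromosomes); decoy/alt contigs
    are never part of ``rn``.
    """

    sample_id: str
    contig_counts: dict[str, int]
    rm: int
    rn: int

    def __post_init__(self) -> None:
        if self.rm < 0 or self.rn < 0:
            raise ValueError("read counts must be non-negative")
        if any(c < 0 for c in self.contig_counts.values()):
            raise ValueError("read counts must be non-negative")


@dataclass(frozen=True)
class SampleMeta:
    """Cohort metadata for one sample.

    ``plate_id`` is the processing-batch label (the unit of the batch-effect
    model) and ``center`` the sequencing center.  ``cancer_type`` groups
    samples into per-study analyses; a single-study cohort may leave it at the
    default.
    """

    sample_id: str
    patient_id: str
    sample_type: str  # tumor | normal_tissue | blood
    platform: str  # WXS | WGS
    center: str
    plate_id: str
    cancer_type: str = "ALL"

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise ValueError(
                f"unknown sample_type {self.sample_type!r} "
                f"(expected one of {sorted(SAMPLE_TYPES)})"
            )
        if self.platform not in PLATFORMS:
            raise ValueError(
                f"unknown platform {self.platform!r} (expected WXS or WGS)"
            )


@dataclass(frozen=True)
class PurityPloidy:
    """Tumor purity (fraction of tumor cells) and average tumor ploidy."""

    sample_id: str
    purity: float
    ploidy: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError(f"purity must be in [0, 1], got {self.purity}")
        if self.ploidy <= 0:
            raise ValueError(f"ploidy must be positive, got {self.ploidy}")


def mapq_alignment_accuracy(mapq: float) -> float:
    """Percent probability that an alignment with this Phred MAPQ is correct.

    MAPQ is -10·log10(P(misalignment)); the accuracy is 100·(1 - 10^(-q/10)).
    """
    return 100.0 * (1.0 - 10.0 ** (-mapq / 10.0))


def _is_mt(name: str, mt_names: Iterable[str]) -> bool:
    return name in set(mt_names)


def count_filtered_reads(
    alignment_file: str | Path,
    mt_contig_names: Sequence[str] = DEFAULT_MT_NAMES,
    *,
    sample_id: str | None = None,
    mapq_threshold: int = DEFAULT_MAPQ_THRESHOLD,
    nonprimary_regex: str = DEFAULT_NONPRIMARY_REGEX,
) -> ReadCountRecord:
    """Count QC-filtered primary alignments per contig in a BAM file.

    A read is counted iff it is mapped, a primary alignment (not secondary or
    supplementary), passed platform QC, is not marked duplicate, is properly
    paired, and has MAPQ strictly greater than ``mapq_threshold``.

    Parameters
    ----------
    alignment_file
        Path to a coordinate-sorted BAM.  An index is not required because the
        whole file is streamed.
    mt_contig_names
        Names the mitochondrial contig may carry in the header; exactly the
        reads on the (single) matching contig populate ``rm``.
    mapq_threshold
        Phred threshold; strict inequality (MAPQ == threshold is excluded).
    nonprimary_regex
        Contigs matching this regex count neither toward ``rm`` nor ``rn``.

    Raises
    ------
    ConfigurationError
        If no listed mitochondrial contig is in the header, or the file
        contains only single-end reads (the properly-paired filter would
        silently discard everything).
    OSError
        If the file is missing, unreadable or truncated.
    """
    path = Path(alignment_file)
    nonprimary = re.compile(nonprimary_regex)
    mt_names = tuple(mt_contig_names)

    with pysam.AlignmentFile(str(path), "rb") as bam:
        references = list(bam.references)
        mt_present = [r for r in references if _is_mt(r, mt_names)]
        if not mt_present:
            raise ConfigurationError(
                f"no mitochondrial contig among {mt_names} in header of {path}"
            )
        mt_contig = mt_present[0]

        counts: dict[str, int] = {r: 0 for r in references}
        saw_any_primary = False
        saw_paired = False
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            saw_any_primary = True
            if read.is_paired:
                saw_paired = True
            if read.is_qcfail or read.is_duplicate:
                continue
            if not read.is_proper_pair:
                continue
            if read.mapping_quality <= mapq_threshold:
                continue
            counts[read.reference_name] += 1

        if saw_any_primary and not saw_paired:
            raise ConfigurationError(
                f"{path} contains only single-end reads; the properly-paired "
                "filter would remove every read. Refusing to count."
            )

    contig_counts = {
        name: n for name, n in counts.items() if not nonprimary.search(name)
    }
    rm = sum(n for name, n in contig_counts.items() if _is_mt(name, mt_names))
    rn = sum(n for name, n in contig_counts.items() if not _is_mt(name, mt_names))
    return ReadCountRecord(
        sample_id=sample_id or path.stem,
        contig_counts=contig_counts,
        rm=rm,
        rn=rn,
    )


# ---------------------------------------------------------------------------
# TSV readers / writers


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error passthrough
        raise ParseError(f"cannot read {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return df


def read_counts_table(
    path: str | Path,
    mt_contig_names: Sequence[str] = DEFAULT_MT_NAMES,
    nonprimary_regex: str = DEFAULT_NONPRIMARY_REGEX,
) -> list[ReadCountRecord]:
    """Read a long-format per-contig counts TSV (sample_id, contig, read_count)."""
    df = _read_tsv(path, ["sample_id", "contig", "read_count"])
    nonprimary = re.compile(nonprimary_regex)
    records: list[ReadCountRecord] = []
    for i, (sid, grp) in enumerate(df.groupby("sample_id", sort=True)):
        contig_counts: dict[str, int] = {}
        for row_idx, row in grp.iterrows():
            try:
                n = int(row["read_count"])
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: row {row_idx + 2}, column read_count: "
                    f"{row['read_count']!r} is not an integer"
                ) from None
            if n < 0:
                raise ParseError(
                    f"{path}: row {row_idx + 2}, column read_count: negative"
                )
            contig = str(row["contig"])
            if contig in contig_counts:
                raise ParseError(
                    f"{path}: duplicate contig {contig!r} for sample {sid!r}"
                )
            if not nonprimary.search(contig):
                contig_counts[contig] = n
        rm = sum(
            n for c, n in contig_counts.items() if c in set(mt_contig_names)
        )
        rn = sum(
            n for c, n in contig_counts.items() if c not in set(mt_contig_names)
        )
        records.append(
            ReadCountRecord(
                sample_id=str(sid), contig_counts=contig_counts, rm=rm, rn=rn
            )
        )
    return records


def write_counts_table(records: Iterable[ReadCountRecord], path: str | Path) -> None:
    rows = [
        {"sample_id": r.sample_id, "contig": c, "read_count": n}
        for r in records
        for c, n in sorted(r.contig_counts.items())
    ]
    pd.DataFrame(rows, columns=["sample_id", "contig", "read_count"]).to_csv(
        path, sep="\t", index=False
    )


def read_metadata(path: str | Path) -> list[SampleMeta]:
    """Read and validate the sample metadata TSV.

    Columns: sample_id, patient_id, sample_type, platform, center, plate_id
    and optionally cancer_type.  sample_id must be unique.
    """
    df = _read_tsv(
        path,
        ["sample_id", "patient_id", "sample_type", "platform", "center", "plate_id"],
    )
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise ParseError(
            f"{path}: duplicate sample_id {dup.iloc[0]!r} "
            f"(row {dup.index[0] + 2}, column sample_id)"
        )
    has_ct = "cancer_type" in df.columns
    out = []
    for row_idx, row in df.iterrows():
        try:
            out.append(
                SampleMeta(
                    sample_id=str(row["sample_id"]),
                    patient_id=str(row["patient_id"]),
                    sample_type=str(row["sample_type"]),
                    platform=str(row["platform"]),
                    center=str(row["center"]),
                    plate_id=str(row["plate_id"]),
                    cancer_type=str(row["cancer_type"]) if has_ct else "ALL",
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: row {row_idx + 2}: {exc}") from None
    return out


def read_purity_ploidy(path: str | Path) -> list[PurityPloidy]:
    """Read the purity/ploidy TSV (sample_id, purity, ploidy)."""
    df = _read_tsv(path, ["sample_id", "purity", "ploidy"])
    out = []
    for row_idx, row in df.iterrows():
        try:
            out.append(
                PurityPloidy(
                    sample_id=str(row["sample_id"]),
                    purity=float(row["purity"]),
                    ploidy=float(row["ploidy"]),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: row {row_idx + 2}: {exc}") from None
    return out


def meta_by_sample(meta: Iterable[SampleMeta]) -> Mapping[str, SampleMeta]:
    """Index metadata records by sample_id."""
    return {m.sample_id: m for m in meta}
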
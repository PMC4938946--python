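"""Variant filtering, load statistics, and orthogonal-validation classification.

Raw calls are filtered to depth strictly greater than 20 and QUAL strictly
greater than 30. Variant load is reported as base pairs per variant. Calls
confirmed by an orthogonal (Sanger) read are classified as reference-sequence
errors (homozygous allele switch in a homozygous line), candidate de novo
heterozygous changes, or sequencing-workflow errors when the orthogonal read
sides with the reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .genome_io import Interval, merge_intervals
from .util import round_half_up

__all__ = [
    "VariantRecord",
    "ValidationCall",
    "FilterResult",
    "read_vcf",
    "read_variant_tsv",
    "filter_variants",
    "variant_load",
    "classify_validation",
]

GENOTYPES = ("hom_ref", "het", "hom_alt")
CATEGORIES = ("reference_error", "heterozygous_denovo", "ngs_error")


@dataclass
class VariantRecord:
    """One called variant with the fields the filters need."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    depth: Optional[int]
    qual: Optional[float]
    genotype: Optional[str] = None
    vtype: Optional[str] = None  # "snv" or "indel"; derived if omitted
    in_unique_region: Optional[bool] = None
    psv_flag: bool = False  # reserved: paralog-misalignment review

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.depth is not None and self.depth < 0:
            raise ValueError("depth must be non-negative")
        if self.genotype is not None and self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.vtype is None:
            self.vtype = "snv" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"
        elif self.vtype not in ("snv", "indel"):
            raise ValueError(f"unknown variant type {self.vtype!r}")


@dataclass
class ValidationCall:
    variant: VariantRecord
    sanger_supports: str  # "ngs" or "reference"
    category: str

    def __post_init__(self) -> None:
        if self.sanger_supports not in ("ngs", "reference"):
            raise ValueError("sanger_supports must be 'ngs' or 'reference'")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass
class FilterResult:
    kept: list[VariantRecord]
    n_input: int
    n_snv: int
    n_indel: int


def _genotype_from_gt(gt) -> Optional[str]:
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return None
    if all(a == 0 for a in alleles):
        return "hom_ref"
    if all(a != 0 for a in alleles):
        return "hom_alt"
    return "het"


def _in_unique(chrom: str, pos1: int, repeat_mask: dict[str, list[Interval]]) -> bool:
    ivs = repeat_mask.get(chrom, [])
    p0 = pos1 - 1
    return not any(s <= p0 < e for s, e in ivs)


def read_repeat_mask_bed(path: str | Path) -> dict[str, list[Interval]]:
    """Repeat intervals per chromosome, normalized, for unique/repeat splits."""
    by_chrom: dict[str, list[Interval]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            c, s, e = line.split("\t")[:3]
            by_chrom.setdefault(c, []).append((int(s), int(e)))
    return {c: merge_intervals(ivs) for c, ivs in by_chrom.items()}


def read_vcf(
    path: str | Path, repeat_mask: dict[str, list[Interval]] | None = None
) -> list[VariantRecord]:
    """Load variant records from a VCF (4.x) via pysam.

    Depth comes from the DP INFO field (or the first sample's DP when INFO
    lacks it); a missing DP leaves depth None, which conservatively fails the
    filter. Genotype comes from the first sample's GT if present.
    """
    import pysam

    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            depth = rec.info.get("DP")
            genotype = None
            if rec.samples:
                sample = rec.samples[0]
                if depth is None and "DP" in sample:
                    depth = sample["DP"]
                gt = sample.get("GT")
                if gt is not None:
                    genotype = _genotype_from_gt(gt)
            alt = rec.alts[0] if rec.alts else None
            if alt is None:
                continue
            records.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    depth=None if depth is None else int(depth),
                    qual=None if rec.qual is None else float(rec.qual),
                    genotype=genotype,
                    in_unique_region=(
                        None
                        if repeat_mask is None
                        else _in_unique(rec.chrom, rec.pos, repeat_mask)
                    ),
                )
            )
    return records


def read_variant_tsv(path: str | Path) -> list[VariantRecord]:
    """Equivalent TSV input: chrom, pos, ref, alt, depth, qual[, genotype].

    Malformed lines are rejected with their line numbers.
    """
    records: list[VariantRecord] = []
    errors: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                errors.append(f"line {lineno}: expected >= 6 columns")
                continue
            try:
                records.append(
                    VariantRecord(
                        chrom=fields[0],
                        pos=int(fields[1]),
                        ref=fields[2],
                        alt=fields[3],
                        depth=int(fields[4]) if fields[4] != "." else None,
                        qual=float(fields[5]) if fields[5] != "." else None,
                        genotype=fields[6] if len(fields) > 6 and fields[6] else None,
                    )
                )
            except (ValueError, IndexError) as exc:
                errors.append(f"line {lineno}: {exc}")
    if errors:
        raise ValueError("malformed variant records: " + "; ".join(errors))
    return records


def filter_variants(
    records: Sequence[VariantRecord],
    min_depth_exclusive: int = 20,
    min_qual_exclusive: float = 30.0,
) -> FilterResult:
    """Keep variants with depth > 20 and QUAL > 30 (strict inequalities).

    Records missing depth or QUAL fail the filter. Idempotent; the kept set
    is always a subset of the input, and SNV + indel counts sum to the total
    kept.
    """
    kept = [
        r
        for r in records
        if r.depth is not None
        and r.qual is not None
        and r.depth > min_depth_exclusive
        and r.qual > min_qual_exclusive
    ]
    return FilterResult(
        kept=kept,
        n_input=len(records),
        n_snv=sum(r.vtype == "snv" for r in kept),
        n_indel=sum(r.vtype == "indel" for r in kept),
    )


def variant_load(n_variants: int, region_bp: int) -> Optional[int]:
    """Base pairs per variant, rounded to an integer for reporting.

    Returns None for zero variants (load undefined).
    """
    if n_variants < 0 or region_bp <= 0:
        raise ValueError("invalid inputs")
    if n_variants == 0:
        return None
    return int(round_half_up(region_bp / n_variants, 0))


def classify_validation(
    variant: VariantRecord,
    sanger_supports: str,
    sample_is_homozygous_line: bool = True,
) -> str:
    """Classify one orthogonally validated variant call.

    * Sanger supports the reference -> ``ngs_error`` (workflow artifact).
    * Sanger supports the call and the genotype is hom_alt in a homozygous
      line -> ``reference_error`` (an a/a -> b/b allele switch is implausible
      biology in a homozygous cell line; the reference base is wrong).
    * Sanger supports the call and the genotype is het ->
      ``heterozygous_denovo`` (candidate de novo polymorphism).
    """
    if sanger_supports not in ("ngs", "reference"):
        raise ValueError("sanger_supports must be 'ngs' or 'reference'")
    if sanger_supports == "reference":
        return "ngs_error"
    if variant.genotype is None:
        raise ValueError("genotype required to classify a confirmed variant")
    if variant.genotype == "hom_alt":
        if not sample_is_homozygous_line:
            raise ValueError(
                "hom_alt confirmed calls are only classifiable for a "
                "homozygous cell line"
            )
        return "reference_error"
    if variant.genotype == "het":
        return "heterozygous_denovo"
    raise ValueError("a confirmed variant cannot be genotyped hom_ref")
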
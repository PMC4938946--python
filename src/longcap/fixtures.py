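"""Synthetic inputs with known ground truth for every other module.

The generators emulate the structure of a repeat-rich, SNP-dense target such
as the MHC at configurable scale: a random genome with planted repeat tracts
(exact copies of seed motifs, so the k-mer uniqueness screen genuinely fails
inside them rather than merely being labeled masked), Poisson-placed SNP
positions, optional exact tandem duplications, depth profiles shaped like
real capture coverage (uniform / peaked at primer sites / gapped), and
variant tables stressing the depth/QUAL filter boundaries. Every fixture is
deterministic given its seed and ships a manifest sufficient to predict the
downstream modules' outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .capture_sim import FragmentLengthModel, relative_capture
from .coverage_eval import CoverageProfile
from .genome_io import Interval, TargetRegion, write_region
from .variant_eval import VariantRecord

__all__ = [
    "FixtureSpec",
    "GenomeFixture",
    "DepthFixture",
    "VariantFixture",
    "make_genome",
    "make_depth_profile",
    "make_variant_table",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class FixtureSpec:
    """Study-condition knobs for the synthetic generators.

    Defaults mirror the targeted-capture study's conditions at the stated
    scale: ~53 % repeat content in tracts of a few hundred bases, SNPs at
    1e-3 per bp (a polymorphism-dense target), mean depth 164x, and a
    boundary-stressing variant table.
    """

    seed: int = 0
    genome_length_bp: int = 100_000
    repeat_fraction: float = 0.53
    repeat_tract_mean_bp: float = 800.0
    snp_density_per_bp: float = 1e-3
    planted_duplication: Optional[tuple[int, int]] = None  # (length, copies)
    depth_profile_shape: str = "primer_peaked"
    mean_depth: float = 164.0
    variant_table_size: int = 500

    def __post_init__(self) -> None:
        if not 0.0 <= self.repeat_fraction <= 1.0:
            raise ValueError("repeat_fraction must be in [0, 1]")
        if self.genome_length_bp <= 0 or self.repeat_tract_mean_bp <= 0:
            raise ValueError("lengths must be positive")
        if not 0.0 <= self.snp_density_per_bp <= 1.0:
            raise ValueError("snp_density_per_bp must be in [0, 1]")
        if self.depth_profile_shape not in ("uniform", "primer_peaked", "gapped"):
            raise ValueError("unknown depth profile shape")
        if self.repeat_fraction >= 1.0:
            raise ValueError("repeat_fraction 1.0 leaves no room for primers")


@dataclass
class GenomeFixture:
    region: TargetRegion
    manifest: dict
    fasta_path: Optional[Path] = None
    repeat_bed_path: Optional[Path] = None
    snp_bed_path: Optional[Path] = None


def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def make_genome(spec: FixtureSpec, out_dir: str | Path | None = None) -> GenomeFixture:
    """Generate a random genome with planted repeat tracts, SNPs and duplications.

    Repeat tracts are laid down by alternating unique gaps and repeat tracts
    whose expected lengths are calibrated so the masked fraction approaches
    ``repeat_fraction`` (within ~2 % at megabase scale). Tract content tiles
    exact copies of a small motif library, so tract interiors fail an exact
    k-mer uniqueness screen. The manifest records every planted feature.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.genome_length_bp
    seq = _random_bases(rng, L).copy()

    repeat_intervals: list[Interval] = []
    motifs = [bytes(_random_bases(rng, 300)) for _ in range(3)]
    f = spec.repeat_fraction
    if f > 0:
        tract_mean = spec.repeat_tract_mean_bp
        gap_mean = tract_mean * (1.0 - f) / f
        pos = 0
        while pos < L:
            gap = int(rng.exponential(gap_mean)) + 1
            pos += gap
            if pos >= L:
                break
            tract = max(int(rng.exponential(tract_mean)), 50)
            end = min(pos + tract, L)
            motif = motifs[int(rng.integers(0, len(motifs)))]
            tiled = (motif * (tract // len(motif) + 1))[: end - pos]
            seq[pos:end] = np.frombuffer(tiled, dtype=np.uint8)
            repeat_intervals.append((pos, end))
            pos = end

    duplication = None
    if spec.planted_duplication is not None:
        dup_len, copies = spec.planted_duplication
        if dup_len * copies > L:
            raise ValueError("planted duplication exceeds genome length")
        src = int(rng.integers(0, L - dup_len * copies + 1))
        unit = seq[src : src + dup_len].copy()
        for c in range(1, copies):
            seq[src + c * dup_len : src + (c + 1) * dup_len] = unit
        duplication = {
            "start": src,
            "unit_length": int(dup_len),
            "copies": int(copies),
        }

    snp_positions = np.flatnonzero(rng.random(L) < spec.snp_density_per_bp)
    snp_intervals = [(int(p), int(p) + 1) for p in snp_positions]

    region = TargetRegion(
        name=f"synthetic_{spec.seed}",
        chrom=f"synthetic_{spec.seed}",
        start=0,
        end=L,
        sequence=seq.tobytes().decode(),
        repeat_mask=repeat_intervals,
        snp_mask=snp_intervals,
    )
    masked_bp = sum(e - s for s, e in region.repeat_mask)
    manifest = {
        "seed": spec.seed,
        "genome_length_bp": L,
        "repeat_intervals": [[int(s), int(e)] for s, e in region.repeat_mask],
        "repeat_fraction_requested": f,
        "repeat_fraction_realized": masked_bp / L,
        "snp_positions": [int(p) for p in snp_positions],
        "duplication": duplication,
    }

    fixture = GenomeFixture(region=region, manifest=manifest)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fixture.fasta_path = out / "region.fa"
        write_region(region, fixture.fasta_path)
        fixture.repeat_bed_path = out / "repeats.bed"
        with open(fixture.repeat_bed_path, "w") as fh:
            for s, e in region.repeat_mask:
                fh.write(f"{region.chrom}\t{s}\t{e}\n")
        fixture.snp_bed_path = out / "snps.bed"
        with open(fixture.snp_bed_path, "w") as fh:
            for s, e in region.snp_mask:
                fh.write(f"{region.chrom}\t{s}\t{e}\n")
        with open(out / "genome_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    return fixture


@dataclass
class DepthFixture:
    profile: CoverageProfile
    manifest: dict
    tsv_path: Optional[Path] = None


def make_depth_profile(
    primer_positions: Sequence[int],
    shape: str,
    params: dict | None = None,
    seed: int = 0,
    out_path: str | Path | None = None,
) -> DepthFixture:
    """Synthesize a per-base depth profile with known structure.

    Shapes
    ------
    uniform : Poisson noise around ``mean_depth`` everywhere.
    primer_peaked : expected depth follows the capture model — proportional
        to the probability a fragment from any primer site covers the
        position (``1 - prod(1 - relative_capture(d_i))``), scaled so the
        expectation at a primer site is ``mean_depth``.
    gapped : uniform with listed (or generated) intervals forced to zero.
    """
    params = dict(params or {})
    positions = sorted(int(p) for p in primer_positions)
    length = int(params.get("region_length_bp", (positions[-1] + 1) if positions else 0))
    if length <= 0:
        raise ValueError("region_length_bp must be positive")
    mean_depth = float(params.get("mean_depth", 164.0))
    rng = np.random.default_rng(seed)
    grid = np.arange(length, dtype=np.int64)

    gaps: list[Interval] = []
    if shape == "uniform":
        lam = np.full(length, mean_depth)
    elif shape == "primer_peaked":
        model = params.get("length_model") or FragmentLengthModel()
        pos_arr = np.asarray(positions, dtype=np.int64)
        max_d = model.support_max()
        dgrid = np.arange(0, int(max_d) + 2, dtype=np.int64)
        decay = np.array([relative_capture(float(d), model) for d in dgrid[:: 100]])
        # piecewise-linear interpolation of the decay curve sampled every 100 bp
        rc_of = lambda d: np.interp(d / 100.0, np.arange(len(decay)), decay, right=0.0)
        log_miss = np.zeros(length)
        for p in pos_arr:
            d = np.abs(grid - p)
            r = np.clip(rc_of(d), 0.0, 1.0 - 1e-12)
            log_miss += np.log1p(-r)
        signal = 1.0 - np.exp(log_miss)
        lam = mean_depth * signal  # == mean_depth where a primer sits (signal ~ 1)
    elif shape == "gapped":
        lam = np.full(length, mean_depth)
        gaps = [tuple(g) for g in params.get("gaps", [])]
        if not gaps:
            n_gaps = int(params.get("n_gaps", 3))
            mids = [
                (positions[i] + positions[i + 1]) // 2
                for i in range(len(positions) - 1)
            ]
            chosen = rng.choice(len(mids), size=min(n_gaps, len(mids)), replace=False)
            width = int(params.get("gap_width_bp", 400))
            gaps = [
                (max(mids[int(c)] - width // 2, 0), min(mids[int(c)] + width // 2, length))
                for c in sorted(chosen)
            ]
        for s, e in gaps:
            lam[s:e] = 0.0
    else:
        raise ValueError(f"unknown shape {shape!r}")

    depth = rng.poisson(lam)
    profile = CoverageProfile(positions=grid, depth=depth)
    manifest = {
        "shape": shape,
        "seed": seed,
        "mean_depth": mean_depth,
        "primer_positions": positions,
        "gaps": [[int(s), int(e)] for s, e in gaps],
        "expected_mean_depth": float(np.mean(lam)),
    }
    fixture = DepthFixture(profile=profile, manifest=manifest)
    if out_path is not None:
        out_path = Path(out_path)
        nz = np.flatnonzero(depth)
        with open(out_path, "w") as fh:
            for i in nz:
                fh.write(f"target\t{int(grid[i]) + 1}\t{int(depth[i])}\n")
        fixture.tsv_path = out_path
        with open(out_path.with_suffix(".manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)
    return fixture


@dataclass
class VariantFixture:
    records: list[VariantRecord]
    manifest: dict
    vcf_path: Optional[Path] = None


_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID={chrom},length={length}>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample
"""


def make_variant_table(
    spec: FixtureSpec, out_dir: str | Path | None = None
) -> VariantFixture:
    """Variant records with depth/QUAL randomized around the filter boundaries.

    Depths are drawn near 20 and QUALs near 30 (plus clearly-passing and
    clearly-failing mass) so strict-inequality behavior is exercised; the
    manifest records the exact pass-set of the (depth > 20, QUAL > 30)
    filter, plus kept counts by variant type.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.genome_length_bp
    chrom = f"synthetic_{spec.seed}"
    n = spec.variant_table_size
    positions = np.sort(rng.choice(np.arange(1, L + 1), size=min(n, L), replace=False))
    records: list[VariantRecord] = []
    pass_ids: list[int] = []
    bases = "ACGT"
    n_snv_pass = n_indel_pass = 0
    for i, pos in enumerate(positions):
        is_indel = rng.random() < 0.05  # ~21 of 430 calls were indels
        ref = bases[int(rng.integers(0, 4))]
        if is_indel:
            alt = ref + bases[int(rng.integers(0, 4))]
        else:
            alt = bases[(bases.index(ref) + int(rng.integers(1, 4))) % 4]
        bucket = rng.random()
        if bucket < 0.4:  # boundary stress
            depth = int(rng.integers(18, 24))
            qual = float(rng.integers(28, 34))
        elif bucket < 0.8:  # clear pass
            depth = int(rng.integers(40, 200))
            qual = float(rng.integers(50, 500))
        else:  # clear fail
            depth = int(rng.integers(0, 15))
            qual = float(rng.integers(0, 25))
        genotype = "hom_alt" if rng.random() < 0.7 else "het"
        rec = VariantRecord(
            chrom=chrom,
            pos=int(pos),
            ref=ref,
            alt=alt,
            depth=depth,
            qual=qual,
            genotype=genotype,
        )
        records.append(rec)
        if depth > 20 and qual > 30:
            pass_ids.append(i)
            if rec.vtype == "snv":
                n_snv_pass += 1
            else:
                n_indel_pass += 1

    manifest = {
        "seed": spec.seed,
        "n_records": len(records),
        "pass_indices": pass_ids,
        "n_pass": len(pass_ids),
        "n_snv_pass": n_snv_pass,
        "n_indel_pass": n_indel_pass,
        "region_bp": L,
    }
    fixture = VariantFixture(records=records, manifest=manifest)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fixture.vcf_path = out / "variants.vcf"
        gt = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1"}
        with open(fixture.vcf_path, "w") as fh:
            fh.write(_VCF_HEADER.format(chrom=chrom, length=L))
            for rec in records:
                fh.write(
                    f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t"
                    f"{rec.qual:g}\t.\tDP={rec.depth}\tGT\t{gt[rec.genotype]}\n"
                )
        with open(out / "variant_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    return fixture
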
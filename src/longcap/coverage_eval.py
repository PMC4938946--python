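"""Enrichment and depth-of-coverage statistics for a targeted region.

The headline statistic is the targeted-enrichment factor

    (reads on target / total mapped reads) / (target size / haploid genome size)

i.e. the fold over-representation of the target among mapped reads relative
to its share of the genome. The remaining operations summarize per-base depth
profiles: fraction of bases called, fractions above depth thresholds, audits
of depth at capture-primer sites and inter-primer midpoints, and the Pearson
correlation used to compare quantification vectors (qPCR copies, amplified
copies, sequencing depth).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .util import round_half_up

__all__ = [
    "EnrichmentInputs",
    "CoverageProfile",
    "SiteAudit",
    "ThresholdSummary",
    "read_depth_table",
    "enrichment_factor",
    "on_target_fraction",
    "fraction_called",
    "depth_threshold_fractions",
    "audit_sites",
    "pearson_correlation",
]


@dataclass
class EnrichmentInputs:
    """Read counts and sizes entering the enrichment formula."""

    reads_on_target: int
    reads_total_mapped: int
    target_size_bp: int
    haploid_genome_size_bp: float

    def __post_init__(self) -> None:
        if not 0 <= self.reads_on_target <= self.reads_total_mapped:
            raise ValueError("require 0 <= reads_on_target <= reads_total_mapped")
        if not 0 < self.target_size_bp <= self.haploid_genome_size_bp:
            raise ValueError("require 0 < target_size_bp <= haploid_genome_size_bp")


@dataclass
class CoverageProfile:
    """Per-base depth over a 0-based position grid."""

    positions: np.ndarray
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if len(self.positions) != len(self.depth):
            raise ValueError("positions and depth must align")
        if len(self.positions) == 0:
            raise ValueError("empty coverage profile")
        if np.any(self.depth < 0):
            raise ValueError("depths must be non-negative")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class SiteAudit:
    """Mean depth around a list of sites, with a below-threshold count."""

    site_positions: list[int]
    mean_depth_per_site: list[float]
    n_below_threshold: int

    def __post_init__(self) -> None:
        if len(self.site_positions) != len(self.mean_depth_per_site):
            raise ValueError("site lists must align")
        if self.n_below_threshold > len(self.site_positions):
            raise ValueError("below-threshold count exceeds site count")


@dataclass
class ThresholdSummary:
    fractions_pct: dict[int, float]
    mean_depth: float


def read_depth_table(
    path: str | Path, region_size_bp: int, start_position: int = 0
) -> CoverageProfile:
    """Read a per-base depth TSV into a dense profile.

    Accepts two columns (1-based position, depth) or three
    (chrom, 1-based position, depth) — the de-facto output of standard depth
    utilities. Positions absent from the file get depth 0 within the declared
    region of ``region_size_bp`` bases starting at ``start_position``.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == 2:
        pos, depth = df[0].to_numpy(), df[1].to_numpy()
    elif df.shape[1] >= 3:
        pos, depth = df[1].to_numpy(), df[2].to_numpy()
    else:
        raise ValueError("depth table needs 2 or 3 columns")
    pos0 = pos.astype(np.int64) - 1  # 1-based file -> 0-based grid
    grid = np.arange(start_position, start_position + region_size_bp, dtype=np.int64)
    dense = np.zeros(region_size_bp, dtype=np.int64)
    idx = pos0 - start_position
    if np.any((idx < 0) | (idx >= region_size_bp)):
        raise ValueError("depth table position outside declared region")
    dense[idx] = depth.astype(np.int64)
    return CoverageProfile(positions=grid, depth=dense)


def enrichment_factor(inputs: EnrichmentInputs) -> float:
    """Fold enrichment of the target among mapped reads."""
    on_frac = inputs.reads_on_target / inputs.reads_total_mapped
    size_frac = inputs.target_size_bp / inputs.haploid_genome_size_bp
    return on_frac / size_frac


def on_target_fraction(reads_on_target: int, reads_total_mapped: int) -> float:
    """Percent of mapped reads landing on the target."""
    if reads_total_mapped <= 0:
        raise ValueError("total mapped reads must be positive")
    if not 0 <= reads_on_target <= reads_total_mapped:
        raise ValueError("on-target reads out of range")
    return 100.0 * reads_on_target / reads_total_mapped


def fraction_called(bases_with_depth_ge1: int, region_size_bp: int) -> float:
    """Percent of region bases with at least one read (bases called)."""
    if region_size_bp <= 0:
        raise ValueError("region size must be positive")
    if not 0 <= bases_with_depth_ge1 <= region_size_bp:
        raise ValueError("called bases out of range")
    return 100.0 * bases_with_depth_ge1 / region_size_bp


def depth_threshold_fractions(
    profile: CoverageProfile, thresholds: Sequence[int]
) -> ThresholdSummary:
    """Percent of positions at or above each depth threshold, plus mean depth."""
    fractions = {
        int(t): 100.0 * float(np.mean(profile.depth >= int(t))) for t in thresholds
    }
    return ThresholdSummary(fractions_pct=fractions, mean_depth=float(np.mean(profile.depth)))


def audit_sites(
    profile: CoverageProfile,
    primer_positions: Sequence[int],
    window_bp: int = 100,
    threshold: int = 30,
) -> tuple[SiteAudit, SiteAudit]:
    """Mean depth around each primer site and each inter-primer midpoint.

    Averages depth over +/- ``window_bp`` at each primer position and at each
    midpoint ``floor((p1+p2)/2)`` between adjacent primers; windows running
    past the profile edge are truncated. Returns (primer audit, midpoint
    audit), each with the count of sites whose mean depth falls below
    ``threshold``.
    """
    positions = sorted(int(p) for p in primer_positions)
    grid0 = int(profile.positions[0])
    n = len(profile)
    if positions and (positions[0] < grid0 or positions[-1] >= grid0 + n):
        raise ValueError("primer positions outside profile")

    def mean_window(center: int) -> float:
        lo = max(center - window_bp - grid0, 0)
        hi = min(center + window_bp + 1 - grid0, n)
        return float(np.mean(profile.depth[lo:hi]))

    prim_means = [mean_window(p) for p in positions]
    midpoints = [(p1 + p2) // 2 for p1, p2 in zip(positions, positions[1:])]
    mid_means = [mean_window(m) for m in midpoints]
    prim_audit = SiteAudit(
        site_positions=positions,
        mean_depth_per_site=prim_means,
        n_below_threshold=sum(m < threshold for m in prim_means),
    )
    mid_audit = SiteAudit(
        site_positions=midpoints,
        mean_depth_per_site=mid_means,
        n_below_threshold=sum(m < threshold for m in mid_means),
    )
    return prim_audit, mid_audit


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson product-moment correlation coefficient."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if len(xa) != len(ya) or len(xa) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("degenerate (constant) vector")
    r, _ = stats.pearsonr(xa, ya)
    return float(r)


def report_value(x: float, ndigits: int) -> float:
    """Round half-up to a report's printed precision (full precision kept upstream)."""
    return round_half_up(x, ndigits)
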
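"""Tiling capture-primer design.

The target region is parsed into ``round(length / spacing)`` contiguous tiles
of near-equal size and one capture oligo is chosen per tile, as close to the
tile center as the constraints allow. Candidates must avoid masked bases,
satisfy GC and melting-temperature windows, show no strong hairpin or
self-dimer structure, and be unique against the background by exact k-mer
accounting on both strands. A final compatibility pass drops and replaces any
primer that would cross-dimerize with an already-accepted one, so the emitted
set is mutually compatible.

Screens are combinatorial (complementarity run lengths, k-mer counts) rather
than free-energy folding: they are deterministic, threshold-controlled, and
exactly checkable against exhaustive enumeration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Optional, Sequence

import numpy as np

from .genome_io import Interval, TargetRegion
from .thermo import melting_temperature
from .util import revcomp

__all__ = [
    "DesignParams",
    "Primer",
    "PrimerSet",
    "KmerIndex",
    "tile_region",
    "gc_content",
    "melting_temperature",
    "uniqueness_screen",
    "hairpin_screen",
    "cross_dimer_score",
    "mutual_three_prime_overlap",
    "design_primer_set",
]

_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _v in zip(b"ACGT", range(4)):
    _CODE_LUT[_b] = _v


@dataclass
class DesignParams:
    """Tunable constraints for capture-primer design.

    Defaults reflect a long-fragment capture design: ~8 kbp spacing between
    20-25 nt oligos at 58 +/- 3 C and 40-60 % GC in 50 mM monovalent salt at
    0.25 uM oligo, with uniqueness enforced by 16-mer counting and structure
    by complementarity-run thresholds.
    """

    spacing_bp: int = 8000
    primer_len_min: int = 20
    primer_len_max: int = 25
    gc_min: float = 0.40
    gc_max: float = 0.60
    tm_target_C: float = 58.0
    tm_tolerance_C: float = 3.0
    monovalent_mM: float = 50.0
    oligo_uM: float = 0.25
    uniqueness_k: int = 16
    max_kmer_hits: int = 1
    max_hairpin_stem: int = 4
    min_hairpin_loop: int = 3
    max_dimer_run: int = 8
    max_3prime_dimer_run: int = 4
    strand_policy: str = "plus"  # "plus" or "alternate"

    def __post_init__(self) -> None:
        if self.spacing_bp <= self.primer_len_max:
            raise ValueError("spacing_bp must exceed primer_len_max")
        if not 0 <= self.gc_min < self.gc_max <= 1:
            raise ValueError("require 0 <= gc_min < gc_max <= 1")
        if self.tm_tolerance_C <= 0:
            raise ValueError("tm_tolerance_C must be positive")
        if self.primer_len_min > self.primer_len_max or self.primer_len_min < 1:
            raise ValueError("invalid primer length bounds")
        if self.strand_policy not in ("plus", "alternate"):
            raise ValueError("strand_policy must be 'plus' or 'alternate'")


@dataclass
class Primer:
    """A capture oligo anchored on the target region.

    ``start``/``end`` are absolute 0-based half-open coordinates; ``sequence``
    is the oligo as synthesized (reverse-complemented relative to the region
    for minus-strand primers).
    """

    name: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    tm_C: float
    gc_fraction: float
    uniqueness_score: float
    structure_score: float

    def __init__(
        self,
        name: str,
        chrom: str,
        start: int,
        end: int,
        strand: str,
        sequence: str,
        tm_C: float,
        gc_fraction: float,
        uniqueness_score: float,
        structure_score: float,
        validate: bool = True,
    ) -> None:
        self.name = name
        self.chrom = chrom
        self.start = int(start)
        self.end = int(end)
        self.strand = strand
        self.sequence = sequence
        self.tm_C = float(tm_C)
        self.gc_fraction = float(gc_fraction)
        self.uniqueness_score = float(uniqueness_score)
        self.structure_score = float(structure_score)
        if validate:
            if self.end <= self.start:
                raise ValueError("primer end must exceed start")
            if len(self.sequence) != self.end - self.start:
                raise ValueError("primer sequence length != interval length")
            if self.strand not in "+-":
                raise ValueError("strand must be '+' or '-'")

    def __len__(self) -> int:
        return self.end - self.start

    def __eq__(self, other) -> bool:
        if not isinstance(other, Primer):
            return NotImplemented
        return (
            self.name == other.name
            and self.chrom == other.chrom
            and self.start == other.start
            and self.end == other.end
            and self.strand == other.strand
            and self.sequence == other.sequence
            and self.tm_C == other.tm_C
            and self.gc_fraction == other.gc_fraction
            and self.uniqueness_score == other.uniqueness_score
            and self.structure_score == other.structure_score
        )


@dataclass
class PrimerSet:
    """An ordered tiling primer set with per-tile bookkeeping.

    ``coverage_ratio`` is target length divided by the summed primer length —
    the factor by which the region outmeasures the synthesized oligo bases.
    """

    primers: list[Primer]
    tiles: list[Interval]
    unfilled_tiles: list[int]
    coverage_ratio: float

    def primer_bp_fraction(self) -> float:
        """Fraction of the target covered by primer bases (1/coverage_ratio)."""
        return 1.0 / self.coverage_ratio if self.coverage_ratio else float("inf")


def tile_region(region_length_bp: int, spacing_bp: int) -> list[Interval]:
    """Partition ``[0, region_length_bp)`` into ``round(length/spacing)`` tiles.

    Tiles are contiguous and balanced: lengths differ by at most 1 bp, longer
    tiles first. Rounding is half-up so tile counts are stable at .5
    boundaries.
    """
    if region_length_bp <= 0 or spacing_bp <= 0:
        raise ValueError("region length and spacing must be positive")
    n = max(1, int(region_length_bp / spacing_bp + 0.5))
    base, rem = divmod(region_length_bp, n)
    tiles: list[Interval] = []
    pos = 0
    for i in range(n):
        ln = base + (1 if i < rem else 0)
        tiles.append((pos, pos + ln))
        pos += ln
    return tiles


def gc_content(sequence: str) -> float:
    """G+C fraction of an unambiguous nucleotide sequence."""
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    if any(b not in "ACGT" for b in seq):
        raise ValueError("gc_content requires A/C/G/T only")
    return (seq.count("G") + seq.count("C")) / len(seq)


class KmerIndex:
    """Sorted-array index of all valid k-mers of a background sequence.

    K-mers overlapping non-ACGT bases are excluded. Counts are forward-strand;
    callers query the reverse complement separately for both-strand totals.
    """

    def __init__(self, sequence: str, k: int) -> None:
        if not 1 <= k <= 32:
            raise ValueError("k must be in [1, 32]")
        seq = sequence.upper()
        if len(seq) < k:
            raise ValueError("background shorter than k")
        self.k = k
        codes = _CODE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
        invalid = codes > 3
        codes64 = codes.astype(np.uint64)
        nw = len(seq) - k + 1
        vals = np.zeros(nw, dtype=np.uint64)
        for t in range(k):
            vals = (vals << np.uint64(2)) | codes64[t : t + nw]
        inv_cum = np.concatenate([[0], np.cumsum(invalid)])
        valid = (inv_cum[k:] - inv_cum[:-k]) == 0
        self._vals = np.sort(vals[valid])

    @staticmethod
    def encode(kmer: str) -> Optional[int]:
        val = 0
        for ch in kmer.upper():
            c = _CODE_LUT[ord(ch)]
            if c > 3:
                return None
            val = (val << 2) | int(c)
        return val

    def count(self, kmer: str) -> int:
        """Occurrences (overlapping allowed) of ``kmer`` on the forward strand."""
        if len(kmer) != self.k:
            raise ValueError("query length != k")
        v = self.encode(kmer)
        if v is None:
            return 0
        # a numpy scalar avoids the slow weak-promotion path on large arrays
        q = np.uint64(v)
        lo = int(np.searchsorted(self._vals, q, side="left"))
        hi = int(np.searchsorted(self._vals, q, side="right"))
        return hi - lo


def _occurrences(text: str, pattern: str) -> int:
    """Overlapping substring count."""
    count = start = 0
    while True:
        i = text.find(pattern, start)
        if i < 0:
            return count
        count += 1
        start = i + 1


class ScreenResult(NamedTuple):
    score: float
    passed: bool


def uniqueness_screen(
    candidate_sequence: str,
    background_sequence: str | None = None,
    k: int = 16,
    max_kmer_hits: int = 1,
    index: KmerIndex | None = None,
    exclude_self: bool = True,
) -> ScreenResult:
    """Exact k-mer accounting of a candidate against a background.

    The score is the maximum, over the candidate's k-mers, of the number of
    occurrences in the background counting both strands, excluding the
    candidate's own locus. Self-exclusion subtracts occurrences of each k-mer
    (and its reverse complement) within the candidate subsequence itself, which
    removes the candidate's own copy when it is present in the background
    exactly once. Pass iff score <= ``max_kmer_hits``.
    """
    cand = candidate_sequence.upper()
    if k > len(cand):
        raise ValueError("k exceeds candidate length")
    if index is None:
        if background_sequence is None:
            raise ValueError("provide background_sequence or a prebuilt index")
        index = KmerIndex(background_sequence, k)
    elif index.k != k:
        raise ValueError("index was built with a different k")
    score = 0
    for i in range(len(cand) - k + 1):
        km = cand[i : i + k]
        rc = revcomp(km)
        total = index.count(km) + index.count(rc)
        if exclude_self:
            total -= _occurrences(cand, km) + _occurrences(cand, rc)
        score = max(score, max(total, 0))
    return ScreenResult(float(score), score <= max_kmer_hits)


class HairpinResult(NamedTuple):
    stem: int
    passed: bool
    coords: Optional[tuple[int, int]]  # outermost paired positions (p, q)


def hairpin_screen(
    sequence: str, min_stem: int = 4, min_loop: int = 3
) -> HairpinResult:
    """Longest self-complementary stem separated by a loop of >= ``min_loop``.

    A stem of length s pairs ``seq[p : p+s]`` with the reverse complement of
    ``seq[q-s+1 : q+1]`` downstream; the unpaired loop between the stem halves
    must hold at least ``min_loop`` bases. Pass iff the longest stem is below
    ``min_stem``.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    n = len(seq)
    best, coords = 0, None
    for p in range(n):
        cp = seq[p]
        for q in range(n - 1, p, -1):
            if q - p - 1 < min_loop:
                break
            if comp.get(cp) != seq[q]:
                continue
            s = 0
            while p + s < q - s and comp.get(seq[p + s]) == seq[q - s]:
                s += 1
                if q - p - 2 * s + 1 >= min_loop and s > best:
                    best, coords = s, (p, q)
    return HairpinResult(best, best < min_stem, coords)


class DimerScore(NamedTuple):
    max_run: int
    max_3prime_run: int


def cross_dimer_score(sequence_a: str, sequence_b: str) -> DimerScore:
    """Longest Watson-Crick complementarity runs between two oligos.

    Considers every ungapped antiparallel alignment of ``a`` against ``b``
    (equivalently, common substrings of ``a`` and revcomp(``b``)).
    ``max_run`` is the longest run of consecutive paired bases anywhere;
    ``max_3prime_run`` is the longest run whose maximal extent includes the
    3'-terminal base of either oligo.
    """
    a = sequence_a.upper()
    rb = revcomp(sequence_b.upper())
    la, lb = len(a), len(rb)
    if la == 0 or lb == 0:
        raise ValueError("both sequences must be non-empty")
    best = best3 = 0
    for shift in range(-(lb - 1), la):
        run = 0
        anchored = False
        for j in range(max(0, -shift), lb):
            i = j + shift
            if i >= la:
                break
            if a[i] == rb[j]:
                if run == 0:
                    anchored = False
                run += 1
                # rb[0] is b's 3'-terminal base; a[la-1] is a's
                if i == la - 1 or j == 0:
                    anchored = True
                if run > best:
                    best = run
                if anchored and run > best3:
                    best3 = run
            else:
                run = 0
    return DimerScore(best, best3)


def mutual_three_prime_overlap(sequence_a: str, sequence_b: str) -> int:
    """Longest duplex in which BOTH oligos' 3'-terminal bases are paired.

    This is the canonical primer-dimer extension geometry: the 3' ends anneal
    to each other so each strand is extensible. Equals the longest r with
    ``a[-r:] == revcomp(b)[:r]`` (symmetric in a and b).
    """
    a = sequence_a.upper()
    rb = revcomp(sequence_b.upper())
    best = 0
    for r in range(1, min(len(a), len(rb)) + 1):
        if a[-r:] == rb[:r]:
            best = r
    return best


class _Candidate(NamedTuple):
    start: int  # region-local
    length: int
    sequence: str
    tm_C: float
    gc_fraction: float
    uniqueness_score: float
    structure_score: float


def _ranked_candidates(
    tile: Interval,
    seq: str,
    params: DesignParams,
    gc_cum: np.ndarray,
    blk_cum: np.ndarray,
    kindex: KmerIndex,
) -> Iterator[_Candidate]:
    """Yield constraint-passing candidates of a tile in selection order.

    Order: distance of the candidate midpoint from the tile center, then
    larger uniqueness pass margin, then smaller |Tm - target|, then leftmost
    start. Screens are evaluated lazily so callers that accept the first
    compatible candidate pay only for the candidates actually inspected.
    """
    t0, t1 = tile
    starts_all, lens_all = [], []
    for ln in range(params.primer_len_min, params.primer_len_max + 1):
        if t1 - t0 < ln:
            continue
        s = np.arange(t0, t1 - ln + 1, dtype=np.int64)
        starts_all.append(s)
        lens_all.append(np.full(len(s), ln, dtype=np.int64))
    if not starts_all:
        return
    starts = np.concatenate(starts_all)
    lens = np.concatenate(lens_all)

    blk = blk_cum[starts + lens] - blk_cum[starts]
    gcn = gc_cum[starts + lens] - gc_cum[starts]
    gcf = gcn / lens
    eps = 1e-12
    ok = (blk == 0) & (gcf >= params.gc_min - eps) & (gcf <= params.gc_max + eps)
    starts, lens, gcf = starts[ok], lens[ok], gcf[ok]
    if len(starts) == 0:
        return
    center = (t0 + t1) / 2.0
    dist = np.abs(starts + lens / 2.0 - center)
    order = np.lexsort((lens, starts, dist))

    i = 0
    while i < len(order):
        d0 = dist[order[i]]
        group: list[_Candidate] = []
        j = i
        while j < len(order) and dist[order[j]] == d0:
            idx = order[j]
            cand = _evaluate_candidate(
                int(starts[idx]), int(lens[idx]), float(gcf[idx]), seq, params, kindex
            )
            if cand is not None:
                group.append(cand)
            j += 1
        group.sort(
            key=lambda c: (
                -(params.max_kmer_hits - c.uniqueness_score),
                abs(c.tm_C - params.tm_target_C),
                c.start,
            )
        )
        yield from group
        i = j


def _evaluate_candidate(
    start: int,
    length: int,
    gcf: float,
    seq: str,
    params: DesignParams,
    kindex: KmerIndex,
) -> Optional[_Candidate]:
    sub = seq[start : start + length]
    tm = melting_temperature(sub, params.monovalent_mM, params.oligo_uM)
    if abs(tm - params.tm_target_C) > params.tm_tolerance_C:
        return None
    hp = hairpin_screen(sub, params.max_hairpin_stem, params.min_hairpin_loop)
    if not hp.passed:
        return None
    sd = cross_dimer_score(sub, sub)
    if sd.max_run > params.max_dimer_run:
        return None
    if mutual_three_prime_overlap(sub, sub) > params.max_3prime_dimer_run:
        return None
    uq = uniqueness_screen(
        sub,
        k=params.uniqueness_k,
        max_kmer_hits=params.max_kmer_hits,
        index=kindex,
        exclude_self=True,
    )
    if not uq.passed:
        return None
    return _Candidate(
        start=start,
        length=length,
        sequence=sub,
        tm_C=tm,
        gc_fraction=gcf,
        uniqueness_score=uq.score,
        structure_score=float(max(hp.stem, sd.max_run)),
    )


def _compatible(
    sequence: str,
    params: DesignParams,
    accepted_run_kmers: set[str],
    accepted_3p_prefixes: set[str],
) -> bool:
    """Cross-dimer compatibility of a candidate against all accepted primers.

    Incompatible iff the candidate shares a complementarity run longer than
    ``max_dimer_run`` with any accepted primer, or forms a mutual 3'-overlap
    duplex longer than ``max_3prime_dimer_run`` with one. Both checks reduce
    to membership of candidate substrings in precomputed sets over the
    reverse complements of accepted primers, so the pass stays O(set size)
    rather than all-pairs rescoring.
    """
    run_k = params.max_dimer_run + 1
    for i in range(len(sequence) - run_k + 1):
        if sequence[i : i + run_k] in accepted_run_kmers:
            return False
    for r in range(params.max_3prime_dimer_run + 1, len(sequence) + 1):
        if sequence[-r:] in accepted_3p_prefixes:
            return False
    return True


def design_primer_set(
    region: TargetRegion,
    params: DesignParams | None = None,
    seed: int = 0,
) -> PrimerSet:
    """Design one mutually compatible capture primer per tile of ``region``.

    Fully deterministic for a given (region, params): tiles are processed left
    to right and each takes its best-ranked candidate that is cross-dimer
    compatible with everything accepted so far (drop-and-replace). Tiles with
    no surviving candidate are reported in ``unfilled_tiles``. ``seed`` is
    accepted for interface symmetry with the stochastic modules; the procedure
    involves no randomness.
    """
    del seed  # deterministic procedure
    if params is None:
        params = DesignParams()
    L = len(region)
    if L < params.spacing_bp:
        raise ValueError("region shorter than one tile")
    tiles = tile_region(L, params.spacing_bp)
    seq = region.sequence

    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    gc = ((arr == ord("G")) | (arr == ord("C"))).astype(np.int64)
    gc_cum = np.concatenate([[0], np.cumsum(gc)])
    blocked = region.local_mask(include_n=True)
    blk_cum = np.concatenate([[0], np.cumsum(blocked.astype(np.int64))])
    kindex = KmerIndex(seq, params.uniqueness_k)

    accepted: list[Primer] = []
    unfilled: list[int] = []
    accepted_run_kmers: set[str] = set()
    accepted_3p_prefixes: set[str] = set()
    run_k = params.max_dimer_run + 1

    for ti, tile in enumerate(tiles):
        chosen: Optional[_Candidate] = None
        for cand in _ranked_candidates(tile, seq, params, gc_cum, blk_cum, kindex):
            if _compatible(
                cand.sequence, params, accepted_run_kmers, accepted_3p_prefixes
            ):
                chosen = cand
                break
        if chosen is None:
            unfilled.append(ti)
            continue
        strand = "+"
        oligo = chosen.sequence
        if params.strand_policy == "alternate" and ti % 2 == 1:
            strand = "-"
            oligo = revcomp(oligo)
        primer = Primer(
            name=f"{region.name}_p{ti + 1:04d}",
            chrom=region.chrom,
            start=region.start + chosen.start,
            end=region.start + chosen.start + chosen.length,
            strand=strand,
            sequence=oligo,
            tm_C=chosen.tm_C,
            gc_fraction=chosen.gc_fraction,
            uniqueness_score=chosen.uniqueness_score,
            structure_score=chosen.structure_score,
        )
        accepted.append(primer)
        rc = revcomp(oligo)
        for i in range(len(rc) - run_k + 1):
            accepted_run_kmers.add(rc[i : i + run_k])
        for r in range(params.max_3prime_dimer_run + 1, len(rc) + 1):
            accepted_3p_prefixes.add(rc[:r])

    total_bp = sum(len(p) for p in accepted)
    coverage_ratio = L / total_bp if total_bp else float("inf")
    if total_bp and coverage_ratio <= 300:
        warnings.warn(
            f"target-to-primer coverage ratio {coverage_ratio:.1f} <= 300; "
            "the primer set is denser than a long-fragment capture design "
            "normally needs",
            stacklevel=2,
        )
    return PrimerSet(
        primers=accepted,
        tiles=tiles,
        unfilled_tiles=unfilled,
        coverage_ratio=coverage_ratio,
    )
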
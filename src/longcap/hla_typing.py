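"""Consensus-based HLA allele typing.

A per-locus consensus sequence (majority base per pileup column) is aligned
globally against every allele of that locus in an IMGT-style database with
the Needleman-Wunsch algorithm under linear gap penalties; the highest-scoring
allele is the call, reported with the percent identity of the winning
alignment. Ambiguous consensus positions (low depth or exact count ties) are
emitted as N, which never matches an allele base: N columns stay in the
identity denominator but cannot enter the numerator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "PileupColumn",
    "AlleleDatabase",
    "AlignmentResult",
    "TypingResult",
    "consensus_from_pileup",
    "global_align",
    "call_allele",
    "read_pileup_tsv",
]

_BASES = ("A", "C", "G", "T")


@dataclass
class PileupColumn:
    """Base counts observed at one reference position."""

    position: int
    counts: dict[str, int]  # keys: A, C, G, T, gap
    depth: int = field(init=False)

    def __post_init__(self) -> None:
        for key in ("A", "C", "G", "T", "gap"):
            self.counts.setdefault(key, 0)
            if self.counts[key] < 0:
                raise ValueError("negative base count")
        extra = set(self.counts) - {"A", "C", "G", "T", "gap"}
        if extra:
            raise ValueError(f"unexpected count keys: {sorted(extra)}")
        self.depth = sum(self.counts.values())


def consensus_from_pileup(
    columns: Sequence[PileupColumn], min_depth: int = 1
) -> str:
    """Majority-vote consensus over ordered pileup columns.

    Per column: depth below ``min_depth`` or an exact tie for the top count
    emits N; a gap majority emits nothing (deletion); otherwise the majority
    base is emitted.
    """
    if not columns:
        raise ValueError("empty pileup")
    if any(
        b.position < a.position for a, b in zip(columns, columns[1:])
    ):
        raise ValueError("pileup columns must be ordered by position")
    out: list[str] = []
    for col in columns:
        if col.depth < min_depth:
            out.append("N")
            continue
        items = [(col.counts[k], k) for k in ("A", "C", "G", "T", "gap")]
        top = max(c for c, _ in items)
        winners = [k for c, k in items if c == top]
        if len(winners) > 1:
            out.append("N")
        elif winners[0] == "gap":
            continue
        else:
            out.append(winners[0])
    return "".join(out)


def read_pileup_tsv(path: str | Path) -> list[PileupColumn]:
    """Read per-position base counts: position, A, C, G, T, gap (TSV)."""
    cols: list[PileupColumn] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("position"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns")
            pos = int(fields[0])
            a, c, g, t, gap = (int(x) for x in fields[1:6])
            cols.append(
                PileupColumn(pos, {"A": a, "C": c, "G": g, "T": t, "gap": gap})
            )
    return cols


_ALLELE_RE = re.compile(r"(?P<locus>[A-Z0-9]+)\*[\d:A-Z]+")


def normalize_locus(locus: str) -> str:
    return locus.upper().removeprefix("HLA-")


@dataclass
class AlleleDatabase:
    """Per-locus map of allele name to sequence."""

    loci: dict[str, dict[str, str]]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "AlleleDatabase":
        """Parse an IMGT-style allele FASTA.

        Headers look like ``HLA:HLA00001 A*01:01:01:01 3503 bp``; the locus is
        the token before '*' in the allele name. Headers carrying only an
        allele name are accepted too.
        """
        loci: dict[str, dict[str, str]] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            name = None
            for token in rec.description.split():
                if _ALLELE_RE.fullmatch(token):
                    name = token
                    break
            if name is None:
                name = rec.id
            m = _ALLELE_RE.fullmatch(name)
            locus = normalize_locus(m.group("locus")) if m else rec.id
            seq = str(rec.seq).upper()
            if not seq:
                raise ValueError(f"empty sequence for allele {name}")
            bucket = loci.setdefault(locus, {})
            if name in bucket:
                raise ValueError(f"duplicate allele name {name} in locus {locus}")
            bucket[name] = seq
        return cls(loci=loci)

    def alleles(self, locus: str) -> dict[str, str]:
        key = normalize_locus(locus)
        if key not in self.loci or not self.loci[key]:
            raise KeyError(f"locus {locus!r} not in database")
        return self.loci[key]


@dataclass
class AlignmentResult:
    score: float
    percent_identity: float
    aligned_a: str
    aligned_b: str


def _nw_matrix(
    a: str, b: str, match: float, mismatch: float, gap: float
) -> np.ndarray:
    """Full global-alignment score matrix (linear gap penalty), row-vectorized.

    Within a row the left-dependency H[i,j] = max(M[j], H[i,j-1]+gap) unrolls
    to a prefix maximum of M[k]-gap*k, which numpy can accumulate, so the DP
    is O(n) vectorized row operations instead of O(n*m) Python steps.
    """
    n, m = len(a), len(b)
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    H = np.empty((n + 1, m + 1), dtype=np.float64)
    H[0, :] = gap * np.arange(m + 1)
    jgap = gap * np.arange(m + 1)
    for i in range(1, n + 1):
        eq = bv == av[i - 1]
        if av[i - 1] == ord("N"):
            eq = np.zeros(m, dtype=bool)
        else:
            eq = eq & (bv != ord("N"))
        s = np.where(eq, match, mismatch)
        M = np.maximum(H[i - 1, :m] + s, H[i - 1, 1:] + gap)  # diag, up for j=1..m
        # candidates B[j] = max over k<=j of (source - gap*k); boundary enters at k=0
        B = np.empty(m + 1)
        B[0] = gap * i  # H[i,0]
        B[1:] = M - jgap[1:]
        np.maximum.accumulate(B, out=B)
        H[i, :] = B + jgap
    return H


def global_align(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -1.0,
) -> AlignmentResult:
    """Optimal Needleman-Wunsch global alignment with linear gap penalty.

    Traceback is deterministic with tie preference diagonal, then up (gap in
    b), then left (gap in a). Percent identity is matches over alignment
    columns times 100; N matches nothing.
    """
    a, b = seq_a.upper(), seq_b.upper()
    if not a or not b:
        raise ValueError("both sequences must be non-empty")
    H = _nw_matrix(a, b, match, mismatch, gap)
    # deterministic traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = len(a), len(b)
    matches = 0
    while i > 0 or j > 0:
        here = H[i, j]
        if i > 0 and j > 0:
            is_match = a[i - 1] == b[j - 1] and a[i - 1] != "N" and b[j - 1] != "N"
            s = match if is_match else mismatch
            if here == H[i - 1, j - 1] + s:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                matches += is_match
                i -= 1
                j -= 1
                continue
        if i > 0 and here == H[i - 1, j] + gap:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
            continue
        out_a.append("-")
        out_b.append(b[j - 1])
        j -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    ncols = len(aligned_a)
    return AlignmentResult(
        score=float(H[len(a), len(b)]),
        percent_identity=100.0 * matches / ncols,
        aligned_a=aligned_a,
        aligned_b=aligned_b,
    )


def nw_score(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -1.0,
) -> float:
    """Alignment score only (no traceback storage beyond two rows)."""
    a, b = seq_a.upper(), seq_b.upper()
    if not a or not b:
        raise ValueError("both sequences must be non-empty")
    m = len(b)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    jgap = gap * np.arange(m + 1)
    prev = gap * np.arange(m + 1)
    for i, ch in enumerate(a, 1):
        if ch == "N":
            eq = np.zeros(m, dtype=bool)
        else:
            eq = (bv == ord(ch)) & (bv != ord("N"))
        s = np.where(eq, match, mismatch)
        M = np.maximum(prev[:m] + s, prev[1:] + gap)
        B = np.empty(m + 1)
        B[0] = gap * i
        B[1:] = M - jgap[1:]
        np.maximum.accumulate(B, out=B)
        prev = B + jgap
    return float(prev[m])


@dataclass
class TypingResult:
    locus: str
    best_allele: str
    alignment_score: float
    percent_identity: float
    runner_up: Optional[str]
    runner_up_score: Optional[float]

    def __post_init__(self) -> None:
        if self.runner_up_score is not None and (
            self.alignment_score < self.runner_up_score
        ):
            raise ValueError("best score must be >= runner-up score")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("identity must be a percentage")


def call_allele(
    consensus: str,
    database: AlleleDatabase,
    locus: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -1.0,
) -> TypingResult:
    """Best-scoring allele of ``locus`` for the consensus sequence.

    Score ties break toward higher percent identity, then the
    lexicographically smallest allele name. The runner-up (second in the same
    ordering) is reported with its score.
    """
    if not consensus:
        raise ValueError("empty consensus sequence")
    alleles = database.alleles(locus)
    scores = {
        name: nw_score(consensus, seq, match, mismatch, gap)
        for name, seq in alleles.items()
    }
    best_score = max(scores.values())
    tied = sorted(name for name, s in scores.items() if s == best_score)
    if len(tied) > 1:
        idents = {
            name: global_align(consensus, alleles[name], match, mismatch, gap)
            for name in tied
        }
        tied.sort(key=lambda name: (-idents[name].percent_identity, name))
        best = tied[0]
        best_aln = idents[best]
    else:
        best = tied[0]
        best_aln = global_align(consensus, alleles[best], match, mismatch, gap)
    ranked = sorted(
        (name for name in scores if name != best),
        key=lambda name: (-scores[name], name),
    )
    runner = ranked[0] if ranked else None
    return TypingResult(
        locus=normalize_locus(locus),
        best_allele=best,
        alignment_score=best_score,
        percent_identity=best_aln.percent_identity,
        runner_up=runner,
        runner_up_score=scores[runner] if runner else None,
    )
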
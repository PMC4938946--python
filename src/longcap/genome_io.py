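"""Readers/writers for the formats the toolkit touches, plus the target-region container.

Coordinate conventions
----------------------
Everything internal is 0-based, half-open — the BED convention. FASTA headers
written by this package additionally carry 1-based inclusive display
coordinates (``chrom:start-end``) for human readability, and such headers are
parsed back on read. Soft-masked (lowercase) FASTA letters are treated as
repeat-masked; the stored sequence is always uppercase.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .util import VALID_BASES

Interval = tuple[int, int]

_HEADER_COORDS = re.compile(r"^(?P<chrom>[^\s:]+):(?P<start>\d+)-(?P<end>\d+)$")

PRIMER_TSV_COLUMNS = [
    "name",
    "chrom",
    "start",
    "end",
    "strand",
    "sequence",
    "tm_C",
    "gc_fraction",
    "uniqueness_score",
    "structure_score",
]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Normalize a set of half-open intervals: sort, merge overlapping/abutting.

    Idempotent; the result covers exactly the boolean union of the inputs.
    """
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[Interval] = []
    for s, e in ivs:
        if e < s:
            raise ValueError(f"interval end before start: ({s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class MaskedBase:
    """A single masked position with the reason it is off-limits for design."""

    position: int
    reason: str  # "repeat" or "snp"

    def __post_init__(self) -> None:
        if self.reason not in ("repeat", "snp"):
            raise ValueError(f"unknown mask reason {self.reason!r}")


@dataclass
class TargetRegion:
    """A named sequence interval with repeat and SNP masks.

    ``start``/``end`` are 0-based half-open coordinates on ``chrom``; mask
    intervals are expressed in the same (absolute) frame and are normalized
    (merged, sorted) on construction. ``sequence`` is uppercase and has length
    ``end - start``.
    """

    name: str
    chrom: str
    start: int
    end: int
    sequence: str
    repeat_mask: list[Interval] = field(default_factory=list)
    snp_mask: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"sequence length {len(self.sequence)} != end-start "
                f"{self.end - self.start}"
            )
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(f"sequence contains invalid characters: {sorted(bad)}")
        self.sequence = self.sequence.upper()
        for attr in ("repeat_mask", "snp_mask"):
            merged = merge_intervals(getattr(self, attr))
            for s, e in merged:
                if s < self.start or e > self.end:
                    raise ValueError(
                        f"{attr} interval ({s}, {e}) outside region "
                        f"[{self.start}, {self.end})"
                    )
            setattr(self, attr, merged)

    def __len__(self) -> int:
        return self.end - self.start

    def local_mask(self, include_n: bool = True):
        """Boolean array over region-local coordinates: True = unusable base.

        Combines repeat mask, SNP mask and (optionally) N bases.
        """
        import numpy as np

        blocked = np.zeros(len(self), dtype=bool)
        for s, e in self.repeat_mask + self.snp_mask:
            blocked[s - self.start : e - self.start] = True
        if include_n:
            seq = np.frombuffer(self.sequence.encode(), dtype=np.uint8)
            blocked |= seq == ord("N")
        return blocked

    def masked_bases(self) -> list[MaskedBase]:
        out = []
        for s, e in self.repeat_mask:
            out.extend(MaskedBase(p, "repeat") for p in range(s, e))
        for s, e in self.snp_mask:
            out.extend(MaskedBase(p, "snp") for p in range(s, e))
        return sorted(out, key=lambda m: (m.position, m.reason))


def _read_bed(path: str | Path, chrom: str, lo: int, hi: int) -> list[Interval]:
    ivs: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has <3 columns")
            c, s, e = fields[0], int(fields[1]), int(fields[2])
            if c != chrom:
                continue
            if s < lo or e > hi:
                raise ValueError(
                    f"{path}:{lineno}: interval ({s}, {e}) outside region "
                    f"[{lo}, {hi})"
                )
            ivs.append((s, e))
    return ivs


def read_region(
    fasta_path: str | Path,
    repeat_bed_paths: Sequence[str | Path] = (),
    snp_bed_paths: Sequence[str | Path] = (),
    record_name: str | None = None,
) -> TargetRegion:
    """Load a target region from FASTA plus optional BED masks.

    The FASTA must contain exactly one record unless ``record_name`` selects
    one. Lowercase letters are soft-masked repeats and are added to the repeat
    mask. A header of the form ``name chrom:start-end`` (1-based inclusive
    display coordinates) anchors the region on its chromosome; otherwise the
    region starts at 0 on a chromosome named after the record id.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {fasta_path}")
    if record_name is not None:
        matches = [r for r in records if r.id == record_name]
        if not matches:
            raise ValueError(f"record {record_name!r} not found in {fasta_path}")
        record = matches[0]
    elif len(records) == 1:
        record = records[0]
    else:
        raise ValueError(
            f"{fasta_path} holds {len(records)} records; pass record_name"
        )

    raw = str(record.seq)
    bad = set(raw) - VALID_BASES
    if bad:
        raise ValueError(f"invalid sequence characters: {sorted(bad)}")

    chrom, start = record.id, 0
    parts = record.description.split()
    for token in parts[1:]:
        m = _HEADER_COORDS.match(token)
        if m:
            chrom = m.group("chrom")
            start = int(m.group("start")) - 1  # display coords are 1-based
            break
    end = start + len(raw)

    # soft-mask -> repeat intervals
    soft: list[Interval] = []
    run_start = None
    for i, ch in enumerate(raw):
        low = ch.islower()
        if low and run_start is None:
            run_start = i
        elif not low and run_start is not None:
            soft.append((start + run_start, start + i))
            run_start = None
    if run_start is not None:
        soft.append((start + run_start, start + len(raw)))

    repeat = list(soft)
    for p in repeat_bed_paths:
        repeat.extend(_read_bed(p, chrom, start, end))
    snp: list[Interval] = []
    for p in snp_bed_paths:
        snp.extend(_read_bed(p, chrom, start, end))

    return TargetRegion(
        name=record.id,
        chrom=chrom,
        start=start,
        end=end,
        sequence=raw.upper(),
        repeat_mask=repeat,
        snp_mask=snp,
    )


def write_region(region: TargetRegion, fasta_path: str | Path) -> None:
    """Write a region as soft-masked FASTA with display coordinates in the header."""
    seq = list(region.sequence)
    for s, e in region.repeat_mask:
        for i in range(s - region.start, e - region.start):
            seq[i] = seq[i].lower()
    header = f">{region.name} {region.chrom}:{region.start + 1}-{region.end}"
    with open(fasta_path, "w") as fh:
        fh.write(header + "\n")
        body = "".join(seq)
        for i in range(0, len(body), 80):
            fh.write(body[i : i + 80] + "\n")


def write_primers(primers: Sequence, path: str | Path, fmt: str = "tsv") -> None:
    """Write a primer collection as TSV, BED or FASTA.

    TSV carries every field and is the lossless round-trip format; BED carries
    coordinates/name/strand; FASTA carries name and sequence. An empty primer
    collection yields a header-only (or empty) file, not an error.
    """
    if fmt not in ("tsv", "bed", "fasta"):
        raise ValueError(f"unknown format {fmt!r}")
    path = Path(path)
    if fmt == "tsv":
        rows = [
            {
                "name": p.name,
                "chrom": p.chrom,
                "start": p.start,
                "end": p.end,
                "strand": p.strand,
                "sequence": p.sequence,
                "tm_C": repr(float(p.tm_C)),
                "gc_fraction": repr(float(p.gc_fraction)),
                "uniqueness_score": repr(float(p.uniqueness_score)),
                "structure_score": repr(float(p.structure_score)),
            }
            for p in primers
        ]
        df = pd.DataFrame(rows, columns=PRIMER_TSV_COLUMNS)
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "bed":
        with open(path, "w") as fh:
            for p in primers:
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t0\t{p.strand}\n"
                )
    else:  # fasta
        with open(path, "w") as fh:
            for p in primers:
                fh.write(f">{p.name} {p.chrom}:{p.start + 1}-{p.end}({p.strand})\n")
                fh.write(p.sequence + "\n")


def read_primers(path: str | Path, fmt: str = "tsv"):
    """Read primers back from a file written by :func:`write_primers`."""
    from .primer_design import Primer

    path = Path(path)
    primers = []
    if fmt == "tsv":
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={"name": str, "chrom": str, "sequence": str, "strand": str},
            float_precision="round_trip",
        )
        for row in df.itertuples(index=False):
            primers.append(
                Primer(
                    name=row.name,
                    chrom=row.chrom,
                    start=int(row.start),
                    end=int(row.end),
                    strand=row.strand,
                    sequence=row.sequence,
                    tm_C=float(row.tm_C),
                    gc_fraction=float(row.gc_fraction),
                    uniqueness_score=float(row.uniqueness_score),
                    structure_score=float(row.structure_score),
                )
            )
    elif fmt == "bed":
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                c, s, e, name, _score, strand = line.rstrip("\n").split("\t")[:6]
                primers.append(
                    Primer(
                        name=name,
                        chrom=c,
                        start=int(s),
                        end=int(e),
                        strand=strand,
                        sequence="N" * (int(e) - int(s)),
                        tm_C=0.0,
                        gc_fraction=0.0,
                        uniqueness_score=0.0,
                        structure_score=0.0,
                        validate=False,
                    )
                )
    elif fmt == "fasta":
        for rec in SeqIO.parse(str(path), "fasta"):
            primers.append(
                Primer(
                    name=rec.id,
                    chrom=rec.id,
                    start=0,
                    end=len(rec.seq),
                    strand="+",
                    sequence=str(rec.seq),
                    tm_C=0.0,
                    gc_fraction=0.0,
                    uniqueness_score=0.0,
                    structure_score=0.0,
                    validate=False,
                )
            )
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return primers
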
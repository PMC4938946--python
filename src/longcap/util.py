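"""Small shared helpers: strand arithmetic and report rounding."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = set("ACGTNacgtn")


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, as printed reports conventionally do.

    Python's built-in round() uses banker's rounding; report tables round
    half-up, so 82.65 -> 82.7 and 9302.5 -> 9303.
    """
    q = Decimal(1).scaleb(-ndigits)
    v = float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
    return v if ndigits > 0 else float(int(v))
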
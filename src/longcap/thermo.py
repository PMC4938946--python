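"""Nearest-neighbor duplex melting temperature (SantaLucia 1998 unified parameters).

The two-state model sums dinucleotide-step enthalpies and entropies with
terminal-initiation terms and predicts

    Tm = dH / (dS + R * ln(C/4)) - 273.15

for a non-self-complementary oligo at total strand concentration C (mol/L).
Monovalent salt enters through the entropic correction
``dS += 0.368 * (N - 1) * ln[Na+]`` with N the oligo length in bases, which is
the correction published alongside the unified parameter set.
"""

from __future__ import annotations

import math

R_CAL = 1.987  # gas constant, cal / (mol K)

# Unified NN parameters: dH in kcal/mol, dS in cal/(mol K), keyed by the
# 5'->3' dinucleotide on the top strand. Reverse-complement steps share values.
NN_DH_DS: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2),
    "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
    "CC": (-8.0, -19.9),
}

# Terminal initiation terms by terminal base identity.
INIT_GC = (0.1, -2.8)
INIT_AT = (2.3, 4.1)


def duplex_dh_ds(sequence: str) -> tuple[float, float]:
    """Total (dH kcal/mol, dS cal/mol/K) for the perfect duplex of ``sequence``."""
    seq = sequence.upper()
    if any(b not in "ACGT" for b in seq):
        raise ValueError("melting temperature requires unambiguous A/C/G/T sequence")
    dh, ds = 0.0, 0.0
    for terminal in (seq[0], seq[-1]):
        h, s = INIT_GC if terminal in "GC" else INIT_AT
        dh += h
        ds += s
    for i in range(len(seq) - 1):
        h, s = NN_DH_DS[seq[i : i + 2]]
        dh += h
        ds += s
    return dh, ds


def melting_temperature(
    sequence: str, monovalent_mM: float = 50.0, oligo_uM: float = 0.25
) -> float:
    """Predicted duplex Tm in degrees Celsius.

    Parameters
    ----------
    sequence : 8-60 nt, A/C/G/T only.
    monovalent_mM : total monovalent cation concentration (Na+ equivalents).
    oligo_uM : total oligonucleotide strand concentration.
    """
    seq = sequence.upper()
    if not 8 <= len(seq) <= 60:
        raise ValueError("sequence length must be in [8, 60] nt")
    if monovalent_mM <= 0 or oligo_uM <= 0:
        raise ValueError("concentrations must be positive")
    dh, ds = duplex_dh_ds(seq)
    ds += 0.368 * (len(seq) - 1) * math.log(monovalent_mM / 1000.0)
    c_quarter = oligo_uM * 1e-6 / 4.0
    tm_K = dh * 1000.0 / (ds + R_CAL * math.log(c_quarter))
    return tm_K - 273.15
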
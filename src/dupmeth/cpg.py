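"""CpG observed/expected ratio of promoter sequences.

Methylated cytosines deaminate to thymine at an elevated rate, so a
promoter's historical methylation leaves a footprint: fewer CpG
dinucleotides than its C and G content would predict. CpG_o/e quantifies
that depletion as the observed CpG dinucleotide frequency divided by the
expected frequency (the product of the C and G mononucleotide
frequencies).
"""

from __future__ import annotations

import math

VALID_BASES = set("ACGTN")


def cpg_oe(sequence: str, convention: str = "length_adjusted") -> float | None:
    """CpG observed/expected ratio of a DNA sequence.

    With the default ``length_adjusted`` convention, dinucleotide
    frequency uses denominator L' - 1 and mononucleotide frequencies L'
    (L' = number of non-N bases):

        CpG_o/e = (n_CpG / (L' - 1)) / ((n_C / L') * (n_G / L'))

    The ``simple`` convention is the other form common in the literature,
    L' * n_CpG / (n_C * n_G). Case-insensitive; N bases are excluded from
    all counts and an N interrupts any CpG spanning it. Returns None
    (undefined) when n_C = 0, n_G = 0, or L' < 2; returns 0.0 when the
    sequence has C and G but no CpG.
    """
    if convention not in ("length_adjusted", "simple"):
        raise ValueError(f"unknown convention {convention!r}")
    seq = sequence.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"invalid symbols in sequence: {sorted(bad)}")

    n_c = seq.count("C")
    n_g = seq.count("G")
    n_cpg = seq.count("CG")
    effective_len = len(seq) - seq.count("N")
    if effective_len < 2 or n_c == 0 or n_g == 0:
        return None
    if convention == "length_adjusted":
        value = (n_cpg / (effective_len - 1)) / ((n_c / effective_len) * (n_g / effective_len))
    else:
        value = effective_len * n_cpg / (n_c * n_g)
    assert value >= 0 and math.isfinite(value)
    return value


def cpg_oe_table(
    sequences: dict[str, str], convention: str = "length_adjusted"
) -> dict[str, float | None]:
    """CpG_o/e per sequence id; undefined values kept as None."""
    return {name: cpg_oe(seq, convention) for name, seq in sequences.items()}
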
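"""Small shared helpers: DNA alphabet, IUPAC codes, report rounding."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

DNA = "ACGT"

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# degenerate code for each non-empty base set
IUPAC_FOR_SET = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}
SET_FOR_IUPAC = {code: s for s, code in IUPAC_FOR_SET.items()}


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_up(x, ndigits: int = 1) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(n: int, d: int, ndigits: int = 1) -> float:
    """Percentage n/d rounded half-up, exact in Decimal arithmetic.

    Report tables round half-up so that printed percentages are reproducible
    from the counts (e.g. 84/88 -> 95.5).
    """
    if d == 0:
        return 0.0
    q = Decimal(1).scaleb(-ndigits) if ndigits > 0 else Decimal(1)
    val = (Decimal(int(n)) * 100 / Decimal(int(d))).quantize(
        q, rounding=ROUND_HALF_UP)
    return float(val)
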
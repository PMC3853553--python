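"""Small shared helpers: reverse complement, mismatch counting, rounding."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: unambiguous DNA letters; N never counts as a match anywhere in the package
DNA_LETTERS = frozenset("ACGT")

_IS_ACGT = np.zeros(256, dtype=bool)
_IS_ACGT[[ord(c) for c in "ACGT"]] = True


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def mismatches(a: str, b: str) -> int:
    """Number of mismatching positions between equal-length strings.

    N (or any non-ACGT letter) matches nothing, including another N.
    """
    if len(a) != len(b):
        raise ValueError("mismatches() requires equal-length strings")
    xa = np.frombuffer(a.encode(), dtype=np.uint8)
    xb = np.frombuffer(b.encode(), dtype=np.uint8)
    matches = int(((xa == xb) & _IS_ACGT[xa]).sum())
    return len(a) - matches


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention of printed tables).

    Returns an int when ndigits == 0.
    """
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return int(d) if ndigits == 0 else float(d)
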
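"""Small shared helpers."""

from __future__ import annotations

import math

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_away(x: float, ndigits: int = 0) -> float | int:
    """Round with ties going away from zero (report convention).

    Python's built-in ``round`` uses banker's rounding, which would turn
    12.5% into 12%; printed report percentages expect 13%.
    """
    q = 10.0**ndigits
    v = x * q
    if v >= 0:
        r = math.floor(v + 0.5)
    else:
        r = math.ceil(v - 0.5)
    return int(r) if ndigits <= 0 else r / q
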
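"""Small shared helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero, avoiding binary-float surprises.

    Percent summaries are reported to one decimal; ``round()``'s banker
    rounding on the nearest binary float would occasionally differ from the
    conventional hand-rounded value.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
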
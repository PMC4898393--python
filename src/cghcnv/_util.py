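"""Small shared helpers."""
from __future__ import annotations

import decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (not banker's rounding).

    Report percentages in the pipeline use conventional half-up rounding.
    """
    q = decimal.Decimal(10) ** -ndigits
    d = decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d) if ndigits > 0 else float(int(d))
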
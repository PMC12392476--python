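"""Small shared numeric helpers."""

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero.

    Display values in rule tables are conventionally printed to two
    decimals with half-up rounding (so a raw lift of 1.125 prints as
    1.13, not the banker's-rounded 1.12 that ``round`` would give).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
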
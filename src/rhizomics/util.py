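"""Small shared numeric helpers."""

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "count_percentage"]


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (half-up), not banker's rounding.

    Printed percentages in genome-mosaicism tables conventionally use
    half-up rounding (e.g. 506/935 -> 54.12), which differs from Python's
    built-in ``round`` on exact ties.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def count_percentage(count: int, total: int, ndigits: int = 2) -> float:
    """Exact ``100 * count / total`` rounded half-up to `ndigits` decimals.

    Works on the integer ratio so no binary floating-point error can leak
    into the rounding decision.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    q = Decimal(1).scaleb(-ndigits)
    return float((Decimal(count) * 100 / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP))
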
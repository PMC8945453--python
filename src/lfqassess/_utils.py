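"""Small shared numerical helpers."""

from __future__ import annotations

import datetime as _dt
from decimal import Decimal, ROUND_HALF_UP


def fractional_year(date: _dt.date) -> float:
    """Convert a calendar date to a decimal year.

    Uses the day-of-year divided by the actual year length, so monthly
    sampling dates map to strictly increasing decimal years.
    """
    start = _dt.date(date.year, 1, 1)
    end = _dt.date(date.year + 1, 1, 1)
    return date.year + (date - start).days / (end - start).days


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, matching printed-table conventions."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
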
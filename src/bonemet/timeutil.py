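"""Calendar arithmetic for month-precision registry data and day-precision claims.

The registry reports diagnosis at month precision only, while claims carry
full service dates, so the package needs two granularities: calendar months
(``pandas.Period`` with monthly frequency) and calendar dates
(``datetime.date``).  All window logic that mixes the two is defined at the
month level; day arithmetic is only used for the 90-day gap rules between
claims.
"""

from __future__ import annotations

import datetime as dt

import pandas as pd

from .errors import RowParseError

__all__ = [
    "parse_month",
    "parse_date",
    "month_index",
    "month_of",
    "add_months",
    "days_between",
]


def parse_month(value: str | pd.Period) -> pd.Period:
    """Parse an ISO ``YYYY-MM`` string into a monthly Period."""
    if isinstance(value, pd.Period):
        if value.freqstr not in ("M", "ME"):
            raise RowParseError(f"period {value!r} is not monthly")
        return value
    text = str(value).strip()
    if len(text) != 7 or text[4] != "-":
        raise RowParseError(f"malformed year-month {value!r} (expected YYYY-MM)")
    try:
        return pd.Period(text, freq="M")
    except Exception as exc:  # pandas raises several parse error types
        raise RowParseError(f"malformed year-month {value!r}: {exc}") from exc


def parse_date(value: str | dt.date) -> dt.date:
    """Parse an ISO ``YYYY-MM-DD`` string into a date."""
    if isinstance(value, dt.date):
        return value
    try:
        return dt.date.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise RowParseError(f"malformed date {value!r} (expected YYYY-MM-DD)") from exc


def month_index(ym: str | pd.Period) -> int:
    """Integer index of a calendar month; consecutive months differ by 1."""
    return parse_month(ym).ordinal


def month_of(date: dt.date) -> pd.Period:
    """Calendar month containing a date."""
    return pd.Period(year=date.year, month=date.month, freq="M")


def add_months(ym: str | pd.Period, k: int) -> pd.Period:
    return parse_month(ym) + k


def days_between(d1: str | dt.date, d2: str | dt.date) -> int:
    """Absolute number of days between two dates (non-negative)."""
    return abs((parse_date(d2) - parse_date(d1)).days)
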
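"""Week-of-year calendar conventions.

Weeks are fixed 7-day blocks counted by day of year: days 1-7 form week 1,
days 8-14 week 2, and so on; the last day(s) of the year (day 365 and a leap
day 366) fold into week 52.  This keeps site-week climatologies aligned
across years, which ISO weeks (which drift by up to 3 days) would not.

A week belongs to a calendar month when its midpoint day of year falls in
that month, evaluated on a 365-day (non-leap) calendar.
"""

from __future__ import annotations

import datetime

import numpy as np

WEEKS_PER_YEAR = 52

#: summer months used throughout the analysis
SUMMER_MONTHS = (6, 7, 8)

MONTH_NAMES = {6: "June", 7: "July", 8: "August"}
MONTH_NUMBERS = {v: k for k, v in MONTH_NAMES.items()}


def week_of_doy(doy):
    """Week number (1-52) for a day of year; days beyond 364 fold into week 52."""
    doy = np.asarray(doy)
    week = (doy - 1) // 7 + 1
    return np.minimum(week, WEEKS_PER_YEAR)


def week_midpoint_doy(week):
    """Midpoint day of year of a week block (day 4 of the 7-day block)."""
    week = np.asarray(week)
    return (week - 1) * 7 + 4


def month_of_week(week) -> np.ndarray:
    """Calendar month containing the week's midpoint day (non-leap calendar)."""
    mid = np.atleast_1d(week_midpoint_doy(week))
    base = datetime.date(2001, 1, 1).toordinal() - 1
    months = np.array([datetime.date.fromordinal(base + int(d)).month for d in mid])
    if np.isscalar(week) or np.ndim(week) == 0:
        return months[0]
    return months


def weeks_in_month(month: int) -> np.ndarray:
    """All week numbers whose midpoint falls in the given month."""
    allw = np.arange(1, WEEKS_PER_YEAR + 1)
    return allw[month_of_week(allw) == month]


def normalize_month(month) -> int:
    """Accept a month number or an English month name; return the number."""
    if isinstance(month, str):
        try:
            return MONTH_NUMBERS[month.capitalize()]
        except KeyError:
            raise ValueError(f"unknown month name: {month!r}") from None
    m = int(month)
    if not 1 <= m <= 12:
        raise ValueError(f"month out of range: {month!r}")
    return m
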
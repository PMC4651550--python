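"""Calendar helpers on a 365-day year.

Time within a study is a float number of days since 00:00 on 1 Jan of the
bear-year's starting calendar year (t = 0.0 is the start of day-of-year 1).
Leap days are dropped, so ordinal dates are always 1-365 and the sentinel
retreat/return values (365, 1) are well defined.
"""

from __future__ import annotations

import numpy as np

DAYS_PER_YEAR = 365


def doy_of(t: float) -> int:
    """Ordinal date (1-365) of a study-time instant or day index."""
    return int(np.floor(t)) % DAYS_PER_YEAR + 1


def week_of_doy(doy: int) -> int:
    """Zero-based 7-day block from 1 Jan; day 365 falls in the short week 52."""
    if not 1 <= doy <= DAYS_PER_YEAR:
        raise ValueError("ordinal date must be in 1..365")
    return (doy - 1) // 7


def week_start_doy(week: int) -> int:
    """Ordinal date of the first day of a zero-based week."""
    return 7 * week + 1


N_WEEKS = week_of_doy(DAYS_PER_YEAR) + 1  # 53 blocks, last has 1 day


def month_of_doy(doy: int) -> int:
    """Calendar month (1-12) of an ordinal date in a 365-day year."""
    cum = np.cumsum([0, 31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
    return int(np.searchsorted(cum, doy, side="left"))


def doy_of_month_day(month: int, day: int) -> int:
    cum = np.cumsum([0, 31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
    return int(cum[month - 1]) + day
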
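"""Fixed 365-day (no-leap) calendar used by all daily series.

A no-leap calendar keeps every year structurally identical, so seasonal
statistics are comparable across years and a noise-free seasonal cycle
repeats exactly year over year.
"""

from __future__ import annotations

import numpy as np

MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
DAYS_PER_YEAR = int(MONTH_LENGTHS.sum())  # 365

#: month (1..12) of each day-of-year (0-based doy)
MONTH_OF_DOY = np.repeat(np.arange(1, 13), MONTH_LENGTHS)

#: first day-of-year (0-based) of each month 1..12
MONTH_START_DOY = np.concatenate([[0], np.cumsum(MONTH_LENGTHS)[:-1]])


def season_length(months: list[int]) -> int:
    """Total number of days in the given calendar months."""
    return int(MONTH_LENGTHS[np.asarray(months) - 1].sum())


def time_axis(first_year: int, n_years: int):
    """Return (year, month, doy) integer arrays for ``n_years`` of daily data.

    ``doy`` is 0-based day of year; arrays have length ``n_years * 365``.
    """
    doy = np.tile(np.arange(DAYS_PER_YEAR), n_years)
    year = np.repeat(np.arange(first_year, first_year + n_years), DAYS_PER_YEAR)
    month = np.tile(MONTH_OF_DOY, n_years)
    return year, month, doy


def absolute_day(first_year: int, year: int, doy: int) -> int:
    """Index of (year, doy) on the daily axis starting at ``first_year``."""
    return (year - first_year) * DAYS_PER_YEAR + doy
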
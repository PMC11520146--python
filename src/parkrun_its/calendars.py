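"""Week-index and seasonal calendar conventions shared across the package.

Every included event happens on a Saturday, so the weekly series is anchored
on Saturdays: week ``k`` of a window is the ``(k+1)``-th Saturday on or after
the window start.  Time in model units is measured in years of 52.1775 weeks
(the mean Gregorian year), so exponentiated trend coefficients read directly
as per-year rate ratios.
"""

from __future__ import annotations

import datetime as dt

#: mean number of weeks per Gregorian year; converts week counts to years
WEEKS_PER_YEAR = 52.1775

#: first Saturday on/after 1 Jan 2015 — the default study anchor
DEFAULT_WINDOW_START = dt.date(2015, 1, 3)

_SATURDAY = 5  # datetime.date.weekday() convention (Monday = 0)


def first_saturday_on_or_after(day: dt.date) -> dt.date:
    """Return ``day`` itself if it is a Saturday, else the next Saturday."""
    return day + dt.timedelta(days=(_SATURDAY - day.weekday()) % 7)


def saturday_of_week(week_index: int, window_start: dt.date = DEFAULT_WINDOW_START) -> dt.date:
    """Calendar Saturday of week ``week_index`` (0-based) of a window."""
    anchor = first_saturday_on_or_after(window_start)
    return anchor + dt.timedelta(weeks=week_index)


def week_of_date(day: dt.date, window_start: dt.date = DEFAULT_WINDOW_START) -> int:
    """Week index of the week whose Saturday is on/after ``day``.

    For a Saturday this is its own week; for mid-week dates it is the week
    of the following Saturday (events happen on Saturdays, so boundaries
    expressed as arbitrary dates bind at the next event day).
    """
    anchor = first_saturday_on_or_after(window_start)
    sat = first_saturday_on_or_after(day)
    return (sat - anchor).days // 7


def weeks_to_years(weeks: float) -> float:
    return weeks / WEEKS_PER_YEAR
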
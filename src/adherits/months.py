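"""Equal-width month bins on a global integer day calendar.

Day 0 is the start of calendar month 1 (the first cohort month).  A month
is an equal-width bin of 365.25/12 = 30.4375 days rounded to integer day
boundaries; real calendar months are not needed anywhere because the
regression treats month as an integer index.
"""

DAYS_PER_MONTH = 365.25 / 12.0  # 30.4375


def month_start_day(month: int) -> int:
    """First day (inclusive) of ``month`` (1-based) on the global calendar."""
    return int(round(DAYS_PER_MONTH * (month - 1)))


def month_of_day(day: int) -> int:
    """Map a global day offset to its 1-based calendar month."""
    if day < 0:
        raise ValueError(f"day offset must be non-negative, got {day}")
    m = int(day / DAYS_PER_MONTH) + 1
    # rounding of bin edges can put us off by one either way
    while day < month_start_day(m):
        m -= 1
    while day >= month_start_day(m + 1):
        m += 1
    return m
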
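"""Independent oracles used by the test suite.

The visit-status oracle steps the observation clock one day at a time
and applies the window definition literally, instead of comparing the
clock against pre-computed interval bounds the way the implementation
does.
"""

import datetime as dt


def day_stepping_visit_status(
    rand_day: int,
    offset: int,
    before: int,
    after: int,
    grace: int,
    actual_day,
    end_day,
    as_of_day: int,
) -> str:
    """Classify one (participant, visit) pair by brute-force day stepping.

    All arguments are day numbers on an arbitrary common origin;
    ``actual_day``/``end_day`` may be None.
    """
    target = rand_day + offset
    w_open = target - before
    w_close = target + after
    g_end = w_close + grace

    if actual_day is not None and actual_day <= as_of_day:
        if w_open <= actual_day <= w_close:
            return "completed-in-window"
        return "completed-out-of-window"

    if end_day is not None and w_open > end_day:
        return "not-applicable"

    status = "pending"
    day = min(rand_day, w_open)
    while day <= as_of_day:
        if day == w_open:
            status = "due"
        if day == w_close + 1:
            status = "overdue"
        if day == g_end + 1:
            status = "missed"
        day += 1
    return status


def to_date(day: int, origin: dt.date = dt.date(2024, 1, 1)) -> dt.date:
    return origin + dt.timedelta(days=day)
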
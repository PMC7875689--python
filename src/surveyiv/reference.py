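"""Published summary counts from HINTS 5 Cycle 1 (2017).

The respondent-level public-use file is not redistributed here, but the
published encouragement-by-outcome and encouragement-by-usage contingency
tables are sufficient inputs for the descriptive statistics, chi-square
tests, and compliance-weight arithmetic, and serve as fixed ground truth for
the desk-scale checks.

Row order in the outcome tables follows the 5-point confidence scale
("Not confident at all" ... "Completely confident"); usage counts follow the
pooled 4-band coding (never / 1-2 / 3-5 / more than 5 times a year).
"""
from __future__ import annotations

import numpy as np

from .descriptives import ContingencyTable

__all__ = [
    "CONFIDENT_GET_HEALTH_INFO",
    "OWN_ABILITY_TAKE_CARE_HEALTH",
    "ENCOURAGEMENT_BY_USAGE",
    "USERS_BY_FREQUENCY",
    "outcome_table",
    "usage_table",
]

_LIKERT = ("Not confident at all", "A little confident", "Somewhat confident",
           "Very confident", "Completely confident")
_ARMS = ("encouraged", "not encouraged")

#: Counts by encouragement arm for "confidence in getting health information"
#: (encouraged n=1353, not encouraged n=1758).
CONFIDENT_GET_HEALTH_INFO = {
    "encouraged": (21, 56, 369, 566, 341),
    "not encouraged": (50, 108, 600, 607, 393),
}

#: Counts by arm for "confidence in own ability to take care of health"
#: (encouraged n=1364, not encouraged n=1801).
OWN_ABILITY_TAKE_CARE_HEALTH = {
    "encouraged": (15, 31, 320, 652, 346),
    "not encouraged": (31, 79, 469, 815, 407),
}

#: Portal-usage counts by arm, pooled 4-band coding
#: (never / 1-2 / 3-5 / >5 times): encouraged n=1375, not encouraged n=1823.
ENCOURAGEMENT_BY_USAGE = {
    "encouraged": (549, 383, 267, 176),
    "not encouraged": (1646, 113, 46, 18),
}

#: Usage-frequency split among the 1003 self-reported portal users
#: (1-2 / 3-5 / 6-9 / 10+ times).
USERS_BY_FREQUENCY = (496, 313, 104, 90)


def outcome_table(which: str) -> ContingencyTable:
    """Published 2x5 encouragement-by-outcome table as a ContingencyTable.

    ``which`` is ``"get_info"`` or ``"own_ability"``; rows are the two
    encouragement arms, columns the five confidence levels.
    """
    src = {"get_info": CONFIDENT_GET_HEALTH_INFO,
           "own_ability": OWN_ABILITY_TAKE_CARE_HEALTH}[which]
    counts = np.array([src[a] for a in _ARMS])
    return ContingencyTable(counts, _ARMS, _LIKERT)


def usage_table() -> ContingencyTable:
    """Published 2x4 encouragement-by-usage table (pooled >5 band)."""
    counts = np.array([ENCOURAGEMENT_BY_USAGE[a] for a in _ARMS])
    return ContingencyTable(counts, _ARMS, ("never", "1-2", "3-5", ">5"))
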
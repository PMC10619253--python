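"""Published characteristics of the three Chinese famine cohorts.

Reference participant counts for the GNHS, GGMP, and CHNS 16S cohorts
(post-exclusion), as published for the famine natural experiment, keyed by
exposure-group code. These are inputs for consistency arithmetic — totals,
percentages, and exposed fractions recomputed from the printed counts — and
for configuring realistic synthetic cohort structures; no sequence data are
involved.
"""

from __future__ import annotations

__all__ = [
    "COHORT_SIZES",
    "GROUP_COUNTS",
    "WOMEN_COUNTS",
    "T2D_COUNTS",
    "total_participants",
    "percent",
    "exposed_total",
    "exposed_percent",
    "in_utero_total",
]

#: Participants retained per cohort after the depth / birth-year / antibiotic
#: exclusions.
COHORT_SIZES = {"GNHS": 1920, "GGMP": 6560, "CHNS": 3033}

WOMEN_COUNTS = {"GNHS": 1288, "GGMP": 3614, "CHNS": 1554}
T2D_COUNTS = {"GNHS": 268, "GGMP": 553, "CHNS": 368}

#: Famine exposure group sizes per cohort. E1-E3 are the in-utero subgroups
#: (born 1959, 1960, 1961); NE2 the 1962-1964 control; NE1 other unexposed.
GROUP_COUNTS = {
    "GNHS": {"NE2": 37, "E1": 34, "E2": 15, "E3": 5, "E4": 341, "E5": 425,
             "E6": 670, "E7": 261, "E8": 91, "NE1": 41},
    "GGMP": {"NE2": 622, "E1": 144, "E2": 111, "E3": 111, "E4": 512, "E5": 502,
             "E6": 822, "E7": 380, "E8": 430, "NE1": 2926},
    "CHNS": {"NE2": 303, "E1": 69, "E2": 58, "E3": 48, "E4": 259, "E5": 300,
             "E6": 340, "E7": 137, "E8": 109, "NE1": 1410},
}

_EXPOSED_CODES = ("E1", "E2", "E3", "E4", "E5", "E6", "E7", "E8")


def total_participants() -> int:
    """Total included participants across the three cohorts."""
    return sum(COHORT_SIZES.values())


def percent(count: int, total: int, digits: int = 1) -> float:
    """Percentage as printed (one decimal place by default)."""
    return round(100.0 * count / total, digits)


def in_utero_total() -> int:
    """Participants exposed in utero (born 1959-1961) across cohorts."""
    return sum(GROUP_COUNTS[c][g] for c in GROUP_COUNTS for g in ("E1", "E2", "E3"))


def exposed_total() -> int:
    """All famine-exposed participants (any E group) across cohorts."""
    return sum(GROUP_COUNTS[c][g] for c in GROUP_COUNTS for g in _EXPOSED_CODES)


def exposed_percent(digits: int = 1) -> float:
    return percent(exposed_total(), total_participants(), digits)
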
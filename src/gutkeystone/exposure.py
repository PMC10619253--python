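"""Famine-exposure classification from birth year.

Participants of the 1959-1961 Great Chinese Famine cohorts are classified into
ten exposure groups by calendar birth year. The group born in 1959 (code E1)
was exposed in utero and through the first two postnatal years — the first
1000 days of life — and is the primary exposure group; the group born
1962-1964 (NE2) is the unexposed reference. Months are ignored: the study
design classifies by birth year only.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["ExposureGroup", "GROUPS", "classify", "classify_series", "regroup"]


@dataclass(frozen=True)
class ExposureGroup:
    code: str
    label: str
    year_min: int | None  # inclusive; None = open below
    year_max: int | None  # inclusive; None = open above

    def contains(self, year: int) -> bool:
        lo = self.year_min is None or year >= self.year_min
        hi = self.year_max is None or year <= self.year_max
        return lo and hi


#: The ten exposure groups; rules partition all integer birth years.
GROUPS: tuple[ExposureGroup, ...] = (
    ExposureGroup("NE1", "no-exposed (born after 1964)", 1965, None),
    ExposureGroup("NE2", "no-exposed control (born 1962-1964)", 1962, 1964),
    ExposureGroup("E1", "first 1000 days exposed (born 1959)", 1959, 1959),
    ExposureGroup("E2", "in utero + first year exposed (born 1960)", 1960, 1960),
    ExposureGroup("E3", "in utero exposed (born 1961)", 1961, 1961),
    ExposureGroup("E4", "infancy and toddler exposed (born 1956-1958)", 1956, 1958),
    ExposureGroup("E5", "preschooler exposed (born 1953-1955)", 1953, 1955),
    ExposureGroup("E6", "school-aged child exposed (born 1947-1952)", 1947, 1952),
    ExposureGroup("E7", "adolescent exposed (born 1942-1946)", 1942, 1946),
    ExposureGroup("E8", "adult exposed (born before 1942)", None, 1941),
)

_BY_CODE = {g.code: g for g in GROUPS}

#: Group codes ordered for modelling; NE2 is the reference.
GROUP_ORDER = ["NE2", "NE1", "E1", "E2", "E3", "E4", "E5", "E6", "E7", "E8"]

REFERENCE_CODE = "NE2"

#: Recognized sensitivity regrouping schemes.
SCHEMES = ("post1978_reference", "control_plus_E4_reference", "utero_combined")


def classify(birth_year: int) -> ExposureGroup:
    """Classify a single birth year into its famine-exposure group.

    Raises ``ValueError`` for a missing (None/NaN) birth year: such samples
    must be excluded upstream, never silently grouped.
    """
    if birth_year is None or pd.isna(birth_year):
        raise ValueError("missing birth year: classification refused")
    year = int(birth_year)
    for g in GROUPS:
        if g.contains(year):
            return g
    raise AssertionError(f"unreachable: no group for {year}")  # pragma: no cover


def classify_series(birth_years: pd.Series) -> pd.Series:
    """Vectorized :func:`classify`: birth-year Series -> group-code Series."""
    return birth_years.map(lambda y: classify(y).code)


def regroup(birth_years: pd.Series, scheme: str) -> pd.Series:
    """Reassign exposure groups under a sensitivity scheme.

    Schemes
    -------
    ``post1978_reference``
        Participants born after 1978 form the new reference group
        (label ``REF_post1978``); everyone else keeps their group code.
    ``control_plus_E4_reference``
        NE2 (1962-1964) and E4 (1956-1958) merge into one age-balanced
        reference (label ``REF_NE2+E4``).
    ``utero_combined``
        The three in-utero groups E1-E3 (born 1959-1961) merge into a single
        ``E_utero`` group.

    Classification is recomputed from birth years because the base group
    codes do not encode enough information for every scheme (NE1 covers all
    post-1964 births, including post-1978 ones).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown regrouping scheme {scheme!r}; expected one of {SCHEMES}")
    codes = classify_series(birth_years)
    if scheme == "post1978_reference":
        out = codes.where(birth_years <= 1978, "REF_post1978")
    elif scheme == "control_plus_E4_reference":
        out = codes.replace({"NE2": "REF_NE2+E4", "E4": "REF_NE2+E4"})
    else:  # utero_combined
        out = codes.replace({"E1": "E_utero", "E2": "E_utero", "E3": "E_utero"})
    return out


def reference_for_scheme(scheme: str | None) -> str:
    """Reference group label used in contrasts under a (re)grouping scheme."""
    if scheme is None:
        return REFERENCE_CODE
    return {
        "post1978_reference": "REF_post1978",
        "control_plus_E4_reference": "REF_NE2+E4",
        "utero_combined": REFERENCE_CODE,
    }[scheme]
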
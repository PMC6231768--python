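"""Symptom-count exacerbation definitions and next-day predictors.

Eight daily binary symptoms are split into three *major* symptoms
(breathlessness, sputum colour, sputum amount; weight 2) and five *minor*
symptoms (cold, wheeze, sore throat, cough, fever; weight 1). Five
literature-derived symptom-counting rules flag the onset of an
exacerbation on day t from the daily counts:

1. nMajor >= 2                                   (single day; practical)
2. nAll >= 5                                     (single day; practical)
3. days t and t+1 are "bad" but t-1 and t-2 are not, where a bad day has
   (nMajor >= 2) or (nMajor = 1 and nMinor >= 1)
4. as 3, with a bad day defined as (nMajor >= 1) and (nAll >= 3)
5. (nAll >= 5 on day t) or (nAll = 4 on day t and nAll >= 4 on day t+1)

Definitions 3-5 read day t+1 (and t-1, t-2), so used as predictors of an
event on day t+1 they give an *upper bound* on achievable performance:
they assume the onset could somehow be recognised on day t. Only
definitions 1 and 2 are practical next-day predictors.

Counts are all-or-nothing: a day with any missing symptom flag has missing
counts, and any rule output that would need a missing count is itself
missing (NaN). Boundary days whose required context lies outside the
series yield no onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import MAJOR_SYMPTOMS, MINOR_SYMPTOMS, SYMPTOMS

__all__ = [
    "PRACTICAL_DEFINITIONS",
    "UPPER_BOUND_DEFINITIONS",
    "ALERT_THRESHOLD",
    "SymptomCounts",
    "symptom_counts",
    "count_frame",
    "symptom_score",
    "is_practical",
    "context_days",
    "bad_day",
    "detect_onsets",
    "definition_predictor",
]

PRACTICAL_DEFINITIONS = (1, 2)
UPPER_BOUND_DEFINITIONS = (3, 4, 5)

#: Telemonitoring alert threshold: clinical staff contacted the patient
#: when the weighted score rose above this value.
ALERT_THRESHOLD = 5


@dataclass(frozen=True)
class SymptomCounts:
    n_major: int
    n_minor: int

    @property
    def n_all(self) -> int:
        return self.n_major + self.n_minor


class MissingSymptomError(ValueError):
    """A required symptom flag is missing; the caller decides scenario handling."""


def symptom_counts(day) -> SymptomCounts:
    """Counts of present major and minor symptoms for one day's record.

    ``day`` is any mapping with the eight symptom fields (0/1, NaN for
    missing). Any missing flag raises: partial counting is never done —
    complete-scenario callers have already excluded such days and
    imputed-scenario callers have already forward-filled them.
    """
    values = {s: day[s] for s in SYMPTOMS}
    missing = [s for s, v in values.items() if v is None or (isinstance(v, float) and np.isnan(v))]
    if missing:
        raise MissingSymptomError(f"missing symptom flags: {missing}")
    n_major = int(sum(int(values[s]) for s in MAJOR_SYMPTOMS))
    n_minor = int(sum(int(values[s]) for s in MINOR_SYMPTOMS))
    return SymptomCounts(n_major, n_minor)


def count_frame(records: pd.DataFrame) -> pd.DataFrame:
    """Vectorised counts for a daily-record table.

    Returns columns ``n_major``, ``n_minor``, ``n_all`` and ``score``
    (the weighted telemonitoring score 2*nMajor + nMinor), NaN on any day
    with a missing symptom flag.
    """
    sym = records[SYMPTOMS]
    ok = sym.notna().all(axis=1)
    n_major = records[MAJOR_SYMPTOMS].sum(axis=1).where(ok)
    n_minor = records[MINOR_SYMPTOMS].sum(axis=1).where(ok)
    out = pd.DataFrame({
        "n_major": n_major,
        "n_minor": n_minor,
        "n_all": n_major + n_minor,
        "score": 2 * n_major + n_minor,
    }, index=records.index)
    return out


def symptom_score(day) -> int:
    """Weighted daily symptom score: 2 per major + 1 per minor, range 0-11."""
    c = symptom_counts(day)
    return 2 * c.n_major + c.n_minor


def is_practical(definition: int) -> bool:
    """True for the single-day definitions (1 and 2) usable prospectively."""
    if definition not in (1, 2, 3, 4, 5):
        raise ValueError(f"unknown definition {definition}")
    return definition in PRACTICAL_DEFINITIONS


def context_days(definition: int) -> tuple[int, int]:
    """(days of past context, days of future context) each definition reads.

    Past context includes day t itself, so definition 1 is (1, 0).
    """
    return {1: (1, 0), 2: (1, 0), 3: (3, 1), 4: (3, 1), 5: (1, 1)}[definition]


def bad_day(definition: int, counts: SymptomCounts) -> bool:
    """The 'bad day' predicate underlying the two-consecutive-day rules."""
    if definition == 3:
        return counts.n_major >= 2 or (counts.n_major == 1 and counts.n_minor >= 1)
    if definition == 4:
        return counts.n_major >= 1 and counts.n_all >= 3
    raise ValueError(f"bad_day is defined only for definitions 3 and 4, got {definition}")


def _bad_series(definition: int, counts: pd.DataFrame) -> pd.Series:
    nmaj, nmin = counts["n_major"], counts["n_minor"]
    if definition == 3:
        bad = (nmaj >= 2) | ((nmaj == 1) & (nmin >= 1))
    else:
        bad = (nmaj >= 1) & ((nmaj + nmin) >= 3)
    return bad.astype(float).where(nmaj.notna())


def detect_onsets(definition: int, counts: pd.DataFrame) -> pd.Series:
    """Per-day onset flags for one patient's consecutive-day count series.

    ``counts`` needs columns ``n_major`` and ``n_minor`` (NaN where the
    day's symptoms were incomplete) indexed in day order with no gaps.
    Returns a float series: 1.0 onset, 0.0 no onset, NaN where a count the
    rule must read is missing. Days whose required context falls off either
    end of the series yield 0.0 (no onset can be asserted there).
    """
    if definition not in (1, 2, 3, 4, 5):
        raise ValueError(f"unknown definition {definition}")
    nmaj = counts["n_major"].astype(float)
    nall = (counts["n_major"] + counts["n_minor"]).astype(float)

    if definition == 1:
        return (nmaj >= 2).astype(float).where(nmaj.notna())
    if definition == 2:
        return (nall >= 5).astype(float).where(nall.notna())

    if definition in (3, 4):
        bad = _bad_series(definition, counts)
        b_t = bad
        b_next = bad.shift(-1)
        b_m1 = bad.shift(1)
        b_m2 = bad.shift(2)
        onset = (b_t == 1) & (b_next == 1) & (b_m1 == 0) & (b_m2 == 0)
        out = onset.astype(float)
        # missing wherever any required count is missing...
        ctx_missing = b_t.isna() | b_next.isna() | b_m1.isna() | b_m2.isna()
        out = out.where(~ctx_missing)
        # ...but boundary days (context off the ends) are definite non-onsets
        n = len(counts)
        if n > 0:
            edge = np.zeros(n, dtype=bool)
            edge[: min(2, n)] = True
            edge[-1] = True
            out.iloc[np.flatnonzero(edge)] = 0.0
        return out

    # definition 5: single-day branch takes priority; the two-day branch
    # needs tomorrow's count.
    branch1 = nall >= 5
    nall_next = nall.shift(-1)
    branch2 = (nall == 4) & (nall_next >= 4)
    out = (branch1 | branch2).astype(float)
    # branch1 decidable from today alone; if it fires, tomorrow irrelevant
    undecided = nall.isna() | (~branch1 & ((nall == 4) & nall_next.isna()))
    out = out.where(~undecided)
    if len(out) > 0 and not bool(branch1.iloc[-1] if nall.notna().iloc[-1] else False):
        # last day: two-day branch has no tomorrow -> no onset unless branch1
        if nall.notna().iloc[-1]:
            out.iloc[-1] = float(branch1.iloc[-1])
    return out


def definition_predictor(definition: int, counts: pd.DataFrame) -> pd.Series:
    """Binary risk score for day t+1: the onset flag of day t, shifted.

    The onset of an exacerbation on day t is used to predict an admission
    (or corticosteroid start) on day t+1, so the series is the onset series
    shifted forward one day. The first day has no yesterday and scores NaN.
    """
    onsets = detect_onsets(definition, counts)
    return onsets.shift(1)
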
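"""Exacerbation-rule tests against independent literal-transcription oracles.

The oracles below re-state each definition directly from its published
wording, structured differently from the library implementation (scalar
loops over explicit day tuples rather than vectorised series), and the
library output is required to match them exhaustively.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from telecopd.cohort import MAJOR_SYMPTOMS, MINOR_SYMPTOMS, SYMPTOMS
from telecopd.rules import (ALERT_THRESHOLD, MissingSymptomError, SymptomCounts,
                            bad_day, context_days, count_frame,
                            definition_predictor, detect_onsets, is_practical,
                            symptom_counts, symptom_score)

from conftest import make_day


# ---------------------------------------------------------------------------
# independent oracles

def oracle_counts(flags):
    """Brute-force counts from an 8-tuple of 0/1 flags in SYMPTOMS order."""
    major = sum(flags[:3])
    minor = sum(flags[3:])
    return major, minor


def oracle_def1(n_major):
    return n_major >= 2


def oracle_def2(n_all):
    return n_all >= 5


def oracle_bad3(n_major, n_minor):
    return (n_major >= 2) or (n_major == 1 and n_minor >= 1)


def oracle_bad4(n_major, n_all):
    return (n_major >= 1) and (n_all >= 3)


def oracle_def34_onset(bad4days):
    """(b_{t-2}, b_{t-1}, b_t, b_{t+1}) -> onset at t."""
    b_m2, b_m1, b_t, b_p1 = bad4days
    return b_t and b_p1 and not b_m1 and not b_m2


def oracle_def5(n_all_t, n_all_next):
    if n_all_t >= 5:
        return True
    return n_all_t == 4 and n_all_next is not None and n_all_next >= 4


def counts_df(pairs):
    return pd.DataFrame({"n_major": [p[0] for p in pairs],
                         "n_minor": [p[1] for p in pairs]})


def canonical_pair(n_all):
    """A (n_major, n_minor) decomposition majoring first: nAll=4 -> (3,1)."""
    major = min(3, n_all)
    return major, n_all - major


# ---------------------------------------------------------------------------
# counts and score

def test_symptom_counts_over_all_256_patterns():
    for flags in itertools.product((0, 1), repeat=8):
        day = dict(zip(SYMPTOMS, map(float, flags)))
        c = symptom_counts(day)
        major, minor = oracle_counts(flags)
        assert (c.n_major, c.n_minor, c.n_all) == (major, minor, major + minor)
        assert symptom_score(day) == 2 * major + minor


def test_counts_examples():
    assert symptom_counts(make_day()) == SymptomCounts(0, 0)
    c = symptom_counts(make_day(("breathlessness", "sputum_colour")))
    assert (c.n_major, c.n_minor, c.n_all) == (2, 0, 2)
    c = symptom_counts(make_day(SYMPTOMS))
    assert (c.n_major, c.n_minor, c.n_all) == (3, 5, 8)


def test_score_range_and_alert_threshold():
    assert symptom_score(make_day()) == 0
    assert symptom_score(make_day(SYMPTOMS)) == 11
    # 2 major + 2 minor = 6: crosses the clinical alert threshold of 5
    day = make_day(("breathlessness", "sputum_amount", "cough", "wheeze"))
    assert symptom_score(day) == 6 > ALERT_THRESHOLD


def test_missing_flag_raises():
    day = make_day(("cough",))
    day["fever"] = np.nan
    with pytest.raises(MissingSymptomError):
        symptom_counts(day)


@given(st.lists(st.booleans(), min_size=8, max_size=8))
def test_score_dominates_nall(flags):
    day = dict(zip(SYMPTOMS, map(float, flags)))
    c = symptom_counts(day)
    score = symptom_score(day)
    assert score >= c.n_all
    assert (score == c.n_all) == (c.n_major == 0)


def test_count_frame_matches_scalar_path(clean_records):
    _, records, _ = clean_records
    cf = count_frame(records)
    for i in records.sample(25, random_state=0).index:
        c = symptom_counts(records.loc[i])
        assert cf.loc[i, "n_major"] == c.n_major
        assert cf.loc[i, "n_all"] == c.n_all


# ---------------------------------------------------------------------------
# single-day definitions: exhaustive over all 2^8 patterns

def test_definitions_1_and_2_match_brute_force_over_all_patterns():
    for flags in itertools.product((0, 1), repeat=8):
        major, minor = oracle_counts(flags)
        cdf = counts_df([(major, minor)])
        assert detect_onsets(1, cdf).iloc[0] == float(oracle_def1(major))
        assert detect_onsets(2, cdf).iloc[0] == float(oracle_def2(major + minor))


def test_bad_day_predicates_over_all_patterns():
    for flags in itertools.product((0, 1), repeat=8):
        major, minor = oracle_counts(flags)
        c = SymptomCounts(major, minor)
        assert bad_day(3, c) == oracle_bad3(major, minor)
        assert bad_day(4, c) == oracle_bad4(major, major + minor)
    with pytest.raises(ValueError):
        bad_day(1, SymptomCounts(0, 0))


# ---------------------------------------------------------------------------
# multi-day definitions: exhaustive over 4-day sequences

def test_definitions_3_and_4_match_oracle_over_all_bad_patterns():
    # realise every bad/not-bad 4-day pattern through actual count pairs
    reps3 = {True: (2, 0), False: (0, 5)}        # bad3 / not-bad3
    reps4 = {True: (1, 2), False: (0, 8)}        # bad4 / not-bad4
    for definition, reps, oracle_bad in ((3, reps3, oracle_bad3),
                                         (4, reps4, oracle_bad4)):
        for pattern in itertools.product((False, True), repeat=4):
            pairs = [reps[b] for b in pattern]
            onsets = detect_onsets(definition, counts_df(pairs))
            # day index 2 has full context (t-2, t-1, t, t+1)
            assert onsets.iloc[2] == float(oracle_def34_onset(pattern)), (
                definition, pattern)
            # boundary days carry no onset
            assert onsets.iloc[0] == 0.0 and onsets.iloc[1] == 0.0
            assert onsets.iloc[3] == 0.0


def test_definition_5_matches_oracle_over_all_nall_sequences():
    for seq in itertools.product(range(9), repeat=4):
        pairs = [canonical_pair(v) for v in seq]
        onsets = detect_onsets(5, counts_df(pairs))
        for t in range(4):
            nxt = seq[t + 1] if t < 3 else None
            assert onsets.iloc[t] == float(oracle_def5(seq[t], nxt)), (seq, t)


def test_definitions_3_and_4_match_oracle_over_all_nall_sequences():
    # canonical decomposition exercises the nAll-level view of defs 3-4 too
    for seq in itertools.product(range(9), repeat=4):
        pairs = [canonical_pair(v) for v in seq]
        for definition, oracle_bad in ((3, oracle_bad3), (4, oracle_bad4)):
            pattern = tuple(oracle_bad(p[0], p[1] if definition == 3 else sum(p))
                            for p in pairs)
            onsets = detect_onsets(definition, counts_df(pairs))
            assert onsets.iloc[2] == float(oracle_def34_onset(pattern)), (
                definition, seq)


# ---------------------------------------------------------------------------
# examples printed with the definitions

def test_printed_examples():
    assert detect_onsets(1, counts_df([(2, 0)])).iloc[0] == 1.0
    assert detect_onsets(2, counts_df([(2, 2)])).iloc[0] == 0.0   # nAll=4 < 5
    # def 3: not-bad, not-bad, bad, bad -> onset at day 2 only
    onsets = detect_onsets(3, counts_df([(0, 0), (0, 0), (2, 0), (2, 0)]))
    assert list(onsets) == [0.0, 0.0, 1.0, 0.0]
    # def 4: (1,1) has nAll=2 -> not bad; (1,2) has nAll=3 -> bad
    assert not bad_day(4, SymptomCounts(1, 1))
    assert bad_day(4, SymptomCounts(1, 2))
    # def 5: nAll series (3,4,4) -> onset at day 1
    onsets = detect_onsets(5, counts_df([(3, 0), (3, 1), (3, 1)]))
    assert list(onsets) == [0.0, 1.0, 0.0]


def test_all_zero_series_has_no_onsets():
    zeros = counts_df([(0, 0)] * 10)
    for d in (1, 2, 3, 4, 5):
        assert (detect_onsets(d, zeros) == 0).all()


def test_missing_counts_propagate_as_missing():
    cdf = counts_df([(0, 0), (2, 0), (0, 0)]).astype(float)
    cdf.loc[1] = np.nan
    assert np.isnan(detect_onsets(1, cdf).iloc[1])
    assert detect_onsets(1, cdf).iloc[0] == 0.0
    # def 5 needs tomorrow only when today's count is exactly 4
    cdf = counts_df([(3, 1), (0, 0)]).astype(float)
    cdf.loc[1] = np.nan
    assert np.isnan(detect_onsets(5, cdf).iloc[0])
    cdf2 = counts_df([(3, 2), (0, 0)]).astype(float)  # nAll=5: decided today
    cdf2.loc[1] = np.nan
    assert detect_onsets(5, cdf2).iloc[0] == 1.0


def test_predictor_is_shifted_onset_series():
    cdf = counts_df([(0, 0)] * 4 + [(2, 0)] + [(0, 0)] * 3)
    pred = definition_predictor(1, cdf)
    assert np.isnan(pred.iloc[0])
    assert pred.iloc[5] == 1.0            # onset day 4 predicts day 5
    assert pred.drop(index=[0, 5]).eq(0).all()


def test_practicality_labels():
    assert [d for d in (1, 2, 3, 4, 5) if is_practical(d)] == [1, 2]
    assert context_days(3) == (3, 1)
    assert context_days(5) == (1, 1)


# ---------------------------------------------------------------------------
# monotonicity: adding a symptom never cancels an onset (defs 1, 2, 4)

@settings(max_examples=200, deadline=None)
@given(st.lists(st.booleans(), min_size=8, max_size=8),
       st.integers(min_value=0, max_value=7))
def test_single_day_monotonicity(flags, add_at):
    flags2 = list(flags)
    flags2[add_at] = True
    m1, n1 = oracle_counts(tuple(map(int, flags)))
    m2, n2 = oracle_counts(tuple(map(int, flags2)))
    for definition in (1, 2):
        before = detect_onsets(definition, counts_df([(m1, n1)])).iloc[0]
        after = detect_onsets(definition, counts_df([(m2, n2)])).iloc[0]
        assert after >= before
    assert bad_day(4, SymptomCounts(m2, n2)) >= bad_day(4, SymptomCounts(m1, n1))
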
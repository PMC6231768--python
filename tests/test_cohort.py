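"""Synthetic-cohort generator: determinism, calibration, missingness."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from telecopd.cohort import (CohortConfig, ConfigError, MASKABLE_FIELDS,
                             SYMPTOMS, apply_missingness, generate_baseline,
                             generate_cohort, generate_daily, generate_weather,
                             oracle_scores)


def cfg(**kw):
    return dataclasses.replace(CohortConfig(), **kw)


# ---------------------------------------------------------------------------
# validation and degenerate inputs

def test_invalid_configs_raise():
    with pytest.raises(ConfigError):
        generate_baseline(cfg(n_patients=-1))
    with pytest.raises(ConfigError):
        generate_baseline(cfg(p_stable_to_prodrome=1.5))
    bad_em = [[0.5] * 8] * 2 + [[2.0] * 8]
    with pytest.raises(ConfigError):
        generate_baseline(cfg(symptom_emission=tuple(map(tuple, bad_em))))
    with pytest.raises(ConfigError):
        apply_missingness(pd.DataFrame(), cfg(preadmission_multiplier=-1))


def test_empty_cohort():
    c = cfg(n_patients=0, n_days=0)
    assert len(generate_baseline(c)) == 0
    baseline, records, truth = generate_cohort(c)
    assert len(records) == 0 and len(truth) == 0


def test_zero_emission_produces_no_symptoms():
    zero = tuple(tuple(0.0 for _ in range(8)) for _ in range(3))
    c = cfg(n_patients=3, n_days=30, symptom_emission=zero,
            day_missing_prob=0.0, field_missing_prob=0.0, weather_coupling=0.0)
    _, records, _ = generate_cohort(c)
    assert (records[SYMPTOMS].to_numpy() == 0).all()


# ---------------------------------------------------------------------------
# determinism and shape

def test_same_seed_gives_identical_cohorts(tiny_config):
    a = generate_cohort(tiny_config)
    b = generate_cohort(tiny_config)
    for x, y in zip(a, b):
        pd.testing.assert_frame_equal(x, y)


def test_different_seeds_differ(tiny_config):
    a = generate_cohort(tiny_config)[1]
    b = generate_cohort(dataclasses.replace(tiny_config, seed=tiny_config.seed + 1))[1]
    assert not a.equals(b)


def test_row_counts_and_ranges(clean_records):
    _, records, truth = clean_records
    assert len(records) == 4 * 40
    assert len(truth) == 4 * 40
    assert records["spo2"].between(50, 100).all()
    assert records["pulse"].between(30, 220).all()
    assert truth["state"].isin([0, 1, 2]).all()
    assert truth["admission_probability"].between(0, 1).all()
    assert truth["corticosteroid_probability"].between(0, 1).all()


def test_baseline_moments_match_configuration():
    c = cfg(n_patients=2000, baseline_missing_prob=0.0)
    bl = generate_baseline(c)
    # clipping to [15, 69] pulls the FEV1 mean slightly below the
    # configured 45; the 3-SE band around 45 still contains it
    se = c.fev1_sd / np.sqrt(len(bl))
    assert abs(bl["fev1_pct"].mean() - c.fev1_mean) < 3 * se + 0.5
    assert bl["fev1_pct"].between(0, 100, inclusive="neither").all() or \
        bl["fev1_pct"].le(100).all()
    assert (bl["prior_admissions"] >= 1).all()
    assert bl["mrc_grade"].between(1, 5).all()


def test_baseline_missingness_injected(tiny_cohort):
    baseline, _, _ = tiny_cohort
    # default 5% missing rate: with 12 patients x 10 fields expect a few
    assert baseline.drop(columns="patient_id").isna().to_numpy().sum() >= 0
    big = generate_baseline(cfg(n_patients=500))
    frac = big.drop(columns="patient_id").isna().to_numpy().mean()
    assert 0.02 < frac < 0.09


# ---------------------------------------------------------------------------
# latent process calibration

def test_transition_frequencies_match_config():
    c = cfg(n_patients=60, n_days=400, day_missing_prob=0.0,
            field_missing_prob=0.0, admit_intercept=-30.0)  # no resets
    baseline = generate_baseline(c)
    _, truth = generate_daily(c, baseline)
    states = truth.sort_values(["patient_id", "day"])["state"].to_numpy()
    pid = truth.sort_values(["patient_id", "day"])["patient_id"].to_numpy()
    prev, nxt = states[:-1], states[1:]
    same = pid[:-1] == pid[1:]
    for s_from, s_to, p in ((0, 1, c.p_stable_to_prodrome),
                            (1, 2, c.p_prodrome_to_exacerbation),
                            (2, 0, c.p_exacerbation_to_stable)):
        at = same & (prev == s_from)
        n = at.sum()
        rate = (nxt[at] == s_to).mean()
        se = np.sqrt(p * (1 - p) / n)
        assert abs(rate - p) < 3 * se, (s_from, s_to, rate, p, n)


def test_intercept_only_admission_rate_is_binomial():
    p = 1.0 / (1.0 + np.exp(6.0))  # sigmoid(-6)
    total_days, admissions = 0, 0
    for seed in range(50):
        c = cfg(n_patients=20, n_days=50, seed=seed,
                admit_intercept=-6.0, admit_severity=0.0,
                admit_spo2_drop=0.0, admit_pulse_rise=0.0,
                day_missing_prob=0.0, field_missing_prob=0.0)
        baseline = generate_baseline(c)
        records, _ = generate_daily(c, baseline)
        total_days += len(records)
        admissions += int(records["admission"].sum())
    lo, hi = stats.binom.interval(0.99, total_days, p)
    assert lo <= admissions <= hi


def test_default_event_rates_have_paper_like_magnitudes(tiny_config):
    """Admissions of order 1e-3 per patient-day; corticosteroid onsets of
    order 1e-2 per eligible patient-day."""
    c = cfg(seed=5)
    _, records, truth = generate_cohort(c)
    adm_rate = records["admission"].mean()
    assert 2e-4 < adm_rate < 5e-3
    # onset = course start: off-course day followed by an on-course day
    ster = records.sort_values(["patient_id", "day"])
    on = ster.groupby("patient_id")["corticosteroid"].ffill()
    prev_on = on.groupby(ster["patient_id"]).shift(1)
    onset = (on == 1) & (prev_on == 0)
    eligible = prev_on == 0
    onset_rate = onset.sum() / eligible.sum()
    assert 3e-3 < onset_rate < 5e-2


# ---------------------------------------------------------------------------
# missingness

def test_no_missingness_is_identity(clean_records):
    _, records, _ = clean_records
    c = cfg(n_patients=4, n_days=40, seed=3,
            day_missing_prob=0.0, field_missing_prob=0.0)
    pd.testing.assert_frame_equal(apply_missingness(records, c), records)


def test_total_masking(clean_records):
    _, records, _ = clean_records
    c = cfg(n_patients=4, n_days=40, seed=3,
            day_missing_prob=1.0, field_missing_prob=0.0)
    out = apply_missingness(records, c)
    assert out[MASKABLE_FIELDS].isna().all().all()
    # outcome events never masked
    assert out["admission"].notna().all()


def test_missing_rate_calibration():
    c = cfg(n_patients=200, n_days=500, day_missing_prob=0.3,
            field_missing_prob=0.0, missing_dispersion=5000.0,
            admit_intercept=-30.0)  # no admissions -> no inflation anywhere
    baseline = generate_baseline(c)
    records, _ = generate_daily(c, baseline)
    masked = apply_missingness(records, c)
    frac = masked["breathlessness"].isna().mean()
    assert 0.29 < frac < 0.31


def test_preadmission_missingness_inflation():
    # base 0.5 x multiplier 2 -> certainty of masking on the 3 days
    # before each admission
    c = cfg(n_patients=30, n_days=200, seed=11, day_missing_prob=0.5,
            field_missing_prob=0.0, missing_dispersion=1e6,
            preadmission_multiplier=2.0, preadmission_window=3)
    baseline = generate_baseline(c)
    records, _ = generate_daily(c, baseline)
    masked = apply_missingness(records, c)
    m = masked.sort_values(["patient_id", "day"]).reset_index(drop=True)
    adm_rows = m.index[m["admission"] == 1]
    checked = 0
    for i in adm_rows:
        pid = m.loc[i, "patient_id"]
        for k in (1, 2, 3):
            j = i - k
            if j >= 0 and m.loc[j, "patient_id"] == pid:
                assert m.loc[j, MASKABLE_FIELDS].isna().all()
                checked += 1
    assert checked > 10


# ---------------------------------------------------------------------------
# weather and oracle

def test_weather_is_seasonal_and_indicator_consistent():
    w = generate_weather(cfg(n_days=365))
    assert ((w["temp_mean_48h"] < 2.0) == (w["cold_mean_lt2"] == 1)).all()
    assert ((w["temp_max_48h"] < 4.0) == (w["cold_max_lt4"] == 1)).all()
    assert w["alert_level"].isin([0, 1, 2, 3]).all()
    # starting in autumn, mid-study (winter) is colder than the start
    assert w["temp_mean_48h"][80:140].mean() < w["temp_mean_48h"][:30].mean()


def test_oracle_scores_select_the_generative_probability(clean_records):
    _, _, truth = clean_records
    adm = oracle_scores(truth, "admission")
    ster = oracle_scores(truth, "corticosteroid")
    assert (adm == truth["admission_probability"]).all()
    assert (ster == truth["corticosteroid_probability"]).all()
    with pytest.raises(ValueError):
        oracle_scores(truth, "antibiotic")


def test_constant_hazard_gives_constant_oracle():
    c = cfg(n_patients=5, n_days=30, admit_severity=0.0, admit_spo2_drop=0.0,
            admit_pulse_rise=0.0, day_missing_prob=0.0, field_missing_prob=0.0)
    baseline = generate_baseline(c)
    _, truth = generate_daily(c, baseline)
    assert truth["admission_probability"].nunique() == 1


def test_severity_driven_oracle_is_informative():
    """With a state-dependent hazard, the generative admission
    probabilities separate event days from non-event days: the oracle AUC
    clears chance with a CI excluding 0.5 at >10^4 patient-days."""
    from telecopd.evaluation import auc, auc_ci
    c = cfg(n_patients=60, n_days=200, seed=21)
    baseline = generate_baseline(c)
    records, truth = generate_daily(c, baseline)
    scores = oracle_scores(truth, "admission").to_numpy()
    labels = records["admission"].to_numpy()
    assert auc(scores, labels) > 0.7
    lo, hi = auc_ci(scores, labels, "delong")
    assert lo > 0.5
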
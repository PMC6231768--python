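"""Synthetic COPD telemonitoring cohorts with known ground truth.

The generator emulates a home-telemonitoring study in moderate-to-severe
COPD: each patient reports eight binary symptoms, pulse and oxygen
saturation daily, together with antibiotic and corticosteroid use, and may
be admitted to hospital. A latent three-state disease process
(stable / prodrome / exacerbation) drives symptoms, physiology and event
hazards, so every downstream detection or prediction method can be scored
against the exact generative event probabilities (the Bayes-optimal risk
scores for the simulated outcomes).

Realistic features deliberately built in:

* admissions are rare (order 10^-3 per patient-day) while corticosteroid
  course onsets are moderately frequent (order 10^-2);
* reporting is bursty: whole days go unreported at a patient-specific rate,
  and the missingness rate is inflated on the days immediately before an
  admission (patients who are becoming very unwell stop reporting);
* weather is a shared exogenous daily series (seasonal temperature with the
  conventional cold-threshold indicators and a population alert level); by
  default it is independent of any individual's risk, but a coupling
  parameter can make cold spells raise population symptom burden.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import stream

__all__ = [
    "SYMPTOMS",
    "MAJOR_SYMPTOMS",
    "MINOR_SYMPTOMS",
    "MASKABLE_FIELDS",
    "WEATHER_FIELDS",
    "STATE_NAMES",
    "ConfigError",
    "CohortConfig",
    "weather_coupled_config",
    "generate_baseline",
    "generate_weather",
    "generate_daily",
    "apply_missingness",
    "generate_cohort",
    "oracle_scores",
]

#: Major symptoms carry weight 2 in the telemonitoring score.
MAJOR_SYMPTOMS = ["breathlessness", "sputum_colour", "sputum_amount"]
#: Minor symptoms carry weight 1.
MINOR_SYMPTOMS = ["cold", "wheeze", "sore_throat", "cough", "fever"]
SYMPTOMS = MAJOR_SYMPTOMS + MINOR_SYMPTOMS

#: Patient-reported fields that the missingness process may blank.
MASKABLE_FIELDS = SYMPTOMS + ["pulse", "spo2", "antibiotic", "corticosteroid"]

#: Exogenous daily covariates (shared across patients, never masked).
WEATHER_FIELDS = [
    "temp_mean_48h",
    "temp_max_48h",
    "cold_mean_lt2",
    "cold_max_lt4",
    "cold_max_lt7",
    "alert_level",
]

STATE_NAMES = ["stable", "prodrome", "exacerbation"]
STABLE, PRODROME, EXACERBATION = 0, 1, 2

BASELINE_CONTINUOUS = [
    "age", "bmi", "fev1_pct", "mrc_grade", "anxiety", "depression",
    "sgrq", "prior_admissions",
]
BASELINE_CATEGORICAL = ["sex", "smoking"]
BASELINE_FIELDS = [
    "age", "sex", "bmi", "fev1_pct", "mrc_grade", "anxiety",
    "depression", "sgrq", "prior_admissions", "smoking",
]


class ConfigError(ValueError):
    """Raised when a configuration fails validation; message lists all problems."""


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class CohortConfig:
    """Parameters of the synthetic telemonitoring cohort.

    Defaults describe the study conditions the package targets: 135 patients
    followed for about a year of daily reports, a handful of admissions per
    thousand patient-days, corticosteroid course onsets two orders of
    magnitude more frequent, and roughly a fifth of days unreported.
    """

    n_patients: int = 135
    n_days: int = 363
    seed: int = 0

    # latent 3-state Markov chain (per-day transition probabilities);
    # states cycle stable -> prodrome -> exacerbation -> stable, with
    # self-loops carrying the remaining mass.
    p_stable_to_prodrome: float = 0.02
    p_prodrome_to_exacerbation: float = 0.25
    p_exacerbation_to_stable: float = 0.30
    reset_state_on_admission: bool = True

    # symptom emission probabilities, one row per state (stable, prodrome,
    # exacerbation), columns in SYMPTOMS order (3 major then 5 minor).
    symptom_emission: tuple = (
        (0.06, 0.05, 0.06, 0.10, 0.12, 0.06, 0.14, 0.03),
        (0.22, 0.18, 0.22, 0.28, 0.35, 0.18, 0.40, 0.10),
        (0.80, 0.72, 0.78, 0.55, 0.65, 0.40, 0.70, 0.45),
    )

    # physiology: patient-level baselines and state-dependent shifts
    pulse_mean: float = 78.0        # bpm, between-patient mean
    pulse_sd: float = 8.0           # bpm, between-patient SD
    pulse_noise_sd: float = 5.0     # bpm, day-to-day noise
    pulse_shift: tuple = (0.0, 4.0, 12.0)   # bpm added per state
    spo2_mean: float = 93.0         # %, between-patient mean
    spo2_sd: float = 2.0
    spo2_noise_sd: float = 1.2
    spo2_shift: tuple = (0.0, -1.0, -3.5)   # % added per state

    # admission hazard on day t reflects the *previous* day's condition
    # (the admission follows the deterioration the patient reported):
    # logit = intercept + severity*state(t-1)
    #       + spo2_drop*(baseline - spo2(t-1)) + pulse_rise*(pulse(t-1) - baseline)
    admit_intercept: float = -9.6
    admit_severity: float = 2.45
    admit_spo2_drop: float = 0.15
    admit_pulse_rise: float = 0.03

    # corticosteroid course onset on day t: logit = intercept + weight *
    # nAll(t-1) (the decision follows the previous day's symptom burden);
    # once started, a course continues each day with ster_continue. The
    # recorded corticosteroid_probability is P(taking steroids on day t |
    # truth on day t-1): the continuation probability when on course,
    # the onset hazard otherwise.
    ster_intercept: float = -4.8
    ster_symptom_weight: float = 0.35
    ster_continue: float = 0.85

    # antibiotic use (covariate only, not an outcome)
    abx_intercept: float = -4.3
    abx_symptom_weight: float = 0.30
    abx_continue: float = 0.80

    # missingness: whole-day non-reporting at a patient-specific rate drawn
    # from a Beta with the given mean and concentration, plus independent
    # per-field dropout; both are multiplied by preadmission_multiplier on
    # the preadmission_window days before each admission.
    day_missing_prob: float = 0.25
    field_missing_prob: float = 0.02
    missing_dispersion: float = 12.0
    preadmission_multiplier: float = 3.0
    preadmission_window: int = 3

    # weather (shared series): seasonal mean temperature with noise
    temp_annual_mean: float = 9.0       # deg C
    temp_amplitude: float = 7.0         # deg C, seasonal swing
    temp_noise_sd: float = 2.5          # marginal SD of the AR(1) anomaly
    temp_noise_ar: float = 0.7          # day-to-day persistence (cold snaps)
    temp_max_offset: float = 4.0        # max-over-48h above mean-over-48h
    coldest_day_of_year: int = 15       # mid-January
    start_day_of_year: int = 274        # study starts in autumn
    # coupling > 0 lets cold spells raise everyone's symptom probabilities:
    # emission probs gain coupling * max(0, (5 - temp_mean)/5), clipped.
    weather_coupling: float = 0.0

    # baseline covariates
    age_mean: float = 69.0
    age_sd: float = 8.0
    fev1_mean: float = 45.0
    fev1_sd: float = 12.0
    bmi_mean: float = 26.5
    bmi_sd: float = 5.0
    mrc_probs: tuple = (0.05, 0.15, 0.30, 0.35, 0.15)
    hads_mean: float = 8.0
    hads_sd: float = 4.0
    sgrq_mean: float = 60.0
    sgrq_sd: float = 15.0
    prior_admission_rate: float = 1.0   # Poisson mean on top of the 1 required
    smoking_prob: float = 0.35
    female_prob: float = 0.5
    baseline_missing_prob: float = 0.05

    def validate(self) -> None:
        errors = []
        if self.n_patients < 0:
            errors.append(f"n_patients must be >= 0, got {self.n_patients}")
        if self.n_days < 0:
            errors.append(f"n_days must be >= 0, got {self.n_days}")
        for name in ("p_stable_to_prodrome", "p_prodrome_to_exacerbation",
                     "p_exacerbation_to_stable", "ster_continue", "abx_continue",
                     "day_missing_prob", "field_missing_prob",
                     "baseline_missing_prob", "smoking_prob", "female_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                errors.append(f"{name} must lie in [0,1], got {v}")
        em = np.asarray(self.symptom_emission, dtype=float)
        if em.shape != (3, 8):
            errors.append(f"symptom_emission must be 3 states x 8 symptoms, got {em.shape}")
        elif ((em < 0) | (em > 1)).any():
            errors.append("symptom_emission probabilities must lie in [0,1]")
        if self.preadmission_multiplier < 0:
            errors.append("preadmission_multiplier must be >= 0")
        if self.preadmission_window < 0:
            errors.append("preadmission_window must be >= 0")
        if self.missing_dispersion <= 0:
            errors.append("missing_dispersion must be > 0")
        if abs(sum(self.mrc_probs) - 1.0) > 1e-9:
            errors.append("mrc_probs must sum to 1")
        if errors:
            raise ConfigError("; ".join(errors))


def weather_coupled_config(coupling: float = 0.25, **overrides) -> CohortConfig:
    """A default cohort in which cold spells raise population symptom burden.

    Used for the population-level symptom-score analysis, where exogenous
    weather covariates are expected to carry real predictive signal.
    """
    return replace(CohortConfig(), weather_coupling=coupling, **overrides)


# ---------------------------------------------------------------------------
# baseline covariates

def generate_baseline(config: CohortConfig) -> pd.DataFrame:
    """One row of static covariates per patient, with injected missingness.

    Deterministic given ``config.seed``. Cohorts emulate trial entry
    criteria for moderate-to-severe COPD: FEV1 % predicted below 70 and at
    least one admission in the prior year.
    """
    config.validate()
    n = config.n_patients
    rng = stream(config.seed, "baseline")
    if n == 0:
        return pd.DataFrame(columns=["patient_id"] + BASELINE_FIELDS)

    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 45, 92).round(0)
    sex = np.where(rng.random(n) < config.female_prob, "F", "M")
    bmi = np.clip(rng.normal(config.bmi_mean, config.bmi_sd, n), 15, 45).round(1)
    fev1 = np.clip(rng.normal(config.fev1_mean, config.fev1_sd, n), 15, 69).round(1)
    mrc = rng.choice(np.arange(1, 6), size=n, p=np.asarray(config.mrc_probs))
    anxiety = np.clip(rng.normal(config.hads_mean, config.hads_sd, n), 0, 21).round(0)
    depression = np.clip(rng.normal(config.hads_mean - 1, config.hads_sd, n), 0, 21).round(0)
    sgrq = np.clip(rng.normal(config.sgrq_mean, config.sgrq_sd, n), 0, 100).round(1)
    prior = 1 + rng.poisson(config.prior_admission_rate, n)
    smoking = np.where(rng.random(n) < config.smoking_prob, "yes", "no")

    df = pd.DataFrame({
        "patient_id": np.arange(n),
        "age": age,
        "sex": sex,
        "bmi": bmi,
        "fev1_pct": fev1,
        "mrc_grade": mrc.astype(float),
        "anxiety": anxiety,
        "depression": depression,
        "sgrq": sgrq,
        "prior_admissions": prior.astype(float),
        "smoking": smoking,
    })
    if config.baseline_missing_prob > 0:
        mask = rng.random((n, len(BASELINE_FIELDS))) < config.baseline_missing_prob
        for j, col in enumerate(BASELINE_FIELDS):
            col_mask = mask[:, j]
            if col_mask.all():  # keep at least one observed value per column
                col_mask[0] = False
            if col in BASELINE_CATEGORICAL:
                df.loc[col_mask, col] = None
            else:
                df.loc[col_mask, col] = np.nan
    return df


# ---------------------------------------------------------------------------
# weather

def generate_weather(config: CohortConfig) -> pd.DataFrame:
    """Shared exogenous daily weather series over the study period.

    Sinusoidal seasonal mean temperature with Gaussian noise; the three
    standard cold-threshold indicators (mean < 2 degC, max < 4, max < 7);
    and a 0-3 population alert level derived from the 7-day smoothed
    temperature, emulating a rule-based seasonal COPD risk forecast.
    """
    config.validate()
    rng = stream(config.seed, "weather")
    d = np.arange(config.n_days)
    doy = (config.start_day_of_year + d) % 365.25
    seasonal = config.temp_annual_mean + config.temp_amplitude * np.cos(
        2 * np.pi * (doy - config.coldest_day_of_year) / 365.25 + np.pi
    )
    # AR(1) anomaly: cold snaps persist for days, as real weather does
    phi = config.temp_noise_ar
    innov_sd = config.temp_noise_sd * np.sqrt(max(1.0 - phi ** 2, 1e-12))
    eps = rng.normal(0.0, innov_sd, config.n_days)
    anom = np.empty(config.n_days)
    prev = rng.normal(0.0, config.temp_noise_sd) if config.n_days else 0.0
    for i in range(config.n_days):
        prev = phi * prev + eps[i]
        anom[i] = prev
    temp_mean = seasonal + anom
    temp_max = temp_mean + config.temp_max_offset + rng.normal(0.0, 1.0, config.n_days)
    smoothed = pd.Series(temp_mean).rolling(7, min_periods=1).mean().to_numpy()
    alert = np.select([smoothed < 1.0, smoothed < 4.0, smoothed < 8.0], [3, 2, 1], default=0)
    return pd.DataFrame({
        "day": d,
        "temp_mean_48h": temp_mean.round(2),
        "temp_max_48h": temp_max.round(2),
        "cold_mean_lt2": (temp_mean < 2.0).astype(int),
        "cold_max_lt4": (temp_max < 4.0).astype(int),
        "cold_max_lt7": (temp_max < 7.0).astype(int),
        "alert_level": alert,
    })


# ---------------------------------------------------------------------------
# daily records

def generate_daily(config: CohortConfig, baseline: pd.DataFrame,
                   weather: pd.DataFrame | None = None,
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the daily record table and the latent ground truth.

    Per patient the latent chain is advanced one day at a time; symptoms are
    drawn from the state's emission probabilities, physiology is the
    patient's personal baseline plus a state shift plus noise, and admission
    / corticosteroid events are drawn from logistic hazards whose exact
    probabilities are recorded in the truth table. An admission resets the
    latent state to stable when so configured.

    Returns the *fully observed* records (no missingness yet) and the
    latent-truth table with one row per patient-day.
    """
    config.validate()
    missing = set(np.arange(config.n_patients)) - set(baseline["patient_id"])
    if missing:
        raise ValueError(f"baseline table lacks patient ids: {sorted(missing)[:5]}")
    n, T = config.n_patients, config.n_days
    if weather is None:
        weather = generate_weather(config)

    latent_rng = stream(config.seed, "latent")
    sym_rng = stream(config.seed, "symptoms")
    phys_rng = stream(config.seed, "physiology")
    event_rng = stream(config.seed, "events")

    if n == 0 or T == 0:
        cols = ["patient_id", "day"] + SYMPTOMS + [
            "pulse", "spo2", "antibiotic", "corticosteroid", "admission",
        ] + WEATHER_FIELDS
        truth_cols = ["patient_id", "day", "state",
                      "admission_probability", "corticosteroid_probability"]
        return pd.DataFrame(columns=cols), pd.DataFrame(columns=truth_cols)

    emission = np.asarray(config.symptom_emission, dtype=float)
    pulse_base = phys_rng.normal(config.pulse_mean, config.pulse_sd, n)
    spo2_base = np.clip(phys_rng.normal(config.spo2_mean, config.spo2_sd, n), 85, 99)
    pulse_shift = np.asarray(config.pulse_shift)
    spo2_shift = np.asarray(config.spo2_shift)

    temp_mean = weather["temp_mean_48h"].to_numpy()
    cold_excess = np.maximum(0.0, (5.0 - temp_mean) / 5.0)

    state = np.zeros(n, dtype=int)
    on_ster = np.zeros(n, dtype=bool)
    on_abx = np.zeros(n, dtype=bool)

    states = np.empty((T, n), dtype=int)
    symptoms = np.empty((T, n, 8), dtype=np.int8)
    pulse = np.empty((T, n))
    spo2 = np.empty((T, n))
    admit = np.empty((T, n), dtype=np.int8)
    ster = np.empty((T, n), dtype=np.int8)
    abx = np.empty((T, n), dtype=np.int8)
    p_admit = np.empty((T, n))
    p_ster = np.empty((T, n))

    for t in range(T):
        if t > 0:
            u = latent_rng.random(n)
            nxt = state.copy()
            nxt[(state == STABLE) & (u < config.p_stable_to_prodrome)] = PRODROME
            nxt[(state == PRODROME) & (u < config.p_prodrome_to_exacerbation)] = EXACERBATION
            nxt[(state == EXACERBATION) & (u < config.p_exacerbation_to_stable)] = STABLE
            if config.reset_state_on_admission:
                nxt[admit[t - 1] == 1] = STABLE
            state = nxt
        states[t] = state

        probs = emission[state]  # (n, 8)
        if config.weather_coupling > 0 and cold_excess[t] > 0:
            probs = np.clip(probs + config.weather_coupling * cold_excess[t], 0.0, 0.95)
        symptoms[t] = (sym_rng.random((n, 8)) < probs).astype(np.int8)

        pulse[t] = pulse_base + pulse_shift[state] + phys_rng.normal(0, config.pulse_noise_sd, n)
        spo2[t] = spo2_base + spo2_shift[state] + phys_rng.normal(0, config.spo2_noise_sd, n)
        pulse[t] = np.clip(pulse[t], 30, 220)
        spo2[t] = np.clip(spo2[t], 50, 100)

        # hazards reflect the previous day's condition: the admission (or
        # treatment decision) follows the deterioration the patient reported
        prev = t - 1 if t > 0 else 0
        logit_a = (config.admit_intercept
                   + config.admit_severity * states[prev]
                   + config.admit_spo2_drop * (spo2_base - spo2[prev])
                   + config.admit_pulse_rise * (pulse[prev] - pulse_base))
        p_admit[t] = _sigmoid(logit_a)
        admit[t] = (event_rng.random(n) < p_admit[t]).astype(np.int8)

        n_all = symptoms[prev].sum(axis=1)
        p_start = _sigmoid(config.ster_intercept + config.ster_symptom_weight * n_all)
        start = (event_rng.random(n) < p_start) & ~on_ster
        cont = (event_rng.random(n) < config.ster_continue) & on_ster
        # generative probability of taking corticosteroids today given
        # yesterday's truth: continuation if on course, onset hazard if not
        p_ster[t] = np.where(on_ster, config.ster_continue, p_start)
        on_ster = start | cont
        ster[t] = on_ster.astype(np.int8)

        pa_start = _sigmoid(config.abx_intercept + config.abx_symptom_weight * n_all)
        a_start = (event_rng.random(n) < pa_start) & ~on_abx
        a_cont = (event_rng.random(n) < config.abx_continue) & on_abx
        on_abx = a_start | a_cont
        abx[t] = on_abx.astype(np.int8)

    pid = np.repeat(np.arange(n), T)
    day = np.tile(np.arange(T), n)

    def flat(a):  # (T, n) -> patient-major order
        return np.asarray(a).T.reshape(-1)

    records = pd.DataFrame({"patient_id": pid, "day": day})
    for j, s in enumerate(SYMPTOMS):
        records[s] = flat(symptoms[:, :, j]).astype(float)
    records["pulse"] = flat(pulse).round(1)
    records["spo2"] = flat(spo2).round(1)
    records["antibiotic"] = flat(abx).astype(float)
    records["corticosteroid"] = flat(ster).astype(float)
    records["admission"] = flat(admit).astype(int)
    records = records.merge(weather, on="day", how="left")

    truth = pd.DataFrame({
        "patient_id": pid,
        "day": day,
        "state": flat(states),
        "admission_probability": flat(p_admit),
        "corticosteroid_probability": flat(p_ster),
    })
    return records, truth


# ---------------------------------------------------------------------------
# missingness

def apply_missingness(records: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Blank patient-reported fields to emulate bursty non-reporting.

    Two mechanisms: whole-day non-reporting at a patient-specific rate
    (Beta-distributed across patients around ``day_missing_prob``), and
    independent per-field dropout at ``field_missing_prob``. Both
    probabilities are multiplied by ``preadmission_multiplier`` on the
    ``preadmission_window`` days before each admission (capped at 1).
    Outcome events (the admission flag) and exogenous weather are never
    masked.
    """
    config.validate()
    out = records.copy()
    if len(out) == 0 or (config.day_missing_prob == 0 and config.field_missing_prob == 0):
        return out
    rng = stream(config.seed, "missingness")

    pids = out["patient_id"].to_numpy()
    unique_pids = np.unique(pids)
    mean, kappa = config.day_missing_prob, config.missing_dispersion
    if mean in (0.0, 1.0):
        day_rate = np.full(len(unique_pids), mean)
    else:
        day_rate = rng.beta(mean * kappa, (1 - mean) * kappa, len(unique_pids))
    rate_map = dict(zip(unique_pids, day_rate))
    base_day = np.array([rate_map[p] for p in pids])

    # pre-admission inflation: mark the m days before each admission
    mult = np.ones(len(out))
    if config.preadmission_multiplier != 1.0 and config.preadmission_window > 0:
        adm = out["admission"].to_numpy() == 1
        near = np.zeros(len(out), dtype=bool)
        for k in range(1, config.preadmission_window + 1):
            shifted = np.zeros(len(out), dtype=bool)
            shifted[:-k] = adm[k:]
            same_patient = pids[:-k] == pids[k:] if k else None
            shifted[:-k] &= same_patient
            near |= shifted
        mult[near] = config.preadmission_multiplier

    p_day = np.clip(base_day * mult, 0.0, 1.0)
    day_masked = rng.random(len(out)) < p_day
    p_field = np.clip(config.field_missing_prob * mult, 0.0, 1.0)
    field_masked = rng.random((len(out), len(MASKABLE_FIELDS))) < p_field[:, None]

    for j, col in enumerate(MASKABLE_FIELDS):
        out.loc[day_masked | field_masked[:, j], col] = np.nan
    return out


def generate_cohort(config: CohortConfig,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full pipeline: baseline, daily records with missingness, latent truth."""
    baseline = generate_baseline(config)
    records, truth = generate_daily(config, baseline)
    observed = apply_missingness(records, config)
    return baseline, observed, truth


# ---------------------------------------------------------------------------
# oracle

def oracle_scores(truth: pd.DataFrame, outcome: str) -> pd.Series:
    """Exact generative per-patient-day event probabilities.

    These are the Bayes-optimal risk scores for the simulated outcome: no
    classifier evaluated on held-out synthetic data can beat their AUC by
    more than sampling noise.
    """
    if outcome == "admission":
        return truth["admission_probability"].copy()
    if outcome == "corticosteroid":
        return truth["corticosteroid_probability"].copy()
    raise ValueError(f"unknown outcome {outcome!r}; expected 'admission' or 'corticosteroid'")
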
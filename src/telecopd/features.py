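"""Fixed-length feature vectors from patient episodes.

Each episode (a W-day window of daily variables ending at day t, plus its
imputation-indicator matrix and the patient's static baseline covariates)
is turned into a named numeric vector. Features come from a declarative
*catalogue* of simple time-series transforms — current value, lags,
rolling means/extrema/SD, linear-trend slopes, counts, days-since-last-use
of a medication, deltas and imputed fractions — each reading only days
<= t, so nothing can leak from the future.

The default telemonitoring catalogue (with imputation indicators) defines
exactly 153 named features; the manifest is programmatically auditable via
:meth:`FeatureCatalogue.to_frame`. Smaller weather-only and larger joint
variants exist for the covariate-set comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import (BASELINE_CATEGORICAL, MASKABLE_FIELDS, SYMPTOMS,
                     WEATHER_FIELDS)
from .episodes import EpisodeSet
from .rules import count_frame

__all__ = [
    "FeatureDef",
    "FeatureCatalogue",
    "default_catalogue",
    "impute_baseline",
    "encode_baseline",
    "BASELINE_FEATURES",
    "extract_features",
    "extract_one",
]

#: Static covariates appended to every episode's vector, after encoding.
BASELINE_FEATURES = [
    "bl_age", "bl_sex_male", "bl_bmi", "bl_fev1_pct", "bl_mrc_grade",
    "bl_anxiety", "bl_depression", "bl_sgrq", "bl_prior_admissions",
    "bl_smoking_yes",
]

_DERIVED = ("score", "n_major", "n_all")
_TRANSFORMS = ("current", "lag", "mean", "min", "max", "sd", "slope",
               "count", "any", "delta", "days_since", "imputed_frac",
               "baseline")


@dataclass(frozen=True)
class FeatureDef:
    """One feature: a transform of one source variable with a day parameter
    (lag length or window width; 0 where not applicable)."""
    name: str
    var: str
    transform: str
    param: int = 0

    def context_needed(self) -> int:
        """Days of history (beyond day t) this feature reads."""
        if self.transform in ("current", "baseline", "days_since", "imputed_frac"):
            return 0
        if self.transform in ("lag", "delta"):
            return self.param
        return self.param - 1  # rolling windows of width param


class FeatureCatalogue:
    """Ordered, named collection of feature definitions."""

    def __init__(self, definitions, window: int):
        self.definitions = list(definitions)
        self.window = int(window)
        names = [d.name for d in self.definitions]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate feature names: {dupes}")
        for d in self.definitions:
            if d.transform not in _TRANSFORMS:
                raise ValueError(f"unknown transform {d.transform!r} in {d.name}")
            if d.context_needed() > self.window - 1:
                raise ValueError(
                    f"feature {d.name} needs {d.context_needed()} days of "
                    f"history but the episode window is {self.window}")

    @property
    def names(self):
        return [d.name for d in self.definitions]

    def __len__(self):
        return len(self.definitions)

    def __iter__(self):
        return iter(self.definitions)

    def to_frame(self) -> pd.DataFrame:
        """The auditable manifest: one row per feature."""
        return pd.DataFrame([{
            "name": d.name, "variable": d.var,
            "transform": d.transform, "param": d.param,
        } for d in self.definitions])


def _tm_definitions(W: int):
    """Telemonitoring feature family (143 features at W=7)."""
    defs = []
    max_lag = W - 1

    def lag_range(upper):
        return range(1, min(upper, max_lag) + 1)

    for s in SYMPTOMS:
        defs.append(FeatureDef(f"{s}", s, "current"))
        for k in lag_range(6):
            defs.append(FeatureDef(f"{s}_lag{k}", s, "lag", k))
        for w in (3, 7):
            if w <= W:
                defs.append(FeatureDef(f"{s}_count{w}", s, "count", w))
        if max_lag >= 1:
            defs.append(FeatureDef(f"{s}_delta1", s, "delta", 1))

    defs.append(FeatureDef("score", "score", "current"))
    for k in lag_range(6):
        defs.append(FeatureDef(f"score_lag{k}", "score", "lag", k))
    for w in (3, 7):
        if w <= W:
            defs.append(FeatureDef(f"score_mean{w}", "score", "mean", w))
    if 7 <= W:
        defs.append(FeatureDef("score_slope7", "score", "slope", 7))
        defs.append(FeatureDef("score_max7", "score", "max", 7))
    if max_lag >= 1:
        defs.append(FeatureDef("score_delta1", "score", "delta", 1))
    defs.append(FeatureDef("n_major", "n_major", "current"))
    defs.append(FeatureDef("n_all", "n_all", "current"))

    for v, extremum in (("pulse", "max"), ("spo2", "min")):
        defs.append(FeatureDef(f"{v}", v, "current"))
        for k in lag_range(6):
            defs.append(FeatureDef(f"{v}_lag{k}", v, "lag", k))
        for w in (3, 7):
            if w <= W:
                defs.append(FeatureDef(f"{v}_mean{w}", v, "mean", w))
        if 7 <= W:
            defs.append(FeatureDef(f"{v}_{extremum}7", v, extremum, 7))
            defs.append(FeatureDef(f"{v}_sd7", v, "sd", 7))
            defs.append(FeatureDef(f"{v}_slope7", v, "slope", 7))
        if max_lag >= 1:
            defs.append(FeatureDef(f"{v}_delta1", v, "delta", 1))

    for m in ("antibiotic", "corticosteroid"):
        defs.append(FeatureDef(f"{m}", m, "current"))
        if max_lag >= 1:
            defs.append(FeatureDef(f"{m}_lag1", m, "lag", 1))
        for w in (3, 7):
            if w <= W:
                defs.append(FeatureDef(f"{m}_any{w}", m, "any", w))
        if W >= 2:
            defs.append(FeatureDef(f"{m}_days_since", m, "days_since", W))
    return defs


def _indicator_definitions(W: int):
    """Imputation-indicator features (13): per-variable and overall
    imputed fraction over the episode window."""
    defs = [FeatureDef(f"{v}_imputed_frac", v, "imputed_frac", W)
            for v in MASKABLE_FIELDS]
    defs.append(FeatureDef("any_imputed_frac", "__all__", "imputed_frac", W))
    return defs


def _weather_definitions(W: int):
    """Weather feature family (30 at W=7)."""
    defs = []
    max_lag = W - 1
    for v in ("temp_mean_48h", "temp_max_48h"):
        defs.append(FeatureDef(f"{v}", v, "current"))
        for k in range(1, min(2, max_lag) + 1):
            defs.append(FeatureDef(f"{v}_lag{k}", v, "lag", k))
        for w in (3, 7):
            if w <= W:
                defs.append(FeatureDef(f"{v}_mean{w}", v, "mean", w))
        if max_lag >= 1:
            defs.append(FeatureDef(f"{v}_delta1", v, "delta", 1))
        if 7 <= W:
            defs.append(FeatureDef(f"{v}_slope7", v, "slope", 7))
    for v in ("cold_mean_lt2", "cold_max_lt4", "cold_max_lt7"):
        defs.append(FeatureDef(f"{v}", v, "current"))
        if max_lag >= 1:
            defs.append(FeatureDef(f"{v}_lag1", v, "lag", 1))
        for w in (3, 7):
            if w <= W:
                defs.append(FeatureDef(f"{v}_count{w}", v, "count", w))
    defs.append(FeatureDef("alert_level", "alert_level", "current"))
    if max_lag >= 1:
        defs.append(FeatureDef("alert_level_lag1", "alert_level", "lag", 1))
    if 7 <= W:
        defs.append(FeatureDef("alert_level_mean7", "alert_level", "mean", 7))
        defs.append(FeatureDef("alert_level_max7", "alert_level", "max", 7))
    return defs


def _baseline_definitions():
    return [FeatureDef(name, name, "baseline") for name in BASELINE_FEATURES]


def default_catalogue(variant: str = "telemonitoring", window: int = 7,
                      indicators: bool = True) -> FeatureCatalogue:
    """Build the default catalogue for one covariate set.

    Variants: ``"telemonitoring"`` (symptoms, score, physiology,
    medications, indicators, baseline — 153 features at W=7 with
    indicators), ``"weather"`` (exogenous weather plus baseline), and
    ``"joint"`` (their union).
    """
    if variant not in ("telemonitoring", "weather", "joint"):
        raise ValueError(f"unknown catalogue variant {variant!r}")
    defs = []
    if variant in ("telemonitoring", "joint"):
        defs += _tm_definitions(window)
        if indicators:
            defs += _indicator_definitions(window)
    if variant in ("weather", "joint"):
        defs += _weather_definitions(window)
    defs += _baseline_definitions()
    return FeatureCatalogue(defs, window)


# ---------------------------------------------------------------------------
# baseline covariates

def impute_baseline(baseline: pd.DataFrame) -> pd.DataFrame:
    """Population median (continuous) / mode (categorical) imputation of
    static covariates, assumed fixed over the study period."""
    out = baseline.copy()
    for col in out.columns:
        if col == "patient_id":
            continue
        if out[col].isna().all():
            raise ValueError(f"baseline column {col!r} has no observed values")
        if col in BASELINE_CATEGORICAL or out[col].dtype == object:
            mode = out[col].mode(dropna=True).iloc[0]
            out[col] = out[col].fillna(mode)
        else:
            out[col] = out[col].fillna(out[col].median())
    return out


def encode_baseline(baseline: pd.DataFrame) -> pd.DataFrame:
    """Numeric encoding of the (already imputed) baseline table, with
    feature-manifest column names."""
    enc = pd.DataFrame({"patient_id": baseline["patient_id"]})
    enc["bl_age"] = baseline["age"].astype(float)
    enc["bl_sex_male"] = (baseline["sex"] == "M").astype(float)
    enc["bl_bmi"] = baseline["bmi"].astype(float)
    enc["bl_fev1_pct"] = baseline["fev1_pct"].astype(float)
    enc["bl_mrc_grade"] = baseline["mrc_grade"].astype(float)
    enc["bl_anxiety"] = baseline["anxiety"].astype(float)
    enc["bl_depression"] = baseline["depression"].astype(float)
    enc["bl_sgrq"] = baseline["sgrq"].astype(float)
    enc["bl_prior_admissions"] = baseline["prior_admissions"].astype(float)
    enc["bl_smoking_yes"] = (baseline["smoking"] == "yes").astype(float)
    return enc


# ---------------------------------------------------------------------------
# extraction

def _slope_kernel(w: int) -> np.ndarray:
    j = np.arange(w, dtype=float)
    c = j - j.mean()
    return c / (c ** 2).sum()


def _grouped(series: pd.Series, pid: np.ndarray):
    return series.groupby(pid, sort=False)


def _rolling(series: pd.Series, pid: np.ndarray, w: int, fn: str) -> pd.Series:
    r = _grouped(series, pid).rolling(w, min_periods=w)
    out = getattr(r, fn)()
    out = out.reset_index(drop=True)
    out.index = series.index
    return out


def _day_features(episodes: EpisodeSet, catalogue: FeatureCatalogue) -> pd.DataFrame:
    """Day-level values of every non-baseline feature, computed once over
    the whole (filled) grid; episode rows are then picked out by (patient,
    day). All transforms look strictly backwards."""
    grid = episodes.grid
    pid = grid["patient_id"].to_numpy()
    counts = count_frame(grid)
    flags = episodes.flags

    def source(var: str) -> pd.Series:
        if var in _DERIVED:
            return counts[var].astype(float)
        if var == "__all__":
            raise KeyError(var)
        if var not in grid.columns:
            raise KeyError(var)
        return grid[var].astype(float)

    cols = {}
    for d in catalogue:
        if d.transform == "baseline":
            continue
        try:
            if d.transform == "imputed_frac":
                if d.var == "__all__":
                    s = flags[MASKABLE_FIELDS].mean(axis=1)
                else:
                    s = flags[d.var].astype(float)
                cols[d.name] = _rolling(s, pid, d.param, "mean")
                continue
            x = source(d.var)
        except KeyError:
            raise KeyError(
                f"feature {d.name!r} requires variable {d.var!r}, absent "
                f"from the episode grid") from None
        if d.transform == "current":
            cols[d.name] = x
        elif d.transform == "lag":
            cols[d.name] = _grouped(x, pid).shift(d.param)
        elif d.transform == "delta":
            cols[d.name] = x - _grouped(x, pid).shift(d.param)
        elif d.transform in ("mean", "min", "max", "sd", "count", "any"):
            fn = {"mean": "mean", "min": "min", "max": "max", "sd": "std",
                  "count": "sum", "any": "max"}[d.transform]
            cols[d.name] = _rolling(x, pid, d.param, fn)
        elif d.transform == "slope":
            kern = _slope_kernel(d.param)
            acc = None
            for k in range(d.param):
                term = _grouped(x, pid).shift(k) * kern[d.param - 1 - k]
                acc = term if acc is None else acc + term
            cols[d.name] = acc
        elif d.transform == "days_since":
            day = grid["day"].astype(float)
            pos_day = day.where(x > 0)
            last_pos = _grouped(pos_day, pid).ffill()
            since = (day - last_pos).clip(upper=d.param)
            cols[d.name] = since.fillna(float(d.param))
        else:  # pragma: no cover - guarded by catalogue validation
            raise ValueError(f"unknown transform {d.transform}")
    return pd.DataFrame(cols, index=grid.index)


def extract_features(episodes: EpisodeSet, catalogue: FeatureCatalogue,
                     baseline: pd.DataFrame,
                     ) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Feature matrix for every episode in the set.

    Returns ``(X, y, groups)``: the named feature matrix (one row per
    episode, catalogue column order), the 0/1 labels, and the patient id of
    each episode for grouped cross-validation. Baseline covariates are
    median/mode-imputed and appended as static features.
    """
    if catalogue.window > episodes.config.window:
        raise ValueError(
            f"catalogue was built for window {catalogue.window} but episodes "
            f"have window {episodes.config.window}")
    day_feats = _day_features(episodes, catalogue)
    day_feats = day_feats.set_index(
        pd.MultiIndex.from_arrays([episodes.grid["patient_id"], episodes.grid["day"]]))
    keys = pd.MultiIndex.from_arrays(
        [episodes.index["patient_id"], episodes.index["t"]])
    X = day_feats.reindex(keys).reset_index(drop=True)

    bl = encode_baseline(impute_baseline(baseline)).set_index("patient_id")
    bl_rows = bl.reindex(episodes.index["patient_id"]).reset_index(drop=True)
    for d in catalogue:
        if d.transform == "baseline":
            X[d.name] = bl_rows[d.var].to_numpy()
    X = X[catalogue.names]
    y = episodes.index["label"].astype(int).rename("label")
    groups = episodes.index["patient_id"].rename("patient_id")
    return X, y, groups


def extract_one(episodes: EpisodeSet, patient_id, t,
                catalogue: FeatureCatalogue, baseline: pd.DataFrame) -> pd.Series:
    """The feature vector of a single episode (convenience for inspection)."""
    sub = episodes.index[(episodes.index["patient_id"] == patient_id)
                         & (episodes.index["t"] == t)]
    if len(sub) == 0:
        raise KeyError(f"no episode for patient {patient_id} at day {t}")
    one = EpisodeSet(episodes.config, episodes.grid, episodes.flags,
                     sub.reset_index(drop=True))
    X, _, _ = extract_features(one, catalogue, baseline)
    return X.iloc[0]
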
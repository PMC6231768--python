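"""Patient episodes: sliding daily windows linked to a next-day outcome.

An *episode* is a fixed-length window of W consecutive days of one
patient's telemonitoring variables ending at day t, labelled by an outcome
(hospital admission or corticosteroid start) on day t+1. Episodes are built
under two scenarios:

* **complete** — only episodes in which every required patient-reported
  variable was actually observed on every window day are kept;
* **imputed** — missing values are first forward-filled per patient for up
  to ``max_fill_horizon`` days (last observation carried forward), a
  same-shaped indicator matrix records which entries were filled, and
  episodes that still contain missing required values (or a missing
  outcome) are dropped.

Only past observations are ever used to fill a value, so no episode can
leak information from beyond its end day. Calendar gaps (days with no
record row at all) are materialised as all-missing rows first, keeping the
day axis contiguous; exogenous weather is restored on such rows from the
shared daily series and is never imputed from patient data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import MASKABLE_FIELDS, SYMPTOMS, WEATHER_FIELDS

__all__ = [
    "EpisodeConfig",
    "EpisodeSet",
    "exclude_sparse_patients",
    "forward_fill",
    "materialize_day_grid",
    "build_episodes",
    "corticosteroid_filter",
]


@dataclass
class EpisodeConfig:
    """How episodes are cut from the daily record stream."""

    window: int = 7                 # W, days per episode (ending at day t)
    max_fill_horizon: int = 15      # LOCF horizon, days
    scenario: str = "imputed"       # "complete" | "imputed"
    outcome: str = "admission"      # "admission" | "corticosteroid"
    sparse_patient_threshold: float = 0.95
    # variables that must be present (after filling, in the imputed
    # scenario) on every window day for the episode to be usable
    required_variables: tuple = tuple(MASKABLE_FIELDS)

    def validate(self) -> None:
        errors = []
        if self.window < 1:
            errors.append(f"window must be >= 1, got {self.window}")
        if self.max_fill_horizon < 0:
            errors.append(f"max_fill_horizon must be >= 0, got {self.max_fill_horizon}")
        if self.scenario not in ("complete", "imputed"):
            errors.append(f"scenario must be 'complete' or 'imputed', got {self.scenario!r}")
        if self.outcome not in ("admission", "corticosteroid"):
            errors.append(f"outcome must be 'admission' or 'corticosteroid', got {self.outcome!r}")
        if not (0.0 <= self.sparse_patient_threshold <= 1.0):
            errors.append("sparse_patient_threshold must lie in [0,1]")
        unknown = set(self.required_variables) - set(MASKABLE_FIELDS)
        if unknown:
            errors.append(f"unknown required variables: {sorted(unknown)}")
        if errors:
            raise ValueError("; ".join(errors))


def exclude_sparse_patients(records: pd.DataFrame, threshold: float = 0.95) -> pd.DataFrame:
    """Drop patients whose overall fraction of missing maskable fields is
    *strictly greater* than ``threshold`` (a patient at exactly the
    threshold is retained).

    The fraction is computed over all maskable patient-reported fields
    (symptoms, physiology and medication flags), not symptoms alone.
    """
    if len(records) == 0:
        return records.copy()
    missing_frac = records[MASKABLE_FIELDS].isna().groupby(records["patient_id"]).mean()
    frac = missing_frac.mean(axis=1)
    keep = frac.index[frac <= threshold]
    return records[records["patient_id"].isin(keep)].copy()


def forward_fill(series: pd.Series, horizon: int) -> tuple[pd.Series, pd.Series]:
    """Last-observation-carried-forward for one patient's variable.

    A missing value is replaced by the most recent observed value if that
    observation is at most ``horizon`` days old; older donors are not used
    and the value stays missing. Returns the filled series and a 0/1 flag
    series marking exactly the entries that were filled. Leading missing
    values have no donor and stay missing (flag 0).
    """
    filled = series.ffill(limit=horizon) if horizon > 0 else series.copy()
    flags = (filled.notna() & series.isna()).astype(int)
    return filled, flags


def materialize_day_grid(records: pd.DataFrame) -> pd.DataFrame:
    """Insert all-missing rows for calendar gaps so each patient's day axis
    is contiguous from their first to their last record.

    Weather columns on inserted rows are restored from the shared daily
    series (weather is exogenous and complete); the admission flag on such
    rows stays missing — those days cannot serve as outcome days.
    """
    if len(records) == 0:
        return records.copy()
    pieces = []
    for pid, grp in records.sort_values(["patient_id", "day"]).groupby("patient_id", sort=True):
        full = np.arange(grp["day"].min(), grp["day"].max() + 1)
        g = grp.set_index("day").reindex(full)
        g.index.name = "day"
        g["patient_id"] = pid
        pieces.append(g.reset_index())
    grid = pd.concat(pieces, ignore_index=True)[records.columns]
    # restore exogenous weather on inserted rows
    weather_cols = [c for c in WEATHER_FIELDS if c in grid.columns]
    if weather_cols:
        wx = (records.dropna(subset=weather_cols)[["day"] + weather_cols]
              .drop_duplicates("day").set_index("day"))
        for c in weather_cols:
            missing = grid[c].isna()
            grid.loc[missing, c] = grid.loc[missing, "day"].map(wx[c])
    return grid


@dataclass
class EpisodeSet:
    """All valid episodes of one (scenario, outcome) analysis.

    ``grid`` holds the (possibly forward-filled) contiguous daily table;
    ``flags`` is a same-indexed 0/1 frame over maskable variables marking
    imputed entries; ``index`` has one row per valid episode with columns
    ``patient_id``, ``t`` (end day) and ``label`` (outcome at t+1).
    """

    config: EpisodeConfig
    grid: pd.DataFrame
    flags: pd.DataFrame
    index: pd.DataFrame

    def __len__(self) -> int:
        return len(self.index)

    @property
    def n_events(self) -> int:
        return int(self.index["label"].sum())

    def episode(self, patient_id, t) -> tuple[pd.DataFrame, pd.DataFrame, int]:
        """Materialise one episode: (W-day value frame, flag frame, label)."""
        row = self.index[(self.index["patient_id"] == patient_id) & (self.index["t"] == t)]
        if len(row) == 0:
            raise KeyError(f"no episode for patient {patient_id} ending at day {t}")
        W = self.config.window
        sel = (self.grid["patient_id"] == patient_id) & \
              self.grid["day"].between(t - W + 1, t)
        values = self.grid[sel].set_index("day")
        flags = self.flags[sel.to_numpy()].set_index(values.index)
        return values, flags, int(row["label"].iloc[0])

    def to_wide(self, variables=None) -> pd.DataFrame:
        """Wide export: one row per episode, columns ``var_d{offset}`` for
        offsets -(W-1)..0 plus ``var_d{offset}_imputed`` indicators and the
        label."""
        variables = list(variables or self.config.required_variables)
        W = self.config.window
        g = self.grid.set_index(["patient_id", "day"])
        f = self.flags.set_index(g.index)
        rows = {}
        keys = pd.MultiIndex.from_frame(self.index[["patient_id", "t"]])
        for off in range(-(W - 1), 1):
            shifted = pd.MultiIndex.from_arrays([
                self.index["patient_id"], self.index["t"] + off])
            for v in variables:
                rows[f"{v}_d{off}"] = g[v].reindex(shifted).to_numpy()
                rows[f"{v}_d{off}_imputed"] = f[v].reindex(shifted).to_numpy()
        out = pd.DataFrame(rows)
        out.insert(0, "patient_id", self.index["patient_id"].to_numpy())
        out.insert(1, "t", self.index["t"].to_numpy())
        out["label"] = self.index["label"].to_numpy()
        return out


def _grouped_ffill(frame: pd.DataFrame, by: pd.Series, columns, horizon: int) -> pd.DataFrame:
    out = frame.copy()
    g = out.groupby(by.to_numpy(), sort=False)
    for col in columns:
        out[col] = g[col].ffill(limit=horizon) if horizon > 0 else out[col]
    return out


def build_episodes(records: pd.DataFrame, config: EpisodeConfig) -> EpisodeSet:
    """Cut all valid episodes from a daily record table.

    Records should already have sparse patients excluded. For the
    corticosteroid outcome the standard onset filter is applied: only
    episodes where the patient reported *not* taking corticosteroids on day
    t are kept, and the label is corticosteroid use on day t+1.
    """
    config.validate()
    W = config.window
    grid = materialize_day_grid(records)
    if len(grid) == 0:
        empty = pd.DataFrame(columns=["patient_id", "t", "label"])
        zero_flags = pd.DataFrame(0, index=grid.index, columns=MASKABLE_FIELDS)
        return EpisodeSet(config, grid, zero_flags, empty)

    raw_missing = grid[MASKABLE_FIELDS].isna()
    if config.scenario == "imputed":
        filled = _grouped_ffill(grid, grid["patient_id"], MASKABLE_FIELDS,
                                config.max_fill_horizon)
    else:
        filled = grid.copy()
    flags = (filled[MASKABLE_FIELDS].notna() & raw_missing).astype(int)

    pid = filled["patient_id"]
    required = list(config.required_variables)
    day_invalid = filled[required].isna().any(axis=1).astype(float)
    window_bad = (day_invalid.groupby(pid.to_numpy(), sort=False)
                  .rolling(W, min_periods=W).sum()
                  .reset_index(drop=True))
    window_bad.index = filled.index

    grp = filled.groupby(pid.to_numpy(), sort=False)
    if config.outcome == "admission":
        label_next = grp["admission"].shift(-1)
    else:
        label_next = grp["corticosteroid"].shift(-1)

    valid = (window_bad == 0) & label_next.notna()

    if config.outcome == "corticosteroid":
        # standard onset filter: not on corticosteroids on day t
        ster_t = filled["corticosteroid"]
        valid &= ster_t.notna() & (ster_t == 0)

    index = pd.DataFrame({
        "patient_id": filled.loc[valid, "patient_id"].to_numpy(),
        "t": filled.loc[valid, "day"].to_numpy(),
        "label": label_next[valid].astype(int).to_numpy(),
    })
    if len(index) == 0 and W > int(grid.groupby("patient_id")["day"].count().max() or 0):
        import warnings
        warnings.warn(f"window {W} exceeds every patient's record length; no episodes built")
    return EpisodeSet(config, filled, flags, index)


def corticosteroid_filter(episodes: EpisodeSet) -> EpisodeSet:
    """Re-apply the corticosteroid onset filter to an episode set.

    ``build_episodes`` already applies this filter when
    ``outcome == 'corticosteroid'``; this standalone entry point exists for
    episode sets built externally. Episodes whose day-t corticosteroid flag
    is missing (after any imputation) are excluded.
    """
    if episodes.config.outcome != "corticosteroid":
        raise ValueError("corticosteroid_filter applies to corticosteroid-outcome episodes")
    g = episodes.grid.set_index(["patient_id", "day"])["corticosteroid"]
    keys = pd.MultiIndex.from_frame(episodes.index[["patient_id", "t"]])
    ster_t = g.reindex(keys)
    keep = (ster_t.notna() & (ster_t == 0)).to_numpy()
    return EpisodeSet(episodes.config, episodes.grid, episodes.flags,
                      episodes.index[keep].reset_index(drop=True))
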
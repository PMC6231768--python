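"""End-to-end experiment orchestration.

One :class:`ExperimentConfig` drives the whole comparison on a single
shared cohort realisation: simulate -> mask -> exclude sparse patients ->
(per outcome and scenario) build episodes -> score the five
symptom-counting definitions -> (imputed scenario) extract features and
run the machine-learning bench under patient-grouped nested CV -> emit a
summary table with one row per grid cell, in the shape
(description, practical, AUC with consensus CI, events N+, samples N).

Imputation and episode construction happen once per (outcome, scenario)
before any fold is drawn, so every model sees identical episodes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (CohortConfig, ConfigError, SYMPTOMS, generate_cohort,
                     oracle_scores)
from .episodes import EpisodeConfig, EpisodeSet, build_episodes, \
    exclude_sparse_patients
from .evaluation import EvaluationReport, make_folds, run_nested_cv
from .features import default_catalogue, extract_features
from .models import ModelSpec, default_specs
from .rules import context_days, count_frame, detect_onsets, is_practical

logger = logging.getLogger("telecopd")

__all__ = [
    "ExperimentConfig",
    "validate_config",
    "definition_scores_for_episodes",
    "oracle_for_episodes",
    "evaluate_definition",
    "run_experiment",
]


@dataclass
class ExperimentConfig:
    """Full experiment grid over one simulated cohort."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    window: int = 7                 # ML episode window W
    max_fill_horizon: int = 15
    sparse_patient_threshold: float = 0.95
    definitions: tuple = (1, 2, 3, 4, 5)
    scenarios: tuple = ("complete", "imputed")
    outcomes: tuple = ("admission", "corticosteroid")
    model_families: tuple = ("boosted",)
    catalogues: tuple = ("telemonitoring",)
    k_outer: int = 10
    k_inner: int = 10
    n_runs: int = 10
    n_boot: int = 1000
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.cohort, dict):
            self.cohort = CohortConfig(**self.cohort)

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_TOP_KEYS = {"cohort", "window", "max_fill_horizon", "sparse_patient_threshold",
             "definitions", "scenarios", "outcomes", "model_families",
             "catalogues", "k_outer", "k_inner", "n_runs", "n_boot", "seed"}


def validate_config(path) -> ExperimentConfig:
    """Load and validate an experiment YAML; all problems are reported in
    one aggregated error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    errors = []
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        errors.append(f"unknown config keys: {sorted(unknown)}")
    cohort_raw = raw.get("cohort", {}) or {}
    cohort_fields = set(CohortConfig.__dataclass_fields__)
    unknown_cohort = set(cohort_raw) - cohort_fields
    if unknown_cohort:
        errors.append(f"unknown cohort keys: {sorted(unknown_cohort)}")
        cohort_raw = {k: v for k, v in cohort_raw.items() if k in cohort_fields}
    try:
        cohort = CohortConfig(**cohort_raw)
        cohort.validate()
    except (ConfigError, TypeError) as exc:
        errors.append(str(exc))
        cohort = None
    kwargs = {k: v for k, v in raw.items() if k in _TOP_KEYS and k != "cohort"}
    for key in ("definitions", "scenarios", "outcomes", "model_families", "catalogues"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    cfg = ExperimentConfig(cohort=cohort or CohortConfig(), **kwargs)
    if cfg.window < 1:
        errors.append(f"window must be >= 1, got {cfg.window}")
    if cfg.max_fill_horizon < 0:
        errors.append("max_fill_horizon must be >= 0")
    if any(d not in (1, 2, 3, 4, 5) for d in cfg.definitions):
        errors.append(f"definitions must be within 1..5, got {cfg.definitions}")
    if any(s not in ("complete", "imputed") for s in cfg.scenarios):
        errors.append(f"unknown scenarios in {cfg.scenarios}")
    if any(o not in ("admission", "corticosteroid") for o in cfg.outcomes):
        errors.append(f"unknown outcomes in {cfg.outcomes}")
    if errors:
        raise ConfigError("; ".join(errors))
    return cfg


# ---------------------------------------------------------------------------
# predictor construction helpers

def definition_scores_for_episodes(definition: int, episodes: EpisodeSet,
                                   ) -> tuple[np.ndarray, pd.DataFrame]:
    """Onset-based risk scores of one definition on an episode set.

    The score for the episode ending at day t is the definition's onset
    flag on day t (predicting the outcome on t+1). Episodes where the rule
    cannot be evaluated (missing required context even after any
    imputation) are dropped; the surviving episode index is returned with
    the aligned scores.
    """
    counts = count_frame(episodes.grid)
    counts["patient_id"] = episodes.grid["patient_id"].to_numpy()
    counts["day"] = episodes.grid["day"].to_numpy()
    pieces = []
    for pid, grp in counts.groupby("patient_id", sort=True):
        onsets = detect_onsets(definition, grp)
        pieces.append(pd.DataFrame({
            "patient_id": pid, "day": grp["day"].to_numpy(),
            "onset": onsets.to_numpy()}))
    onset_tab = pd.concat(pieces, ignore_index=True).set_index(["patient_id", "day"])
    keys = pd.MultiIndex.from_frame(episodes.index[["patient_id", "t"]])
    scores = onset_tab["onset"].reindex(keys).to_numpy()
    keep = ~np.isnan(scores)
    return scores[keep], episodes.index[keep].reset_index(drop=True)


def oracle_for_episodes(truth: pd.DataFrame, episode_index: pd.DataFrame,
                        outcome: str) -> np.ndarray:
    """Generative event probabilities for day t+1 of each episode — the
    Bayes-optimal risk scores for the simulated outcome."""
    probs = truth.set_index(["patient_id", "day"])
    col = oracle_scores(truth, outcome).name or (
        "admission_probability" if outcome == "admission"
        else "corticosteroid_probability")
    keys = pd.MultiIndex.from_arrays(
        [episode_index["patient_id"], episode_index["t"] + 1])
    return probs[col].reindex(keys).to_numpy()


def evaluate_definition(definition: int, episodes: EpisodeSet,
                        folds=None, n_boot: int = 1000,
                        name: str | None = None) -> EvaluationReport:
    """Score one symptom-counting definition as a next-day predictor on an
    episode set and evaluate it exactly as the fitted models are."""
    scores, index = definition_scores_for_episodes(definition, episodes)
    labels = index["label"].to_numpy()
    groups = index["patient_id"].to_numpy()
    report = run_nested_cv(None, labels, groups, scores, _folds_or_dummy(folds),
                           name=name or f"Definition {definition}",
                           n_boot=n_boot)
    return report


def _folds_or_dummy(folds):
    from .evaluation import FoldAssignment
    return folds if folds is not None else FoldAssignment(1, 1, 1, 0)


# ---------------------------------------------------------------------------
# the full grid

def run_experiment(config: ExperimentConfig) -> dict:
    """Execute the full comparison grid on one shared cohort realisation.

    Returns a bundle with the summary table (one row per grid cell), the
    per-row :class:`EvaluationReport` objects, and a provenance block
    (config hash, seed, package version) sufficient to reproduce any row.
    """
    t0 = time.time()
    cohort_cfg = replace(config.cohort, seed=config.seed)
    logger.info("simulating cohort: %d patients x %d days",
                cohort_cfg.n_patients, cohort_cfg.n_days)
    baseline, records, truth = generate_cohort(cohort_cfg)
    records = exclude_sparse_patients(records, config.sparse_patient_threshold)

    reports: dict[str, EvaluationReport] = {}
    rows = []

    def add(key, report, practical, scenario, outcome):
        reports[key] = report
        row = report.to_row()
        row.update({"practical": "Yes" if practical else "No",
                    "scenario": scenario, "outcome": outcome})
        rows.append(row)

    for outcome in config.outcomes:
        for scenario in config.scenarios:
            for d in config.definitions:
                past, _future = context_days(d)
                ep_cfg = EpisodeConfig(
                    window=past, max_fill_horizon=config.max_fill_horizon,
                    scenario=scenario, outcome=outcome,
                    sparse_patient_threshold=config.sparse_patient_threshold,
                    required_variables=tuple(SYMPTOMS) if outcome == "admission"
                    else tuple(SYMPTOMS) + ("corticosteroid",))
                eps = build_episodes(records, ep_cfg)
                try:
                    report = evaluate_definition(d, eps, n_boot=config.n_boot)
                except ValueError as exc:
                    logger.warning("definition %d %s/%s skipped: %s",
                                   d, scenario, outcome, exc)
                    continue
                key = f"def{d}_{scenario}_{outcome}"
                logger.info("%s: AUC %.3f (N=%d, N+=%d)", key,
                            report.aggregated_auc, report.n, report.n_events)
                add(key, report, is_practical(d), scenario, outcome)

        if config.model_families:
            ep_cfg = EpisodeConfig(
                window=config.window, max_fill_horizon=config.max_fill_horizon,
                scenario="imputed", outcome=outcome,
                sparse_patient_threshold=config.sparse_patient_threshold)
            eps = build_episodes(records, ep_cfg)
            folds = make_folds(eps.index, config.k_outer, config.k_inner,
                               config.n_runs, config.seed)
            specs = default_specs(config.seed)
            oracle = oracle_for_episodes(truth, eps.index, outcome)
            rep = run_nested_cv(None, eps.index["label"], eps.index["patient_id"],
                                oracle, folds, name=f"Oracle ({outcome})",
                                n_boot=config.n_boot)
            add(f"oracle_{outcome}", rep, True, "imputed", outcome)
            for variant in config.catalogues:
                cat = default_catalogue(variant, config.window)
                X, y, groups = extract_features(eps, cat, baseline)
                for family in config.model_families:
                    spec = specs[family]
                    key = f"{family}_{variant}_{outcome}"
                    logger.info("fitting %s on %d episodes x %d features",
                                key, len(X), X.shape[1])
                    rep = run_nested_cv(X, y, groups, spec, folds,
                                        name=f"ML ({family}, {variant})",
                                        n_boot=config.n_boot)
                    logger.info("%s: AUC %.3f", key, rep.aggregated_auc)
                    add(key, rep, True, "imputed", outcome)

    summary = pd.DataFrame(rows)[
        ["outcome", "scenario", "description", "practical", "auc",
         "ci_low", "ci_high", "events", "samples", "fpr_at_80_tpr"]]
    bundle = {
        "summary": summary,
        "reports": reports,
        "provenance": {
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "version": __version__,
            "n_patients": int(records["patient_id"].nunique()),
            "runtime_s": round(time.time() - t0, 1),
        },
    }
    return bundle
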
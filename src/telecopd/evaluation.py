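"""Patient-grouped nested cross-validation and AUC machinery.

Episodes from the same patient are strongly dependent, so all data splits
here are made at the *patient* level: a patient's episodes appear either
entirely in a training fold or entirely in a test fold, never both, and
inner (hyperparameter) folds are drawn only from the outer-training
patients. Performance is the *aggregated AUC*: test-fold predictions are
merged across the outer folds of one run (rescuing folds too sparse to
carry an AUC of their own), the merged AUC is computed per run, and runs
with different random partitions are averaged.

Confidence intervals come from three methods — an asymptotic interval
based on the DeLong structural-components variance, a distribution-free
Chebyshev interval using the same variance, and a patient-level (cluster)
bootstrap — plus their interval hull as a conservative consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import stream, substream

__all__ = [
    "FoldAssignment",
    "make_folds",
    "audit_folds",
    "auc",
    "delong_variance",
    "auc_ci",
    "consensus_ci",
    "EvaluationReport",
    "run_nested_cv",
    "fpr_at_tpr",
    "PopulationReport",
    "population_score_prediction",
]


# ---------------------------------------------------------------------------
# folds

@dataclass
class FoldAssignment:
    """Patient-level nested fold structure over several repeated runs.

    ``outer[r]`` maps patient id -> outer fold (0..k_outer-1) in run r;
    ``inner[r][f]`` maps each patient *outside* outer fold f to an inner
    fold (0..k_inner-1) used when f is the test fold.
    """

    k_outer: int
    k_inner: int
    n_runs: int
    seed: int
    outer: list = field(default_factory=list)   # per run: {pid: fold}
    inner: list = field(default_factory=list)   # per run: {outer fold: {pid: fold}}

    def outer_balance(self, episode_counts: pd.Series) -> pd.DataFrame:
        """Episode count per (run, outer fold) and the max/min ratio per run."""
        rows = []
        for r, mapping in enumerate(self.outer):
            counts = np.zeros(self.k_outer)
            for pid, f in mapping.items():
                counts[f] += episode_counts.get(pid, 0)
            rows.append({"run": r, **{f"fold{f}": counts[f] for f in range(self.k_outer)},
                         "max_min_ratio": counts.max() / max(counts.min(), 1)})
        return pd.DataFrame(rows)


def _greedy_balance(pids: np.ndarray, weights: np.ndarray, k: int,
                    rng: np.random.Generator) -> dict:
    """Assign patients to k folds, heaviest first, each to the currently
    lightest fold. The ordering weights are randomly jittered so repeated
    runs give distinct (still episode-balanced) partitions."""
    jitter = rng.uniform(0.5, 1.5, len(pids))
    order = np.argsort(-weights * jitter, kind="stable")
    totals = np.zeros(k)
    out = {}
    for i in order:
        f = int(np.argmin(totals))
        out[pids[i]] = f
        totals[f] += weights[i]
    return out


def make_folds(episode_index: pd.DataFrame, k_outer: int = 10,
               k_inner: int = 10, n_runs: int = 10, seed: int = 0,
               ) -> FoldAssignment:
    """Build patient-disjoint nested folds balanced by episode count.

    ``episode_index`` needs a ``patient_id`` column (one row per episode).
    Raises if there are fewer patients than outer folds.
    """
    counts = episode_index.groupby("patient_id").size()
    pids = counts.index.to_numpy()
    if len(pids) < k_outer:
        raise ValueError(f"{len(pids)} patients cannot fill {k_outer} outer folds")
    rng = stream(seed, "folds")
    fa = FoldAssignment(k_outer, k_inner, n_runs, seed)
    for _ in range(n_runs):
        outer = _greedy_balance(pids, counts.to_numpy().astype(float), k_outer, rng)
        fa.outer.append(outer)
        inner_maps = {}
        for f in range(k_outer):
            train_pids = np.array([p for p in pids if outer[p] != f])
            k_in = min(k_inner, len(train_pids))
            inner_maps[f] = _greedy_balance(
                train_pids, counts.loc[train_pids].to_numpy().astype(float),
                k_in, rng)
        fa.inner.append(inner_maps)
    return fa


def audit_folds(fa: FoldAssignment, patient_ids) -> dict:
    """Exhaustive leakage audit over every (run, outer fold, inner fold).

    Verifies that outer folds partition the patients disjointly and that
    no inner-fold patient sits in the outer test fold. Returns counters;
    raises AssertionError on any violation.
    """
    patient_ids = set(patient_ids)
    n_checked = 0
    for r in range(fa.n_runs):
        outer = fa.outer[r]
        assert set(outer) == patient_ids, f"run {r}: outer folds do not cover all patients"
        for f in range(fa.k_outer):
            test = {p for p, g in outer.items() if g == f}
            inner = fa.inner[r][f]
            train = set(inner)
            assert not (test & train), f"run {r} fold {f}: patient in test and training"
            assert test | train == patient_ids, f"run {r} fold {f}: lost patients"
            for g in set(inner.values()):
                val = {p for p, h in inner.items() if h == g}
                fit_ = train - val
                assert not (val & fit_), "inner fold overlap"
                assert not (val & test), "inner validation overlaps outer test"
                n_checked += 1
    return {"runs": fa.n_runs, "outer_folds": fa.k_outer,
            "inner_folds_checked": n_checked, "shared_patients": 0}


# ---------------------------------------------------------------------------
# AUC and confidence intervals

def auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score+ > score-) + 0.5 * P(tie).

    Ties count one half, so coarse (even binary) scores yield values
    strictly between chance and perfect when they carry partial signal.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = labels == 1
    m, n = int(pos.sum()), int((~pos).sum())
    if m == 0 or n == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - m * (m + 1) / 2) / (m * n))


def delong_variance(scores, labels) -> tuple[float, float]:
    """(AUC, variance) via DeLong's structural components."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("AUC undefined: both classes must be present")
    all_r = stats.rankdata(np.concatenate([pos, neg]))
    pos_r = stats.rankdata(pos)
    neg_r = stats.rankdata(neg)
    v10 = (all_r[:m] - pos_r) / n          # per-positive components
    v01 = 1.0 - (all_r[m:] - neg_r) / m    # per-negative components
    a = float(v10.mean())
    if m < 2 or n < 2:
        return a, float("nan")
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    return a, float(var)


def _cluster_bootstrap_ci(scores, labels, patients, alpha, n_boot, seed):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    patients = np.asarray(patients)
    rng = stream(seed, "bootstrap")
    unique = np.unique(patients)
    groups = {p: np.flatnonzero(patients == p) for p in unique}
    stats_ = []
    for _ in range(n_boot):
        chosen = rng.choice(unique, size=len(unique), replace=True)
        idx = np.concatenate([groups[p] for p in chosen])
        yb = labels[idx]
        if yb.min() == yb.max():
            continue  # single-class replicate carries no AUC
        stats_.append(auc(scores[idx], yb))
    if len(stats_) < max(10, n_boot // 10):
        raise ValueError("bootstrap failed: almost all replicates single-class")
    lo, hi = np.quantile(stats_, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def auc_ci(scores, labels, method: str = "delong", alpha: float = 0.05,
           patients=None, n_boot: int = 1000, seed: int = 0,
           ) -> tuple[float, float]:
    """95% (by default) confidence interval for the AUC.

    ``delong``: normal interval from the structural-components variance.
    ``chebyshev``: point +/- sqrt(variance/alpha) with the same variance —
    distribution-free and always at least as wide as the DeLong interval.
    ``resample``: percentile interval over patient-level (cluster)
    bootstrap replicates; requires ``patients``.
    All intervals are truncated to [0, 1].
    """
    if method == "resample":
        if patients is None:
            raise ValueError("resample CI needs per-observation patient ids")
        return _cluster_bootstrap_ci(scores, labels, patients, alpha, n_boot, seed)
    a, var = delong_variance(scores, labels)
    if not np.isfinite(var):
        if patients is None:
            raise ValueError("too few events for the DeLong variance and no "
                             "patient ids for the bootstrap fallback")
        import warnings
        warnings.warn("fewer than 2 events: falling back to cluster bootstrap")
        return _cluster_bootstrap_ci(scores, labels, patients, alpha, n_boot, seed)
    if method == "delong":
        z = stats.norm.ppf(1 - alpha / 2)
        half = z * np.sqrt(var)
    elif method == "chebyshev":
        half = np.sqrt(var / alpha)
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return float(max(0.0, a - half)), float(min(1.0, a + half))


def consensus_ci(intervals: dict) -> tuple[float, float]:
    """Conservative consensus across CI methods: the interval hull
    (smallest lower bound, largest upper bound)."""
    if len(intervals) < 2:
        raise ValueError("consensus needs at least two intervals")
    los, his = zip(*intervals.values())
    return float(min(los)), float(max(his))


def fpr_at_tpr(scores, labels, target_tpr: float = 0.80,
               interpolate: bool = False) -> float:
    """False-positive rate of the cheapest threshold reaching the target
    sensitivity.

    With ``interpolate=True`` the value is read off the linearly
    interpolated ROC polyline instead — the relevant reading for coarse
    (e.g. binary) scores, corresponding to randomized thresholding.
    """
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(labels, scores)
    if interpolate:
        return float(np.interp(target_tpr, tpr, fpr))
    ok = tpr >= target_tpr - 1e-12
    return float(fpr[ok].min())


# ---------------------------------------------------------------------------
# nested cross-validation

@dataclass
class EvaluationReport:
    """Aggregated result of one predictor over the nested CV."""

    name: str
    aggregated_auc: float
    per_run_auc: list
    ci: dict                    # method -> (lo, hi), computed on pooled predictions
    consensus: tuple
    n: int
    n_events: int
    fpr_at_80_tpr: float
    fpr_at_80_tpr_interp: float
    pooled_scores: np.ndarray = field(repr=False, default=None)
    pooled_labels: np.ndarray = field(repr=False, default=None)

    def to_row(self) -> dict:
        lo, hi = self.consensus
        return {
            "description": self.name,
            "auc": round(self.aggregated_auc, 3),
            "ci_low": round(lo, 3), "ci_high": round(hi, 3),
            "events": self.n_events, "samples": self.n,
            "fpr_at_80_tpr": round(self.fpr_at_80_tpr_interp, 3),
        }


def _evaluate_pooled(name, pooled_scores, pooled_labels, pooled_patients,
                     per_run_auc, n, n_events, alpha, n_boot, seed):
    methods = {}
    methods["delong"] = auc_ci(pooled_scores, pooled_labels, "delong", alpha)
    methods["chebyshev"] = auc_ci(pooled_scores, pooled_labels, "chebyshev", alpha)
    methods["resample"] = auc_ci(pooled_scores, pooled_labels, "resample", alpha,
                                 patients=pooled_patients, n_boot=n_boot, seed=seed)
    return EvaluationReport(
        name=name,
        aggregated_auc=float(np.mean(per_run_auc)),
        per_run_auc=list(map(float, per_run_auc)),
        ci=methods,
        consensus=consensus_ci(methods),
        n=n, n_events=n_events,
        fpr_at_80_tpr=fpr_at_tpr(pooled_scores, pooled_labels, 0.80),
        fpr_at_80_tpr_interp=fpr_at_tpr(pooled_scores, pooled_labels, 0.80,
                                        interpolate=True),
        pooled_scores=pooled_scores, pooled_labels=pooled_labels,
    )


def run_nested_cv(X, y, groups, model, folds: FoldAssignment,
                  name: str | None = None, alpha: float = 0.05,
                  n_boot: int = 1000) -> EvaluationReport:
    """Evaluate one predictor under the patient-grouped nested CV.

    ``model`` is either a :class:`~telecopd.models.ModelSpec` — in which
    case each outer fold's hyperparameters are tuned on its inner folds,
    the model is refitted on the full outer-training set and scored on the
    test fold — or a precomputed score vector aligned with the episodes
    (e.g. a symptom-counting definition predictor or the generative
    oracle), which bypasses fitting and is simply scored on the identical
    episodes.

    Test predictions are merged across outer folds per run; the aggregated
    AUC is the mean of per-run merged AUCs; CIs are computed on the
    all-runs pooled predictions.
    """
    from .models import ModelSpec, fit, predict_scores, tune

    y = np.asarray(y, dtype=int)
    groups = np.asarray(groups)
    n = len(y)
    n_events = int(y.sum())
    if y.min() == y.max():
        raise ValueError("merged labels are single-class; AUC undefined")

    if not isinstance(model, ModelSpec):
        scores = np.asarray(model, dtype=float)
        if scores.shape != y.shape:
            raise ValueError("precomputed scores must align with the episodes")
        a = auc(scores, y)
        return _evaluate_pooled(name or "precomputed", scores, y, groups,
                                [a] * folds.n_runs, n, n_events, alpha,
                                n_boot, folds.seed)

    name = name or model.family
    pooled_s, pooled_y, pooled_g, per_run_auc = [], [], [], []
    for r in range(folds.n_runs):
        outer = folds.outer[r]
        fold_of = np.array([outer[p] for p in groups])
        merged = np.full(n, np.nan)
        for f in range(folds.k_outer):
            test_idx = np.flatnonzero(fold_of == f)
            train_idx = np.flatnonzero(fold_of != f)
            if len(test_idx) == 0:
                continue
            inner_map = folds.inner[r][f]
            inner_of = np.array([inner_map[p] for p in groups[train_idx]])
            inner_folds = []  # positions relative to the outer-training subset
            for g in sorted(set(inner_of)):
                va = np.flatnonzero(inner_of == g)
                tr = np.flatnonzero(inner_of != g)
                if len(np.unique(y[train_idx][tr])) == 2 and len(va):
                    inner_folds.append((tr, va))
            best, _ = tune(X.iloc[train_idx], y[train_idx], groups[train_idx],
                           inner_folds, model)
            m = fit(X.iloc[train_idx], y[train_idx], model, best)
            fold_scores = predict_scores(m, X.iloc[test_idx])
            # each fold's model has its own score scale; only within-fold
            # comparisons are meaningful, so merge fractional ranks
            # (the pooled-rank estimator of the merged AUC)
            merged[test_idx] = stats.rankdata(fold_scores) / (len(fold_scores) + 1)
        ok = ~np.isnan(merged)
        per_run_auc.append(auc(merged[ok], y[ok]))
        pooled_s.append(merged[ok])
        pooled_y.append(y[ok])
        pooled_g.append(groups[ok])
    return _evaluate_pooled(name, np.concatenate(pooled_s),
                            np.concatenate(pooled_y), np.concatenate(pooled_g),
                            per_run_auc, n, n_events, alpha, n_boot, folds.seed)


# ---------------------------------------------------------------------------
# population-level symptom-score prediction

@dataclass
class PopulationReport:
    """Held-out rank correlations of two block-level predictors of the
    population-averaged, baseline-adjusted symptom score."""

    blocks: pd.DataFrame
    lagged_spearman: float
    lagged_kendall: float
    exogenous_spearman: float
    exogenous_kendall: float
    per_fold: pd.DataFrame


def population_score_prediction(records: pd.DataFrame, window: int = 14,
                                n_splits: int = 3, baseline_days: int = 28,
                                seed: int = 0) -> PopulationReport:
    """Predict the 2-week population-averaged baseline-adjusted symptom
    score, comparing a lagged persistence heuristic against a regression
    on exogenous weather/alert covariates.

    The target for block b is the mean over patients and days of
    (daily weighted symptom score - that patient's baseline score), where
    the baseline is the patient's median score over their first
    ``baseline_days`` observed days. Predictor A is the previous block's
    target; predictor B is a linear regression on block-averaged weather
    covariates, fitted on training blocks only. Both are scored by
    Spearman and Kendall rank correlation on held-out blocks.
    """
    from sklearn.linear_model import LinearRegression

    from .rules import count_frame

    counts = count_frame(records)
    score = counts["score"]
    df = records[["patient_id", "day"]].copy()
    df["score"] = score

    def patient_baseline(g):
        obs = g.dropna().iloc[:baseline_days]
        return obs.median() if len(obs) else np.nan

    base = df.groupby("patient_id")["score"].apply(patient_baseline)
    df["adjusted"] = df["score"] - df["patient_id"].map(base)
    daily = df.groupby("day")["adjusted"].mean()

    df["block"] = df["day"] // window
    blocks = df.groupby("block")["adjusted"].mean().rename("target").to_frame()

    wx_cols = [c for c in ("temp_mean_48h", "temp_max_48h", "cold_mean_lt2",
                           "cold_max_lt4", "cold_max_lt7", "alert_level")
               if c in records.columns]
    wx = records.drop_duplicates("day")[["day"] + wx_cols].copy()
    wx["block"] = wx["day"] // window
    blocks = blocks.join(wx.groupby("block")[wx_cols].mean())
    blocks["lagged"] = blocks["target"].shift(1)
    blocks = blocks.dropna()
    if len(blocks) < 3:
        raise ValueError(f"need at least 3 complete blocks, got {len(blocks)}")
    n_splits = min(n_splits, len(blocks))

    rng = substream(seed, "folds", 1)
    order = rng.permutation(len(blocks))
    fold_of = np.empty(len(blocks), dtype=int)
    fold_of[order] = np.arange(len(blocks)) % n_splits

    rows = []
    pred_b = np.full(len(blocks), np.nan)
    for f in range(n_splits):
        test = fold_of == f
        train = ~test
        reg = LinearRegression().fit(blocks.loc[train, wx_cols],
                                     blocks.loc[train, "target"])
        pred_b[test] = reg.predict(blocks.loc[test, wx_cols])
        t_true = blocks.loc[test, "target"]
        if len(t_true) >= 2:
            rows.append({
                "fold": f,
                "lagged_spearman": stats.spearmanr(t_true, blocks.loc[test, "lagged"])[0],
                "lagged_kendall": stats.kendalltau(t_true, blocks.loc[test, "lagged"])[0],
                "exogenous_spearman": stats.spearmanr(t_true, pred_b[test])[0],
                "exogenous_kendall": stats.kendalltau(t_true, pred_b[test])[0],
            })
    blocks["exogenous_pred"] = pred_b
    target = blocks["target"]
    return PopulationReport(
        blocks=blocks,
        lagged_spearman=float(stats.spearmanr(target, blocks["lagged"])[0]),
        lagged_kendall=float(stats.kendalltau(target, blocks["lagged"])[0]),
        exogenous_spearman=float(stats.spearmanr(target, blocks["exogenous_pred"])[0]),
        exogenous_kendall=float(stats.kendalltau(target, blocks["exogenous_pred"])[0]),
        per_fold=pd.DataFrame(rows),
    )
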
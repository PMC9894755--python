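"""Race-composite nested cross-validation framework for sPTB prediction.

Samples are split into 10 outer folds block-stratified on deciles of
gestational age at birth (and race, for microbiome/metabolome models),
repeated 5 times. Within each outer training set, hyperparameters
(feature-pipeline switches plus gradient-boosted-tree parameters) are
tuned on inner folds: candidates are ranked by mean inner R^2 of the
predicted probability against the 0/1 outcome, and among the top five
the one with the best mean inner auROC is selected. A composite
predictor trains a separate model per race stratum ({Black, non-Black});
train-test sterility is strict - no statistic of any test sample enters
a fitted component. Held-out scores are also re-evaluated, without
retraining, against reclassified outcomes (GAB<32, GAB<28); only the
ground-truth labels change, never the scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.feature_selection import mutual_info_classif
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_auc_score, roc_curve

from .cohort_io import CohortMetadata, TaxaTable

__all__ = [
    "FoldPlan",
    "CompositePredictor",
    "PredictionReport",
    "FeatureAttribution",
    "build_fold_plan",
    "sample_hyperparameters",
    "tune_nested",
    "fit_composite",
    "evaluate",
    "compare_auroc",
    "select_final_model",
    "apply_external",
    "attribute_features",
    "nested_cv",
    "lightgbm_factory",
    "StubLearner",
    "clinical_features",
    "microbiome_features",
    "DEFAULT_SPACE",
    "FAST_SPACE",
    "race_strata",
]


# ---------------------------------------------------------------------------
# fold plan
# ---------------------------------------------------------------------------


@dataclass
class FoldPlan:
    n_folds: int
    n_repeats: int
    seed: int | None
    assignment: dict[tuple[int, int], list[str]]  # (repeat, fold) -> test ids

    def test_ids(self, repeat: int, fold: int) -> list[str]:
        return self.assignment[(repeat, fold)]

    def train_ids(self, repeat: int, fold: int) -> list[str]:
        test = set(self.assignment[(repeat, fold)])
        all_ids = [s for f in range(self.n_folds) for s in self.assignment[(repeat, f)]]
        return [s for s in all_ids if s not in test]


def _gab_deciles(gab: pd.Series, n_bins: int = 10) -> pd.Series:
    return pd.qcut(gab, n_bins, labels=False, duplicates="drop")


def race_strata(metadata: CohortMetadata) -> pd.Series:
    """Binary race grouping for composite models: Black vs non-Black."""
    race = metadata.table["race"]
    return pd.Series(np.where(race == "Black", "Black", "non-Black"), index=race.index)


def build_fold_plan(
    metadata: CohortMetadata,
    n_folds: int = 10,
    n_repeats: int = 5,
    stratify_race: bool = False,
    seed: int | None = None,
) -> FoldPlan:
    """Block-stratified k-fold plan: GAB deciles (x race when requested)
    are shuffled within strata and dealt round-robin across folds, with
    independent repeats drawn from seed substreams."""
    n = len(metadata.sample_ids)
    if n_folds > n:
        raise ValueError("more folds than samples")
    deciles = _gab_deciles(metadata.table["gab_weeks"])
    blocks = deciles.astype(str)
    if stratify_race:
        blocks = blocks + "|" + race_strata(metadata)
    ss = np.random.SeedSequence(seed)
    assignment: dict[tuple[int, int], list[str]] = {}
    for repeat, child in enumerate(ss.spawn(n_repeats)):
        rng = np.random.default_rng(child)
        folds: list[list[str]] = [[] for _ in range(n_folds)]
        offset = 0
        for block in sorted(blocks.unique()):
            members = list(blocks.index[blocks == block])
            rng.shuffle(members)
            for i, s in enumerate(members):
                folds[(offset + i) % n_folds].append(s)
            offset += len(members)
        for fold, ids in enumerate(folds):
            assignment[(repeat, fold)] = sorted(ids)
    return FoldPlan(n_folds, n_repeats, seed, assignment)


# ---------------------------------------------------------------------------
# hyperparameters
# ---------------------------------------------------------------------------

#: full search space (the study-scale budget draws 1000 candidates from this)
DEFAULT_SPACE: dict = {
    "pca": [None, None, None, 10, 20, 50],
    "fs_method": ["none", "sparsity", "importance", "info_gain", "rank_corr"],
    "fs_keep": [0.1, 0.25, 0.5, 0.75, 1.0],
    "learner": {
        "n_estimators": [50, 100, 200, 400],
        "num_leaves": [7, 15, 31, 63],
        "max_depth": [-1, 3, 5, 8],
        "learning_rate": ("log", 0.005, 0.3),
        "subsample": [0.6, 0.8, 1.0],
        "colsample_bytree": [0.4, 0.6, 0.8, 1.0],
        "reg_alpha": ("log", 1e-3, 10.0),
        "reg_lambda": ("log", 1e-3, 10.0),
        "min_child_samples": [5, 10, 20],
    },
}

#: reduced space for desk-scale benchmarks
FAST_SPACE: dict = {
    "pca": [None, None, 20],
    "fs_method": ["none", "sparsity", "rank_corr"],
    "fs_keep": [0.25, 0.5, 1.0],
    "learner": {
        "n_estimators": [30, 60],
        "num_leaves": [7, 15],
        "max_depth": [3, 5],
        "learning_rate": ("log", 0.02, 0.2),
        "subsample": [0.8, 1.0],
        "colsample_bytree": [0.6, 1.0],
        "reg_alpha": ("log", 1e-2, 1.0),
        "reg_lambda": ("log", 1e-2, 1.0),
        "min_child_samples": [5, 20],
    },
}


def _draw(space_entry, rng: np.random.Generator):
    if isinstance(space_entry, tuple) and space_entry and space_entry[0] == "log":
        lo, hi = space_entry[1], space_entry[2]
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return space_entry[int(rng.integers(len(space_entry)))]


def sample_hyperparameters(space: dict, n: int = 1000, seed: int | None = None) -> list[dict]:
    """n independent reproducible draws from the declared search space."""
    if not space:
        raise ValueError("empty hyperparameter space")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        hp = {k: _draw(v, rng) for k, v in space.items() if k != "learner"}
        hp["learner"] = {k: _draw(v, rng) for k, v in space.get("learner", {}).items()}
        out.append(hp)
    return out


# ---------------------------------------------------------------------------
# learners
# ---------------------------------------------------------------------------


def lightgbm_factory(params: dict, seed: int):
    import lightgbm as lgb

    return lgb.LGBMClassifier(
        **params,
        random_state=seed,
        n_jobs=1,
        verbose=-1,
        deterministic=True,
        force_col_wise=True,
    )


class StubLearner:
    """Deterministic linear stand-in honouring the fit/predict_proba
    contract, used to test the framework without boosting costs."""

    def __init__(self, **_params):
        self.weights_: np.ndarray | None = None

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        yc = y - y.mean()
        Xc = X - X.mean(axis=0)
        denom = (Xc**2).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.weights_ = np.where(denom > 0, (Xc * yc[:, None]).sum(axis=0) / denom, 0.0)
        self.intercept_ = y.mean()
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        score = self.intercept_ + X @ self.weights_ / max(1, (self.weights_ != 0).sum())
        p1 = 1.0 / (1.0 + np.exp(np.clip(-4 * (score - 0.5), -500, 500)))
        return np.column_stack([1 - p1, p1])


def stub_factory(params: dict, seed: int):
    return StubLearner(**params)


# ---------------------------------------------------------------------------
# feature pipeline
# ---------------------------------------------------------------------------


class FeaturePipeline:
    """Standardize (training median / SD) -> impute (training minimum)
    -> optional PCA -> optional feature selection; every statistic comes
    from training data only."""

    def __init__(self, hp: dict, learner_factory: Callable, seed: int):
        self.hp = hp
        self.learner_factory = learner_factory
        self.seed = seed

    def fit(self, X: pd.DataFrame, y: np.ndarray) -> "FeaturePipeline":
        self.columns_ = list(X.columns)
        V = X.to_numpy(dtype=float)
        self.center_ = np.nanmedian(V, axis=0)
        sd = np.nanstd(V, axis=0, ddof=1)
        self.scale_ = np.where((sd > 0) & np.isfinite(sd), sd, 1.0)
        self.center_ = np.where(np.isfinite(self.center_), self.center_, 0.0)
        Z = (V - self.center_) / self.scale_
        mins = np.nanmin(np.where(np.isnan(Z), np.inf, Z), axis=0)
        self.impute_ = np.where(np.isfinite(mins), mins, 0.0)
        Z = np.where(np.isnan(Z), self.impute_, Z)
        self.post_median_ = np.median(Z, axis=0)

        self.selected_ = self._select(X, Z, y)
        Z = Z[:, self.selected_]
        self.pca_ = None
        n_comp = self.hp.get("pca")
        if n_comp:
            n_comp = int(min(n_comp, Z.shape[1], Z.shape[0]))
            if n_comp >= 1:
                self.pca_ = PCA(n_components=n_comp, random_state=self.seed)
                Z = self.pca_.fit_transform(Z)
        self.train_matrix_ = Z
        return self

    def _select(self, X_raw: pd.DataFrame, Z: np.ndarray, y: np.ndarray) -> np.ndarray:
        method = self.hp.get("fs_method", "none")
        keep_frac = float(self.hp.get("fs_keep", 1.0))
        F = Z.shape[1]
        m = max(1, math.ceil(keep_frac * F))
        if method == "none" or m >= F:
            return np.arange(F)
        if method == "sparsity":
            detection = (~X_raw.isna()).mean(axis=0).to_numpy()
            order = np.argsort(-detection, kind="stable")
        elif method == "rank_corr":
            R = stats.rankdata(Z, axis=0)
            Rc = R - R.mean(axis=0)
            yc = stats.rankdata(y) - stats.rankdata(y).mean()
            denom = np.sqrt((Rc**2).sum(axis=0) * (yc**2).sum())
            with np.errstate(invalid="ignore", divide="ignore"):
                score = np.abs(np.where(denom > 0, Rc.T @ yc / denom, 0.0))
            score = np.nan_to_num(score)
            order = np.argsort(-score, kind="stable")
        elif method == "info_gain":
            score = mutual_info_classif(Z, y, random_state=self.seed)
            order = np.argsort(-score, kind="stable")
        elif method == "importance":
            probe = self.learner_factory(dict(self.hp.get("learner", {})), self.seed)
            probe.fit(Z, y)
            if hasattr(probe, "feature_importances_"):
                score = np.asarray(probe.feature_importances_, dtype=float)
            elif hasattr(probe, "weights_"):
                score = np.abs(probe.weights_)
            else:
                raise ValueError("learner exposes no importances for importance-based selection")
            order = np.argsort(-score, kind="stable")
        else:
            raise ValueError(f"unknown feature-selection method {method!r}")
        return np.sort(order[:m])

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        V = X.reindex(columns=self.columns_).to_numpy(dtype=float)
        Z = (V - self.center_) / self.scale_
        Z = np.where(np.isnan(Z), self.impute_, Z)
        Z = Z[:, self.selected_]
        if self.pca_ is not None:
            Z = self.pca_.transform(Z)
        return Z

    def fill_external(self, X: pd.DataFrame) -> tuple[pd.DataFrame, float]:
        """Map external features by identifier; absent features take the
        training post-standardization median (in original units so that
        transform() reproduces it exactly)."""
        overlap = [c for c in self.columns_ if c in X.columns]
        if not overlap:
            raise ValueError("zero feature overlap with the predictor's universe")
        filled = pd.DataFrame(index=X.index, columns=self.columns_, dtype=float)
        for j, col in enumerate(self.columns_):
            if col in X.columns:
                filled[col] = X[col].to_numpy(dtype=float)
            else:
                filled[col] = self.post_median_[j] * self.scale_[j] + self.center_[j]
        return filled, len(overlap) / len(self.columns_)


# ---------------------------------------------------------------------------
# composite predictor
# ---------------------------------------------------------------------------


@dataclass
class CompositePredictor:
    hp: dict
    seed: int
    pipelines: dict[str, FeaturePipeline] = field(default_factory=dict)
    learners: dict[str, object] = field(default_factory=dict)

    @property
    def strata(self) -> list[str]:
        return sorted(self.pipelines)

    def predict(self, X: pd.DataFrame, strata: pd.Series) -> pd.Series:
        scores = pd.Series(np.nan, index=X.index, dtype=float)
        for key in self.strata:
            idx = strata.index[strata == key]
            idx = [i for i in idx if i in X.index]
            if not idx:
                continue
            Z = self.pipelines[key].transform(X.loc[idx])
            scores.loc[idx] = self.learners[key].predict_proba(Z)[:, 1]
        if scores.isna().any():
            missing = sorted(set(strata.loc[scores.index[scores.isna()]]))
            raise ValueError(f"no fitted model for strata {missing}")
        return scores


def fit_composite(
    X: pd.DataFrame,
    y: pd.Series,
    strata: pd.Series | None,
    hp: dict,
    learner_factory: Callable = lightgbm_factory,
    seed: int = 0,
) -> CompositePredictor:
    """Fit one pipeline+learner per stratum (single stratum when
    ``strata`` is None); errors if any stratum is single-class."""
    if strata is None:
        strata = pd.Series("all", index=X.index)
    predictor = CompositePredictor(hp=hp, seed=seed)
    for k, key in enumerate(sorted(strata.loc[X.index].unique())):
        ids = [i for i in X.index if strata[i] == key]
        y_s = y.loc[ids].to_numpy()
        if len(np.unique(y_s)) < 2:
            raise ValueError(f"stratum {key!r} has a single outcome class in training data")
        pipe = FeaturePipeline(hp, learner_factory, seed + k)
        pipe.fit(X.loc[ids], y_s)
        learner = learner_factory(dict(hp.get("learner", {})), seed + k)
        learner.fit(pipe.train_matrix_, y_s)
        predictor.pipelines[key] = pipe
        predictor.learners[key] = learner
    return predictor


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclass
class PredictionReport:
    outcome_definition: str
    scores: dict[str, float]
    labels: dict[str, int]
    auroc: float
    aupr: float
    roc_points: tuple
    pr_points: tuple
    per_repeat_auroc: list[float] = field(default_factory=list)
    per_repeat_scores: list[dict[str, float]] = field(default_factory=list)


def evaluate(scores: pd.Series, metadata: CohortMetadata, outcome_definition: str = "sPTB") -> PredictionReport:
    """Score a fixed prediction vector against an outcome definition.

    auROC uses the rank statistic with tie averaging; auPR uses
    precision-recall step integration. Reclassified outcomes (GAB<32,
    GAB<28) change only the labels - the scores are reused untouched.
    """
    y = metadata.outcome_binary(outcome_definition).loc[scores.index]
    if y.nunique() < 2:
        raise ValueError(f"single-class labels for outcome {outcome_definition!r}")
    s = scores.to_numpy(dtype=float)
    auroc = float(roc_auc_score(y, s))
    aupr = float(average_precision_score(y, s))
    fpr, tpr, _ = roc_curve(y, s)
    prec, rec, _ = precision_recall_curve(y, s)
    return PredictionReport(
        outcome_definition,
        {i: float(v) for i, v in scores.items()},
        {i: int(v) for i, v in y.items()},
        auroc,
        aupr,
        (fpr.tolist(), tpr.tolist()),
        (rec.tolist(), prec.tolist()),
    )


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2) + (n_neg - 1) * (q2 - auc**2)) / (
        n_pos * n_neg
    )
    return math.sqrt(max(var, 0.0))


def compare_auroc(scores_a: pd.Series, scores_b: pd.Series, labels: pd.Series) -> tuple[float, float]:
    """z-comparison of two auROCs on the same samples using
    Hanley-McNeil standard errors."""
    if not scores_a.index.equals(scores_b.index):
        raise ValueError("score vectors must cover the same samples")
    y = labels.loc[scores_a.index].to_numpy()
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("degenerate label vector")
    a = roc_auc_score(y, scores_a.to_numpy(dtype=float))
    b = roc_auc_score(y, scores_b.to_numpy(dtype=float))
    se = math.sqrt(_hanley_mcneil_se(a, n_pos, n_neg) ** 2 + _hanley_mcneil_se(b, n_pos, n_neg) ** 2)
    if se == 0:
        return 0.0, 1.0
    z = (a - b) / se
    return float(z), float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------


def tune_nested(r2_means: np.ndarray, auroc_means: np.ndarray, top: int = 5) -> int:
    """Selection rule: among the ``top`` candidates by mean inner R^2,
    pick the one with the best mean inner auROC; ties go to the earlier
    candidate draw."""
    r2_means = np.asarray(r2_means, dtype=float)
    auroc_means = np.asarray(auroc_means, dtype=float)
    ok = np.isfinite(r2_means) & np.isfinite(auroc_means)
    if not ok.any():
        raise ValueError("no viable candidates (all degenerate fits)")
    idx = np.nonzero(ok)[0]
    by_r2 = idx[np.argsort(-r2_means[idx], kind="stable")][:top]
    best = by_r2[np.argsort(-auroc_means[by_r2], kind="stable")][0]
    return int(best)


def _r2_binary(y: np.ndarray, p: np.ndarray) -> float:
    denom = np.sum((y - y.mean()) ** 2)
    if denom == 0:
        return float("nan")
    return 1.0 - float(np.sum((y - p) ** 2) / denom)


def nested_cv(
    X: pd.DataFrame,
    metadata: CohortMetadata,
    candidates: list[dict],
    outcome_definition: str = "sPTB",
    stratify_race: bool = True,
    composite: bool = True,
    n_outer_folds: int = 10,
    n_outer_repeats: int = 5,
    n_inner_folds: int = 5,
    n_inner_repeats: int = 5,
    learner_factory: Callable = lightgbm_factory,
    seed: int | None = None,
) -> tuple[PredictionReport, list[dict]]:
    """Full nested-CV evaluation; returns the out-of-fold report (pooled
    across repeats) and the per-outer-fold selected hyperparameters."""
    y_all = metadata.outcome_binary(outcome_definition)
    strata = race_strata(metadata) if composite else None
    plan = build_fold_plan(
        metadata, n_outer_folds, n_outer_repeats, stratify_race=stratify_race, seed=seed
    )
    ss = np.random.SeedSequence(seed).spawn(n_outer_repeats * n_outer_folds + 1)
    selected_log: list[dict] = []
    per_repeat_scores: list[pd.Series] = []
    per_repeat_auroc: list[float] = []

    for repeat in range(n_outer_repeats):
        fold_scores: dict[str, float] = {}
        for fold in range(n_outer_folds):
            child = ss[repeat * n_outer_folds + fold]
            sub_seed = int(np.random.default_rng(child).integers(2**31 - 1))
            train_ids = plan.train_ids(repeat, fold)
            test_ids = plan.test_ids(repeat, fold)
            meta_train = metadata.subset(train_ids)
            inner_plan = build_fold_plan(
                meta_train, n_inner_folds, n_inner_repeats, stratify_race=stratify_race,
                seed=sub_seed,
            )
            r2 = np.full((len(candidates), n_inner_repeats * n_inner_folds), np.nan)
            auc = np.full_like(r2, np.nan)
            for ci, hp in enumerate(candidates):
                col = 0
                for irep in range(n_inner_repeats):
                    for ifold in range(n_inner_folds):
                        it_train = inner_plan.train_ids(irep, ifold)
                        it_test = inner_plan.test_ids(irep, ifold)
                        try:
                            model = fit_composite(
                                X.loc[it_train], y_all, strata, hp,
                                learner_factory, seed=sub_seed + ci,
                            )
                            s = model.predict(
                                X.loc[it_test],
                                strata if strata is not None else pd.Series("all", index=X.index),
                            )
                        except ValueError:
                            col += 1
                            continue
                        yt = y_all.loc[it_test].to_numpy()
                        r2[ci, col] = _r2_binary(yt, s.to_numpy())
                        if len(np.unique(yt)) == 2:
                            auc[ci, col] = roc_auc_score(yt, s.to_numpy())
                        col += 1
            with np.errstate(invalid="ignore"):
                best = tune_nested(np.nanmean(r2, axis=1), np.nanmean(auc, axis=1))
            hp = candidates[best]
            selected_log.append({"repeat": repeat, "fold": fold, "candidate": best, "hp": hp})
            model = fit_composite(X.loc[train_ids], y_all, strata, hp, learner_factory, seed=sub_seed)
            s = model.predict(
                X.loc[test_ids], strata if strata is not None else pd.Series("all", index=X.index)
            )
            fold_scores.update({i: float(v) for i, v in s.items()})
        rep_scores = pd.Series(fold_scores).loc[metadata.sample_ids]
        per_repeat_scores.append(rep_scores)
        per_repeat_auroc.append(float(roc_auc_score(y_all.loc[rep_scores.index], rep_scores)))

    pooled = pd.concat(per_repeat_scores, axis=1).mean(axis=1)
    report = evaluate(pooled, metadata, outcome_definition)
    report.per_repeat_auroc = per_repeat_auroc
    report.per_repeat_scores = [{i: float(v) for i, v in s.items()} for s in per_repeat_scores]
    return report, selected_log


def select_final_model(
    X: pd.DataFrame,
    metadata: CohortMetadata,
    selected_hps: list[dict],
    composite: bool = True,
    learner_factory: Callable = lightgbm_factory,
    seed: int = 0,
) -> tuple[CompositePredictor, pd.DataFrame]:
    """Refit every outer-fold-selected hyperparameter set on the whole
    cohort and keep the one with the best training-fit auROC. The
    selection table flags the metric as a training fit, not an estimate
    of generalization."""
    if not selected_hps:
        raise ValueError("empty candidate list")
    y = metadata.outcome_binary()
    strata = race_strata(metadata) if composite else None
    rows = []
    best = None
    for i, entry in enumerate(selected_hps):
        hp = entry["hp"] if "hp" in entry else entry
        model = fit_composite(X, y, strata, hp, learner_factory, seed=seed)
        s = model.predict(X, strata if strata is not None else pd.Series("all", index=X.index))
        auc = float(roc_auc_score(y.loc[s.index], s))
        rows.append({"candidate": i, "training_fit_auroc": auc, "metric": "training_fit"})
        if best is None or auc > best[1] + 1e-15:
            best = (model, auc, i)
    return best[0], pd.DataFrame(rows)


def apply_external(
    predictor: CompositePredictor,
    external: pd.DataFrame,
    stratum: str | None = None,
) -> tuple[pd.Series, float]:
    """Score an external cohort with partial feature overlap.

    Overlapping features are mapped by identifier and standardized with
    training statistics; absent features take the training
    post-standardization median. Returns scores and the overlap fraction
    |intersection| / |training universe|.
    """
    key = stratum if stratum is not None else predictor.strata[0]
    pipe = predictor.pipelines[key]
    filled, overlap = pipe.fill_external(external)
    Z = pipe.transform(filled)
    scores = pd.Series(predictor.learners[key].predict_proba(Z)[:, 1], index=external.index)
    return scores, overlap


@dataclass
class FeatureAttribution:
    feature_ids: list[str]
    contributions: np.ndarray  # samples x features
    baseline: np.ndarray  # per-sample expected value (raw margin)
    ranking: list[tuple[str, float]]


def attribute_features(
    predictor: CompositePredictor, X: pd.DataFrame, stratum: str | None = None
) -> FeatureAttribution:
    """Additive per-feature contributions (TreeSHAP via the boosted-tree
    learner's native pred_contrib); contributions + baseline equal the
    raw-margin model output for each sample."""
    key = stratum if stratum is not None else predictor.strata[0]
    learner = predictor.learners[key]
    booster = getattr(learner, "booster_", None)
    if booster is None:
        raise ValueError("feature attribution requires a tree-ensemble learner")
    pipe = predictor.pipelines[key]
    Z = pipe.transform(X)
    contrib = booster.predict(Z, pred_contrib=True)
    values, baseline = contrib[:, :-1], contrib[:, -1]
    if pipe.pca_ is not None:
        names = [f"PC{i + 1}" for i in range(values.shape[1])]
    else:
        names = [pipe.columns_[j] for j in pipe.selected_]
    mean_abs = np.abs(values).mean(axis=0)
    order = np.argsort(-mean_abs, kind="stable")
    ranking = [(names[j], float(mean_abs[j])) for j in order]
    return FeatureAttribution(names, values, baseline, ranking)


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------

CLINICAL_COLUMNS = ("age_years", "bmi", "nulliparous", "ptb_history")


def clinical_features(metadata: CohortMetadata, include_race: bool = True) -> pd.DataFrame:
    """Maternal covariates: age, BMI, nulliparity, PTB history (+ race
    indicator for the non-composite clinical model)."""
    df = pd.DataFrame(index=metadata.table.index)
    for col in CLINICAL_COLUMNS:
        if col in metadata.table.columns:
            df[col] = metadata.table[col].astype(float)
    if include_race:
        df["race_black"] = (metadata.table["race"] == "Black").astype(float)
    return df


def microbiome_features(taxa: TaxaTable, train_ids: Sequence[str]) -> pd.DataFrame:
    """Absolute-abundance features; samples with missing qPCR load get the
    mean load of the training samples (training statistics only)."""
    load = pd.Series(taxa.total_load, index=taxa.sample_ids)
    train_loads = load.loc[[s for s in train_ids if s in load.index]].dropna()
    if train_loads.empty:
        raise ValueError("no training sample has a measured total load")
    filled = load.fillna(float(train_loads.mean()))
    absolute = taxa.rel_abundance * filled.to_numpy()[:, None]
    return pd.DataFrame(absolute, index=taxa.sample_ids, columns=taxa.taxon_ids)
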
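"""Gradient-boosting diagnostic classification and model comparison.

Three gradient-boosted tree classifiers with identical hyperparameters
(250 estimators, learning rate 0.1, max depth 8, logistic loss) are trained
on three nested feature sets — raw MEP amplitude + ISI, the excitability
ratios delta/rho + ISI, and all four features — over identical 10-fold
stratified cross-validation splits.  Each fold yields eight performance
metrics; fold means, paired t-tests between feature sets, per-fold SHAP
attributions on held-out rows, and loss-reduction (Gini) importances make
up the comparison report.

The cross-validation unit is the individual stimulation row (stratified on
diagnosis only), which lets a subject contribute to both train and test
folds; a subject-grouped mode is available for the stricter split.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy import stats
from sklearn import metrics as skm
from sklearn.model_selection import GroupKFold, StratifiedKFold

POSITIVE_CLASS = "MDD"

#: The three nested feature sets compared in the experiment.
FEATURE_SETS: dict[str, list[str]] = {
    "mep_isi": ["amplitude_uv", "isi_ms"],
    "deltarho_isi": ["delta", "rho", "isi_ms"],
    "all": ["amplitude_uv", "isi_ms", "delta", "rho"],
}

GBDT_HYPER = {"n_estimators": 250, "learning_rate": 0.1, "max_depth": 8}

METRIC_NAMES = [
    "accuracy",
    "balanced_accuracy",
    "cohen_kappa",
    "mcc",
    "f1",
    "recall",
    "roc_auc",
    "pr_auc",
]


@dataclass(frozen=True)
class FoldMetrics:
    accuracy: float
    balanced_accuracy: float
    cohen_kappa: float
    mcc: float
    f1: float
    recall: float
    roc_auc: float
    pr_auc: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ComparisonReport:
    """Per-fold and fold-mean metrics for the three models, plus paired tests."""

    fold_metrics: dict[str, pd.DataFrame]
    mean_metrics: pd.DataFrame
    paired_tests: pd.DataFrame
    confusion_matrix_all: np.ndarray  # row-normalized over true class (HC, MDD)
    fold_hash: str  # identical fold assignment across the three models
    n_rows: int
    cv_k: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "fold_metrics": {k: v.to_dict(orient="list") for k, v in self.fold_metrics.items()},
            "mean_metrics": self.mean_metrics.to_dict(orient="index"),
            "paired_tests": self.paired_tests.to_dict(orient="records"),
            "confusion_matrix_all": self.confusion_matrix_all.tolist(),
            "fold_hash": self.fold_hash,
            "n_rows": self.n_rows,
            "cv_k": self.cv_k,
            "seed": self.seed,
        }


@dataclass
class AttributionReport:
    """SHAP and Gini attributions for the fitted models."""

    shap_per_fold: list[pd.DataFrame]  # held-out rows of the all-features model
    shap_pooled: pd.DataFrame  # all test folds stacked, + combined delta+rho column
    gini: pd.DataFrame  # fold-averaged loss-reduction importance per model

    def to_dict(self) -> dict:
        return {
            "shap_pooled_mean_abs": self.shap_pooled.drop(columns=["base_value", "margin"])
            .abs()
            .mean()
            .to_dict(),
            "gini": self.gini.to_dict(orient="index"),
        }


@dataclass
class _FoldArtifacts:
    """Fitted per-fold models and split indices, kept for attribution."""

    models: dict[str, list[xgb.XGBClassifier]]
    test_indices: list[np.ndarray]
    X: pd.DataFrame
    y: np.ndarray


def stratified_folds(labels, k: int = 10, seed: int = 0) -> np.ndarray:
    """Assign each row to one of ``k`` stratified folds; deterministic in seed."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} members; needs >= k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignment[test_idx] = fold
    return assignment


def grouped_folds(labels, groups, k: int = 10, seed: int = 0) -> np.ndarray:
    """Subject-grouped alternative: no subject spans train and test."""
    labels = np.asarray(labels)
    gkf = GroupKFold(n_splits=k)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(gkf.split(np.zeros(len(labels)), labels, groups)):
        assignment[test_idx] = fold
    return assignment


def fit_gbdt(
    X: pd.DataFrame,
    y: np.ndarray,
    hyper: dict | None = None,
    seed: int = 0,
) -> xgb.XGBClassifier:
    """Fit the gradient-boosted tree classifier with logistic loss."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    params = dict(GBDT_HYPER)
    if hyper:
        params.update(hyper)
    model = xgb.XGBClassifier(
        objective="binary:logistic",
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        eval_metric="logloss",
        **params,
    )
    model.fit(X, y)
    return model


def classification_metrics(y_true, y_pred, y_score) -> FoldMetrics:
    """The eight-metric panel; MDD (encoded 1) is the positive class.

    Degenerate denominators follow the usual conventions: MCC and kappa are 0
    when undefined, F1/recall use zero_division=0.  Single-class ``y_true``
    leaves balanced accuracy and the AUCs undefined and raises.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    y_score = np.asarray(y_score, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise ValueError("y_true contains a single class: balanced accuracy/AUC undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return FoldMetrics(
            accuracy=float(skm.accuracy_score(y_true, y_pred)),
            balanced_accuracy=float(skm.balanced_accuracy_score(y_true, y_pred)),
            cohen_kappa=float(skm.cohen_kappa_score(y_true, y_pred)),
            mcc=float(skm.matthews_corrcoef(y_true, y_pred)),
            f1=float(skm.f1_score(y_true, y_pred, zero_division=0)),
            recall=float(skm.recall_score(y_true, y_pred, zero_division=0)),
            roc_auc=float(skm.roc_auc_score(y_true, y_score)),
            pr_auc=float(skm.average_precision_score(y_true, y_score)),
        )


def _paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, bool]:
    diffs = np.asarray(a) - np.asarray(b)
    if np.allclose(diffs.std(ddof=1), 0.0):
        return float("nan"), 1.0, True  # identical metric vectors: no evidence
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p), False


def run_feature_set_comparison(
    features: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    positive_class: str = POSITIVE_CLASS,
    threshold: float = 0.5,
    group_by_subject: bool = False,
) -> tuple[ComparisonReport, _FoldArtifacts]:
    """Train/evaluate the three feature sets on identical CV splits.

    Returns the comparison report and the fitted per-fold models (for
    :func:`attribution`).  Labels are thresholded at ``threshold`` on the
    predicted MDD probability; raw probabilities feed the AUCs.
    """
    y = (features["group"].to_numpy() == positive_class).astype(int)
    X = features[FEATURE_SETS["all"]].astype(float).reset_index(drop=True)
    if group_by_subject:
        assignment = grouped_folds(y, features["subject_id"].to_numpy(), k=k, seed=seed)
    else:
        assignment = stratified_folds(y, k=k, seed=seed)
    fold_hash = hashlib.sha256(assignment.tobytes()).hexdigest()

    per_fold: dict[str, list[FoldMetrics]] = {name: [] for name in FEATURE_SETS}
    models: dict[str, list[xgb.XGBClassifier]] = {name: [] for name in FEATURE_SETS}
    test_indices: list[np.ndarray] = []
    cm_total = np.zeros((2, 2))

    for fold in range(k):
        test_idx = np.flatnonzero(assignment == fold)
        train_idx = np.flatnonzero(assignment != fold)
        test_indices.append(test_idx)
        for name, cols in FEATURE_SETS.items():
            model = fit_gbdt(X.iloc[train_idx][cols], y[train_idx], seed=seed)
            score = model.predict_proba(X.iloc[test_idx][cols])[:, 1]
            pred = (score >= threshold).astype(int)
            per_fold[name].append(classification_metrics(y[test_idx], pred, score))
            models[name].append(model)
            if name == "all":
                cm_total += skm.confusion_matrix(y[test_idx], pred, labels=[0, 1])

    fold_metrics = {
        name: pd.DataFrame([m.to_dict() for m in ms]) for name, ms in per_fold.items()
    }
    mean_metrics = pd.DataFrame(
        {name: df.mean() for name, df in fold_metrics.items()}
    ).T[METRIC_NAMES]

    tests = []
    for first, second in [("mep_isi", "deltarho_isi"), ("deltarho_isi", "all")]:
        for metric in METRIC_NAMES:
            t, p, degenerate = _paired_t(
                fold_metrics[second][metric].to_numpy(),
                fold_metrics[first][metric].to_numpy(),
            )
            tests.append(
                {
                    "comparison": f"{first}_vs_{second}",
                    "metric": metric,
                    "t": t,
                    "p_value": p,
                    "zero_variance": degenerate,
                }
            )

    cm_norm = cm_total / cm_total.sum(axis=1, keepdims=True)
    report = ComparisonReport(
        fold_metrics=fold_metrics,
        mean_metrics=mean_metrics,
        paired_tests=pd.DataFrame(tests),
        confusion_matrix_all=cm_norm,
        fold_hash=fold_hash,
        n_rows=len(features),
        cv_k=k,
        seed=seed,
    )
    artifacts = _FoldArtifacts(models=models, test_indices=test_indices, X=X, y=y)
    return report, artifacts


def shap_values(model: xgb.XGBClassifier, X: pd.DataFrame) -> pd.DataFrame:
    """Exact path-dependent TreeSHAP contributions on the log-odds scale.

    Computed in float64 on the parsed tree ensemble (see ``mepx._treeshap``)
    so that local accuracy — base_value + sum(contributions) == margin —
    holds to full double precision per row.  Returns one column per feature
    plus ``base_value`` and the model ``margin``.
    """
    from ._treeshap import tree_shap_values

    phi, base, margins = tree_shap_values(
        model.get_booster(), X.to_numpy(), list(X.columns)
    )
    out = pd.DataFrame(phi, columns=list(X.columns), index=X.index)
    out["base_value"] = base
    out["margin"] = margins
    return out


def xgboost_native_contribs(model: xgb.XGBClassifier, X: pd.DataFrame) -> np.ndarray:
    """xgboost's built-in (float32) TreeSHAP; independent cross-check route."""
    dm = xgb.DMatrix(X, feature_names=list(X.columns))
    return model.get_booster().predict(dm, pred_contribs=True).astype(np.float64)


def gini_importance(model: xgb.XGBClassifier, columns: list[str]) -> pd.Series:
    """Normalized total loss reduction attributed to splits on each feature."""
    raw = model.get_booster().get_score(importance_type="total_gain")
    vals = pd.Series({c: raw.get(c, 0.0) for c in columns}, dtype=float)
    total = vals.sum()
    return vals / total if total > 0 else vals


def attribution(artifacts: _FoldArtifacts) -> AttributionReport:
    """SHAP on held-out rows per fold (all-features model) + per-model Gini.

    delta and rho are collinear by construction, so their SHAP columns are
    additionally summed into a combined ``delta_rho`` column in the pooled
    table.  Gini importances are normalized per fold and averaged across
    folds for each of the three models.
    """
    cols_all = FEATURE_SETS["all"]
    per_fold = []
    for model, test_idx in zip(artifacts.models["all"], artifacts.test_indices):
        sv = shap_values(model, artifacts.X.iloc[test_idx][cols_all])
        sv.insert(0, "fold", len(per_fold))
        per_fold.append(sv)
    pooled = pd.concat(per_fold, ignore_index=True)
    pooled["delta_rho"] = pooled["delta"] + pooled["rho"]

    gini_rows = {}
    for name, cols in FEATURE_SETS.items():
        folds = [gini_importance(m, cols) for m in artifacts.models[name]]
        gini_rows[name] = pd.concat(folds, axis=1).mean(axis=1).reindex(cols_all)
    gini = pd.DataFrame(gini_rows).T  # models x features; NaN = feature not in set
    return AttributionReport(shap_per_fold=per_fold, shap_pooled=pooled, gini=gini)
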
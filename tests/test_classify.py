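"""CV mechanics, metric panel, GBDT behaviour and attribution identities."""

import numpy as np
import pandas as pd
import pytest

from mepx import (
    FEATURE_SETS,
    attribution,
    classification_metrics,
    fit_gbdt,
    gini_importance,
    run_feature_set_comparison,
    shap_values,
    stratified_folds,
)
from mepx.classify import METRIC_NAMES, _paired_t, xgboost_native_contribs


def test_stratified_folds_exact_divisibility():
    labels = np.r_[np.zeros(40, int), np.ones(60, int)]
    folds = stratified_folds(labels, k=10, seed=0)
    for f in range(10):
        fold_labels = labels[folds == f]
        assert len(fold_labels) == 10
        assert (fold_labels == 1).sum() == 6 and (fold_labels == 0).sum() == 4


def test_stratified_folds_determinism_and_error():
    labels = np.r_[np.zeros(40, int), np.ones(60, int)]
    a = stratified_folds(labels, k=10, seed=3)
    b = stratified_folds(labels, k=10, seed=3)
    assert (a == b).all()
    with pytest.raises(ValueError):
        stratified_folds(np.r_[np.zeros(100, int), np.ones(9, int)], k=10)


def _toy_xy(n=200, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"])
    y = (X["a"] > 0).astype(int).to_numpy()
    return X, y


def test_gbdt_separable_data_training_accuracy():
    X, y = _toy_xy()
    model = fit_gbdt(X, y, hyper={"n_estimators": 50, "max_depth": 3})
    assert (model.predict(X) == y).mean() == 1.0


def test_gbdt_refit_determinism():
    X, y = _toy_xy(seed=1)
    p1 = fit_gbdt(X, y, seed=5).predict_proba(X)
    p2 = fit_gbdt(X, y, seed=5).predict_proba(X)
    np.testing.assert_array_equal(p1, p2)


def test_gbdt_single_class_error():
    X, _ = _toy_xy()
    with pytest.raises(ValueError):
        fit_gbdt(X, np.zeros(len(X), int))


def test_noise_labels_near_chance():
    rng = np.random.default_rng(7)
    X = pd.DataFrame(rng.normal(size=(600, 2)), columns=["a", "b"])
    y = rng.integers(0, 2, size=600)
    folds = stratified_folds(y, k=5, seed=0)
    bals = []
    for f in range(5):
        m = fit_gbdt(X[folds != f], y[folds != f], hyper={"n_estimators": 50})
        score = m.predict_proba(X[folds == f])[:, 1]
        bals.append(
            classification_metrics(y[folds == f], (score >= 0.5).astype(int), score
                                   ).balanced_accuracy
        )
    assert abs(np.mean(bals) - 0.5) < 0.1


def test_metrics_perfect_prediction():
    y = np.r_[np.zeros(10, int), np.ones(10, int)]
    m = classification_metrics(y, y, y.astype(float))
    for name in METRIC_NAMES:
        assert getattr(m, name) == pytest.approx(1.0)


def test_metrics_worked_confusion_matrix():
    """Confusion [[TN=40, FP=10], [FN=5, TP=45]] hand-evaluated."""
    y_true = np.r_[np.zeros(50, int), np.ones(50, int)]
    y_pred = np.r_[np.zeros(40, int), np.ones(10, int), np.zeros(5, int), np.ones(45, int)]
    m = classification_metrics(y_true, y_pred, y_pred.astype(float))
    assert m.accuracy == pytest.approx(0.85)
    assert m.balanced_accuracy == pytest.approx(0.85)
    assert m.cohen_kappa == pytest.approx(0.70)
    assert m.mcc == pytest.approx(1750 / np.sqrt(55 * 45 * 50 * 50))
    assert m.recall == pytest.approx(0.90)
    assert m.f1 == pytest.approx(2 * (45 / 55) * 0.9 / (45 / 55 + 0.9))


def test_metrics_degenerate_predictor():
    y_true = np.r_[np.zeros(30, int), np.ones(70, int)]
    ones = np.ones(100, int)
    m = classification_metrics(y_true, ones, ones.astype(float))
    assert m.balanced_accuracy == pytest.approx(0.5)
    assert m.cohen_kappa == pytest.approx(0.0)
    assert m.mcc == pytest.approx(0.0)  # zero-denominator convention


def test_metrics_single_class_truth_rejected():
    with pytest.raises(ValueError):
        classification_metrics([1, 1, 1], [1, 0, 1], [0.9, 0.2, 0.8])


def test_metric_oracles_random_instances():
    """kappa/MCC/F1/balanced-acc vs contingency arithmetic; AUC vs pairwise."""
    rng = np.random.default_rng(8)
    for _ in range(100):
        n = rng.integers(10, 60)
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            continue
        pred = rng.integers(0, 2, n)
        score = rng.random(n)
        m = classification_metrics(y, pred, score)
        tp = int(((y == 1) & (pred == 1)).sum())
        tn = int(((y == 0) & (pred == 0)).sum())
        fp = int(((y == 0) & (pred == 1)).sum())
        fn = int(((y == 1) & (pred == 0)).sum())
        acc = (tp + tn) / n
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        po, pe = acc, ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
        kappa = (po - pe) / (1 - pe) if pe != 1 else 0.0
        denom = np.sqrt(float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
        mcc = (tp * tn - fp * fn) / denom if denom > 0 else 0.0
        f1 = 2 * tp / (2 * tp + fp + fn) if tp + fp + fn > 0 else 0.0
        assert m.accuracy == pytest.approx(acc, abs=1e-12)
        assert m.balanced_accuracy == pytest.approx((sens + spec) / 2, abs=1e-12)
        assert m.cohen_kappa == pytest.approx(kappa, abs=1e-12)
        assert m.mcc == pytest.approx(mcc, abs=1e-12)
        assert m.f1 == pytest.approx(f1, abs=1e-12)
        assert m.recall == pytest.approx(sens, abs=1e-12)
        pos, neg = score[y == 1], score[y == 0]
        wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
        assert m.roc_auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)


def test_paired_t_zero_variance_convention():
    t, p, degenerate = _paired_t(np.ones(10), np.ones(10))
    assert p == 1.0 and degenerate


@pytest.fixture(scope="module")
def small_comparison(small_features):
    return run_feature_set_comparison(small_features, k=3, seed=2)


def test_comparison_report_structure(small_comparison):
    report, artifacts = small_comparison
    assert set(report.fold_metrics) == set(FEATURE_SETS)
    for df in report.fold_metrics.values():
        assert len(df) == 3
        assert list(df.columns) == METRIC_NAMES
    # fold-mean lies between fold extremes
    for name, df in report.fold_metrics.items():
        for metric in METRIC_NAMES:
            mean = report.mean_metrics.loc[name, metric]
            assert df[metric].min() - 1e-12 <= mean <= df[metric].max() + 1e-12
    assert report.confusion_matrix_all.shape == (2, 2)
    np.testing.assert_allclose(report.confusion_matrix_all.sum(axis=1), 1.0)
    assert len(report.paired_tests) == 2 * len(METRIC_NAMES)


def test_models_share_identical_splits(small_features):
    r1, _ = run_feature_set_comparison(small_features, k=3, seed=2)
    r2, _ = run_feature_set_comparison(small_features, k=3, seed=2)
    assert r1.fold_hash == r2.fold_hash
    r3, _ = run_feature_set_comparison(small_features, k=3, seed=4)
    assert r1.fold_hash != r3.fold_hash


def test_attribution_local_accuracy_and_gini(small_comparison):
    _, artifacts = small_comparison
    report = attribution(artifacts)
    sv = report.shap_pooled
    cols = FEATURE_SETS["all"]
    err = (sv[cols].sum(axis=1) + sv["base_value"] - sv["margin"]).abs()
    assert err.max() <= 1e-9  # local accuracy, full double precision
    assert sv["delta_rho"].equals(sv["delta"] + sv["rho"])
    for name, cols_set in FEATURE_SETS.items():
        row = report.gini.loc[name, cols_set]
        assert row.sum() == pytest.approx(1.0, abs=1e-9)
        assert (row >= 0).all()
    # features outside a model's set carry no importance
    assert report.gini.loc["mep_isi", ["delta", "rho"]].isna().all()


def test_shap_matches_xgboost_native_route():
    """Float64 TreeSHAP agrees with xgboost's built-in contributions."""
    rng = np.random.default_rng(9)
    X = pd.DataFrame(rng.normal(size=(300, 4)), columns=FEATURE_SETS["all"])
    y = (X["delta"] + 0.3 * rng.normal(size=300) > 0).astype(int).to_numpy()
    model = fit_gbdt(X, y, hyper={"n_estimators": 40, "max_depth": 5})
    mine = shap_values(model, X)
    native = xgboost_native_contribs(model, X)
    np.testing.assert_allclose(
        mine[FEATURE_SETS["all"]].to_numpy(), native[:, :4], atol=5e-5
    )
    np.testing.assert_allclose(mine["base_value"].iloc[0], native[0, 4], atol=5e-5)


def test_unused_feature_gets_zero_attribution():
    rng = np.random.default_rng(10)
    X = pd.DataFrame(rng.normal(size=(200, 2)), columns=["signal", "constant"])
    X["constant"] = 1.0  # never splittable
    y = (X["signal"] > 0).astype(int).to_numpy()
    model = fit_gbdt(X, y, hyper={"n_estimators": 20, "max_depth": 3})
    sv = shap_values(model, X)
    assert np.allclose(sv["constant"], 0.0)
    assert gini_importance(model, ["signal", "constant"])["constant"] == 0.0
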
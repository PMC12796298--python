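"""PC1 extraction, aggregation and the Laplace-ML mixed logistic model."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from mepx import aggregate_pc1, fit_glmm, run_pc_glmm, standardize_and_pc1
from mepx.glmm import IntegrityError

DATA = Path(__file__).parent / "data"


def _features(n, rng, collinear=False):
    amp = rng.gamma(2.0, 150.0, n)
    if collinear:
        delta, rho = 2.0 * amp, 3.0 * amp
    else:
        delta, rho = rng.normal(size=n), rng.normal(size=n)
    return pd.DataFrame(
        {
            "subject_id": "s",
            "isi_ms": 0,
            "group": "HC",
            "amplitude_uv": amp,
            "delta": delta,
            "rho": rho,
        }
    )


def test_pc1_collinear_limit():
    pc = standardize_and_pc1(_features(200, np.random.default_rng(0), collinear=True))
    assert pc.variance_explained == pytest.approx(1.0, abs=1e-12)
    assert np.linalg.norm(pc.loadings) == pytest.approx(1.0, abs=1e-12)


def test_pc1_isotropic_limit():
    pc = standardize_and_pc1(_features(100_000, np.random.default_rng(1)))
    assert pc.variance_explained == pytest.approx(1 / 3, abs=0.01)


def test_pc1_scores_centered_and_sign_convention(default_features):
    pc = standardize_and_pc1(default_features)
    assert abs(pc.scores.mean()) < 1e-10
    assert pc.loadings[0] >= 0  # non-negative loading on MEP amplitude


def test_pc1_zero_variance_column_named():
    df = _features(50, np.random.default_rng(2))
    df["delta"] = 1.0
    with pytest.raises(ValueError, match="delta"):
        standardize_and_pc1(df)


def test_aggregate_counts(default_features):
    pc = standardize_and_pc1(default_features)
    agg = aggregate_pc1(
        pc.scores,
        default_features["subject_id"],
        default_features["isi_ms"],
        default_features["group"],
    )
    assert len(agg) == 43 * 7 == 301


def test_aggregate_trivial_mean():
    agg = aggregate_pc1([-1.0, 1.0], ["a", "a"], [0, 0], ["HC", "HC"])
    assert len(agg) == 1
    assert agg["pc1"].iloc[0] == pytest.approx(0.0)


def test_aggregate_group_flip_is_integrity_error():
    with pytest.raises(IntegrityError):
        aggregate_pc1([0.0, 1.0], ["a", "a"], [0, 4], ["HC", "MDD"])


def test_glmm_matches_lme4_oracle():
    """Frozen lme4::glmer (Laplace, independent intercept/slope) estimates.

    Oracle: glmer(y ~ x + (1|g) + (0+x|g), family=binomial) on the stored
    synthetic dataset gives beta = (0.448068, 0.524628), SE = (0.199265,
    0.118564), var = (0.469285, 0.069081), logLik = -372.425298,
    AIC = 752.8506, BIC = 770.4383.
    """
    d = pd.read_csv(DATA / "glmm_oracle_synthetic.csv")
    agg = pd.DataFrame(
        {"pc1": d["x"], "isi_ms": d["g"], "group": np.where(d["y"] == 1, "MDD", "HC")}
    )
    res = fit_glmm(agg)
    assert res.converged and not res.boundary
    assert res.beta0 == pytest.approx(0.448068, abs=1e-3)
    assert res.beta1 == pytest.approx(0.524628, abs=1e-3)
    assert res.se0 == pytest.approx(0.199265, abs=5e-3)
    assert res.se1 == pytest.approx(0.118564, abs=5e-3)
    assert res.var_intercept == pytest.approx(0.469285, abs=2e-3)
    assert res.var_slope == pytest.approx(0.069081, abs=2e-3)
    assert res.loglik == pytest.approx(-372.425298, abs=1e-3)
    assert res.aic == pytest.approx(752.8506, abs=2e-3)
    assert res.bic == pytest.approx(770.4383, abs=2e-3)


def test_zero_variance_fit_equals_plain_logistic():
    """With variances pinned at 0 the GLMM is ordinary logistic regression."""
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(3)
    x = rng.normal(size=400)
    g = rng.integers(0, 7, size=400)
    y = (rng.random(400) < 1 / (1 + np.exp(-(0.4 + 0.5 * x)))).astype(int)
    agg = pd.DataFrame({"pc1": x, "isi_ms": g, "group": np.where(y == 1, "MDD", "HC")})
    res = fit_glmm(agg, fix_variances=(0.0, 0.0))
    logit = sm.Logit(y, np.column_stack([np.ones_like(x), x])).fit(disp=0)
    assert res.beta0 == pytest.approx(logit.params[0], abs=1e-6)
    assert res.beta1 == pytest.approx(logit.params[1], abs=1e-6)
    assert res.loglik == pytest.approx(logit.llf, abs=1e-6)


def test_boundary_variance_detected():
    rng = np.random.default_rng(4)
    x = rng.normal(size=350)
    g = np.repeat(np.arange(7), 50)
    y = (rng.random(350) < 1 / (1 + np.exp(-(0.4 + 0.3 * x)))).astype(int)
    agg = pd.DataFrame({"pc1": x, "isi_ms": g, "group": np.where(y == 1, "MDD", "HC")})
    res = fit_glmm(agg)
    assert res.boundary
    assert res.var_intercept < 1e-6 and res.var_slope < 1e-6


def test_degenerate_single_class_flagged():
    agg = pd.DataFrame({"pc1": [0.1, 0.2, 0.3, 0.4], "isi_ms": [0, 0, 4, 4], "group": "MDD"})
    res = fit_glmm(agg)
    assert not res.converged
    assert any("degenerate" in f for f in res.flags)


def test_aic_bic_penalty_ordering(default_features):
    _, _, res = run_pc_glmm(default_features)
    assert res.n_obs > 8
    assert res.bic > res.aic
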
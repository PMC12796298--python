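"""PCA predictor extraction and the mixed-effects diagnostic logistic model.

The three excitability features (MEP amplitude, delta, rho) are strongly
collinear, so instead of entering them jointly the pipeline standardizes
them, takes the first principal component PC1 as the sole predictor,
averages PC1 within subject x ISI, and fits

    logit P(y_ij = MDD) = beta0 + beta1 * PC1_ij + b0_j + b1_j * PC1_ij

where j indexes ISI level, b0_j ~ N(0, var_intercept) is a random intercept
and b1_j ~ N(0, var_slope) an independent random slope.  The model is fitted
by maximum likelihood with a Laplace approximation to the marginal
likelihood (the same approximation lme4::glmer uses at nAGQ = 1).  Variance
estimates on the boundary (zero) are legitimate ML solutions and are
returned with a flag, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from sklearn.decomposition import PCA

PC_FEATURES = ["amplitude_uv", "delta", "rho"]

#: Random-effect standard deviations below this are reported as boundary (zero).
_BOUNDARY_SD = 1e-4
#: Dimensions with sd below this are dropped from the Laplace integral; the
#: marginal likelihood is continuous through this limit.
_DROP_SD = 1e-6


class IntegrityError(ValueError):
    """Input rows contradict each other (e.g. one subject, two group labels)."""


@dataclass(frozen=True)
class PCResult:
    """First principal component of the standardized (MEP, delta, rho) triple."""

    loadings: np.ndarray  # unit-norm, loading on MEP amplitude >= 0
    variance_explained: float
    scores: np.ndarray  # per-row PC1 value, mean 0


@dataclass
class GLMMResult:
    """Fixed effects, random-effect variances and fit statistics."""

    beta0: float
    beta1: float
    se0: float
    se1: float
    z0: float
    z1: float
    p0: float
    p1: float
    var_intercept: float
    var_slope: float
    loglik: float
    aic: float
    bic: float
    n_obs: int
    n_groups: int
    converged: bool
    boundary: bool
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def standardize_and_pc1(features: pd.DataFrame) -> PCResult:
    """Z-score MEP amplitude, delta and rho; return their first PC.

    The eigenvector sign is arbitrary, so it is fixed by requiring a
    non-negative loading on MEP amplitude; higher PC1 then means higher
    amplitude/excitability, making the logistic slope's sign interpretable.
    """
    if len(features) < 3:
        raise ValueError("need at least 3 rows for PCA")
    x = features[PC_FEATURES].to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=0)
    zero_var = [c for c, s in zip(PC_FEATURES, sd) if s == 0]
    if zero_var:
        raise ValueError(f"zero-variance feature column(s): {zero_var}")
    z = (x - x.mean(axis=0)) / sd
    pca = PCA(n_components=3).fit(z)
    loadings = pca.components_[0].copy()
    scores = z @ loadings
    if loadings[0] < 0:
        loadings, scores = -loadings, -scores
    return PCResult(
        loadings=loadings,
        variance_explained=float(pca.explained_variance_ratio_[0]),
        scores=scores,
    )


def aggregate_pc1(scores, subject_id, isi_ms, group) -> pd.DataFrame:
    """Average PC1 within subject x ISI, keeping the subject's group label."""
    df = pd.DataFrame(
        {
            "subject_id": np.asarray(subject_id),
            "isi_ms": np.asarray(isi_ms),
            "group": np.asarray(group),
            "pc1": np.asarray(scores, dtype=float),
        }
    )
    if (df.groupby("subject_id")["group"].nunique() > 1).any():
        bad = df.groupby("subject_id")["group"].nunique()
        raise IntegrityError(
            f"inconsistent group labels for subjects: {list(bad[bad > 1].index)}"
        )
    out = df.groupby(["subject_id", "isi_ms", "group"], as_index=False)["pc1"].mean()
    return out[["subject_id", "isi_ms", "group", "pc1"]]


# --- Laplace-approximate marginal likelihood ---------------------------------


def _bernoulli_ll(y: np.ndarray, eta: np.ndarray) -> float:
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _group_laplace_ll(
    y: np.ndarray, x: np.ndarray, eta_fixed: np.ndarray, sds: np.ndarray
) -> float:
    """Laplace-approximate log marginal likelihood of one ISI group."""
    cols = [k for k in range(2) if sds[k] > _DROP_SD]
    if not cols:
        return _bernoulli_ll(y, eta_fixed)
    Z = np.column_stack([np.ones_like(x), x])[:, cols]
    d = sds[cols] ** 2
    b = np.zeros(len(cols))

    def penalized(bv: np.ndarray) -> float:
        return _bernoulli_ll(y, eta_fixed + Z @ bv) - 0.5 * float(np.sum(bv**2 / d))

    obj = penalized(b)
    for _ in range(100):
        eta = eta_fixed + Z @ b
        mu = expit(eta)
        grad = Z.T @ (y - mu) - b / d
        if np.max(np.abs(grad)) < 1e-10:
            break
        w = mu * (1.0 - mu)
        H = (Z.T * w) @ Z + np.diag(1.0 / d)
        step = np.linalg.solve(H, grad)
        # step halving keeps the penalized objective monotone
        t = 1.0
        while t > 1e-8:
            cand = b + t * step
            cand_obj = penalized(cand)
            if cand_obj >= obj - 1e-14:
                b, obj = cand, cand_obj
                break
            t /= 2.0
        else:
            break

    eta = eta_fixed + Z @ b
    mu = expit(eta)
    w = mu * (1.0 - mu)
    H = (Z.T * w) @ Z + np.diag(1.0 / d)
    sign, logdet_h = np.linalg.slogdet(H)
    return obj - 0.5 * logdet_h - 0.5 * float(np.sum(np.log(d)))


def _marginal_ll(theta: np.ndarray, y_by_g, x_by_g) -> float:
    beta0, beta1 = theta[0], theta[1]
    sds = np.abs(theta[2:4])
    total = 0.0
    for y, x in zip(y_by_g, x_by_g):
        total += _group_laplace_ll(y, x, beta0 + beta1 * x, sds)
    return total


def _numeric_hessian(f, x0: np.ndarray, h: float = 1e-4) -> np.ndarray:
    n = len(x0)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            pp = x0.copy(); pp[i] += h; pp[j] += h
            pm = x0.copy(); pm[i] += h; pm[j] -= h
            mp = x0.copy(); mp[i] -= h; mp[j] += h
            mm = x0.copy(); mm[i] -= h; mm[j] -= h
            H[i, j] = H[j, i] = (f(pp) - f(pm) - f(mp) + f(mm)) / (4 * h * h)
    return H


def _plain_logistic_init(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    beta = np.zeros(2)
    X = np.column_stack([np.ones_like(x), x])
    for _ in range(25):
        mu = expit(X @ beta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        grad = X.T @ (y - mu)
        H = (X.T * w) @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + np.clip(step, -5, 5)
        if np.max(np.abs(step)) < 1e-8:
            break
    return np.clip(beta, -25, 25)


def fit_glmm(
    aggregated: pd.DataFrame,
    fix_variances: tuple[float, float] | None = None,
    positive_class: str = "MDD",
) -> GLMMResult:
    """Fit the random-intercept/random-slope logistic model by Laplace ML.

    ``aggregated`` needs columns ``pc1``, ``isi_ms`` and ``group``; the
    grouping factor is ISI level.  ``fix_variances`` pins
    (var_intercept, var_slope) instead of estimating them — with (0, 0) the
    fit reduces exactly to ordinary logistic regression.  Degenerate inputs
    (single outcome class) and suspected complete separation are returned as
    flagged, non-converged results rather than exceptions.
    """
    required = {"pc1", "isi_ms", "group"}
    if not required <= set(aggregated.columns):
        raise ValueError(f"aggregated table needs columns {sorted(required)}")
    levels = np.unique(aggregated["isi_ms"])
    if len(levels) < 2:
        raise ValueError("need at least 2 ISI levels as grouping factor")

    y_all = (aggregated["group"].to_numpy() == positive_class).astype(float)
    x_all = aggregated["pc1"].to_numpy(dtype=float)
    n = len(y_all)
    y_by_g = [y_all[aggregated["isi_ms"].to_numpy() == g] for g in levels]
    x_by_g = [x_all[aggregated["isi_ms"].to_numpy() == g] for g in levels]

    flags: list[str] = []
    if len(np.unique(y_all)) < 2:
        flags.append("degenerate: single outcome class")
        nan = float("nan")
        return GLMMResult(
            nan, nan, nan, nan, nan, nan, nan, nan, nan, nan, nan, nan, nan,
            n_obs=n, n_groups=len(levels), converged=False, boundary=False, flags=flags,
        )

    beta_init = _plain_logistic_init(y_all, x_all)

    if fix_variances is not None:
        sd_fix = np.sqrt(np.asarray(fix_variances, dtype=float))
        nll = lambda b: -_marginal_ll(np.r_[b, sd_fix], y_by_g, x_by_g)
        res = optimize.minimize(nll, beta_init, method="BFGS")
        theta = np.r_[res.x, sd_fix]
        success = bool(res.success)
        k_params = 2
    else:
        nll4 = lambda t: -_marginal_ll(t, y_by_g, x_by_g)
        res = optimize.minimize(
            nll4,
            np.r_[beta_init, 0.3, 0.3],
            method="L-BFGS-B",
            bounds=[(-50, 50), (-50, 50), (0.0, 10.0), (0.0, 10.0)],
        )
        theta = res.x.copy()
        theta[2:4] = np.abs(theta[2:4])
        success = bool(res.success)
        k_params = 4

    beta0, beta1 = float(theta[0]), float(theta[1])
    sds = theta[2:4]
    ll = _marginal_ll(theta, y_by_g, x_by_g)

    boundary = bool((sds < _BOUNDARY_SD).any()) and fix_variances is None
    if max(abs(beta0), abs(beta1)) > 25:
        flags.append("separation suspected: fixed effect at parameter bound")
        success = False

    # Wald SEs from the curvature of the Laplace log-likelihood in the fixed
    # effects, holding the variance parameters at their estimates.
    H = _numeric_hessian(
        lambda b: -_marginal_ll(np.r_[b, sds], y_by_g, x_by_g), theta[:2]
    )
    try:
        cov = np.linalg.inv(H)
        se0, se1 = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    except (np.linalg.LinAlgError, FloatingPointError):
        se0 = se1 = float("nan")
        flags.append("singular fixed-effect information matrix")

    from scipy.stats import norm

    z0 = beta0 / se0 if se0 > 0 else float("nan")
    z1 = beta1 / se1 if se1 > 0 else float("nan")
    return GLMMResult(
        beta0=beta0,
        beta1=beta1,
        se0=se0,
        se1=se1,
        z0=z0,
        z1=z1,
        p0=float(2 * norm.sf(abs(z0))),
        p1=float(2 * norm.sf(abs(z1))),
        var_intercept=float(sds[0] ** 2),
        var_slope=float(sds[1] ** 2),
        loglik=float(ll),
        aic=float(2 * k_params - 2 * ll),
        bic=float(k_params * np.log(n) - 2 * ll),
        n_obs=n,
        n_groups=len(levels),
        converged=success,
        boundary=boundary,
        flags=flags,
    )


def run_pc_glmm(features: pd.DataFrame) -> tuple[PCResult, pd.DataFrame, GLMMResult]:
    """Convenience wrapper: PC1 extraction, aggregation, GLMM fit."""
    pc = standardize_and_pc1(features)
    agg = aggregate_pc1(
        pc.scores, features["subject_id"], features["isi_ms"], features["group"]
    )
    return pc, agg, fit_glmm(agg)
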
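"""Two-stage acceptability modeling over (storage time, sauce saturation).

Stage one describes saturation kinetics with a quadratic OLS fit

    f(t) = b0 + b1 * t + b2 * t**2,

reported with R^2, RMSE (divisor n) and a t-test of the curvature term.
Stage two is a logistic classifier of binary consumer acceptability

    P(y = 1 | t, S) = 1 / (1 + exp(-(a0 + a1 * t + a2 * S))),

fitted by Newton/IRLS on internally standardized predictors with a tiny
quadratic penalty (1e-8) guarding complete separation; coefficients are
reported on the original scale.  Storage temperature is deliberately not
a predictor: its effect on degradation is already integrated in the
observed saturation, and it is carried only as grouping metadata.

Evaluation follows the small-n protocol of the study design:
leave-one-out cross-validation pooled over all folds, accuracy at the
0.5 threshold, AUC as the Mann-Whitney concordance probability,
percentile-bootstrap bands for the probability-vs-saturation curve at a
fixed time, closed-form inversion of the 0.5 crossing to a saturation
acceptability limit S*(t) = -(a0 + a1 t)/a2, and a weighted-average
composite confidence score over bounded sub-scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import rankdata

__all__ = [
    "PolyFit",
    "LogitFit",
    "LoocvResult",
    "fit_quadratic",
    "predict_saturation",
    "logistic_fit",
    "fit_logistic",
    "predict_prob",
    "loocv",
    "roc_auc",
    "bootstrap_curve",
    "acceptability_limit",
    "ccc",
]

_RIDGE = 1e-8
_LL_TOL = 1e-10
_MAX_ITER = 100


# ---------------------------------------------------------------------------
# quadratic saturation kinetics


@dataclass
class PolyFit:
    """Quadratic OLS fit of saturation over time."""

    beta: tuple[float, float, float]
    r2: float
    rmse: float
    p_beta2: float
    se: tuple[float, float, float]
    df_resid: int
    n: int
    flags: list = field(default_factory=list)

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        """Per-coefficient t-intervals, rows (lower, upper)."""
        from scipy.stats import t as t_dist

        crit = t_dist.ppf(0.5 + level / 2.0, self.df_resid)
        b = np.asarray(self.beta)
        s = np.asarray(self.se)
        return np.column_stack([b - crit * s, b + crit * s])


def fit_quadratic(t, S) -> PolyFit:
    """OLS on the design [1, t, t^2]; RMSE uses divisor n."""
    t = np.asarray(t, dtype=float)
    S = np.asarray(S, dtype=float)
    if t.shape != S.shape:
        raise ValueError("t and S must have the same length")
    n = t.size
    if n < 4:
        raise ValueError("fit_quadratic: need at least 4 observations")
    if np.unique(t).size < 3:
        raise ValueError(
            "fit_quadratic: rank-deficient design (fewer than 3 distinct times)"
        )
    X = np.column_stack([np.ones(n), t, t**2])
    res = sm.OLS(S, X).fit()
    resid = S - res.fittedvalues
    rmse = float(np.sqrt(np.mean(resid**2)))
    flags = []
    sst = float(np.sum((S - S.mean()) ** 2))
    if sst == 0.0:
        r2 = 0.0
        flags.append("zero_total_variance")
    else:
        r2 = float(res.rsquared)
    return PolyFit(
        beta=tuple(float(b) for b in res.params),
        r2=r2,
        rmse=rmse,
        p_beta2=float(res.pvalues[2]) if sst > 0 else 1.0,
        se=tuple(float(s) for s in res.bse),
        df_resid=int(res.df_resid),
        n=n,
        flags=flags,
    )


def predict_saturation(fit: PolyFit, t) -> np.ndarray | float:
    """f(t) = b0 + b1 t + b2 t^2."""
    b0, b1, b2 = fit.beta
    t = np.asarray(t, dtype=float)
    out = b0 + b1 * t + b2 * t**2
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# logistic acceptability classifier


@dataclass
class LogitFit:
    """Maximum-likelihood logistic fit, coefficients on the original scale."""

    alpha: np.ndarray  # intercept first
    se: np.ndarray
    cov: np.ndarray
    log_likelihood: float
    converged: bool
    separation: bool
    n: int
    predictor_names: tuple[str, ...] = ("t", "S")


def logistic_fit(X, y, predictor_names: tuple[str, ...] | None = None) -> LogitFit:
    """Newton/IRLS logistic regression with a separation guard.

    Predictors are standardized internally; a ridge penalty of 1e-8 on
    the standardized coefficients keeps complete separation finite, and a
    ``separation`` flag marks fits driven to that guard.  Convergence:
    log-likelihood change < 1e-10 or 100 iterations.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y length mismatch")
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all():
        raise ValueError("labels must be binary 0/1")
    if classes.size < 2:
        raise ValueError("logistic_fit: both classes must be present")

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("logistic_fit: constant predictor column")
    Z = np.column_stack([np.ones(n), (X - mu) / sd])

    b = np.zeros(p + 1)
    ll_old = -np.inf
    converged = False
    for _ in range(_MAX_ITER):
        eta = Z @ b
        prob = expit(eta)
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)) - 0.5 * _RIDGE * b @ b)
        w = prob * (1.0 - prob)
        H = Z.T @ (Z * w[:, None]) + _RIDGE * np.eye(p + 1)
        grad = Z.T @ (y - prob) - _RIDGE * b
        step = np.linalg.solve(H, grad)
        b = b + step
        if abs(ll - ll_old) < _LL_TOL:
            converged = True
            break
        ll_old = ll
    separation = bool(np.max(np.abs(b)) > 10.0)
    if not converged:
        warnings.warn("logistic_fit: did not converge within the iteration cap")

    prob = expit(Z @ b)
    w = prob * (1.0 - prob)
    cov_std = np.linalg.inv(Z.T @ (Z * w[:, None]) + _RIDGE * np.eye(p + 1))
    # map standardized coefficients back to the original predictor scale
    A = np.eye(p + 1)
    A[0, 1:] = -mu / sd
    A[np.arange(1, p + 1), np.arange(1, p + 1)] = 1.0 / sd
    alpha = A @ b
    cov = A @ cov_std @ A.T
    eta_orig = alpha[0] + X @ alpha[1:]
    ll_final = float(np.sum(y * eta_orig - np.logaddexp(0.0, eta_orig)))
    names = predictor_names if predictor_names is not None else tuple(f"x{j}" for j in range(p))
    return LogitFit(
        alpha=alpha,
        se=np.sqrt(np.diag(cov)),
        cov=cov,
        log_likelihood=ll_final,
        converged=converged,
        separation=separation,
        n=n,
        predictor_names=names,
    )


def fit_logistic(t, S, y) -> LogitFit:
    """Acceptability classifier P(y=1 | t, S); needs n >= 6 and both classes."""
    t = np.asarray(t, dtype=float)
    S = np.asarray(S, dtype=float)
    if t.size < 6:
        raise ValueError("fit_logistic: need at least 6 observations")
    return logistic_fit(np.column_stack([t, S]), y, predictor_names=("t", "S"))


def predict_prob(fit: LogitFit, t, S) -> np.ndarray | float:
    """P(acceptable) = logistic(a0 + a1 t + a2 S)."""
    a0, a1, a2 = fit.alpha
    t = np.asarray(t, dtype=float)
    S = np.asarray(S, dtype=float)
    out = expit(a0 + a1 * t + a2 * S)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class LoocvResult:
    """Pooled out-of-fold LOOCV predictions and metrics."""

    probabilities: np.ndarray  # NaN for flagged folds
    predicted_labels: np.ndarray  # -1 for flagged folds
    accuracy: float
    auc: float
    fold_ids: np.ndarray
    flagged_folds: list
    n_folds: int


def loocv(t, S, y) -> LoocvResult:
    """Leave-one-out cross-validation of the (t, S) logistic classifier.

    Each record is held out exactly once and never participates in its
    own fold's fit; accuracy (0.5 threshold) and AUC are computed on the
    pooled out-of-fold probabilities.  Folds whose training partition is
    single-class are flagged and excluded from pooling.
    """
    t = np.asarray(t, dtype=float)
    S = np.asarray(S, dtype=float)
    y = np.asarray(y, dtype=int)
    n = t.size
    if n < 6:
        raise ValueError("loocv: need at least 6 records")
    if np.unique(y).size < 2:
        raise ValueError("loocv: both classes must be present")
    probs = np.full(n, np.nan)
    flagged = []
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        if np.unique(y[keep]).size < 2:
            warnings.warn(f"loocv: fold {i} has a single-class training partition; flagged")
            flagged.append(i)
            continue
        fit = fit_logistic(t[keep], S[keep], y[keep])
        probs[i] = predict_prob(fit, t[i], S[i])
    valid = ~np.isnan(probs)
    preds = np.where(valid, (probs >= 0.5).astype(int), -1)
    accuracy = float(np.mean(preds[valid] == y[valid]))
    auc = roc_auc(probs[valid], y[valid])
    return LoocvResult(
        probabilities=probs,
        predicted_labels=preds,
        accuracy=accuracy,
        auc=auc,
        fold_ids=np.arange(n),
        flagged_folds=flagged,
        n_folds=n,
    )


def roc_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney concordance probability (ties count 0.5).

    Equivalent to trapezoidal integration of the empirical ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels length mismatch")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc: both classes must be present")
    ranks = rankdata(scores)  # average ranks handle ties as 0.5
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def bootstrap_curve(
    t,
    S,
    y,
    t_fixed: float,
    S_grid,
    n_boot: int = 1000,
    seed: int = 42,
    max_retries: int = 100,
) -> pd.DataFrame:
    """Percentile-bootstrap band for P(acceptable) vs S at a fixed time.

    Records are resampled with replacement ``n_boot`` times, the
    classifier refitted, and the curve over ``S_grid`` evaluated at
    ``t_fixed``; bands are the 2.5/97.5 percentiles, the point estimate
    the full-data fit.  Single-class resamples are redrawn up to
    ``max_retries`` times, then flagged and skipped (count stored in
    ``df.attrs['n_flagged']``).
    """
    t = np.asarray(t, dtype=float)
    S = np.asarray(S, dtype=float)
    y = np.asarray(y, dtype=int)
    S_grid = np.asarray(S_grid, dtype=float)
    if n_boot < 100:
        raise ValueError("bootstrap_curve: n_boot must be >= 100")
    n = t.size
    rng = np.random.default_rng(seed)
    full = fit_logistic(t, S, y)
    point = predict_prob(full, np.full_like(S_grid, t_fixed), S_grid)

    curves = np.empty((n_boot, S_grid.size))
    n_flagged = 0
    for b in range(n_boot):
        for _ in range(max_retries):
            idx = rng.integers(0, n, size=n)
            if np.unique(y[idx]).size == 2:
                break
        else:
            warnings.warn("bootstrap_curve: resample stayed single-class; flagged")
            curves[b] = np.nan
            n_flagged += 1
            continue
        fit = fit_logistic(t[idx], S[idx], y[idx])
        curves[b] = predict_prob(fit, np.full_like(S_grid, t_fixed), S_grid)
    lower = np.nanpercentile(curves, 2.5, axis=0)
    upper = np.nanpercentile(curves, 97.5, axis=0)
    out = pd.DataFrame(
        {"S": S_grid, "point": point, "lower95": lower, "upper95": upper}
    )
    out.attrs["n_flagged"] = n_flagged
    out.attrs["t_fixed"] = float(t_fixed)
    return out


def acceptability_limit(fit: LogitFit, t: float) -> float:
    """Saturation S* at which P(acceptable | t, S) crosses 0.5.

    Closed-form root of the linear predictor: S* = -(a0 + a1 t) / a2.
    Reported even outside the 8-bit scale, with a warning flag.
    """
    a0, a1, a2 = fit.alpha
    if a2 == 0:
        raise ValueError("acceptability_limit: a2 = 0, probability has no crossing in S")
    s_star = float(-(a0 + a1 * t) / a2)
    if not (0.0 <= s_star <= 255.0):
        warnings.warn(
            f"acceptability_limit: S* = {s_star:.2f} lies outside the 8-bit scale [0, 255]"
        )
    return s_star


def ccc(sub_scores, weights) -> float:
    """Composite confidence score: weighted average of [0, 1] sub-scores.

    The default configuration of the pipeline uses K = 3 sub-scores
    (R^2 of the kinetics fit, LOOCV accuracy, LOOCV AUC) with weights
    (0.68, 0.25, 0.25); weights need not sum to 1 since the score is
    normalized by their total.
    """
    c = np.asarray(sub_scores, dtype=float)
    w = np.asarray(weights, dtype=float)
    if c.shape != w.shape or c.ndim != 1 or c.size == 0:
        raise ValueError("ccc: sub_scores and weights must be equal-length 1-D")
    if np.any((c < 0) | (c > 1)):
        raise ValueError("ccc: every sub-score must lie in [0, 1]")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("ccc: weights must be >= 0 with positive total")
    return float(np.sum(w * c) / np.sum(w))
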
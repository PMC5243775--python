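"""Statistical layer: binary logit, model selection, fit diagnostics.

The ascent outcome of the decision matrix is related to the measured
predictors (length and the three personality indices) through a binary
logistic regression fitted by iteratively reweighted least squares
(IRLS).  Because the matrix outcome is a deterministic function of the
predictors, quasi-complete separation is the expected regime on pipeline
output: the fitter therefore caps coefficient magnitudes, flags
separation, and still reports deviance and AIC at the capped solution
rather than failing.

Also provided: Hosmer-Lemeshow deciles-of-risk goodness of fit, Spearman
rank-correlation matrices with average ranks for ties, all-subset AIC
model building tables, and a sample-moment check (skewness / excess
kurtosis) that the arithmetic mean represents a trait's centre.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "LogitFit",
    "GofResult",
    "MomentCheck",
    "SpearmanResult",
    "fit_logit",
    "predict_proba",
    "hosmer_lemeshow",
    "spearman_matrix",
    "subset_model_table",
    "moment_check",
]

#: Coefficient magnitude cap under (quasi-)separation.  On the logit
#: scale |eta| = 25 corresponds to probabilities within ~1e-11 of 0/1,
#: far beyond any data resolution, so capping there changes no finite
#: answer while keeping the IRLS iteration bounded.
COEF_CAP = 25.0
MAX_ITER = 100
DEVIANCE_TOL = 1e-8


@dataclass
class LogitFit:
    """Maximum-likelihood binary logit fit (intercept always included)."""

    predictor_names: list[str]
    coefficients: np.ndarray
    intercept: float
    log_likelihood: float
    deviance: float
    aic: float
    lr_chi2: float
    lr_df: int
    lr_p: float
    pct_correct: float
    converged: bool
    separation_warning: bool
    n_obs: int = 0
    degenerate: bool = False


@dataclass
class GofResult:
    """Hosmer-Lemeshow deciles-of-risk test result."""

    statistic: float
    df: int
    p_value: float
    group_table: pd.DataFrame
    n_groups_merged: int = 0


@dataclass
class MomentCheck:
    """Sample skewness / excess kurtosis screen for mean-representativeness."""

    skewness: float
    excess_kurtosis: float
    mean: float
    median: float
    flagged: bool
    reason: str | None = None


@dataclass
class SpearmanResult:
    """Rank-correlation matrix plus any undefined (constant-column) pairs."""

    matrix: pd.DataFrame
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Logistic regression by IRLS

def _bernoulli_loglik(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _null_deviance(y: np.ndarray) -> float:
    p_bar = float(np.mean(y))
    if p_bar in (0.0, 1.0):
        return 0.0
    n1 = int(np.sum(y))
    n0 = len(y) - n1
    return -2.0 * (n1 * math.log(p_bar) + n0 * math.log(1 - p_bar))


def predict_proba(fit: LogitFit, X: np.ndarray) -> np.ndarray:
    """Fitted ascent probabilities for a design matrix (no intercept col)."""
    eta = fit.intercept + np.asarray(X, dtype=float) @ fit.coefficients
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))


def fit_logit(design: np.ndarray, outcome: np.ndarray,
              predictor_names: list[str] | None = None,
              max_iter: int = MAX_ITER, tol: float = DEVIANCE_TOL,
              coef_cap: float = COEF_CAP) -> LogitFit:
    """Fit a binary logit by IRLS.

    ``design`` is (n, k) without an intercept column; the intercept is
    added internally.  The likelihood-ratio chi-square compares against
    the intercept-only model; classification accuracy uses a 0.5 cut.

    A one-class outcome yields a flagged degenerate fit (no exception);
    (quasi-)complete separation is detected when any coefficient hits the
    magnitude cap, and the capped solution is reported.
    """
    X = np.atleast_2d(np.asarray(design, dtype=float))
    y = np.asarray(outcome, dtype=float).ravel()
    n, k = X.shape
    if len(y) != n:
        raise ValueError("design and outcome lengths differ")
    if k < 1:
        raise ValueError("need at least one predictor")
    names = list(predictor_names) if predictor_names is not None \
        else [f"x{j}" for j in range(k)]

    if len(np.unique(y)) < 2:
        # all successes or all failures: the MLE intercept diverges
        sign = 1.0 if y.mean() > 0.5 else -1.0
        p = 1.0 / (1.0 + math.exp(-sign * coef_cap))
        ll = _bernoulli_loglik(y, np.full(n, p))
        dev = -2.0 * ll
        return LogitFit(
            predictor_names=names, coefficients=np.zeros(k),
            intercept=sign * coef_cap, log_likelihood=ll, deviance=dev,
            aic=dev + 2 * (k + 1), lr_chi2=0.0, lr_df=k, lr_p=1.0,
            pct_correct=100.0 * float(np.mean((p >= 0.5) == y)),
            converged=False, separation_warning=True, n_obs=n, degenerate=True,
        )

    Xd = np.column_stack([np.ones(n), X])

    def _deviance(b: np.ndarray) -> float:
        eta = np.clip(Xd @ b, -700, 700)
        return -2.0 * _bernoulli_loglik(y, 1.0 / (1.0 + np.exp(-eta)))

    beta = np.zeros(k + 1)
    dev_old = _deviance(beta)
    converged = False
    capped = False
    for _ in range(max_iter):
        eta = np.clip(Xd @ beta, -700, 700)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(p * (1 - p), 1e-10, None)
        z = eta + (y - p) / w
        sw = np.sqrt(w)
        target, *_ = np.linalg.lstsq(Xd * sw[:, None], z * sw, rcond=None)
        # step-halving: never accept a deviance-increasing step (the raw
        # IRLS step explodes under (quasi-)complete separation)
        step = target - beta
        cand = beta + step
        for _half in range(40):
            if _deviance(np.clip(cand, -coef_cap, coef_cap)) <= dev_old + 1e-12:
                break
            step *= 0.5
            cand = beta + step
        if np.any(np.abs(cand) > coef_cap):
            capped = True
        beta = np.clip(cand, -coef_cap, coef_cap)
        dev = _deviance(beta)
        if abs(dev_old - dev) < tol:
            converged = True
            break
        dev_old = dev

    eta = np.clip(Xd @ beta, -700, 700)
    p = 1.0 / (1.0 + np.exp(-eta))
    ll = _bernoulli_loglik(y, p)
    dev = -2.0 * ll
    lr = max(_null_deviance(y) - dev, 0.0)
    lr_p = float(stats.chi2.sf(lr, k))
    if capped:
        logger.warning("logit fit hit the coefficient cap: (quasi-)complete "
                       "separation likely; reported values are at the capped "
                       "solution")
    return LogitFit(
        predictor_names=names, coefficients=beta[1:], intercept=float(beta[0]),
        log_likelihood=ll, deviance=dev, aic=dev + 2 * (k + 1),
        lr_chi2=lr, lr_df=k, lr_p=lr_p,
        pct_correct=100.0 * float(np.mean((p >= 0.5) == y)),
        converged=converged, separation_warning=capped, n_obs=n,
    )


# ---------------------------------------------------------------------------
# Goodness of fit

def hosmer_lemeshow(p_hat: np.ndarray, outcome: np.ndarray,
                    n_groups: int = 10) -> GofResult:
    """Hosmer-Lemeshow deciles-of-risk goodness-of-fit test.

    Individuals are sorted by predicted probability and split into
    ``n_groups`` near-equal groups; the statistic sums
    ``(O - E)^2 / (E (1 - E/n_g))`` over groups and is referred to a
    chi-square with ``n_groups - 2`` degrees of freedom.  Groups with
    (numerically) zero expected variance are merged into a neighbour.
    """
    p = np.asarray(p_hat, dtype=float).ravel()
    y = np.asarray(outcome, dtype=float).ravel()
    if len(p) != len(y):
        raise ValueError("probability and outcome lengths differ")
    if len(p) < n_groups:
        raise ValueError(f"need at least n_groups={n_groups} observations")
    order = np.argsort(p, kind="stable")
    groups = np.array_split(order, n_groups)

    rows = [{"n": len(g), "observed": float(np.sum(y[g])),
             "expected": float(np.sum(p[g]))} for g in groups]
    # merge groups whose variance term E(1 - E/n) is degenerate
    merged = 0
    i = 0
    while i < len(rows):
        r = rows[i]
        var = r["expected"] * (1 - r["expected"] / r["n"])
        if var <= 1e-12 and len(rows) > 1:
            j = i + 1 if i + 1 < len(rows) else i - 1
            rows[j] = {"n": rows[j]["n"] + r["n"],
                       "observed": rows[j]["observed"] + r["observed"],
                       "expected": rows[j]["expected"] + r["expected"]}
            del rows[i]
            merged += 1
            logger.info("merged a degenerate risk group into its neighbour")
            i = 0  # re-scan: the merge may still be degenerate
        else:
            i += 1

    stat = 0.0
    for r in rows:
        var = r["expected"] * (1 - r["expected"] / r["n"])
        if var <= 1e-12:
            # a fully degenerate table (e.g. a separated fit where every
            # prediction is numerically 0 or 1): observed == expected
            # contributes nothing, a mismatch contributes its squared size
            # against the smallest representable variance
            resid = r["observed"] - r["expected"]
            if abs(resid) > 1e-9:
                stat += resid ** 2 / 1e-12
            continue
        stat += (r["observed"] - r["expected"]) ** 2 / var
    df = max(len(rows) - 2, 1)
    return GofResult(statistic=float(stat), df=df,
                     p_value=float(stats.chi2.sf(stat, df)),
                     group_table=pd.DataFrame(rows), n_groups_merged=merged)


# ---------------------------------------------------------------------------
# Rank correlations

def spearman_matrix(columns: dict[str, np.ndarray] | pd.DataFrame) -> SpearmanResult:
    """Pairwise Spearman rank correlations with average ranks for ties.

    Computed as the Pearson correlation of the average-rank transforms.
    Pairs involving a constant column are undefined: they are listed in
    ``undefined_pairs`` and set to NaN, never silently propagated.
    """
    df = pd.DataFrame(columns)
    if len(df) < 3:
        raise ValueError("need at least three observations")
    names = list(df.columns)
    ranks = {c: stats.rankdata(df[c].to_numpy(dtype=float), method="average")
             for c in names}
    constant = {c for c in names if np.std(ranks[c]) == 0}
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    undefined: list[tuple[str, str]] = []
    for a, b in itertools.combinations(names, 2):
        if a in constant or b in constant:
            mat.loc[a, b] = mat.loc[b, a] = np.nan
            undefined.append((a, b))
            logger.warning("Spearman undefined for constant column pair (%s, %s)",
                           a, b)
            continue
        ra, rb = ranks[a], ranks[b]
        r = float(np.corrcoef(ra, rb)[0, 1])
        mat.loc[a, b] = mat.loc[b, a] = r
    for c in constant:
        mat.loc[c, c] = np.nan
    return SpearmanResult(matrix=mat, undefined_pairs=undefined)


# ---------------------------------------------------------------------------
# Model building over all predictor subsets

def subset_model_table(design: np.ndarray, outcome: np.ndarray,
                       predictor_names: list[str]) -> pd.DataFrame:
    """Fit every nonempty predictor subset and tabulate df / AIC / LR.

    One row per subset, sorted by subset size descending then AIC
    ascending, mirroring the usual model-building presentation.  ``df``
    is the subset size; AIC counts the intercept (deviance + 2(k+1)).
    """
    X = np.atleast_2d(np.asarray(design, dtype=float))
    names = list(predictor_names)
    k = X.shape[1]
    if k != len(names):
        raise ValueError("predictor_names length must match design columns")
    if k > 12:
        raise ValueError("all-subsets table limited to 12 predictors")
    rows = []
    for size in range(k, 0, -1):
        for subset in itertools.combinations(range(k), size):
            fit = fit_logit(X[:, subset], outcome,
                            [names[j] for j in subset])
            rows.append({
                "predictors": "+".join(names[j] for j in subset),
                "df": size,
                "aic": fit.aic,
                "deviance": fit.deviance,
                "lr_chi2": fit.lr_chi2,
                "p_value": fit.lr_p,
                "converged": fit.converged,
                "separation_warning": fit.separation_warning,
            })
    df = pd.DataFrame(rows)
    return (df.sort_values(["df", "aic"], ascending=[False, True])
              .reset_index(drop=True))


# ---------------------------------------------------------------------------
# Moment screen

def moment_check(values: np.ndarray) -> MomentCheck:
    """Sample skewness and excess kurtosis of a trait distribution.

    Uses the standard biased sample moments g1 = m3/m2^1.5 and
    g2 = m4/m2^2 - 3.  |skewness| > 1 flags that the arithmetic mean may
    not represent the distribution's centre (and hence would be a poor
    a-priori threshold); zero variance is flagged outright.
    """
    x = np.asarray(values, dtype=float).ravel()
    if len(x) < 4:
        raise ValueError("need at least four observations")
    m = float(np.mean(x))
    d = x - m
    m2 = float(np.mean(d ** 2))
    if m2 == 0:
        return MomentCheck(skewness=math.nan, excess_kurtosis=math.nan,
                           mean=m, median=float(np.median(x)), flagged=True,
                           reason="zero variance")
    g1 = float(np.mean(d ** 3) / m2 ** 1.5)
    g2 = float(np.mean(d ** 4) / m2 ** 2 - 3.0)
    flagged = abs(g1) > 1.0
    return MomentCheck(
        skewness=g1, excess_kurtosis=g2, mean=m, median=float(np.median(x)),
        flagged=flagged,
        reason="mean may not represent center" if flagged else None,
    )
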
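"""Recurrence-prediction statistics.

Group comparisons (pooled-variance t-test, exact tests for categorical
margins), univariable discrimination (Mann-Whitney C statistic with DeLong
confidence intervals), Firth multivariable models with backwards stepwise AIC
selection, Youden operating points with exact binomial intervals, PC1
augmentation of the clinical model, paired DeLong AUC comparison, repeated
stratified cross-validation, univariable Cox proportional hazards, and
precision-recall curves. All p-values are nominal (no multiplicity
adjustment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, precision_recall_curve as _sk_pr
from sklearn.model_selection import StratifiedKFold
from statsmodels.duration.hazard_regression import PHReg
from statsmodels.stats.proportion import proportion_confint

from .firth import FirthLogit, FirthLogitResults

__all__ = [
    "equal_variance_ttest",
    "fisher_exact_test",
    "roc_auc_mann_whitney",
    "delong_analysis",
    "DelongResult",
    "firth_logistic_fit",
    "backwards_stepwise_aic",
    "youden_operating_point",
    "OperatingPoint",
    "pc1_of_metrics",
    "PCAResult",
    "repeated_kfold_cv_auc",
    "cox_ph_univariable",
    "precision_recall_points",
    "ModelReport",
    "evaluate_model",
]


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def equal_variance_ttest(x, y):
    """Two-sided pooled-variance (equal-variance) independent t-test.

    Returns (t, p, df) with df = n_x + n_y - 2. With zero pooled variance the
    convention is p = 1 for equal means and p = 0 for unequal means.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    df = x.size + y.size - 2
    sp2 = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / df
    if sp2 == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0, df
        return float("inf") if x.mean() > y.mean() else float("-inf"), 0.0, df
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p), df


def _freeman_halton_2xk(table: np.ndarray) -> float:
    """Exact two-sided p for a 2xK table by full enumeration (small tables)."""
    from math import lgamma

    r1 = int(table[0].sum())
    cols = table.sum(axis=0).astype(int)
    n = int(cols.sum())

    def logc(a, b):
        if b < 0 or b > a:
            return -np.inf
        return lgamma(a + 1) - lgamma(b + 1) - lgamma(a - b + 1)

    log_denom = logc(n, r1)

    def logp(counts):
        return sum(logc(c, a) for c, a in zip(cols, counts)) - log_denom

    obs = logp(table[0].astype(int))
    total = 0.0
    k = len(cols)

    def rec(j, remaining, acc):
        nonlocal total
        if j == k - 1:
            if 0 <= remaining <= cols[j]:
                lp = acc + logc(cols[j], remaining) - log_denom
                if lp <= obs + 1e-9:
                    total += np.exp(lp)
            return
        tail = int(cols[j + 1:].sum())
        lo = max(0, remaining - tail)
        hi = min(cols[j], remaining)
        for a in range(lo, hi + 1):
            rec(j + 1, remaining - a, acc + logc(cols[j], a))

    rec(0, r1, 0.0)
    return float(min(1.0, total))


def fisher_exact_test(table) -> float:
    """Two-sided exact test of independence for a 2xK contingency table.

    2x2 tables use the hypergeometric point-probability rule; 2xK tables use
    Freeman-Halton enumeration. A zero margin returns p = 1 by convention.
    """
    table = np.asarray(table)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] < 2:
        raise ValueError("table must be 2xK with K >= 2")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        table = table.astype(float)
        if np.any(table < 0) or np.any(table != np.round(table)):
            raise ValueError("counts must be non-negative integers")
        table = table.astype(int)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        return 1.0
    if table.shape[1] == 2:
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    return _freeman_halton_2xk(table)


# ---------------------------------------------------------------------------
# ROC / DeLong
# ---------------------------------------------------------------------------

def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    return y


def roc_auc_mann_whitney(scores, labels) -> float:
    """C statistic as the Mann-Whitney concordance probability (ties count 0.5)."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    r = stats.rankdata(s)
    n1 = int(y.sum())
    n0 = y.size - n1
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _placements(scores, y):
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    pos = np.asarray(scores, dtype=float)[y == 1]
    neg = np.asarray(scores, dtype=float)[y == 0]
    # V10_i = fraction of negatives below positive i (+0.5 ties)
    order = np.argsort(neg, kind="mergesort")
    sneg = neg[order]
    v10 = (np.searchsorted(sneg, pos, side="left")
           + 0.5 * (np.searchsorted(sneg, pos, side="right")
                    - np.searchsorted(sneg, pos, side="left"))) / neg.size
    order = np.argsort(pos, kind="mergesort")
    spos = pos[order]
    v01 = (pos.size - np.searchsorted(spos, neg, side="right")
           + 0.5 * (np.searchsorted(spos, neg, side="right")
                    - np.searchsorted(spos, neg, side="left"))) / pos.size
    return v10, v01


@dataclass
class DelongResult:
    auc: float
    ci: tuple
    variance: float
    auc_b: float | None = None
    z: float | None = None
    pvalue: float | None = None
    degenerate: bool = False


def delong_analysis(scores_a, labels, scores_b=None, level: float = 0.95) -> DelongResult:
    """DeLong AUC variance / CI, and the paired AUC-difference test.

    The Wald interval is clipped to [0, 1]. An AUC of exactly 1 with no score
    ties has zero estimated variance; the result is flagged degenerate.
    """
    y = _check_binary(labels)
    v10a, v01a = _placements(scores_a, y)
    auc_a = float(v10a.mean())
    n1, n0 = v10a.size, v01a.size
    var_a = (np.var(v10a, ddof=1) / n1 if n1 > 1 else 0.0) + \
            (np.var(v01a, ddof=1) / n0 if n0 > 1 else 0.0)
    zq = stats.norm.ppf(0.5 + level / 2.0)
    half = zq * np.sqrt(var_a)
    ci = (float(max(0.0, auc_a - half)), float(min(1.0, auc_a + half)))
    res = DelongResult(auc=auc_a, ci=ci, variance=float(var_a),
                       degenerate=var_a == 0.0)
    if scores_b is None:
        return res
    v10b, v01b = _placements(scores_b, y)
    auc_b = float(v10b.mean())
    var_b = (np.var(v10b, ddof=1) / n1 if n1 > 1 else 0.0) + \
            (np.var(v01b, ddof=1) / n0 if n0 > 1 else 0.0)
    cov = 0.0
    if n1 > 1:
        cov += float(np.cov(v10a, v10b, ddof=1)[0, 1]) / n1
    if n0 > 1:
        cov += float(np.cov(v01a, v01b, ddof=1)[0, 1]) / n0
    var_diff = var_a + var_b - 2.0 * cov
    res.auc_b = auc_b
    if auc_a == auc_b:
        res.z, res.pvalue = 0.0, 1.0
    elif var_diff <= 0:
        res.z = float("inf") if auc_a > auc_b else float("-inf")
        res.pvalue = 0.0
        res.degenerate = True
    else:
        res.z = float((auc_a - auc_b) / np.sqrt(var_diff))
        res.pvalue = float(2.0 * stats.norm.sf(abs(res.z)))
    return res


# ---------------------------------------------------------------------------
# Firth fitting / selection
# ---------------------------------------------------------------------------

def firth_logistic_fit(exog, labels, exog_names=None,
                       add_constant: bool = True) -> FirthLogitResults:
    """Fit a Firth penalized logistic model (see `FirthLogit`)."""
    return FirthLogit(labels, exog, exog_names=exog_names,
                      add_constant=add_constant).fit()


def backwards_stepwise_aic(df: pd.DataFrame, outcome: str, candidates: list[str]):
    """Backwards stepwise selection by AIC over Firth main-effects models.

    Starting from the full model, repeatedly drop the single predictor whose
    removal most reduces AIC = -2 (penalized log-likelihood) + 2 k, stopping
    when no drop improves. Ties break by candidate order. Returns
    (selected names, fitted FirthLogitResults).
    """
    if len(candidates) > 15:
        raise ValueError("too many candidates for stepwise selection")
    current = list(candidates)

    def fit_on(cols):
        if cols:
            return FirthLogit.from_dataframe(df, outcome, cols).fit()
        sub = df[[outcome]].dropna()
        return FirthLogit(sub[outcome].to_numpy(),
                          np.empty((len(sub), 0)), exog_names=[]).fit()

    best_fit = fit_on(current)
    while current:
        trials = []
        for j, name in enumerate(current):
            reduced = [c for c in current if c != name]
            trials.append((fit_on(reduced).aic, j, reduced))
        aic_best, j_best, reduced_best = min(trials, key=lambda t: (t[0], t[1]))
        if aic_best < best_fit.aic:
            current = reduced_best
            best_fit = fit_on(current)
        else:
            break
    return current, best_fit


# ---------------------------------------------------------------------------
# operating point
# ---------------------------------------------------------------------------

@dataclass
class OperatingPoint:
    cutoff: float
    youden_j: float
    sensitivity: float
    specificity: float
    ppv: float
    sensitivity_ci: tuple
    specificity_ci: tuple
    ppv_ci: tuple


def _exact_ci(k: int, n: int, level: float = 0.95) -> tuple:
    if n == 0:
        return (float("nan"), float("nan"))
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="beta")
    return (float(lo), float(hi))


def youden_operating_point(scores, labels, level: float = 0.95) -> OperatingPoint:
    """Operating point maximizing sensitivity + specificity - 1.

    Cutoffs are midpoints between consecutive distinct observed scores plus
    open extremes ("predict positive" means score >= cutoff); ties in J break
    toward the higher-specificity (larger) cutoff. Sensitivity, specificity
    and PPV carry Clopper-Pearson exact intervals.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    u = np.unique(s)
    cuts = np.concatenate([[u[0] - 1.0], (u[:-1] + u[1:]) / 2.0 if u.size > 1 else [],
                           [u[-1] + 1.0]])
    n1, n0 = int(y.sum()), int((1 - y).sum())
    best = None
    for c in cuts:
        pred = s >= c
        tp = int(np.sum(pred & (y == 1)))
        tn = int(np.sum(~pred & (y == 0)))
        j = tp / n1 + tn / n0 - 1.0
        if best is None or j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12 and c > best[1]):
            best = (j, c, tp, tn, int(pred.sum()))
    j, c, tp, tn, npos = best
    sens, spec = tp / n1, tn / n0
    ppv = tp / npos if npos > 0 else float("nan")
    return OperatingPoint(
        cutoff=float(c), youden_j=float(j), sensitivity=sens, specificity=spec,
        ppv=ppv,
        sensitivity_ci=_exact_ci(tp, n1, level),
        specificity_ci=_exact_ci(tn, n0, level),
        ppv_ci=_exact_ci(tp, npos, level) if npos else (float("nan"), float("nan")),
    )


# ---------------------------------------------------------------------------
# PCA of the MRI metric block
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: pd.Series
    eigenvalues: np.ndarray
    loadings: pd.DataFrame
    columns: list = field(default_factory=list)


def pc1_of_metrics(metrics: pd.DataFrame, sign_column: str | None = "ktrans_v4") -> PCAResult:
    """PC1 of the standardized metric block (correlation-matrix PCA).

    Constant columns are dropped with a warning; rows with missing values are
    excluded (their score is NaN). The leading eigenvector's sign is fixed so
    the `sign_column` loading is positive.
    """
    df = metrics.copy()
    const = [c for c in df.columns if df[c].dropna().nunique() <= 1]
    if const:
        warnings.warn(f"dropping constant metric columns: {const}", stacklevel=2)
        df = df.drop(columns=const)
    complete = df.dropna()
    if complete.shape[0] <= df.shape[1]:
        raise ValueError("need more complete rows than retained metrics")
    z = (complete - complete.mean()) / complete.std(ddof=1)
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    v1 = evecs[:, 0]
    if sign_column is not None and sign_column in df.columns:
        if v1[list(df.columns).index(sign_column)] < 0:
            v1 = -v1
    elif v1.sum() < 0:
        v1 = -v1
    scores = pd.Series(z.to_numpy() @ v1, index=complete.index).reindex(df.index)
    loadings = pd.DataFrame(evecs, index=df.columns,
                            columns=[f"PC{i + 1}" for i in range(evecs.shape[1])])
    loadings["PC1"] = v1
    return PCAResult(scores=scores, eigenvalues=evals, loadings=loadings,
                     columns=list(df.columns))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def repeated_kfold_cv_auc(exog, labels, k: int = 5, repeats: int = 100,
                          seed: int = 0) -> float:
    """Mean cross-validated AUC over repeated stratified k-fold splits.

    Per repeat a Firth model is fitted on each training fold and out-of-fold
    linear predictors are pooled into one AUC; the mean over repeats is
    returned. Deterministic given `seed`.
    """
    y = _check_binary(labels)
    X = np.asarray(exog, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if int(y.sum()) < k:
        raise ValueError(
            f"only {int(y.sum())} events for {k} folds; use fewer folds")
    rng = np.random.default_rng(seed)
    aucs = np.empty(repeats)
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=int(rng.integers(2**31 - 1)))
        oof = np.empty(y.size)
        for train, test in skf.split(X, y):
            fit = FirthLogit(y[train], X[train]).fit()
            oof[test] = fit.predict_linear(X[test])
        aucs[r] = roc_auc_mann_whitney(oof, y)
    return float(aucs.mean())


# ---------------------------------------------------------------------------
# survival and PR
# ---------------------------------------------------------------------------

def cox_ph_univariable(time, event, covariate):
    """Univariable Cox proportional-hazards fit (Breslow ties).

    Returns (hazard ratio, Wald p, beta).
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    x = np.asarray(covariate, dtype=float)
    if e.sum() < 2:
        raise ValueError("need at least 2 events")
    if np.unique(x[np.isfinite(x)]).size < 2:
        raise ValueError("covariate is constant; hazard ratio not identifiable")
    keep = np.isfinite(t) & np.isfinite(x)
    model = PHReg(t[keep], x[keep, None], status=e[keep], ties="breslow")
    res = model.fit(disp=False)
    beta = float(res.params[0])
    return float(np.exp(beta)), float(res.pvalues[0]), beta


def precision_recall_points(scores, labels):
    """Precision-recall curve points and step-integrated average precision."""
    y = _check_binary(labels)
    precision, recall, thresholds = _sk_pr(y, np.asarray(scores, dtype=float))
    ap = float(average_precision_score(y, np.asarray(scores, dtype=float)))
    return precision, recall, thresholds, ap


# ---------------------------------------------------------------------------
# model reports
# ---------------------------------------------------------------------------

@dataclass
class ModelReport:
    """Fitted predictive model with apparent and cross-validated performance."""

    predictors: list
    coefficients: pd.Series
    wald_pvalues: pd.Series
    added_metric: str | None
    added_metric_wald_p: float | None
    auc: float
    auc_ci: tuple
    cv_auc: float | None
    operating_point: OperatingPoint
    delong_vs_reference_p: float | None
    nobs: int
    scores: np.ndarray = field(repr=False, default=None)

    def validate(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC out of range")
        if self.auc_ci[0] > self.auc_ci[1]:
            raise ValueError("CI bounds out of order")


def evaluate_model(df: pd.DataFrame, outcome: str, predictors: list[str],
                   added_metric: str | None = None,
                   reference_scores: pd.Series | None = None,
                   cv_repeats: int | None = 100, cv_folds: int = 5,
                   seed: int = 0) -> ModelReport:
    """Fit a Firth model and assemble its full performance report.

    Complete cases on `predictors` are used; `added_metric` names the
    predictor whose Wald p is reported as the incremental contribution.
    `reference_scores` (indexed like `df`) triggers a paired DeLong test on
    the common complete cases.
    """
    sub = df[[outcome] + predictors].dropna()
    y = sub[outcome].to_numpy().astype(int)
    X = sub[predictors].to_numpy()
    fit = FirthLogit(y, X, exog_names=predictors).fit()
    scores = fit.predict_linear(X)
    dl = delong_analysis(scores, y)
    op = youden_operating_point(scores, y)
    cv = None
    if cv_repeats:
        cv = repeated_kfold_cv_auc(X, y, k=cv_folds, repeats=cv_repeats, seed=seed)
    pair_p = None
    if reference_scores is not None:
        ref = np.asarray(pd.Series(reference_scores).reindex(sub.index), dtype=float)
        ok = np.isfinite(ref)
        pair = delong_analysis(scores[ok], y[ok], ref[ok])
        pair_p = pair.pvalue
    report = ModelReport(
        predictors=list(predictors),
        coefficients=fit.params,
        wald_pvalues=fit.pvalues,
        added_metric=added_metric,
        added_metric_wald_p=(float(fit.pvalues[added_metric])
                             if added_metric in fit.pvalues.index else None),
        auc=dl.auc,
        auc_ci=dl.ci,
        cv_auc=cv,
        operating_point=op,
        delong_vs_reference_p=pair_p,
        nobs=len(sub),
        scores=scores,
    )
    report.validate()
    return report
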
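"""Firth penalized logistic regression.

Maximizes the Jeffreys-prior penalized log-likelihood

    l*(b) = l(b) + 0.5 log det I(b),      I(b) = X' W X,  W = diag(p(1-p))

by modified-score Newton iterations with step-halving. The penalty removes the
first-order small-sample bias of the MLE and yields finite estimates under
complete or quasi-complete separation — the regime of a rare-event outcome in
a small cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["FirthLogit", "FirthLogitResults"]

MAX_ITER = 100
SCORE_TOL = 1e-8


def _drop_collinear(X: np.ndarray, names: list[str]):
    """Drop columns that are linearly dependent on earlier ones (QR pivots)."""
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return X, names, []
    keep, dropped = [], []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
        else:
            dropped.append(names[j])
    if dropped:
        warnings.warn(f"dropping collinear columns: {dropped}", stacklevel=3)
    return X[:, keep], [names[j] for j in keep], dropped


@dataclass
class FirthLogitResults:
    """Penalized-likelihood estimates with Wald inference."""

    params: pd.Series
    bse: pd.Series
    llf_penalized: float
    llf: float
    n_iter: int
    converged: bool
    nobs: int
    dropped_columns: list = field(default_factory=list)
    cov_params: np.ndarray = field(default=None, repr=False)

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        """Two-sided Wald p-values."""
        z = self.tvalues
        return pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=z.index)

    @property
    def aic(self) -> float:
        """AIC = -2 l(b*) + 2k with l the unpenalized log-likelihood at the
        penalized estimates.

        The Jeffreys penalty itself is excluded from the criterion: it grows
        by roughly 0.5 log(n w) per added column, which would overwhelm AIC's
        2-per-parameter charge and make backward elimination inert.
        """
        return -2.0 * self.llf + 2.0 * len(self.params)

    def predict_linear(self, X) -> np.ndarray:
        """Linear predictor for a raw design (constant prepended if needed)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] + 1 == len(self.params) and self.params.index[0] == "const":
            X = np.column_stack([np.ones(X.shape[0]), X])
        return X @ self.params.to_numpy()

    def summary(self) -> str:
        tab = pd.DataFrame({
            "coef": self.params,
            "std err": self.bse,
            "z": self.tvalues,
            "P>|z|": self.pvalues,
        })
        head = (
            f"Firth penalized logistic regression  (n = {self.nobs}, "
            f"iterations = {self.n_iter}, converged = {self.converged})\n"
            f"penalized log-likelihood = {self.llf_penalized:.4f}, "
            f"AIC = {self.aic:.3f}\n"
        )
        return head + tab.to_string(float_format=lambda v: f"{v: .4f}")


class FirthLogit:
    """Firth logistic model: binary `endog` on design `exog`.

    An intercept column is prepended unless `add_constant=False`. Collinear
    columns are dropped with a warning; a design that remains rank-deficient
    raises.
    """

    def __init__(self, endog, exog, exog_names=None, add_constant: bool = True):
        y = np.asarray(endog, dtype=float).ravel()
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("endog must be binary 0/1")
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != y.size:
            raise ValueError("endog and exog lengths differ")
        if not np.isfinite(X).all():
            raise ValueError("exog contains non-finite values")
        names = list(exog_names) if exog_names is not None else [
            f"x{j + 1}" for j in range(X.shape[1])
        ]
        if add_constant:
            X = np.column_stack([np.ones(y.size), X])
            names = ["const"] + names
        X, names, dropped = _drop_collinear(X, names)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient after pruning")
        self.endog, self.exog, self.exog_names = y, X, names
        self._dropped = dropped

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str, predictors: list[str],
                       add_constant: bool = True) -> "FirthLogit":
        sub = df[[outcome] + list(predictors)].dropna()
        return cls(sub[outcome].to_numpy(), sub[predictors].to_numpy(),
                   exog_names=list(predictors), add_constant=add_constant)

    # -- likelihood pieces -------------------------------------------------
    def _pll(self, beta):
        eta = self.exog @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        eps = 1e-300
        ll = float(self.endog @ np.log(p + eps)
                   + (1.0 - self.endog) @ np.log(1.0 - p + eps))
        w = p * (1.0 - p)
        info = self.exog.T @ (self.exog * w[:, None])
        sign, logdet = np.linalg.slogdet(info)
        if sign <= 0:
            return ll - 1e12, ll, p, info
        return ll + 0.5 * logdet, ll, p, info

    def fit(self, max_iter: int = MAX_ITER, tol: float = SCORE_TOL) -> FirthLogitResults:
        X, y = self.exog, self.endog
        beta = np.zeros(X.shape[1])
        pll, ll, p, info = self._pll(beta)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            w = p * (1.0 - p)
            info_inv = np.linalg.inv(info)
            # leverages of the weighted hat matrix
            h = np.einsum("ij,jk,ik->i", X * w[:, None], info_inv, X)
            score = X.T @ (y - p + h * (0.5 - p))
            if np.max(np.abs(score)) < tol:
                converged = True
                break
            step = info_inv @ score
            # step-halve until the penalized likelihood does not decrease
            for _ in range(30):
                cand = beta + step
                pll_new, ll_new, p_new, info_new = self._pll(cand)
                if pll_new >= pll - 1e-12:
                    break
                step *= 0.5
            beta, pll, ll, p, info = cand, pll_new, ll_new, p_new, info_new
        cov = np.linalg.inv(info)
        idx = pd.Index(self.exog_names)
        return FirthLogitResults(
            params=pd.Series(beta, index=idx),
            bse=pd.Series(np.sqrt(np.diag(cov)), index=idx),
            llf_penalized=pll,
            llf=ll,
            n_iter=it,
            converged=converged,
            nobs=y.size,
            dropped_columns=self._dropped,
            cov_params=cov,
        )
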
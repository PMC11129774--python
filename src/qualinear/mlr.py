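"""Ordinary least-squares multiple linear regression with standard inference.

The model is

    y = beta_0 + beta_1 x_1 + ... + beta_p x_p + eps,   eps ~ N(0, sigma^2)

fitted by a QR factorization of the design matrix (numerically stable in the
presence of near-collinear indicator columns).  Standard errors come from
the diagonal of ``sigma_hat^2 (X'X)^{-1}``, t statistics are
estimate / standard error, and p-values are two-sided Student-t with
``n - p - 1`` residual degrees of freedom — the usual layout of a regression
summary table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from .data import Dataset, design_matrix
from .errors import CollinearityError, ConfigError, DataError

__all__ = ["LinearModel", "LinearRegressionResults", "mse"]

_RANK_TOL = 1e-10  # smallest/largest singular value below this => collinear


class LinearModel:
    """OLS regression model ``y ~ X`` (statsmodels-style: ``fit`` returns results).

    Parameters
    ----------
    endog : array-like, shape (n,)
        Response vector.
    exog : array-like, shape (n, p+1)
        Design matrix, including the intercept column if one is wanted.
    names : sequence of str, optional
        One name per design column; defaults to ``x0..xp``.
    """

    def __init__(self, endog, exog, names=None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.shape[0]:
            raise DataError(
                f"response length {self.endog.shape[0]} != design rows "
                f"{self.exog.shape[0]}"
            )
        self.names = (list(names) if names is not None
                      else [f"x{j}" for j in range(self.exog.shape[1])])
        if len(self.names) != self.exog.shape[1]:
            raise ConfigError("one name required per design column")

    @classmethod
    def from_dataset(cls, dataset: Dataset, add_intercept: bool = True) -> "LinearModel":
        """Build from a :class:`Dataset` whose categoricals are already encoded."""
        if dataset.categorical:
            raise ConfigError(
                "encode categorical predictors before fitting: "
                f"{list(dataset.categorical)}"
            )
        X, names = design_matrix(dataset, add_intercept=add_intercept)
        return cls(dataset.response_values, X, names)

    def _check_rank(self):
        sv = linalg.svdvals(self.exog)
        if sv[-1] / sv[0] < _RANK_TOL:
            # identify the offending columns via pivoted QR: the pivots whose
            # R diagonal collapses are the ones expressible by earlier columns
            _, R, piv = linalg.qr(self.exog, mode="economic", pivoting=True)
            diag = np.abs(np.diag(R))
            bad = diag < _RANK_TOL * diag.max()
            cols = [self.names[piv[k]] for k in np.flatnonzero(bad)]
            raise CollinearityError(cols or self.names)

    def fit(self) -> "LinearRegressionResults":
        n, p1 = self.exog.shape
        if n <= p1:
            raise DataError(f"need n > p+1 observations (n={n}, p+1={p1})")
        self._check_rank()
        Q, R = np.linalg.qr(self.exog)
        params = linalg.solve_triangular(R, Q.T @ self.endog)
        fitted = self.exog @ params
        resid = self.endog - fitted
        df_resid = n - p1
        sse = float(resid @ resid)
        scale = sse / df_resid
        Rinv = linalg.solve_triangular(R, np.eye(p1))
        cov = scale * (Rinv @ Rinv.T)  # sigma^2 (X'X)^{-1}
        return LinearRegressionResults(self, params, fitted, resid, scale, cov)


@dataclass
class LinearRegressionResults:
    """Estimates, inference and goodness of fit for an OLS model."""

    model: LinearModel
    params: np.ndarray
    fittedvalues: np.ndarray
    resid: np.ndarray
    scale: float          # sigma_hat^2, the residual variance
    cov_params: np.ndarray

    @property
    def names(self):
        return self.model.names

    @property
    def nobs(self) -> int:
        return self.model.exog.shape[0]

    @property
    def df_resid(self) -> int:
        return self.nobs - self.model.exog.shape[1]

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def tvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.t.sf(np.abs(self.tvalues), self.df_resid)

    @property
    def ssr(self) -> float:
        return float(self.resid @ self.resid)

    @property
    def rsquared(self) -> float:
        y = self.model.endog
        sst = float(((y - y.mean()) ** 2).sum())
        if sst == 0.0:
            return 1.0
        return 1.0 - self.ssr / sst

    @property
    def rsquared_adj(self) -> float:
        n, p1 = self.model.exog.shape
        return 1.0 - (1.0 - self.rsquared) * (n - 1) / (n - p1)

    def predict(self, exog) -> np.ndarray:
        """Point predictions ``X_new @ beta_hat``."""
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        if X.shape[1] != len(self.params):
            raise DataError(
                f"new design has {X.shape[1]} columns, fit has {len(self.params)}"
            )
        return X @ self.params

    def summary(self) -> str:
        """Aligned-text coefficient table (Estimated, Std. error, t-value, p-values)."""
        header = f"{'':<14}{'Estimated':>12}{'Std. error':>12}{'t-value':>10}{'p-values':>12}"
        lines = [header]
        for nm, b, se, t, p in zip(self.names, self.params, self.bse,
                                   self.tvalues, self.pvalues):
            pv = "<0.001" if p < 1e-3 else f"{p:.3f}"
            lines.append(f"{nm:<14}{b:>12.4f}{se:>12.4f}{t:>10.2f}{pv:>12}")
        lines.append("")
        lines.append(
            f"n = {self.nobs}   df_resid = {self.df_resid}   "
            f"R-squared = {self.rsquared:.4f}   adj. R-squared = {self.rsquared_adj:.4f}"
        )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "coefficients": [
                {"name": nm, "estimate": float(b), "std_error": float(se),
                 "t_value": float(t), "p_value": float(p)}
                for nm, b, se, t, p in zip(self.names, self.params, self.bse,
                                           self.tvalues, self.pvalues)
            ],
            "n": int(self.nobs),
            "df_resid": int(self.df_resid),
            "r_squared": float(self.rsquared),
            "adj_r_squared": float(self.rsquared_adj),
            "residual_variance": float(self.scale),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def mse(actual, predicted) -> float:
    """Mean squared error between two equal-length vectors."""
    a = np.asarray(actual, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if a.size == 0:
        raise DataError("empty vectors")
    if a.size != p.size:
        raise DataError(f"length mismatch: {a.size} vs {p.size}")
    return float(np.mean((a - p) ** 2))
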
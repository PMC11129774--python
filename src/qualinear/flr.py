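"""Possibilistic fuzzy linear regression with triangular fuzzy coefficients.

The model is

    Y~ = A~_0 + A~_1 x_1 + ... + A~_p x_p

where each coefficient A~_j is a triangular fuzzy number with center ``a_j``
and non-negative left/right spreads ``s_j^L, s_j^R`` (the symmetric case of
a single vagueness ``c_j`` is recovered when the two spreads coincide).

Estimation is two-stage:

1. centers by ordinary least squares on the crisp data;
2. spreads by a linear program that minimizes total vagueness

       sum_i sum_j (s_j^L + s_j^R) |x_ij|

   subject to every training response lying inside the predicted support at
   membership level ``h``:

       sum_j a_j x_ij - (1-h) sum_j s_j^L |x_ij|  <=  y_i
       sum_j a_j x_ij + (1-h) sum_j s_j^R |x_ij|  >=  y_i

   with ``x_i0 = 1`` for the intercept and all spreads >= 0.  This is the
   classical possibilistic (Tanaka-style) construction; larger ``h`` forces
   wider spreads, and noiseless data yields zero spreads.

The LP is always feasible because the intercept spreads alone can absorb any
residual.  Lower/upper boundary response functions substitute each
coefficient's support endpoint, bracketing every training observation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .data import Dataset, design_matrix
from .errors import ConfigError, DataError, LPInfeasibleError
from .mlr import LinearModel

__all__ = [
    "TriangularFuzzyCoefficient",
    "FuzzyPrediction",
    "PossibilisticLinearModel",
    "FuzzyRegressionResults",
]


@dataclass(frozen=True)
class TriangularFuzzyCoefficient:
    """A triangular fuzzy number: membership 1 at ``center``, falling
    linearly to 0 at ``center - left_spread`` and ``center + right_spread``."""

    name: str
    center: float
    left_spread: float
    right_spread: float

    def __post_init__(self):
        if self.left_spread < 0 or self.right_spread < 0:
            raise ConfigError(f"negative spread for coefficient {self.name!r}")

    @property
    def lower(self) -> float:
        return self.center - self.left_spread

    @property
    def upper(self) -> float:
        return self.center + self.right_spread


@dataclass(frozen=True)
class FuzzyPrediction:
    """Central value plus the support interval of a fuzzy response."""

    central: float
    lower: float
    upper: float

    def __post_init__(self):
        if not (self.lower <= self.central <= self.upper):
            raise ConfigError("prediction interval must satisfy lower <= central <= upper")


class PossibilisticLinearModel:
    """Fuzzy linear regression model with crisp inputs and output.

    Parameters
    ----------
    endog, exog, names
        As in :class:`~qualinear.mlr.LinearModel`; the design matrix should
        include the intercept column.
    h : float in [0, 1)
        Membership level at which the inclusion constraints are enforced.
    """

    method_tag = "ls-center+lp-spread"

    def __init__(self, endog, exog, names=None, h: float = 0.0):
        if not 0.0 <= h < 1.0:
            raise ConfigError(f"h must lie in [0, 1), got {h}")
        self._ols = LinearModel(endog, exog, names)
        self.endog = self._ols.endog
        self.exog = self._ols.exog
        self.names = self._ols.names
        self.h = float(h)

    @classmethod
    def from_dataset(cls, dataset: Dataset, h: float = 0.0,
                     add_intercept: bool = True) -> "PossibilisticLinearModel":
        X, names = design_matrix(dataset, add_intercept=add_intercept)
        return cls(dataset.response_values, X, names, h=h)

    def fit(self) -> "FuzzyRegressionResults":
        centers = self._ols.fit().params
        sl, sr, objective = _solve_spreads(self.exog, self.endog, centers, self.h)
        coefs = [
            TriangularFuzzyCoefficient(nm, float(a), float(l), float(r))
            for nm, a, l, r in zip(self.names, centers, sl, sr)
        ]
        return FuzzyRegressionResults(self, coefs, self.h, objective)


def _solve_spreads(X, y, centers, h):
    """Minimum-vagueness spreads via ``scipy.optimize.linprog`` (HiGHS)."""
    n, m = X.shape
    absX = np.abs(X)
    resid = y - X @ centers
    shrink = 1.0 - h
    # variables: [s^L_0..s^L_p, s^R_0..s^R_p]
    cost = np.concatenate([absX.sum(axis=0), absX.sum(axis=0)])
    zeros = np.zeros_like(absX)
    # -(1-h)|x_i| . s^L <= y_i - yhat_i   and   -(1-h)|x_i| . s^R <= yhat_i - y_i
    A_ub = np.vstack([
        np.hstack([-shrink * absX, zeros]),
        np.hstack([zeros, -shrink * absX]),
    ])
    b_ub = np.concatenate([resid, -resid])
    res = linprog(cost, A_ub=A_ub, b_ub=b_ub, bounds=(0, None), method="highs")
    if not res.success:  # free intercept spreads make this unreachable
        raise LPInfeasibleError(f"spread LP failed: {res.message}")
    s = np.maximum(res.x, 0.0)
    return s[:m], s[m:], float(res.fun)


@dataclass
class FuzzyRegressionResults:
    """Fitted triangular fuzzy coefficients and prediction machinery."""

    model: PossibilisticLinearModel | None
    coefficients: list = field(default_factory=list)
    h: float = 0.0
    total_spread: float = 0.0   # LP objective: total weighted vagueness

    @classmethod
    def from_coefficients(cls, coefficients, h: float = 0.0) -> "FuzzyRegressionResults":
        """Build a results object directly from known coefficients.

        Useful for evaluating published coefficient tables without refitting.
        """
        return cls(model=None, coefficients=list(coefficients), h=h,
                   total_spread=float("nan"))

    @property
    def names(self):
        return [c.name for c in self.coefficients]

    @property
    def centers(self) -> np.ndarray:
        return np.array([c.center for c in self.coefficients])

    @property
    def left_spreads(self) -> np.ndarray:
        return np.array([c.left_spread for c in self.coefficients])

    @property
    def right_spreads(self) -> np.ndarray:
        return np.array([c.right_spread for c in self.coefficients])

    def boundary_equations(self):
        """(central, lower, upper) coefficient vectors.

        ``lower_j = a_j - s_j^L`` and ``upper_j = a_j + s_j^R``; substituting
        these endpoint coefficients gives the lower/upper boundary response
        functions of the model support interval.
        """
        return (self.centers,
                self.centers - self.left_spreads,
                self.centers + self.right_spreads)

    def _check_exog(self, exog):
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        if X.shape[1] != len(self.coefficients):
            raise DataError(
                f"new design has {X.shape[1]} columns, fit has {len(self.coefficients)}"
            )
        return X

    def predict(self, exog) -> list:
        """Fuzzy predictions, one :class:`FuzzyPrediction` per row.

        Central values use the center coefficients; the support uses
        ``central -/+ |x| . s`` so that for the non-negative regressors of a
        dummy-coded design it coincides with substituting each coefficient's
        boundary value, while signed regressors still give lower <= upper.
        """
        X = self._check_exog(exog)
        central = X @ self.centers
        lo = central - np.abs(X) @ self.left_spreads
        hi = central + np.abs(X) @ self.right_spreads
        return [FuzzyPrediction(float(c), float(l), float(u))
                for c, l, u in zip(central, lo, hi)]

    def predict_central(self, exog) -> np.ndarray:
        return self._check_exog(exog) @ self.centers

    def summary(self) -> str:
        """Aligned table of central tendency and support boundaries per coefficient."""
        _, lower, upper = self.boundary_equations()
        lines = [f"{'':<14}{'Central tendency':>18}{'Lower boundary':>16}{'Upper boundary':>16}"]
        for nm, a, l, u in zip(self.names, self.centers, lower, upper):
            lines.append(f"{nm:<14}{a:>18.4f}{l:>16.4f}{u:>16.4f}")
        lines.append("")
        lines.append(f"h = {self.h}   method = {PossibilisticLinearModel.method_tag}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "h": self.h,
            "method": PossibilisticLinearModel.method_tag,
            "coefficients": [
                {"name": c.name, "center": c.center,
                 "lower": c.lower, "upper": c.upper}
                for c in self.coefficients
            ],
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)
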
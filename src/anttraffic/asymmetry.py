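"""Directional symmetry of the flow and its effect on throughput.

The asymmetry of a second of traffic is the outbound share
``a = n_out/(n_out + n_in)``: 1 or 0 means unidirectional traffic, 0.5
fully mixed bidirectional traffic.  A quadratic response surface of the
flow on standardized density and asymmetry terms quantifies whether
throughput depends on how mixed the two directions are; near-zero
asymmetry coefficients mean the flow is set by density alone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import DataFormatError

__all__ = ["asymmetry_series", "ResponseSurfaceRegressor", "response_surface"]

TERMS = ("density", "density2", "asym", "asym2", "density_asym")


def asymmetry_series(obs: pd.DataFrame) -> pd.DataFrame:
    """Per-second asymmetry records (k, q, a) from an observation table.

    Seconds with zero flow have undefined outbound share; their ``a`` is
    missing (NaN) and downstream regressions drop them.
    """
    total = obs["n_out"] + obs["n_in"]
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(total > 0, obs["n_out"] / total.replace(0, np.nan), np.nan)
    return pd.DataFrame({"k": obs["k"], "q": obs["q"], "a": a})


def _zscore(x: np.ndarray, what: str) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise DataFormatError(f"response surface: {what} has no variation")
    return (x - x.mean()) / sd


class ResponseSurfaceRegressor(RegressorMixin, BaseEstimator):
    """Standardized quadratic regression of flow on density and asymmetry.

    Density and asymmetry are z-scored, the quadratic and interaction
    terms are formed from the z-scores, and the response is z-scored, so
    the coefficients are standardized betas comparable across terms.

    Attributes
    ----------
    coef_ : dict
        Standardized betas keyed ``density``, ``density2``, ``asym``,
        ``asym2``, ``density_asym``.
    r2_ : float
    """

    def __init__(self, min_records: int = 100):
        self.min_records = min_records

    def fit(self, X, y):
        """X is (n, 2): columns density and asymmetry; y is the flow."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[1] != 2:
            raise DataFormatError("response surface expects two predictors (k, a)")
        keep = np.isfinite(X).all(axis=1) & np.isfinite(y)
        X, y = X[keep], y[keep]
        if X.shape[0] < self.min_records:
            raise DataFormatError(
                f"response surface: need at least {self.min_records} complete "
                f"records, got {X.shape[0]}"
            )
        self._loc = (X[:, 0].mean(), X[:, 1].mean(), y.mean())
        self._scale = (X[:, 0].std(ddof=0), X[:, 1].std(ddof=0), y.std(ddof=0))
        zk = _zscore(X[:, 0], "density")
        za = _zscore(X[:, 1], "asymmetry")
        zq = _zscore(y, "flow")
        design = np.column_stack([zk, zk**2, za, za**2, zk * za])
        res = sm.OLS(zq, sm.add_constant(design)).fit()
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise DataFormatError("response surface: collinear design")
        self.coef_ = dict(zip(TERMS, map(float, res.params[1:])))
        self.se_ = dict(zip(TERMS, map(float, res.bse[1:])))
        self.r2_ = float(res.rsquared)
        self.n_ = int(X.shape[0])
        self._result = res
        return self

    def predict(self, X):
        """Predicted flow in original units at (density, asymmetry) pairs."""
        X = np.asarray(X, dtype=float)
        zk = (X[:, 0] - self._loc[0]) / self._scale[0]
        za = (X[:, 1] - self._loc[1]) / self._scale[1]
        design = np.column_stack([zk, zk**2, za, za**2, zk * za])
        zq = self._result.predict(sm.add_constant(design, has_constant="add"))
        return zq * self._scale[2] + self._loc[2]


def response_surface(records: pd.DataFrame) -> ResponseSurfaceRegressor:
    """Fit the standardized surface to an asymmetry table (k, q, a)."""
    est = ResponseSurfaceRegressor()
    return est.fit(records[["k", "a"]].to_numpy(float), records["q"])
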
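"""Macroscopic flow-density models, fitting, and Akaike-weight selection.

Four fundamental-diagram models relate trail density ``k`` (ants/cm^2)
to per-width flow ``q`` (ants/cm/s):

* ``greenshields``  — linear speed decay, v = v_f (1 - k/k_j); flow is a
  parabola vanishing at the jam density k_j.
* ``pipes_munjal``  — power-law speed decay, v = v_f (1 - (k/k_j)^p).
* ``underwood``     — exponential speed decay, v = v_f exp(-k/k_m).
* ``two_phase``     — piecewise-linear flow: q = v*k below the breakpoint
  k_j and constant q = v*k_j above it.  Unlike the classical models the
  flow never returns to zero: traffic saturates instead of jamming.

All models are fitted to (k, q) observation pairs by nonlinear least
squares and compared with Akaike weights derived from the least-squares
AIC ``n*ln(SSE/n) + 2*(p+1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, minimize
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import ConfigurationError, DataFormatError, FitConvergenceError

__all__ = [
    "greenshields_speed",
    "pipes_munjal_speed",
    "underwood_speed",
    "two_phase_flow",
    "DiagramModel",
    "MODELS",
    "DiagramFit",
    "FundamentalDiagramRegressor",
    "fit_diagram",
    "fit_all_diagrams",
    "akaike_weights",
    "bin_summary",
]


def _check_positive(**kwargs) -> None:
    for name, value in kwargs.items():
        if value <= 0:
            raise ConfigurationError(f"{name} must be positive, got {value}")


def greenshields_speed(k, v_f: float, k_j: float):
    """Linear speed-density relation; v(0) = v_f, v(k_j) = 0, clamped at 0."""
    _check_positive(v_f=v_f, k_j=k_j)
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ConfigurationError("density must be non-negative")
    v = v_f * np.clip(1.0 - k / k_j, 0.0, None)
    return v if v.ndim else float(v)


def pipes_munjal_speed(k, v_f: float, k_j: float, p: float):
    """Power-law speed-density relation; reduces to Greenshields at p = 1."""
    _check_positive(v_f=v_f, k_j=k_j, p=p)
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ConfigurationError("density must be non-negative")
    v = v_f * np.clip(1.0 - (k / k_j) ** p, 0.0, None)
    return v if v.ndim else float(v)


def underwood_speed(k, v_f: float, k_m: float):
    """Exponential speed-density relation; v(k_m) = v_f / e."""
    _check_positive(v_f=v_f, k_m=k_m)
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ConfigurationError("density must be non-negative")
    v = v_f * np.exp(-k / k_m)
    return v if v.ndim else float(v)


def two_phase_flow(k, v: float, k_j: float):
    """Piecewise-linear flow: q = v*min(k, k_j).

    Linear free-flow phase below the breakpoint ``k_j``, constant plateau
    ``q_j = v*k_j`` above it; continuous and non-decreasing in ``k``.
    """
    _check_positive(v=v, k_j=k_j)
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ConfigurationError("density must be non-negative")
    q = v * np.minimum(k, k_j)
    return q if q.ndim else float(q)


@dataclass(frozen=True)
class DiagramModel:
    """A named flow-density model: ordered parameters and a flow function."""

    name: str
    param_names: tuple[str, ...]
    flow_fn: "callable" = field(repr=False)
    speed_fn: "callable | None" = field(default=None, repr=False)


def _q_greenshields(k, v_f, k_j):
    return k * greenshields_speed(k, v_f, k_j)


def _q_pipes_munjal(k, v_f, k_j, p):
    return k * pipes_munjal_speed(k, v_f, k_j, p)


def _q_underwood(k, v_f, k_m):
    return k * underwood_speed(k, v_f, k_m)


MODELS: dict[str, DiagramModel] = {
    "greenshields": DiagramModel(
        "greenshields", ("v_f", "k_j"), _q_greenshields, greenshields_speed
    ),
    "pipes_munjal": DiagramModel(
        "pipes_munjal", ("v_f", "k_j", "p"), _q_pipes_munjal, pipes_munjal_speed
    ),
    "underwood": DiagramModel(
        "underwood", ("v_f", "k_m"), _q_underwood, underwood_speed
    ),
    "two_phase": DiagramModel("two_phase", ("v", "k_j"), two_phase_flow),
}


@dataclass
class DiagramFit:
    """Result of fitting one flow-density model to an observation set."""

    model: str
    param_names: tuple[str, ...]
    estimates: np.ndarray
    se: np.ndarray
    sse: float
    n: int
    aic: float
    akaike_weight: float | None = None

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": dict(zip(self.param_names, map(float, self.estimates))),
            "se": dict(zip(self.param_names, map(float, self.se))),
            "sse": float(self.sse),
            "n": int(self.n),
            "aic": float(self.aic),
            "akaike_weight": (
                None if self.akaike_weight is None else float(self.akaike_weight)
            ),
        }


def _aic_ls(sse: float, n: int, n_params: int) -> float:
    # Gaussian least-squares AIC; +1 counts the error variance.
    # SSE floored at machine tiny so exact fits give a finite AIC.
    return n * np.log(max(sse, np.finfo(float).tiny) / n) + 2 * (n_params + 1)


class FundamentalDiagramRegressor(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares fit of one fundamental-diagram model.

    Parameters
    ----------
    model : str
        One of ``greenshields``, ``pipes_munjal``, ``underwood``,
        ``two_phase``.
    init : "auto" or sequence of float
        Starting values; "auto" derives them from the data (free-flow
        slope from the lowest-density decile, breakpoint near the top of
        the observed density range).
    kj_step : float
        Breakpoint grid step for the two-phase profile search.

    The two-phase model is non-smooth at the breakpoint, so it is fitted
    by profiling: for each candidate breakpoint on a grid the slope has a
    closed-form weighted-least-squares solution; the best grid point then
    seeds a continuous Nelder-Mead refinement.

    Attributes
    ----------
    params_ : ndarray        Fitted parameter vector.
    se_ : ndarray            Asymptotic standard errors.
    sse_ : float             Residual sum of squares.
    aic_ : float             Least-squares AIC.
    """

    def __init__(self, model: str = "two_phase", init="auto", kj_step: float = 0.1):
        self.model = model
        self.init = init
        self.kj_step = kj_step

    # -- initialisation -----------------------------------------------------
    def _auto_init(self, k, q):
        low = k <= np.quantile(k[k > 0], 0.1)
        with np.errstate(divide="ignore", invalid="ignore"):
            slopes = q[low & (k > 0)] / k[low & (k > 0)]
        v0 = float(np.nanmedian(slopes)) if slopes.size else 1.0
        v0 = v0 if np.isfinite(v0) and v0 > 0 else 1.0
        if self.model == "underwood":
            return [v0, float(np.median(k[k > 0]))]
        if self.model == "pipes_munjal":
            return [v0, 1.2 * float(k.max()), 2.0]
        return [v0, 1.2 * float(k.max())]

    # -- two-phase profile --------------------------------------------------
    def _fit_two_phase(self, k, q):
        kj_grid = np.arange(self.kj_step, k.max() + self.kj_step, self.kj_step)
        best = (np.inf, None, None)
        qm_sum = None
        for kj in kj_grid:
            m = np.minimum(k, kj)
            denom = float(m @ m)
            if denom == 0:
                continue
            v = float(q @ m) / denom
            sse = float(np.sum((q - v * m) ** 2))
            if sse < best[0]:
                best = (sse, v, kj)
        if best[1] is None:
            raise FitConvergenceError("two-phase profile search failed")

        def sse_fn(theta):
            v, kj = theta
            if v <= 0 or kj <= 0:
                return np.inf
            return float(np.sum((q - v * np.minimum(k, kj)) ** 2))

        res = minimize(
            sse_fn,
            x0=[best[1], best[2]],
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-12},
        )
        v, kj = (res.x if res.fun <= best[0] else (best[1], best[2]))
        sse = min(float(res.fun), best[0])
        # Gauss-Newton covariance from the a.e. Jacobian of v*min(k, kj)
        J = np.column_stack([np.minimum(k, kj), np.where(k > kj, v, 0.0)])
        dof = max(k.size - 2, 1)
        sigma2 = sse / dof
        try:
            cov = sigma2 * np.linalg.inv(J.T @ J)
            se = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            se = np.full(2, np.nan)
        return np.array([v, kj]), se, sse

    # -- api ----------------------------------------------------------------
    def fit(self, X, y):
        """Fit to densities ``X`` and per-width flows ``y``."""
        if self.model not in MODELS:
            raise ConfigurationError(f"unknown diagram model {self.model!r}")
        k = np.asarray(X, dtype=float).ravel()
        q = np.asarray(y, dtype=float).ravel()
        if k.size != q.size:
            raise DataFormatError("density and flow lengths differ")
        if k.size < 10:
            raise DataFormatError(
                f"need at least 10 observations, got {k.size}"
            )
        if np.ptp(k) == 0:
            raise DataFormatError("no density spread in observations")
        if np.all(q == 0):
            raise DataFormatError("all flows are zero; degenerate data")
        spec = MODELS[self.model]

        if self.model == "two_phase":
            params, se, sse = self._fit_two_phase(k, q)
        else:
            p0 = self._auto_init(k, q) if self.init == "auto" else list(self.init)
            bounds = ([1e-8] * len(p0), [np.inf] * len(p0))
            last_err = None
            for scale in (1.0, 0.5, 2.0):
                try:
                    popt, pcov = curve_fit(
                        spec.flow_fn,
                        k,
                        q,
                        p0=np.asarray(p0) * scale,
                        bounds=bounds,
                        maxfev=20000,
                    )
                    break
                except RuntimeError as err:
                    last_err = err
            else:
                raise FitConvergenceError(
                    f"{self.model} fit did not converge: {last_err}"
                )
            params = popt
            se = np.sqrt(np.diag(pcov))
            sse = float(np.sum((q - spec.flow_fn(k, *popt)) ** 2))

        self.params_ = np.asarray(params, dtype=float)
        self.se_ = np.asarray(se, dtype=float)
        self.sse_ = float(sse)
        self.n_ = int(k.size)
        self.param_names_ = spec.param_names
        self.aic_ = _aic_ls(self.sse_, self.n_, len(self.params_))
        return self

    def predict(self, X):
        k = np.asarray(X, dtype=float)
        return MODELS[self.model].flow_fn(k, *self.params_)

    def result_(self) -> DiagramFit:
        """Package the fitted state as a :class:`DiagramFit`."""
        return DiagramFit(
            model=self.model,
            param_names=self.param_names_,
            estimates=self.params_.copy(),
            se=self.se_.copy(),
            sse=self.sse_,
            n=self.n_,
            aic=self.aic_,
        )


def fit_diagram(obs: pd.DataFrame, model: str, init="auto") -> DiagramFit:
    """Fit one named model to an observation table with columns k, q."""
    est = FundamentalDiagramRegressor(model=model, init=init)
    est.fit(obs["k"], obs["q"])
    return est.result_()


def akaike_weights(fits: list[DiagramFit]) -> list[DiagramFit]:
    """Attach Akaike weights w_i = exp(-d_i/2)/sum_j exp(-d_j/2).

    ``d_i = AIC_i - min AIC``.  All fits must be on the same observation
    set (checked via n).  Returns the same fit objects, updated.
    """
    if not fits:
        raise DataFormatError("akaike_weights: empty fit list")
    ns = {f.n for f in fits}
    if len(ns) != 1:
        raise DataFormatError(
            f"akaike_weights: fits use different observation counts {sorted(ns)}"
        )
    aics = np.array([f.aic for f in fits])
    delta = aics - aics.min()
    w = np.exp(-delta / 2)
    w /= w.sum()
    for f, wi in zip(fits, w):
        f.akaike_weight = float(wi)
    return fits


def fit_all_diagrams(obs: pd.DataFrame, models=None) -> list[DiagramFit]:
    """Fit every registered model to one observation table and weight them."""
    models = list(MODELS) if models is None else list(models)
    return akaike_weights([fit_diagram(obs, m) for m in models])


def bin_summary(obs: pd.DataFrame, bin_width: float) -> pd.DataFrame:
    """Per-density-bin mean and SD of the flow.

    Bins are half-open ``[lo, lo + width)``; empty bins are omitted and
    the SD of a single-observation bin is reported as missing (the
    unbiased SD is undefined at n = 1).
    """
    if bin_width <= 0:
        raise ConfigurationError("bin_width must be positive")
    k = obs["k"].to_numpy(float)
    q = obs["q"].to_numpy(float)
    idx = np.floor(k / bin_width).astype(int)
    rows = []
    for b in np.unique(idx):
        sel = idx == b
        n = int(sel.sum())
        rows.append(
            {
                "bin_lo": b * bin_width,
                "bin_center": (b + 0.5) * bin_width,
                "n": n,
                "q_mean": float(q[sel].mean()),
                "q_sd": float(q[sel].std(ddof=1)) if n > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)
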
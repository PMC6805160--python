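"""Individual-level traffic chain: contacts, travel time, speed and flow.

The microscopic model links trail density ``k`` (ants/cm^2) to individual
speed through two competing effects:

* contacts: the number of physical contacts an ant incurs while crossing
  the monitored section grows linearly with density, ``C(k) = c*k``, and
  each contact costs a fixed delay ``dT``, so travel time is
  ``T = T0 + dT*C``;
* pheromone: a well-marked trail speeds ants up, modelled by the
  density-dependent factor ``phi(k) = alpha + beta*k*exp(-gamma*k)``,
  maximal at ``k = 1/gamma``.

Combining both, the expected speed over the section of length ``L`` is

    v(k) = L / (T0 + dT*c*k) * (alpha + beta*k*exp(-gamma*k))

and the per-width flow is ``q(k) = k*v(k)``, which saturates at the limit
``L*alpha/(dT*c)`` as density grows: contacts slow each ant, but only
linearly, so the flow plateaus instead of collapsing into a jam.

Fitting is exposed as sklearn-style estimators (:class:`ContactRateRegressor`,
:class:`TravelTimeRegressor`, :class:`SpeedModelRegressor`) plus thin
functional wrappers operating on tracked-ant tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import ConfigurationError, DataFormatError, FitConvergenceError

__all__ = [
    "MicroParams",
    "MicroFit",
    "pheromone_factor",
    "speed_model",
    "predict_flow",
    "limit_flow",
    "free_flow_speed",
    "ContactRateRegressor",
    "TravelTimeRegressor",
    "SpeedModelRegressor",
    "fit_contact_rate",
    "fit_travel_time",
    "fit_speed_model",
    "fit_microscopic",
    "travel_time_curves",
]


@dataclass(frozen=True)
class MicroParams:
    """Microscopic constants of the speed model.

    Defaults are the fitted values for Argentine-ant trail traffic:
    monitored length ``L`` = 2 cm, free travel time ``T0`` = 0.95 s,
    delay per contact ``dT`` = 0.24 s, contact-rate slope ``c`` = 0.61
    contacts per (ant/cm^2), and pheromone-factor constants
    ``alpha`` = 0.812, ``beta`` = 0.160, ``gamma`` = 0.156.
    """

    L: float = 2.0
    T0: float = 0.95
    dT: float = 0.24
    c: float = 0.61
    alpha: float = 0.812
    beta: float = 0.160
    gamma: float = 0.156

    def __post_init__(self) -> None:
        for name in ("L", "T0", "dT", "c", "alpha", "beta", "gamma"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"MicroParams.{name} must be positive")


def pheromone_factor(k, params: MicroParams = MicroParams()):
    """Density-dependent speed multiplier ``alpha + beta*k*exp(-gamma*k)``.

    Peaks at ``k = 1/gamma`` (about 6.4 ants/cm^2 at defaults) and decays
    back to ``alpha`` at high density.
    """
    k = np.asarray(k, dtype=float)
    out = params.alpha + params.beta * k * np.exp(-params.gamma * k)
    return out if out.ndim else float(out)


def speed_model(k, params: MicroParams = MicroParams()):
    """Expected individual speed v(k) in cm/s."""
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ConfigurationError("density must be non-negative")
    v = params.L / (params.T0 + params.dT * params.c * k) * pheromone_factor(k, params)
    return v if v.ndim else float(v)


def predict_flow(k, params: MicroParams = MicroParams()):
    """Predicted per-width flow q(k) = k * v(k), in ants/cm/s."""
    k = np.asarray(k, dtype=float)
    q = k * speed_model(k, params)
    return q if q.ndim else float(q)


def limit_flow(params: MicroParams = MicroParams()) -> float:
    """Asymptotic flow ``L*alpha/(dT*c)`` as density tends to infinity."""
    return params.L * params.alpha / (params.dT * params.c)


def free_flow_speed(T, C, dT: float = 0.24, L: float = 2.0):
    """Contact-corrected free-flow speed ``v_f = L/(T - C*dT)`` in cm/s.

    Records whose corrected time ``T - C*dT`` is non-positive are invalid
    (the linear contact correction overshoots) and come back as NaN so
    callers can count and exclude them.
    """
    T = np.asarray(T, dtype=float)
    C = np.asarray(C, dtype=float)
    denom = T - C * dT
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom > 0, L / np.where(denom > 0, denom, np.nan), np.nan)
    return v if v.ndim else float(v)


# ---------------------------------------------------------------------------
# estimators


def _check_1d(x, y, min_n: int, what: str):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise DataFormatError(f"{what}: x and y lengths differ")
    if x.size < min_n:
        raise DataFormatError(f"{what}: need at least {min_n} records, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DataFormatError(f"{what}: non-finite values in input")
    return x, y


class ContactRateRegressor(RegressorMixin, BaseEstimator):
    """Through-origin regression of contact count on density, C = c*k.

    The model has no intercept: zero density forces zero contacts.

    Attributes
    ----------
    slope_ : float
        Estimated contacts per unit density (cm^2/ant).
    se_ : float
        Standard error of the slope.
    r2_ : float
        Uncentered R^2 of the through-origin fit.
    """

    def __init__(self, min_records: int = 30):
        self.min_records = min_records

    def fit(self, X, y):
        k, C = _check_1d(X, y, self.min_records, "contact-rate regression")
        if np.all(k == 0):
            raise DataFormatError("contact-rate regression: all densities are zero")
        res = sm.OLS(C, k[:, None]).fit()
        self.slope_ = float(res.params[0])
        self.se_ = float(res.bse[0])
        r2 = float(res.rsquared)
        self.r2_ = r2 if np.isfinite(r2) else 0.0
        self.n_ = int(k.size)
        return self

    def predict(self, X):
        return np.asarray(X, dtype=float) * self.slope_


class TravelTimeRegressor(RegressorMixin, BaseEstimator):
    """OLS of travel time on contact count, T = T0 + dT*C.

    Attributes
    ----------
    intercept_ : float
        Free travel time T0 (s).
    slope_ : float
        Delay per contact dT (s).
    se_intercept_, se_slope_ : float
    r2_ : float
    """

    def __init__(self, min_records: int = 30):
        self.min_records = min_records

    def fit(self, X, y):
        C, T = _check_1d(X, y, self.min_records, "travel-time regression")
        if np.ptp(C) == 0:
            raise DataFormatError(
                "travel-time regression: contact count is constant; "
                "slope unidentifiable"
            )
        res = sm.OLS(T, sm.add_constant(C)).fit()
        self.intercept_ = float(res.params[0])
        self.slope_ = float(res.params[1])
        self.se_intercept_ = float(res.bse[0])
        self.se_slope_ = float(res.bse[1])
        self.r2_ = float(res.rsquared)
        self.n_ = int(C.size)
        return self

    def predict(self, X):
        return self.intercept_ + self.slope_ * np.asarray(X, dtype=float)


class SpeedModelRegressor(RegressorMixin, BaseEstimator):
    """Nonlinear fit of the pheromone-factor parameters (alpha, beta, gamma).

    With the contact chain (L, T0, dT, c) held fixed, the expected travel
    time at density ``k`` is

        T(k) = (T0 + dT*c*k) / (alpha + beta*k*exp(-gamma*k)).

    The fit minimizes squared residuals in travel-time space, where the
    tracked-record noise (contact-count dispersion and timing error) is
    additive and zero-mean; fitting reciprocal speeds instead would bias
    the parameters upward.  Levenberg-Marquardt from the neutral start
    (1, 0.1, 0.1), with a fallback restart from (0.5, 0.05, 0.05).

    Attributes
    ----------
    alpha_, beta_, gamma_ : float
    se_ : ndarray of shape (3,)
        Standard errors in (alpha, beta, gamma) order.
    """

    def __init__(
        self,
        L: float = 2.0,
        T0: float = 0.95,
        dT: float = 0.24,
        c: float = 0.61,
        p0: tuple[float, float, float] = (1.0, 0.1, 0.1),
    ):
        self.L = L
        self.T0 = T0
        self.dT = dT
        self.c = c
        self.p0 = p0

    def _travel_time(self, k, a, b, g):
        return (self.T0 + self.dT * self.c * k) / (a + b * k * np.exp(-g * k))

    def fit(self, X, y):
        """Fit to densities ``X`` and observed travel times ``y`` (s)."""
        k, T = _check_1d(X, y, 30, "speed-model fit")
        if np.ptp(k) < 1.0:
            raise DataFormatError(
                "speed-model fit: density spread too small; beta and gamma "
                "are unidentifiable"
            )
        if np.any(T <= 0):
            raise DataFormatError("speed-model fit: non-positive travel times")
        last_err: Exception | None = None
        for p0 in (self.p0, (0.5, 0.05, 0.05)):
            try:
                popt, pcov = curve_fit(
                    self._travel_time, k, T, p0=p0, maxfev=20000
                )
                break
            except RuntimeError as err:  # no convergence
                last_err = err
        else:
            raise FitConvergenceError(f"speed-model fit did not converge: {last_err}")
        self.alpha_, self.beta_, self.gamma_ = map(float, popt)
        self.se_ = np.sqrt(np.diag(pcov))
        self.n_ = int(k.size)
        return self

    def predict(self, X):
        """Predicted speed v(k) at the fitted parameters."""
        k = np.asarray(X, dtype=float)
        return self.L / self._travel_time(k, self.alpha_, self.beta_, self.gamma_)


# ---------------------------------------------------------------------------
# tracked-table wrappers


@dataclass
class MicroFit:
    """Bundle of all microscopic estimates from one tracked-ant table."""

    c_hat: float
    c_se: float
    c_r2: float
    T0_hat: float
    T0_se: float
    dT_hat: float
    dT_se: float
    tt_r2: float
    alpha_hat: float
    beta_hat: float
    gamma_hat: float
    pher_se: tuple[float, float, float]
    L: float = 2.0
    n: int = 0

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        d["pher_se"] = list(self.pher_se)
        return d


def _usable(tracked: pd.DataFrame) -> pd.DataFrame:
    """Drop U-turning ants: they never complete the crossing, so their
    travel times and contact counts do not belong in the regressions."""
    if "uturn" in tracked.columns:
        return tracked.loc[~tracked["uturn"].astype(bool)]
    return tracked


def fit_contact_rate(tracked: pd.DataFrame) -> ContactRateRegressor:
    """Fit C = c*k on the non-U-turn records of a tracked table."""
    df = _usable(tracked)
    return ContactRateRegressor().fit(df["k_local"], df["C"])


def fit_travel_time(tracked: pd.DataFrame) -> TravelTimeRegressor:
    """Fit T = T0 + dT*C on the non-U-turn records of a tracked table."""
    df = _usable(tracked)
    return TravelTimeRegressor().fit(df["C"], df["T"])


def fit_speed_model(
    tracked: pd.DataFrame,
    fixed: MicroParams | dict | None = None,
) -> SpeedModelRegressor:
    """Fit (alpha, beta, gamma) with the contact chain held at ``fixed``.

    ``fixed`` supplies L, T0, dT and c (a :class:`MicroParams` or a dict);
    defaults to the package defaults.
    """
    df = _usable(tracked)
    if fixed is None:
        fixed = MicroParams()
    if isinstance(fixed, MicroParams):
        fixed = {"L": fixed.L, "T0": fixed.T0, "dT": fixed.dT, "c": fixed.c}
    est = SpeedModelRegressor(**{k: fixed[k] for k in ("L", "T0", "dT", "c")})
    return est.fit(df["k_local"], df["T"])


def fit_microscopic(tracked: pd.DataFrame, L: float = 2.0) -> MicroFit:
    """Run the full microscopic chain on one tracked table."""
    cr = fit_contact_rate(tracked)
    tt = fit_travel_time(tracked)
    sp = fit_speed_model(
        tracked,
        {"L": L, "T0": tt.intercept_, "dT": tt.slope_, "c": cr.slope_},
    )
    return MicroFit(
        c_hat=cr.slope_,
        c_se=cr.se_,
        c_r2=cr.r2_,
        T0_hat=tt.intercept_,
        T0_se=tt.se_intercept_,
        dT_hat=tt.slope_,
        dT_se=tt.se_slope_,
        tt_r2=tt.r2_,
        alpha_hat=sp.alpha_,
        beta_hat=sp.beta_,
        gamma_hat=sp.gamma_,
        pher_se=tuple(sp.se_),
        L=L,
        n=cr.n_,
    )


# ---------------------------------------------------------------------------
# local regression of T on k per contact stratum


def _local_quadratic(x, y, grid, span: float, degree: int = 2):
    """Loess-style local polynomial fit with tricube weights.

    For each grid point the nearest ``span`` fraction of observations is
    weighted by the tricube kernel and a degree-``degree`` polynomial is
    fitted by weighted least squares.
    """
    n = x.size
    m = max(degree + 2, int(np.ceil(span * n)))
    m = min(m, n)
    fitted = np.empty(grid.size)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    for i, x0 in enumerate(grid):
        d = np.abs(xs - x0)
        idx = np.argpartition(d, m - 1)[:m]
        dmax = d[idx].max()
        if dmax == 0:
            fitted[i] = ys[idx].mean()
            continue
        w = (1 - (d[idx] / dmax) ** 3) ** 3
        X = np.vander(xs[idx] - x0, degree + 1, increasing=True)
        sw = np.sqrt(np.maximum(w, 0))
        coef, *_ = np.linalg.lstsq(X * sw[:, None], ys[idx] * sw, rcond=None)
        fitted[i] = coef[0]
    return fitted


def travel_time_curves(
    tracked: pd.DataFrame,
    contact_levels: list[int] | None = None,
    span: float = 0.75,
    n_grid: int = 50,
    min_records: int = 30,
) -> pd.DataFrame:
    """Smoothed travel-time-versus-density curve for each contact stratum.

    Stratifying by contact count isolates the density effect that is not
    mediated by contacts: within a stratum, travel time dips where the
    pheromone factor peaks (k near 1/gamma).  Strata with fewer than
    ``min_records`` records are skipped with a warning.

    Returns a tidy frame with columns ``C``, ``k``, ``T_fit``.
    """
    df = _usable(tracked)
    if contact_levels is None:
        counts = df["C"].value_counts()
        contact_levels = sorted(counts[counts >= min_records].index[:6])
    frames = []
    for level in contact_levels:
        sub = df.loc[df["C"] == level]
        if len(sub) < min_records:
            warnings.warn(
                f"contact stratum C={level} has {len(sub)} < {min_records} "
                "records; skipped",
                stacklevel=2,
            )
            continue
        k = sub["k_local"].to_numpy(float)
        T = sub["T"].to_numpy(float)
        grid = np.linspace(k.min(), k.max(), n_grid)
        fitted = _local_quadratic(k, T, grid, span=span)
        frames.append(pd.DataFrame({"C": level, "k": grid, "T_fit": fitted}))
    if not frames:
        raise DataFormatError("no contact stratum has enough records")
    return pd.concat(frames, ignore_index=True)
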
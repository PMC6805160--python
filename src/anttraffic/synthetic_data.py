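"""Seeded generator of synthetic trail-traffic data.

Produces the two table kinds the analysis consumes, with the statistical
structure the models assume, so every downstream stage can be exercised
without the experimental recordings:

* macroscopic per-second observations (density, directional crossing
  counts, per-width flow) whose mean flow follows the microscopic
  prediction q(k) = k*v(k), with Poisson counting noise;
* microscopic tracked-ant records (local density, contact count, travel
  time, direction, U-turn flag) with contacts Poisson-linear in density
  and travel time (T0 + dT*C)/phi(k) plus additive timing noise.

The generator is statistical, not spatially explicit: no positions,
lanes or collision geometry, and no pheromone-field dynamics.  Density
follows a logistic recruitment ramp to a plateau; the outbound fraction
relaxes from 1 (everyone heading to the food) to 0.5 as the first
foragers return.  All randomness flows from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .microscopic import MicroParams, pheromone_factor, predict_flow

__all__ = [
    "GeneratorConfig",
    "density_trajectory",
    "outbound_fraction",
    "generate_macroscopic",
    "generate_tracked",
]

FLOW_COLUMNS = ["t", "k", "n_out", "n_in", "width", "q", "experiment_id"]
TRACKED_COLUMNS = ["direction", "k_local", "C", "T", "uturn"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic experiment.

    Parameters
    ----------
    bridge_width : float
        Trail width in cm (the study used 0.5, 1.0 and 2.0).
    duration : int
        Recording length in seconds (one hour by default).
    density_max : float
        Equilibrium density in ants/cm^2; the colonies self-limited at 18.
    ramp_time : float
        Recruitment build-up time in seconds (equilibrium after ~10 min).
    seed : int
        Seed for all randomness in a run.
    uturn_prob : float
        Per-crossing probability of turning back (observed: 0.01).
    count_noise : bool
        Poisson noise on the per-second directional counts.
    contact_noise : bool
        Poisson contacts (else the deterministic mean c*k).
    travel_noise_sd : float
        SD (s) of the additive timing noise on travel time; 0 disables.
    pheromone : bool
        Apply the density-dependent speed factor phi(k).
    density_noise : bool
        Gaussian jitter (SD 5% of level, floored at 0) on the trajectory.
    density_profile : str
        "logistic" recruitment ramp, or "uniform" iid densities on
        [0, density_max] per second (useful for fitting benchmarks).
    asym_profile : callable or None
        t -> outbound fraction; None selects the logistic 1 -> 0.5 decay
        on the same recruitment clock.
    """

    bridge_width: float = 1.0
    duration: int = 3600
    density_max: float = 18.0
    ramp_time: float = 600.0
    seed: int = 0
    uturn_prob: float = 0.01
    count_noise: bool = True
    contact_noise: bool = True
    travel_noise_sd: float = 0.3
    pheromone: bool = True
    density_noise: bool = True
    density_profile: str = "logistic"
    asym_profile: Callable[[np.ndarray], np.ndarray] | None = None
    experiment_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        if self.bridge_width <= 0:
            raise ConfigurationError("bridge_width must be positive")
        if not 0 <= self.uturn_prob <= 1:
            raise ConfigurationError("uturn_prob must be in [0, 1]")
        if self.density_max < 0:
            raise ConfigurationError("density_max must be non-negative")
        if self.ramp_time < 0:
            raise ConfigurationError("ramp_time must be non-negative")
        if self.travel_noise_sd < 0:
            raise ConfigurationError("travel_noise_sd must be non-negative")
        if self.density_profile not in ("logistic", "uniform"):
            raise ConfigurationError(
                f"unknown density_profile {self.density_profile!r}"
            )


def _logistic_clock(t: np.ndarray, ramp_time: float) -> np.ndarray:
    """Recruitment clock rising 0 -> 1 over the ramp; a step when ramp is 0."""
    if ramp_time == 0:
        return np.ones_like(t, dtype=float)
    t_half = ramp_time / 2.0
    tau = ramp_time / 8.0
    return 1.0 / (1.0 + np.exp(-(t - t_half) / tau))


def density_trajectory(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Per-second density series in ants/cm^2, clipped to [0, density_max]."""
    t = np.arange(config.duration, dtype=float)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.density_profile == "uniform":
        return rng.uniform(0.0, config.density_max, size=config.duration)
    k = config.density_max * _logistic_clock(t, config.ramp_time)
    if config.density_noise and config.density_max > 0:
        k = k + rng.normal(0.0, 0.05 * k)
    return np.clip(k, 0.0, config.density_max)


def outbound_fraction(config: GeneratorConfig) -> np.ndarray:
    """Per-second outbound share of the flow; defaults to 1 -> 0.5 decay."""
    t = np.arange(config.duration, dtype=float)
    if config.asym_profile is not None:
        a = np.asarray(config.asym_profile(t), dtype=float)
        if a.shape != t.shape or np.any((a < 0) | (a > 1)):
            raise ConfigurationError("asym_profile must map t to fractions in [0,1]")
        return a
    return 1.0 - 0.5 * _logistic_clock(t, config.ramp_time)


def generate_macroscopic(
    config: GeneratorConfig,
    params: MicroParams = MicroParams(),
    flow_fn: Callable[[np.ndarray], np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-second flow/density observation table.

    The expected total crossing count in second ``t`` is
    ``q(k_t) * width`` with ``q`` from the microscopic flow prediction
    (or ``flow_fn`` if given, e.g. a planted two-phase curve for fitting
    benchmarks).  Counts are Poisson when ``count_noise`` is on, the
    rounded mean otherwise; the recorded flow is exactly
    ``(n_out + n_in)/width``.
    """
    rng = np.random.default_rng(config.seed)
    k = density_trajectory(config, rng)
    a = outbound_fraction(config)
    q_mean = flow_fn(k) if flow_fn is not None else predict_flow(k, params)
    total_mean = np.clip(q_mean, 0.0, None) * config.bridge_width
    out_mean = total_mean * a
    in_mean = total_mean * (1.0 - a)
    if config.count_noise:
        n_out = rng.poisson(out_mean)
        n_in = rng.poisson(in_mean)
    else:
        n_out = np.round(out_mean).astype(int)
        n_in = np.round(in_mean).astype(int)
    return pd.DataFrame(
        {
            "t": np.arange(config.duration),
            "k": k,
            "n_out": n_out,
            "n_in": n_in,
            "width": config.bridge_width,
            "q": (n_out + n_in) / config.bridge_width,
            "experiment_id": config.experiment_id,
        }
    )


def _default_k_sampler(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.uniform(0.0, 16.0, size=n)


def generate_tracked(
    n: int,
    k_sampler: Callable[[np.random.Generator, int], np.ndarray]
    | float
    | None = None,
    params: MicroParams = MicroParams(),
    config: GeneratorConfig = GeneratorConfig(),
) -> pd.DataFrame:
    """Individually tracked crossings of the monitored section.

    Each record carries the local density during the crossing, a contact
    count ``C ~ Poisson(c*k)`` (or the mean ``c*k`` with contact noise
    off), the travel time ``T = (T0 + dT*C)/phi(k)`` plus additive
    truncated-normal timing noise (floored at ``0.1*T0`` so times stay
    physical), a random direction and a Bernoulli U-turn flag.

    ``k_sampler`` may be a callable ``(rng, n) -> densities``, a scalar
    (constant density) or None (uniform on [0, 16], the study's range).
    """
    if n <= 0:
        raise ConfigurationError("n must be positive")
    rng = np.random.default_rng(config.seed)
    if k_sampler is None:
        k = _default_k_sampler(rng, n)
    elif callable(k_sampler):
        k = np.asarray(k_sampler(rng, n), dtype=float)
        if k.shape != (n,):
            raise ConfigurationError("k_sampler must return n densities")
    else:
        k = np.full(n, float(k_sampler))
    if np.any(k < 0):
        raise ConfigurationError("sampled densities must be non-negative")

    if config.contact_noise:
        C = rng.poisson(params.c * k).astype(float)
    else:
        C = params.c * k
    factor = pheromone_factor(k, params) if config.pheromone else 1.0
    T = (params.T0 + params.dT * C) / factor
    if config.travel_noise_sd > 0:
        T = T + rng.normal(0.0, config.travel_noise_sd, size=n)
        T = np.maximum(T, 0.1 * params.T0)
    direction = np.where(rng.random(n) < 0.5, "outbound", "inbound")
    uturn = rng.random(n) < config.uturn_prob
    return pd.DataFrame(
        {
            "direction": direction,
            "k_local": k,
            "C": C,
            "T": T,
            "uturn": uturn,
        }
    )
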
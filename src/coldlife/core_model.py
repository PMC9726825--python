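"""Stochastic speed-limit model of single-cell doubling times.

A cell's doubling time is the sum of a reactive-oxygen-species (ROS)
independent floor and a ROS-dependent G1 delay::

    tau = t + dt
    t   = c_t * r(T) ** (-alpha)                 # protein-synthesis floor
    dt  = (c_delta / r(T)) * exp(ros / s_ros)    # ROS-removal delay

where ``r(T)`` is the protein-synthesis rate, modelled as an Arrhenius
function of temperature.  Cells whose ROS fluorescence exceeds
``ros_threshold`` never divide: they stay in G1, keep growing, and burst.
This caps the doubling time at ``tau_max(T) = t(T) + dt(ros_threshold, T)``
and floors it at ``tau_min(T) = t(T)`` — the temperature-specific low- and
high-speed limits of replicative life.

ROS varies among cells and is approximately log-normal, so the doubling
time of a cohort is a stochastic variable; :func:`simulate_cohort` samples
it and :func:`prob_slower_than` evaluates its exceedance in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CalibrationError, InsufficientDataError, InvalidInputError
from .units import GAS_CONSTANT, hours, kelvin

__all__ = [
    "ModelParams",
    "RosDistribution",
    "CohortResult",
    "SpeedLimits",
    "PowerLawFit",
    "CalibrationAnchors",
    "DEFAULT_ANCHORS",
    "arrhenius_rate",
    "min_doubling_time",
    "ros_delay",
    "doubling_time",
    "speed_limits",
    "simulate_cohort",
    "prob_slower_than",
    "fit_power_law",
    "calibrate",
    "default_params",
]


@dataclass(frozen=True)
class ModelParams:
    """Constants of the speed-limit model.

    Parameters
    ----------
    alpha : float
        Power-law exponent linking the minimum doubling time to the
        protein-synthesis rate, ``t = c_t * r**(-alpha)``.  Dimensionless,
        must lie in (0, 2).
    r_ref : float
        Protein-synthesis rate at the reference temperature, in arbitrary
        rate units per hour.
    T_ref : float
        Reference temperature in Kelvin.
    E_a : float
        Apparent activation energy of the protein-synthesis rate, J/mol.
    c_t : float
        Prefactor of the minimum doubling time, hours * (rate units)**alpha.
    c_delta : float
        Scale of the ROS-dependent delay, hours * rate units.
    s_ros : float
        ROS fluorescence scale mapping arbitrary units to the dimensionless
        argument of the delay exponential.
    ros_threshold : float
        ROS fluorescence above which a cell never divides (arb. units).
    """

    alpha: float = 0.77
    r_ref: float = 1.0
    T_ref: float = 278.15
    E_a: float = 4.6e5
    c_t: float = 72.0
    c_delta: float = 1.9
    s_ros: float = 1000.0
    ros_threshold: float = 6000.0

    def __post_init__(self) -> None:
        for name in ("r_ref", "T_ref", "E_a", "c_t", "c_delta", "s_ros", "ros_threshold"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise InvalidInputError(f"ModelParams.{name} must be strictly positive, got {value!r}")
        if not 0.0 < self.alpha < 2.0:
            raise InvalidInputError(f"ModelParams.alpha must lie in (0, 2), got {self.alpha!r}")


@dataclass(frozen=True)
class RosDistribution:
    """Log-normal distribution of ROS fluorescence across a population."""

    mu_log: float
    sigma_log: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.sigma_log < 0:
            raise InvalidInputError(f"sigma_log must be >= 0, got {self.sigma_log!r}")

    def divider_fraction(self, ros_threshold: float) -> float:
        """P(ROS < threshold) under the log-normal, i.e. the dividing fraction."""
        if ros_threshold <= 0:
            return 0.0
        if self.sigma_log == 0:
            return float(self.mu_log < math.log(ros_threshold))
        z = (math.log(ros_threshold) - self.mu_log) / self.sigma_log
        return float(stats.norm.cdf(z))


class SpeedLimits(NamedTuple):
    """Shortest and longest allowed doubling times at a temperature, hours."""

    tau_min: float
    tau_max: float


@dataclass(frozen=True)
class CohortResult:
    """Outcome of a simulated cohort of cells at one temperature.

    ``cells`` has one row per cell with columns ``ros`` (sampled
    fluorescence), ``divides`` (bool fate; False means the cell bursts)
    and ``tau_h`` (doubling time in hours, NaN for bursters).
    """

    cells: pd.DataFrame
    temperature_K: float
    seed: int
    params: ModelParams = field(repr=False)

    @property
    def divider_fraction(self) -> float:
        return float(self.cells["divides"].mean())

    @property
    def tau_mean(self) -> float:
        """Mean doubling time of dividers, hours (NaN if none divide)."""
        return float(self.cells.loc[self.cells["divides"], "tau_h"].mean())

    def tau_quantiles(self, q=(0.25, 0.5, 0.75)) -> pd.Series:
        return self.cells.loc[self.cells["divides"], "tau_h"].quantile(list(q))


class PowerLawFit(NamedTuple):
    """Result of a log-log power-law fit ``t = prefactor * r**(-exponent)``."""

    exponent: float
    prefactor: float
    correlation: float


def arrhenius_rate(T, params: ModelParams):
    """Protein-synthesis rate at temperature ``T`` (Kelvin).

    ``r(T) = r_ref * exp(-(E_a / R) * (1/T - 1/T_ref))``; strictly
    increasing in ``T``.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise InvalidInputError("temperature must be positive Kelvin")
    r = params.r_ref * np.exp(-(params.E_a / GAS_CONSTANT) * (1.0 / T - 1.0 / params.T_ref))
    return float(r) if np.isscalar(T) or T.ndim == 0 else r


def min_doubling_time(r, params: ModelParams):
    """ROS-independent floor of the doubling time, ``t = c_t * r**(-alpha)`` (hours)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise InvalidInputError("rate must be positive")
    t = params.c_t * r ** (-params.alpha)
    return float(t) if r.ndim == 0 else t


def ros_delay(ros, r, params: ModelParams):
    """ROS-dependent G1 delay, ``dt = (c_delta / r) * exp(ros / s_ros)`` (hours)."""
    ros = np.asarray(ros, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(ros < 0):
        raise InvalidInputError("ros fluorescence must be non-negative")
    if np.any(r <= 0):
        raise InvalidInputError("rate must be positive")
    dt = (params.c_delta / r) * np.exp(ros / params.s_ros)
    return float(dt) if ros.ndim == 0 and r.ndim == 0 else dt


def doubling_time(ros, T, params: ModelParams):
    """A cell's doubling time ``tau = t + dt`` at ROS level ``ros`` and temperature ``T`` (hours)."""
    r = arrhenius_rate(T, params)
    return min_doubling_time(r, params) + ros_delay(ros, r, params)


def speed_limits(T, params: ModelParams) -> SpeedLimits:
    """Shortest and longest allowed doubling times at temperature ``T`` (Kelvin).

    ``tau_min`` is the floor of a minimal-ROS cell; ``tau_max`` is the
    doubling time of a cell sitting exactly at the ROS threshold — any
    cell above it bursts instead of dividing.
    """
    r = arrhenius_rate(T, params)
    tau_min = min_doubling_time(r, params)
    tau_max = tau_min + ros_delay(params.ros_threshold, r, params)
    return SpeedLimits(tau_min=tau_min, tau_max=tau_max)


def simulate_cohort(
    n: int,
    T: float,
    ros_dist: RosDistribution,
    params: ModelParams,
    seed: int,
) -> CohortResult:
    """Sample a cohort of ``n`` cells at temperature ``T`` (Kelvin).

    Each cell draws a ROS level from ``ros_dist``; it divides iff its ROS
    is below ``params.ros_threshold``, in which case its doubling time is
    ``doubling_time(ros, T)``.  Above-threshold cells burst.  Deterministic
    for a fixed seed.
    """
    if n < 1:
        raise InvalidInputError(f"cohort size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    ros = rng.lognormal(mean=ros_dist.mu_log, sigma=ros_dist.sigma_log, size=n)
    divides = ros < params.ros_threshold
    tau = np.full(n, np.nan)
    if divides.any():
        tau[divides] = doubling_time(ros[divides], T, params)
    lim = speed_limits(T, params)
    finite = tau[divides]
    # hard invariant of the construction: every divider within the limits
    assert finite.size == 0 or (
        np.all(finite >= lim.tau_min * (1 - 1e-12)) and np.all(finite <= lim.tau_max * (1 + 1e-12))
    )
    cells = pd.DataFrame({"ros": ros, "divides": divides, "tau_h": tau})
    return CohortResult(cells=cells, temperature_K=float(T), seed=seed, params=params)


def prob_slower_than(tau0: float, T: float, ros_dist: RosDistribution, params: ModelParams) -> float:
    """P(cell divides AND its doubling time exceeds ``tau0`` hours), in closed form.

    Inverts the delay for the ROS level at which ``tau = tau0`` and
    integrates the log-normal ROS density between that level and the
    division threshold.
    """
    if tau0 < 0:
        raise InvalidInputError("tau0 must be non-negative")
    r = arrhenius_rate(T, params)
    t_floor = min_doubling_time(r, params)
    p_div = ros_dist.divider_fraction(params.ros_threshold)
    excess = tau0 - t_floor
    min_delay = params.c_delta / r  # delay at ros = 0
    if excess < min_delay:
        return p_div  # every divider is slower than tau0
    ros_star = params.s_ros * math.log(excess * r / params.c_delta)
    if ros_star >= params.ros_threshold:
        return 0.0
    if ros_dist.sigma_log == 0:
        mid = math.exp(ros_dist.mu_log)
        return float(ros_star < mid < params.ros_threshold)
    z_lo = (math.log(ros_star) - ros_dist.mu_log) / ros_dist.sigma_log if ros_star > 0 else -math.inf
    z_hi = (math.log(params.ros_threshold) - ros_dist.mu_log) / ros_dist.sigma_log
    return float(stats.norm.cdf(z_hi) - stats.norm.cdf(z_lo))


def fit_power_law(rates, times) -> PowerLawFit:
    """Least-squares power law ``t = prefactor * r**(-exponent)`` in log-log space.

    Returns the negated slope as the exponent and the magnitude of the
    Pearson correlation of the (ln r, ln t) points as the goodness of fit.
    """
    rates = np.asarray(rates, dtype=float)
    times = np.asarray(times, dtype=float)
    if rates.shape != times.shape:
        raise InvalidInputError("rates and times must have the same length")
    if rates.size < 3:
        raise InsufficientDataError(f"need >= 3 (rate, time) pairs, got {rates.size}")
    if np.any(rates <= 0) or np.any(times <= 0):
        raise InvalidInputError("rates and times must be strictly positive")
    res = stats.linregress(np.log(rates), np.log(times))
    return PowerLawFit(
        exponent=float(-res.slope),
        prefactor=float(math.exp(res.intercept)),
        correlation=float(abs(res.rvalue)),
    )


@dataclass(frozen=True)
class CalibrationAnchors:
    """Printed anchors that exactly identify the model constants.

    ``t_anchors`` maps temperature (Kelvin) to the minimum doubling time
    (hours) at exactly two temperatures; ``tau_max_anchor`` is the longest
    allowed doubling time (Kelvin, hours) at one temperature.  ``alpha``
    and ``s_ros`` are fixed, not re-fit.
    """

    t_anchors: Mapping[float, float]
    tau_max_anchor: tuple[float, float]
    ros_threshold: float = 6000.0
    alpha: float = 0.77
    s_ros: float = 1000.0


#: Default anchors: a minimal-ROS doubling floor of 3 days at 5 degC (ample
#: antioxidant), the 28.4-day replicative (S-G2-M) duration at 1 degC as the
#: 1 degC floor, the slowest observed 5 degC population doubling (35 days,
#: ROS-reduction-deficient knockout) as the 5 degC low-speed limit, and the
#: 6000 arb.-unit ROS division threshold.
DEFAULT_ANCHORS = CalibrationAnchors(
    t_anchors={kelvin(5.0): hours(3.0), kelvin(1.0): hours(28.4)},
    tau_max_anchor=(kelvin(5.0), hours(35.0)),
    ros_threshold=6000.0,
)


def calibrate(anchors: CalibrationAnchors = DEFAULT_ANCHORS) -> ModelParams:
    """Solve the model constants exactly from a set of anchors.

    Closed-form solve order: the rate ratio between the two ``t`` anchors
    follows from the power law, giving ``E_a``; the reference rate is set
    to 1 at the tau_max anchor temperature, giving ``c_t`` from one ``t``
    anchor; and ``c_delta`` follows from the delay part of the tau_max
    anchor with ``s_ros`` held fixed.
    """
    if len(anchors.t_anchors) != 2:
        raise CalibrationError(
            f"need minimum-doubling-time anchors at exactly 2 temperatures, got {len(anchors.t_anchors)}"
        )
    (T_a, t_a), (T_b, t_b) = sorted(anchors.t_anchors.items(), reverse=True)  # T_a warmer
    if T_a == T_b:
        raise CalibrationError("the two t anchors must be at distinct temperatures")
    for name, value in (("t anchors", min(t_a, t_b)), ("ros_threshold", anchors.ros_threshold)):
        if value <= 0:
            raise CalibrationError(f"{name} must be positive")
    T_m, tau_max_h = anchors.tau_max_anchor
    alpha = anchors.alpha

    # power law: t_a/t_b = (r_b/r_a)**alpha  =>  r_a/r_b = (t_b/t_a)**(1/alpha)
    log_rate_ratio = math.log(t_b / t_a) / alpha
    E_a = GAS_CONSTANT * log_rate_ratio / (1.0 / T_b - 1.0 / T_a)
    if E_a <= 0:
        raise CalibrationError("t anchors imply a non-positive activation energy (t must fall with T)")

    T_ref, r_ref = T_m, 1.0
    partial = ModelParams(
        alpha=alpha, r_ref=r_ref, T_ref=T_ref, E_a=E_a,
        c_t=1.0, c_delta=1.0, s_ros=anchors.s_ros, ros_threshold=anchors.ros_threshold,
    )
    r_at_a = arrhenius_rate(T_a, partial)
    c_t = t_a * r_at_a ** alpha

    r_at_m = arrhenius_rate(T_m, partial)
    t_at_m = c_t * r_at_m ** (-alpha)
    delay = tau_max_h - t_at_m
    if delay <= 0:
        raise CalibrationError(
            f"tau_max anchor ({tau_max_h} h) must exceed the minimum doubling time at that temperature ({t_at_m:.3g} h)"
        )
    c_delta = delay * r_at_m / math.exp(anchors.ros_threshold / anchors.s_ros)
    return ModelParams(
        alpha=alpha, r_ref=r_ref, T_ref=T_ref, E_a=E_a,
        c_t=c_t, c_delta=c_delta, s_ros=anchors.s_ros, ros_threshold=anchors.ros_threshold,
    )


def default_params() -> ModelParams:
    """Model constants calibrated from the default printed anchors."""
    return calibrate(DEFAULT_ANCHORS)
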
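"""Kinetics of gene expression: metabolic-labeling mRNA time courses,
reporter-induction traces, Arrhenius temperature dependence, and
copies-per-cell calibration.

Newly synthesized (4-thiouracil-labeled) mRNA per cell follows the
constitutive synthesis/degradation rate equation
``M(t) = (k_syn / k_deg) * (1 - exp(-k_deg * t))``; its fit yields the
genome-wide synthesis rate, the mean mRNA half-life ``ln2 / k_deg`` and
the steady-state plateau.  Reporter induction after galactose addition is
modelled as a delayed saturating exponential whose initial slope is the
protein-synthesis rate.  Rates across temperatures follow an Arrhenius
law fitted in (1/T, ln rate) space.  Sequencing-scale transcript
abundances (TPM) are converted to absolute copies per cell using
single-molecule FISH anchor genes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import InsufficientDataError, InvalidInputError
from .units import GAS_CONSTANT

__all__ = [
    "RateFit",
    "InductionFit",
    "ArrheniusFit",
    "fit_labeling_kinetics",
    "tpm_to_copies",
    "fit_induction",
    "fit_arrhenius",
    "characteristic_fraction",
]


@dataclass(frozen=True)
class RateFit:
    """Fitted mRNA synthesis/degradation kinetics.

    ``k_syn`` is in copies per hour per cell, ``k_deg`` per hour;
    ``degradation_identifiable`` is False when the time course shows no
    curvature, in which case ``k_syn`` is the initial slope and ``k_deg``
    only a lower-bound artefact.
    """

    k_syn: float
    k_deg: float
    correlation: float
    degradation_identifiable: bool = True

    @property
    def half_life(self) -> float:
        """Mean mRNA half-life, hours (= ln2 / k_deg exactly)."""
        return math.log(2.0) / self.k_deg

    @property
    def plateau(self) -> float:
        """Steady-state labeled copies per cell (= k_syn / k_deg)."""
        return self.k_syn / self.k_deg


@dataclass(frozen=True)
class InductionFit:
    """Delayed saturating-exponential fit of a reporter-induction trace.

    ``f(t) = A * (1 - exp(-k * (t - t0)))`` for ``t > t0``, else 0.
    The protein-synthesis rate is the initial slope ``A * k``.
    """

    A: float
    k: float
    t0: float
    correlation: float

    @property
    def rate(self) -> float:
        return self.A * self.k


@dataclass(frozen=True)
class ArrheniusFit:
    """Arrhenius fit ``ln r = ln A - E_a / (R T)`` of rates vs temperature."""

    E_a: float  # J/mol
    ln_prefactor: float
    correlation: float

    def rate_at(self, T_kelvin) -> np.ndarray | float:
        T = np.asarray(T_kelvin, dtype=float)
        r = np.exp(self.ln_prefactor - self.E_a / (GAS_CONSTANT * T))
        return float(r) if T.ndim == 0 else r


def _labeling_model(t, k_syn, k_deg):
    return (k_syn / k_deg) * (1.0 - np.exp(-k_deg * t))


def fit_labeling_kinetics(t_h, copies) -> RateFit:
    """Fit the synthesis/degradation rate equation to a labeling time course.

    ``t_h`` are hours since label addition; ``copies`` are labeled mRNA
    per cell (replicates may simply be pooled as repeated time points).
    Fitting minimizes residuals on the log1p scale, appropriate for
    multiplicative noise across orders of magnitude, with positive
    parameterization.  A course with no detectable curvature (saturation
    not reached) returns the initial-slope synthesis rate with the
    degradation rate flagged non-identifiable.
    """
    t = np.asarray(t_h, dtype=float)
    y = np.asarray(copies, dtype=float)
    if t.size != y.size:
        raise InvalidInputError("time and copy arrays must have the same length")
    if np.unique(t[t > 0]).size < 4:
        raise InsufficientDataError("need >= 4 positive time points")
    if np.any(y < 0):
        raise InvalidInputError("copy numbers must be non-negative")
    pos = t > 0
    t, y = t[pos], y[pos]

    # initial guesses: plateau from the latest points, k_deg from where the
    # curve reaches half of it, k_syn from the product
    plateau0 = max(float(np.mean(y[t >= np.percentile(t, 75)])), 1.0)
    half_t = float(np.interp(0.5 * plateau0, np.sort(y), t[np.argsort(y)]))
    k_deg0 = math.log(2.0) / max(half_t, float(t.min()) / 2.0)
    k_syn0 = max(plateau0 * k_deg0, 1e-9)

    def residuals(x):
        k_syn, k_deg = np.exp(x)
        return np.log1p(_labeling_model(t, k_syn, k_deg)) - np.log1p(y)

    sol = optimize.least_squares(residuals, x0=[math.log(k_syn0), math.log(k_deg0)])
    k_syn, k_deg = map(float, np.exp(sol.x))

    identifiable = k_deg * float(t.max()) >= 0.1
    if not identifiable:
        # no curvature: the plateau is unconstrained; report the initial slope
        slope = float(np.sum(t * y) / np.sum(t * t))
        k_syn = slope
        warnings.warn(
            "labeling time course spans < 0.1 degradation lifetimes; "
            "k_deg is not identifiable",
            stacklevel=2,
        )
    fitted = np.log1p(_labeling_model(t, k_syn, k_deg))
    obs = np.log1p(y)
    corr = 1.0 if np.std(obs) == 0 else float(np.corrcoef(fitted, obs)[0, 1])
    return RateFit(k_syn=k_syn, k_deg=k_deg, correlation=corr, degradation_identifiable=identifiable)


def tpm_to_copies(tpm: pd.Series, anchors: pd.DataFrame) -> tuple[pd.Series, float]:
    """Convert TPM expression values to absolute mRNA copies per cell.

    ``anchors`` must have columns ``gene``, ``tpm``, ``fish_copies_per_cell``
    for genes with single-molecule-FISH absolute counts.  The scale factor
    is the median over anchors of (FISH copies / TPM) — robust to a single
    discordant anchor — and is applied uniformly, so relative abundances
    are conserved.  Returns (copies series, scale factor).
    """
    required = {"gene", "tpm", "fish_copies_per_cell"}
    if not required.issubset(anchors.columns):
        raise InvalidInputError(f"anchor table needs columns {sorted(required)}")
    if anchors.empty:
        raise InvalidInputError("need at least one anchor gene")
    missing = [g for g in anchors["gene"] if g not in tpm.index]
    if missing:
        raise InvalidInputError(f"anchor genes missing from the TPM table: {missing}")
    ratios = anchors["fish_copies_per_cell"].to_numpy() / anchors["tpm"].to_numpy()
    if np.any(~np.isfinite(ratios)) or np.any(ratios <= 0):
        raise InvalidInputError("anchor TPM and FISH values must be positive")
    factor = float(np.median(ratios))
    return tpm * factor, factor


def _induction_model(t, A, k, t0):
    return np.where(t > t0, A * (1.0 - np.exp(-k * np.maximum(t - t0, 0.0))), 0.0)


def fit_induction(t_h, signal) -> InductionFit:
    """Fit the delayed saturating exponential to an induction trace.

    The onset delay ``t0`` absorbs transcription, translation and
    fluorophore-maturation lags before reporter signal appears.
    """
    t = np.asarray(t_h, dtype=float)
    y = np.asarray(signal, dtype=float)
    if t.size < 5:
        raise InsufficientDataError("need >= 5 induction time points")
    if np.any(y < -1e-9):
        raise InvalidInputError("signal must be baseline-subtracted (non-negative)")
    slope_all = stats.linregress(t, y).slope
    if slope_all <= 0 and y[-1] < y[0]:
        raise InvalidInputError("monotone-decreasing trace is not an induction curve")

    A0 = max(float(y.max()), 1e-9)
    scale = max(A0, 1.0)
    span = float(t.max() - t.min())

    best = None
    for t0_guess in np.linspace(t.min(), t.min() + 0.5 * span, 6):
        rising = t > t0_guess
        k0 = 1.0 / max(span / 4.0, 1e-6)
        if rising.sum() >= 3:
            mid = float(np.interp(0.5 * A0, y[rising], t[rising]))
            k0 = math.log(2.0) / max(mid - t0_guess, span / 50.0)

        def residuals(x):
            A, k = np.exp(x[:2])
            t0 = x[2]
            return (_induction_model(t, A, k, t0) - y) / scale

        sol = optimize.least_squares(
            residuals,
            x0=[math.log(A0), math.log(k0), t0_guess],
            bounds=([-np.inf, -np.inf, float(t.min()) - span], [np.inf, np.inf, float(t.max())]),
        )
        if best is None or sol.cost < best.cost:
            best = sol
    A, k = map(float, np.exp(best.x[:2]))
    t0 = float(best.x[2])
    fitted = _induction_model(t, A, k, t0)
    corr = 1.0 if np.std(y) == 0 else float(np.corrcoef(fitted, y)[0, 1])
    return InductionFit(A=A, k=k, t0=max(t0, 0.0), correlation=corr)


def fit_arrhenius(T_kelvin, rates) -> ArrheniusFit:
    """Fit ``ln rate`` against ``1/T`` and return the activation energy.

    ``E_a = -slope * R`` with R the gas constant; the correlation is the
    magnitude of the Pearson correlation of the linearized points.
    """
    T = np.asarray(T_kelvin, dtype=float)
    r = np.asarray(rates, dtype=float)
    if T.size < 3:
        raise InsufficientDataError("need >= 3 (temperature, rate) pairs")
    if np.unique(T).size < 2:
        raise InsufficientDataError("temperatures are all identical")
    if np.any(r <= 0) or np.any(T <= 0):
        raise InvalidInputError("temperatures and rates must be positive")
    res = stats.linregress(1.0 / T, np.log(r))
    return ArrheniusFit(
        E_a=float(-res.slope * GAS_CONSTANT),
        ln_prefactor=float(res.intercept),
        correlation=float(abs(res.rvalue)),
    )


def characteristic_fraction(rate: float, doubling_time_h: float, quantum: float) -> float:
    """Characteristic synthesis time as a fraction of the doubling time.

    The characteristic time is ``quantum / rate`` — the time to make a
    fixed amount of product (e.g. 10,000 mRNAs or 100 arb. units of
    reporter); dividing by the doubling time makes it comparable across
    temperatures.
    """
    if rate <= 0:
        raise InvalidInputError("rate must be positive (zero rate leaves the fraction undefined)")
    if doubling_time_h <= 0 or quantum <= 0:
        raise InvalidInputError("doubling time and quantum must be positive")
    return (quantum / rate) / doubling_time_h
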
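"""Cooperative enzyme kinetics: Hill fits, weighted linearization, quantification.

Guanylate cyclase activity versus Mg-GTP concentration follows a
sigmoidal saturation curve described by the Hill model

    v(S) = Vmax * S^h / (EC50^h + S^h)

with Vmax in pmol cGMP/(ug total protein * min), EC50 (the
half-saturating substrate concentration, equivalent to an apparent KM)
in mM, and the dimensionless Hill coefficient h expressing
cooperativity.  Because of the cooperativity, the classical
Lineweaver-Burk plot of 1/v against 1/S is curved; weighting the
abscissa with the Hill coefficient, 1/S^h, restores a straight line
with intercept 1/Vmax and slope EC50^h/Vmax, so the apparent KM read
off the line equals the EC50 of the nonlinear fit exactly when the
same h is used on noiseless data.

Catalytic parameters: kcat (s^-1) is the turnover number of the enzyme
monomer, derived from Vmax and the immunoblot-calibrated enzyme
content of the membrane preparation; kcat/KM (M^-1 s^-1) is the
catalytic efficiency, equivalent to the apparent association rate
constant of substrate and enzyme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from gce_dynamics.errors import ConditioningError, DegenerateDataError

__all__ = [
    "KineticsDataset",
    "HillFit",
    "LinearizationResult",
    "CatalyticParams",
    "CalibrationCurve",
    "QuantifiedAmount",
    "hill_activity",
    "fit_hill",
    "hill_linearization",
    "catalytic_efficiency",
    "kcat_from_vmax",
    "catalytic_params",
    "fit_calibration",
    "quantify_from_calibration",
]


def hill_activity(
    substrate: np.ndarray | float, vmax: float, ec50: float, h: float
) -> np.ndarray | float:
    """Hill model v = vmax * S^h / (ec50^h + S^h); v(0) = 0."""
    s = np.asarray(substrate, dtype=float)
    scalar = s.ndim == 0
    s = np.atleast_1d(s)
    sh = np.zeros_like(s)
    pos = s > 0
    sh[pos] = s[pos] ** h
    out = vmax * sh / (ec50**h + sh)
    return float(out[0]) if scalar else out


@dataclass
class KineticsDataset:
    """Substrate (mM) vs. cyclase activity (pmol/(ug*min)) for one condition."""

    substrate: np.ndarray
    activity: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.substrate, dtype=float)
        v = np.asarray(self.activity, dtype=float)
        if s.shape != v.shape or s.ndim != 1:
            raise ValueError("substrate and activity must be parallel 1-D arrays")
        if np.any(s < 0):
            raise ValueError("substrate concentrations must be >= 0")
        if len(np.unique(s)) != len(s):
            order = np.argsort(s, kind="stable")
        else:
            order = np.argsort(s)
        self.substrate = s[order]
        self.activity = v[order]

    def __len__(self) -> int:
        return len(self.substrate)


@dataclass
class HillFit:
    """Least-squares Hill-model parameters for one saturation curve."""

    vmax: float  # a, pmol/(ug*min)
    ec50: float  # c, mM
    h: float
    rss: float
    converged: bool

    def predict(self, substrate: np.ndarray | float) -> np.ndarray | float:
        return hill_activity(substrate, self.vmax, self.ec50, self.h)


@dataclass
class LinearizationResult:
    """OLS line of 1/v on 1/S^h and the saturation parameters it implies."""

    slope: float
    intercept: float
    r_squared: float
    h_used: float
    vmax_lb: float  # 1/intercept
    km_app: float  # (slope/intercept)^(1/h), mM


@dataclass
class CatalyticParams:
    kcat: float  # s^-1
    km: float  # mM
    efficiency: float  # M^-1 s^-1


@dataclass
class CalibrationCurve:
    """Immunoblot band intensity as a linear function of protein amount (ng)."""

    slope: float
    intercept: float
    r_squared: float
    valid_range: tuple[float, float]


@dataclass
class QuantifiedAmount:
    amount_ng: float
    extrapolated: bool


_DEFAULT_H_BOUNDS = (0.5, 5.0)


def fit_hill(
    data: KineticsDataset,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> HillFit:
    """Fit the Hill model to a saturation dataset by least squares.

    The fit is deterministic: a fixed multi-start over initial Hill
    coefficients h0 in {1, 2} (with a0 = max activity and c0 at the
    interpolated half-maximum) feeds bounded trust-region least
    squares, and the start with the lowest residual sum of squares
    wins.  Points at S = 0 participate with model value 0.
    """
    if len(data) < 5:
        raise ConditioningError(
            f"Hill fit needs >= 5 points, got {len(data)}"
        )
    s = data.substrate
    v = data.activity
    if np.allclose(v, 0):
        raise DegenerateDataError("all activities are zero; nothing to fit")

    a0 = float(v.max())
    c0 = _half_saturation_guess(s, v, a0)
    default_bounds = {
        "a": (1e-9, 10.0 * a0),
        "c": (1e-9, 2.0 * float(s.max())),
        "h": _DEFAULT_H_BOUNDS,
    }
    if bounds:
        default_bounds.update(bounds)
    lo = np.array([default_bounds[k][0] for k in ("a", "c", "h")])
    hi = np.array([default_bounds[k][1] for k in ("a", "c", "h")])

    def residuals(theta: np.ndarray) -> np.ndarray:
        return hill_activity(s, *theta) - v

    best: optimize.OptimizeResult | None = None
    for h0 in (1.0, 2.0):
        x0 = np.clip(np.array([a0, c0, h0]), lo, hi)
        result = optimize.least_squares(
            residuals, x0, bounds=(lo, hi), method="trf", xtol=1e-14, ftol=1e-14,
            gtol=1e-14,
        )
        if best is None or result.cost < best.cost:
            best = result
    assert best is not None
    rss = float(2.0 * best.cost)
    return HillFit(
        vmax=float(best.x[0]),
        ec50=float(best.x[1]),
        h=float(best.x[2]),
        rss=rss,
        converged=bool(best.success),
    )


def _half_saturation_guess(s: np.ndarray, v: np.ndarray, a0: float) -> float:
    target = a0 / 2.0
    order = np.argsort(s)
    guess = float(np.interp(target, v[order], s[order]))
    if not np.isfinite(guess) or guess <= 0:
        positive = s[s > 0]
        guess = float(np.median(positive)) if positive.size else 1.0
    return guess


def hill_linearization(data: KineticsDataset, h: float) -> LinearizationResult:
    """Hill-weighted Lineweaver-Burk: OLS of 1/v on 1/S^h.

    Points with S = 0 are excluded (1/S undefined); points with v <= 0
    at S > 0 are dropped with a warning.  On noiseless Hill data with
    matching h the identity holds exactly: intercept = 1/Vmax, slope =
    EC50^h/Vmax, km_app = EC50, r^2 = 1.
    """
    if h <= 0:
        raise ValueError("Hill coefficient must be positive")
    mask = data.substrate > 0
    s = data.substrate[mask]
    v = data.activity[mask]
    usable = v > 0
    if np.any(~usable):
        warnings.warn(
            f"{int((~usable).sum())} point(s) with non-positive activity at "
            "S > 0 excluded from linearization",
            stacklevel=2,
        )
    s, v = s[usable], v[usable]
    if len(s) < 3:
        raise ConditioningError(
            f"linearization needs >= 3 usable points, got {len(s)}"
        )
    x = 1.0 / np.power(s, h)
    y = 1.0 / v
    fit = stats.linregress(x, y)
    slope, intercept = float(fit.slope), float(fit.intercept)
    r_squared = float(fit.rvalue**2)
    vmax_lb = 1.0 / intercept if intercept != 0 else np.inf
    ratio = slope / intercept if intercept != 0 else np.nan
    km_app = float(ratio ** (1.0 / h)) if ratio > 0 else np.nan
    return LinearizationResult(
        slope=slope,
        intercept=intercept,
        r_squared=min(r_squared, 1.0),
        h_used=float(h),
        vmax_lb=float(vmax_lb),
        km_app=km_app,
    )


def catalytic_efficiency(kcat: float, km: float) -> float:
    """kcat/KM in M^-1 s^-1 from kcat (s^-1) and KM (mM)."""
    if km <= 0:
        raise ValueError("KM must be positive")
    if kcat < 0:
        raise ValueError("kcat must be non-negative")
    return kcat / (km * 1e-3)


def catalytic_params(kcat: float, km: float) -> CatalyticParams:
    return CatalyticParams(kcat=kcat, km=km, efficiency=catalytic_efficiency(kcat, km))


def kcat_from_vmax(
    vmax: float, gc_fraction: float, monomer_mass: float
) -> float:
    """Turnover number from specific activity and enzyme content.

    ``vmax`` is in pmol/(ug total protein * min), ``gc_fraction`` is ug
    of cyclase per ug of total membrane protein (from the immunoblot
    calibration), ``monomer_mass`` in g/mol.  The conversion is

        kcat = vmax * 1e-12 * monomer_mass / (gc_fraction * 1e-6 * 60)  [s^-1]

    i.e. product moles per minute per ug protein divided by enzyme
    moles per ug protein, converted to seconds.
    """
    if vmax < 0:
        raise ValueError("vmax must be non-negative")
    if gc_fraction <= 0 or monomer_mass <= 0:
        raise ValueError("gc_fraction and monomer_mass must be positive")
    return vmax * 1e-12 * monomer_mass / (gc_fraction * 1e-6 * 60.0)


def fit_calibration(
    amounts: Sequence[float], intensities: Sequence[float]
) -> CalibrationCurve:
    """OLS calibration of band intensity against protein amount (ng)."""
    a = np.asarray(amounts, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if a.shape != y.shape or a.ndim != 1:
        raise ValueError("amounts and intensities must be parallel 1-D sequences")
    if len(a) < 3:
        raise ConditioningError(f"calibration needs >= 3 standards, got {len(a)}")
    if np.allclose(a, a[0]):
        raise ConditioningError("calibration standards have identical amounts")
    fit = stats.linregress(a, y)
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        valid_range=(float(a.min()), float(a.max())),
    )


def quantify_from_calibration(
    intensity: float, curve: CalibrationCurve
) -> QuantifiedAmount:
    """Invert the calibration line; flag values outside the standard range."""
    if curve.slope == 0:
        raise ZeroDivisionError("calibration slope is zero; cannot invert")
    amount = (intensity - curve.intercept) / curve.slope
    lo, hi = curve.valid_range
    return QuantifiedAmount(amount_ng=float(amount), extrapolated=not lo <= amount <= hi)
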
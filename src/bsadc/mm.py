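"""Michaelis-Menten parameter estimation from initial-rate data.

Two routes are provided: the double-reciprocal (Lineweaver-Burk) line the
study used, and direct nonlinear least squares on v = Vmax*S/(Km+S).  On
noiseless data the two agree to machine precision; under noise the nonlinear
fit is the statistically better estimator and the reciprocal fit is kept for
fidelity to the original analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError, ValidationError
from .units import S_PER_MIN, UM_PER_MM

__all__ = [
    "RatePoint",
    "MMFit",
    "initial_rate",
    "fit_double_reciprocal",
    "fit_mm_nonlinear",
    "kcat_from_vmax",
    "activity_units",
]


@dataclass(frozen=True)
class RatePoint:
    """One initial-rate measurement: substrate mM, rate mM/min."""

    S: float
    v: float

    def __post_init__(self) -> None:
        if not self.S > 0:
            raise ValidationError(f"substrate must be > 0, got {self.S}")
        if self.v < 0:
            raise ValidationError(f"rate must be >= 0, got {self.v}")


@dataclass(frozen=True)
class MMFit:
    """Fitted Michaelis-Menten parameters.

    Km in mM, Vmax in mM/min; kcat (1/s) is present only when the enzyme
    molarity was supplied.  kcat/Km is always derived, never independently set.
    """

    Km: float
    Vmax: float
    method: str  # "double-reciprocal" | "nonlinear"
    se_Km: float = float("nan")
    se_Vmax: float = float("nan")
    kcat: float | None = None

    @property
    def kcat_over_Km(self) -> float | None:
        """Catalytic efficiency, 1/(s*mM)."""
        return None if self.kcat is None else self.kcat / self.Km

    def with_kcat(self, E0_uM: float) -> "MMFit":
        return MMFit(
            Km=self.Km,
            Vmax=self.Vmax,
            method=self.method,
            se_Km=self.se_Km,
            se_Vmax=self.se_Vmax,
            kcat=kcat_from_vmax(self.Vmax, E0_uM),
        )


def initial_rate(product_mM: float, duration_min: float) -> float:
    """Endpoint pseudo-initial rate: product formed / assay duration (mM/min)."""
    if duration_min <= 0:
        raise ValidationError(f"duration must be > 0, got {duration_min}")
    if product_mM < 0:
        raise ValidationError(f"product must be >= 0, got {product_mM}")
    return product_mM / duration_min


def _unpack(points: Sequence[RatePoint]) -> tuple[np.ndarray, np.ndarray]:
    if len(points) < 3:
        raise ValidationError(f"need >= 3 rate points, got {len(points)}")
    S = np.array([p.S for p in points], dtype=float)
    v = np.array([p.v for p in points], dtype=float)
    return S, v


def fit_double_reciprocal(points: Sequence[RatePoint]) -> MMFit:
    """Unweighted least-squares line of 1/v on 1/S; Km = slope/intercept,
    Vmax = 1/intercept."""
    S, v = _unpack(points)
    if np.any(v == 0):
        raise ValidationError(
            "zero rates have no reciprocal; use fit_mm_nonlinear for such data"
        )
    if len(np.unique(S)) < 2:
        raise FitError("all substrate concentrations identical: singular regression")
    x, y = 1.0 / S, 1.0 / v
    (slope, intercept), cov = np.polyfit(x, y, 1, cov=True)
    if intercept <= 0:
        raise FitError(
            f"non-positive reciprocal intercept ({intercept:g}): data are "
            "inconsistent with saturation kinetics"
        )
    Km = slope / intercept
    Vmax = 1.0 / intercept
    # delta-method standard errors from the linear-regression covariance
    var_s, var_i = cov[0, 0], cov[1, 1]
    cov_si = cov[0, 1]
    se_Vmax = math.sqrt(var_i) / intercept**2
    dKm_ds, dKm_di = 1.0 / intercept, -slope / intercept**2
    se_Km = math.sqrt(
        max(dKm_ds**2 * var_s + dKm_di**2 * var_i + 2 * dKm_ds * dKm_di * cov_si, 0.0)
    )
    return MMFit(Km=Km, Vmax=Vmax, method="double-reciprocal", se_Km=se_Km, se_Vmax=se_Vmax)


def _mm(S: np.ndarray, Vmax: float, Km: float) -> np.ndarray:
    return Vmax * S / (Km + S)


def fit_mm_nonlinear(points: Sequence[RatePoint]) -> MMFit:
    """Direct least squares on v = Vmax*S/(Km+S), initialized from the
    double-reciprocal estimate when that is available."""
    S, v = _unpack(points)
    if len(np.unique(S)) < 3:
        raise ValidationError("need >= 3 distinct substrate concentrations")
    try:
        init = fit_double_reciprocal(points)
        p0 = [init.Vmax, init.Km]
    except (ValidationError, FitError):
        p0 = [float(v.max()) * 1.2 or 1.0, float(np.median(S))]
    try:
        popt, pcov = curve_fit(
            _mm,
            S,
            v,
            p0=p0,
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            maxfev=10000,
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
    except RuntimeError as exc:
        raise FitError(
            f"nonlinear fit did not converge from p0=(Vmax={p0[0]:g}, Km={p0[1]:g})"
        ) from exc
    se = np.sqrt(np.diag(pcov))
    return MMFit(
        Km=float(popt[1]),
        Vmax=float(popt[0]),
        method="nonlinear",
        se_Km=float(se[1]),
        se_Vmax=float(se[0]),
    )


def kcat_from_vmax(Vmax_mM_per_min: float, E0_uM: float) -> float:
    """Turnover number kcat (1/s) from Vmax (mM/min) and enzyme molarity (uM):
    Vmax in mM/s divided by E0 in mM."""
    if E0_uM <= 0:
        raise ValidationError(f"E0 must be > 0, got {E0_uM}")
    if Vmax_mM_per_min < 0:
        raise ValidationError(f"Vmax must be >= 0, got {Vmax_mM_per_min}")
    return (Vmax_mM_per_min / S_PER_MIN) * (UM_PER_MM / E0_uM)


def activity_units(rate_umol_per_min: float, enzyme_mass_mg: float) -> float:
    """Specific activity in U/mg; 1 U = 1 umol product per minute."""
    if enzyme_mass_mg <= 0:
        raise ValidationError(f"enzyme mass must be > 0, got {enzyme_mass_mg}")
    if rate_umol_per_min < 0:
        raise ValidationError(f"rate must be >= 0, got {rate_umol_per_min}")
    return rate_umol_per_min / enzyme_mass_mg
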
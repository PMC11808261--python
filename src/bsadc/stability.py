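"""Catalytic-stability pipeline: progress curve -> polynomial fit ->
instantaneous activity -> residual activity -> first-order decay fit.

"Catalytic stability" here means resistance to turnover-coupled mechanism-based
inactivation, quantified from a single product-accumulation time course:

1. fit product(t) with a zero-intercept polynomial (no product at t=0);
2. differentiate analytically to get instantaneous activity (mM/min);
3. normalize to the t=0 activity (defined as 100 %) -> residual activity;
4. fit 100*exp(-lambda*t) to the residual series; half-life = ln2/lambda.

The decay constant is also reported per second for comparison with
inactivation rates quoted on that scale, and an empirical total turnover
number (moles of product at plateau per mole of enzyme) is computed directly
from the raw curve.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError, NoPlateauError, ValidationError
from .kinetics import ReactionConditions
from .units import mm_to_um, per_min_to_per_s

__all__ = [
    "ProgressCurve",
    "PolyFit",
    "InactivationFit",
    "StabilityProfile",
    "fit_progress_polynomial",
    "instantaneous_activity",
    "residual_activity",
    "fit_inactivation",
    "empirical_ttn",
    "analyze_stability",
]


@dataclass(frozen=True)
class ProgressCurve:
    """Timed product measurements for one reaction (minutes, mM)."""

    times_min: np.ndarray
    product_mM: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        p = np.asarray(self.product_mM, dtype=float)
        if t.ndim != 1 or p.shape != t.shape:
            raise ValidationError("times and product must be 1-D of equal length")
        if not np.all(np.diff(t) > 0):
            raise ValidationError("times must be strictly increasing")
        if t[0] < 0:
            raise ValidationError("times must be >= 0")
        if np.any(p < 0):
            raise ValidationError("product concentrations must be >= 0")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "product_mM", p)

    def __len__(self) -> int:
        return len(self.times_min)


@dataclass(frozen=True)
class PolyFit:
    """Zero-intercept polynomial P(t) = c1*t + c2*t^2 + ... fitted to a curve.

    coeffs are ascending powers starting at t^1; r_squared is NaN (and
    ``degenerate`` True) when the data carry no variance to explain.
    """

    coeffs: np.ndarray
    t_max_min: float
    r_squared: float
    degenerate: bool = False

    @property
    def degree(self) -> int:
        return len(self.coeffs)

    def value(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return sum(c * t ** (i + 1) for i, c in enumerate(self.coeffs))

    def derivative(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return sum((i + 1) * c * t**i for i, c in enumerate(self.coeffs))


@dataclass(frozen=True)
class InactivationFit:
    lambda_per_min: float
    half_life_min: float

    @property
    def lambda_per_s(self) -> float:
        return per_min_to_per_s(self.lambda_per_min)


@dataclass(frozen=True)
class StabilityProfile:
    """Full derived stability record for one progress curve."""

    poly: PolyFit
    eval_times_min: np.ndarray
    activity_mM_per_min: np.ndarray
    residual_pct: np.ndarray
    lambda_per_min: float
    half_life_min: float
    label: str = ""

    @property
    def kinact_per_s(self) -> float:
        """Fitted decay constant on the per-second scale."""
        return per_min_to_per_s(self.lambda_per_min)


def fit_progress_polynomial(curve: ProgressCurve, degree: int = 3) -> PolyFit:
    """Least-squares zero-intercept polynomial of ``product`` on ``time``.

    The intercept is pinned to 0 (no product before the reaction starts), so
    the design matrix holds powers t^1..t^degree only.
    """
    if degree < 2:
        raise ValidationError(f"degree must be >= 2, got {degree}")
    n = len(curve)
    if n <= degree:
        raise ValidationError(
            f"need more than {degree} points for a degree-{degree} fit, got {n}"
        )
    t = curve.times_min
    p = curve.product_mM
    if np.all(p == 0):
        return PolyFit(
            coeffs=np.zeros(degree),
            t_max_min=float(t[-1]),
            r_squared=float("nan"),
            degenerate=True,
        )
    X = np.column_stack([t ** (k + 1) for k in range(degree)])
    coeffs, _, _, _ = np.linalg.lstsq(X, p, rcond=None)
    fitted = X @ coeffs
    ss_res = float(np.sum((p - fitted) ** 2))
    ss_tot = float(np.sum((p - p.mean()) ** 2))
    r2 = float("nan") if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return PolyFit(coeffs=coeffs, t_max_min=float(t[-1]), r_squared=r2)


def instantaneous_activity(fit: PolyFit, t_min: float | np.ndarray) -> np.ndarray:
    """Analytic derivative of the fitted polynomial (mM/min) at time(s) t.

    Refuses extrapolation outside the fitted time range.
    """
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0) or np.any(t > fit.t_max_min):
        raise ValidationError(
            f"activity requested outside fitted range [0, {fit.t_max_min}] min"
        )
    return fit.derivative(t)


def residual_activity(fit: PolyFit, t_grid_min: Sequence[float]) -> np.ndarray:
    """Instantaneous activity as a percentage of the t=0 activity.

    Negative fitted derivatives (polynomial artifacts at late times) are
    clipped to 0 with a warning rather than failing.
    """
    a0 = float(fit.derivative(np.asarray(0.0)))
    if a0 <= 0:
        raise ValidationError(
            f"initial activity must be > 0 to normalize, got {a0:g} mM/min"
        )
    act = instantaneous_activity(fit, np.asarray(t_grid_min, dtype=float))
    if np.any(act < 0):
        warnings.warn(
            "negative fitted activity clipped to 0 (polynomial edge artifact)",
            stacklevel=2,
        )
    return np.clip(100.0 * act / a0, 0.0, None)


def _exp_decay(t: np.ndarray, lam: float) -> np.ndarray:
    return 100.0 * np.exp(-lam * t)


def fit_inactivation(
    times_min: Sequence[float],
    residual_pct: Sequence[float],
    trim_nonpositive: bool = False,
) -> InactivationFit:
    """Fit 100*exp(-lambda*t) to a residual-activity series.

    The series must start at (0, 100) by construction of residual_activity.
    Non-positive residuals beyond t=0 make the log-linear problem degenerate;
    by default they raise (suggesting the tail be trimmed), or are dropped
    when ``trim_nonpositive`` is set.
    """
    t = np.asarray(times_min, dtype=float)
    r = np.asarray(residual_pct, dtype=float)
    if t.shape != r.shape or t.ndim != 1:
        raise ValidationError("times and residuals must be 1-D of equal length")
    if len(t) < 3:
        raise ValidationError(f"need >= 3 residual points, got {len(t)}")
    if t[0] != 0:
        raise ValidationError("residual series must start at t = 0")
    bad = r[1:] <= 0
    if np.any(bad):
        if not trim_nonpositive:
            raise FitError(
                "non-positive residual activities make the decay fit degenerate; "
                "trim the late-time tail (trim_nonpositive=True)"
            )
        keep = np.concatenate([[True], ~bad])
        t, r = t[keep], r[keep]
        if len(t) < 3:
            raise FitError("fewer than 3 positive residual points after trimming")

    # log-linear slope as starting value; flat series -> lambda = 0
    with np.errstate(divide="ignore"):
        slope = np.polyfit(t, np.log(np.clip(r, 1e-12, None) / 100.0), 1)[0]
    lam0 = max(-slope, 0.0)
    if np.allclose(r, 100.0):
        return InactivationFit(0.0, math.inf)
    popt, _ = curve_fit(
        _exp_decay, t, r, p0=[max(lam0, 1e-6)], bounds=(0.0, np.inf), maxfev=10000
    )
    lam = float(popt[0])
    half = math.inf if lam == 0 else math.log(2.0) / lam
    return InactivationFit(lam, half)


def empirical_ttn(
    curve: ProgressCurve,
    cond: ReactionConditions,
    plateau_rel_tol: float = 0.02,
    force: bool = False,
) -> float:
    """Empirical total turnover number: product formed at plateau per enzyme.

    Dimensionless mol/mol; requires the curve to have flattened (relative
    change between the last two samples below ``plateau_rel_tol``) unless
    ``force`` is set.
    """
    p = curve.product_mM
    if p[-1] <= 0:
        raise ValidationError("curve has no product; TTN undefined")
    if len(p) < 2:
        raise ValidationError("need at least two points to judge a plateau")
    rel_change = abs(p[-1] - p[-2]) / p[-1]
    if rel_change >= plateau_rel_tol and not force:
        raise NoPlateauError(
            f"last two points differ by {rel_change:.1%} (>= {plateau_rel_tol:.0%}); "
            "extend the assay/simulation or pass force=True"
        )
    return mm_to_um(p[-1]) / cond.E0  # (mM -> uM product) / uM enzyme


def analyze_stability(
    curve: ProgressCurve,
    degree: int = 3,
    eval_times_min: Sequence[float] | None = None,
) -> StabilityProfile:
    """Run the full pipeline on one progress curve.

    ``eval_times_min`` defaults to the curve's own sample times; the decay fit
    automatically trims any clipped (zero) residuals in the tail.
    """
    fit = fit_progress_polynomial(curve, degree=degree)
    if fit.degenerate:
        raise ValidationError("flat zero curve: stability analysis undefined")
    grid = (
        curve.times_min
        if eval_times_min is None
        else np.asarray(eval_times_min, dtype=float)
    )
    if grid[0] != 0:
        grid = np.concatenate([[0.0], grid])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        act = fit.derivative(grid)
        resid = residual_activity(fit, grid)
    decay = fit_inactivation(grid, resid, trim_nonpositive=True)
    return StabilityProfile(
        poly=fit,
        eval_times_min=grid,
        activity_mM_per_min=act,
        residual_pct=resid,
        lambda_per_min=decay.lambda_per_min,
        half_life_min=decay.half_life_min,
        label=curve.label,
    )
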
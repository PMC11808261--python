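"""Tests for the progress-curve catalytic-stability pipeline."""

import math

import numpy as np
import pytest

from bsadc import (
    KineticParams,
    ReactionConditions,
    NoiseModel,
    ProgressCurve,
    analyze_stability,
    empirical_ttn,
    fit_inactivation,
    fit_progress_polynomial,
    gen_progress_curves,
    instantaneous_activity,
    residual_activity,
)
from bsadc.errors import FitError, NoPlateauError, ValidationError
from bsadc.kinetics import effective_decay_constant, final_product


def curve(t, p, label="test"):
    return ProgressCurve(times_min=np.asarray(t, float), product_mM=np.asarray(p, float), label=label)


class TestProgressCurve:
    def test_rejects_non_increasing_times(self):
        with pytest.raises(ValidationError):
            curve([0, 10, 10], [0, 1, 2])

    def test_rejects_negative_product(self):
        with pytest.raises(ValidationError):
            curve([0, 10, 20], [0, -1, 2])


class TestPolynomialFit:
    def test_exact_linear_data(self):
        c = curve([5, 10, 20, 30, 60], [10, 20, 40, 60, 120])
        fit = fit_progress_polynomial(c, degree=3)
        assert fit.coeffs == pytest.approx([2.0, 0.0, 0.0], abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        """Independent brute-force least squares on the saturating curve
        P(t) = 6.5*(1 - exp(-0.04 t)); cubic must beat the quadratic."""
        t = np.array([5.0, 10.0, 20.0, 30.0, 60.0])
        p = 6.5 * (1.0 - np.exp(-0.04 * t))

        def brute(degree):
            X = np.column_stack([t ** (k + 1) for k in range(degree)])
            coeffs = np.linalg.solve(X.T @ X, X.T @ p)
            return coeffs, float(np.sum((p - X @ coeffs) ** 2))

        c3, ss3 = brute(3)
        fit = fit_progress_polynomial(curve(t, p), degree=3)
        assert fit.coeffs == pytest.approx(c3, rel=1e-8)
        _, ss2 = brute(2)
        fit_resid = float(np.sum((p - fit.value(t)) ** 2))
        assert fit_resid == pytest.approx(ss3, abs=1e-12)
        assert ss3 < ss2

    def test_all_zero_product_flagged_degenerate(self):
        fit = fit_progress_polynomial(curve([0, 10, 20, 30], [0, 0, 0, 0]), degree=3)
        assert fit.degenerate
        assert math.isnan(fit.r_squared)
        assert np.all(fit.coeffs == 0)

    def test_underdetermined_fit_names_required_points(self):
        with pytest.raises(ValidationError, match="degree-3"):
            fit_progress_polynomial(curve([0, 10, 20], [0, 1, 2]), degree=3)
        with pytest.raises(ValidationError):
            fit_progress_polynomial(curve([0, 10, 20, 30], [0, 1, 2, 3]), degree=1)


class TestInstantaneousActivity:
    def test_linear_curve_has_constant_activity(self):
        fit = fit_progress_polynomial(curve([5, 10, 20, 30, 60], [10, 20, 40, 60, 120]), 3)
        for t in (0.0, 15.0, 60.0):
            assert instantaneous_activity(fit, t) == pytest.approx(2.0, abs=1e-9)

    def test_initial_activity_approximates_analytic_slope(self):
        """Derivative at 0 of the cubic fitted to A(1-exp(-bt)) approximates A*b."""
        t = np.array([5.0, 10.0, 20.0, 30.0, 60.0])
        A, b = 6.5, 0.04
        p = A * (1.0 - np.exp(-b * t))
        fit = fit_progress_polynomial(curve(t, p), degree=3)
        # polynomial-approximation error bound: compare against the analytic
        # derivative; agreement is to the fit's own sup-error scale, not exact
        sup_err = max(abs(fit.value(ti) - A * (1 - math.exp(-b * ti))) for ti in np.linspace(0, 60, 121))
        assert abs(instantaneous_activity(fit, 0.0) - A * b) <= 20 * sup_err + 0.05 * A * b

    def test_extrapolation_refused(self):
        fit = fit_progress_polynomial(curve([5, 10, 20, 30], [1, 2, 4, 6]), 2)
        with pytest.raises(ValidationError, match="outside"):
            instantaneous_activity(fit, 31.0)

    def test_zero_polynomial_has_zero_activity(self):
        fit = fit_progress_polynomial(curve([0, 10, 20, 30], [0, 0, 0, 0]), degree=3)
        assert instantaneous_activity(fit, 10.0) == 0.0


class TestResidualActivity:
    def test_linear_progress_stays_at_100(self):
        fit = fit_progress_polynomial(curve([5, 10, 20, 30, 60], [10, 20, 40, 60, 120]), 3)
        resid = residual_activity(fit, [0, 10, 30, 60])
        assert resid == pytest.approx([100.0] * 4, abs=1e-6)

    def test_tracks_true_exponential_decay(self, wt_like_decay, wt_cond, minute_grid):
        """Fitted residual series stays within 5 % of 100*exp(-lambda t) over
        two half-lives of a noiseless model curve."""
        lam = effective_decay_constant(wt_like_decay, wt_cond.S0) * 60.0
        c = gen_progress_curves(wt_like_decay, wt_cond, minute_grid, NoiseModel())[0]
        fit = fit_progress_polynomial(c, degree=3)
        resid = residual_activity(fit, minute_grid)
        truth = 100.0 * np.exp(-lam * minute_grid)
        assert np.all(np.abs(resid - truth) < 5.0)

    def test_negative_derivative_clipped_with_warning(self):
        # strongly concave data force a negative cubic derivative at the end
        t = np.array([2.0, 5.0, 10.0, 20.0, 30.0])
        p = np.array([2.0, 4.5, 6.3, 6.9, 7.0])
        fit = fit_progress_polynomial(curve(t, p), degree=3)
        with pytest.warns(UserWarning, match="clipped"):
            resid = residual_activity(fit, np.linspace(0, 30, 31))
        assert np.all(resid >= 0.0)

    def test_zero_initial_activity_is_an_error(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        p = t**2  # derivative 0 at t=0
        fit = fit_progress_polynomial(curve(t, p), degree=2)
        with pytest.raises(ValidationError, match="initial activity"):
            residual_activity(fit, t)

    def test_invariant_to_product_unit_rescaling(self):
        t = np.array([5.0, 10.0, 20.0, 30.0, 60.0])
        p = 6.5 * (1.0 - np.exp(-0.04 * t))
        grid = np.linspace(0, 60, 13)
        r1 = residual_activity(fit_progress_polynomial(curve(t, p), 3), grid)
        r2 = residual_activity(fit_progress_polynomial(curve(t, 1000 * p), 3), grid)
        assert r1 == pytest.approx(r2, rel=1e-9)


class TestInactivationFit:
    def test_recovers_exact_exponential(self):
        t = np.linspace(0.0, 60.0, 13)
        fit = fit_inactivation(t, 100.0 * np.exp(-0.0387 * t))
        assert fit.lambda_per_min == pytest.approx(0.0387, rel=1e-6)
        assert fit.half_life_min == pytest.approx(math.log(2) / 0.0387, rel=1e-6)  # 17.91
        assert fit.lambda_per_s == pytest.approx(0.0387 / 60.0, rel=1e-6)

    def test_constant_activity_means_no_decay(self):
        fit = fit_inactivation([0.0, 10.0, 20.0, 30.0], [100.0] * 4)
        assert fit.lambda_per_min == 0.0
        assert math.isinf(fit.half_life_min)

    def test_noisy_replicates_recover_lambda(self):
        """200 seeded replicates at sigma = 3 percentage points, lambda = 0.0115."""
        rng = np.random.default_rng(7)
        t = np.linspace(0.0, 60.0, 13)
        lam = 0.0115
        estimates = []
        for _ in range(200):
            r = 100.0 * np.exp(-lam * t) + rng.normal(0.0, 3.0, size=t.shape)
            r[0] = 100.0
            r = np.clip(r, 1e-6, None)
            estimates.append(fit_inactivation(t, r).lambda_per_min)
        assert abs(np.median(estimates) - lam) / lam < 0.05

    def test_nonpositive_residuals_raise_unless_trimmed(self):
        t = np.array([0.0, 10.0, 20.0, 30.0, 40.0])
        r = np.array([100.0, 60.0, 30.0, 0.0, 0.0])
        with pytest.raises(FitError, match="trim"):
            fit_inactivation(t, r)
        fit = fit_inactivation(t, r, trim_nonpositive=True)
        assert fit.lambda_per_min > 0

    def test_requires_start_at_zero(self):
        with pytest.raises(ValidationError):
            fit_inactivation([5.0, 10.0, 20.0], [100.0, 80.0, 60.0])


class TestEmpiricalTTN:
    def test_simulated_plateau_matches_partition_ratio(self, wt_params, wt_cond):
        """By model construction the empirical TTN equals kcat/kinact = 3863.6
        when the curve reaches its enzyme-limited plateau."""
        t_min = np.linspace(0.0, 120.0, 25)
        c = gen_progress_curves(wt_params, wt_cond, t_min, NoiseModel())[0]
        assert empirical_ttn(c, wt_cond) == pytest.approx(3863.6, rel=5e-3)

    def test_hand_computed_mole_ratio(self):
        """1.41 umol product over 1.7 nmol enzyme -> 829.4 turnovers
        (1.41 mM plateau in the 1 mL assay with 1.7 uM enzyme)."""
        cond = ReactionConditions(E0=1.7, S0=40.0)
        c = curve([0, 20, 40, 60], [0.0, 1.2, 1.40, 1.41])
        assert empirical_ttn(c, cond) == pytest.approx(829.4, rel=1e-3)

    def test_zero_product_is_an_error(self, wt_cond):
        with pytest.raises(ValidationError):
            empirical_ttn(curve([0, 10, 20], [0, 0, 0]), wt_cond)

    def test_unreached_plateau_raises_unless_forced(self, wt_cond):
        c = curve([0, 10, 20], [0.0, 2.0, 4.0])
        with pytest.raises(NoPlateauError):
            empirical_ttn(c, wt_cond)
        assert empirical_ttn(c, wt_cond, force=True) > 0


class TestPipelineRoundTrip:
    def test_noiseless_recovery_of_effective_decay_constant(
        self, wt_like_decay, wt_cond, minute_grid
    ):
        lam_true = effective_decay_constant(wt_like_decay, wt_cond.S0) * 60.0
        c = gen_progress_curves(wt_like_decay, wt_cond, minute_grid, NoiseModel())[0]
        prof = analyze_stability(c, degree=3)
        assert abs(prof.lambda_per_min - lam_true) / lam_true < 0.05
        assert prof.kinact_per_s == pytest.approx(prof.lambda_per_min / 60.0)

    def test_noisy_recovery_median_within_10pct(self, wt_like_decay, wt_cond, minute_grid):
        lam_true = effective_decay_constant(wt_like_decay, wt_cond.S0) * 60.0
        curves = gen_progress_curves(
            wt_like_decay, wt_cond, minute_grid, NoiseModel(sigma_rel=0.01, seed=11), 100
        )
        lams = [analyze_stability(c, degree=3).lambda_per_min for c in curves]
        assert abs(np.median(lams) - lam_true) / lam_true < 0.10

    @pytest.mark.parametrize("degree", [3, 4, 5])
    def test_half_life_ratio_preserved(self, degree, minute_grid):
        """Variants whose true half-lives differ 2-fold keep that ratio within
        3 % through the pipeline, independent of polynomial degree.  Low enzyme
        loading keeps substrate saturating so activity loss is inactivation only."""
        Km, S0 = 3.69, 40.0
        cond = ReactionConditions(E0=0.2, S0=S0)
        lam_fast = math.log(2) / 17.91 / 60.0 * (Km + S0) / S0
        fast = KineticParams(Km=Km, kcat=4.25, kinact=lam_fast)
        slow = KineticParams(Km=Km, kcat=8.29, kinact=lam_fast / 2.0)
        cf = gen_progress_curves(fast, cond, minute_grid, NoiseModel())[0]
        cs = gen_progress_curves(slow, cond, minute_grid, NoiseModel())[0]
        ratio = (
            analyze_stability(cs, degree=degree).half_life_min
            / analyze_stability(cf, degree=degree).half_life_min
        )
        assert abs(ratio - 2.0) / 2.0 < 0.03
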
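"""Inversion properties: recovery, oracle agreement, averaging, sensitivity."""

import numpy as np
import pytest
from scipy.optimize import minimize

from dcsflow import (
    AutocorrCurve,
    CurveMeta,
    FitOptions,
    FlowModel,
    NoiseModel,
    NoSignalWarning,
    average_repeats,
    fit_curve,
    g1_semi_infinite,
    g2_siegert,
    grid_oracle,
    mua_sensitivity,
    simulate_curve,
)
from dcsflow.errors import DegenerateInputError
from dcsflow.forward import LagGrid, semi_infinite_geometry


def _noiseless_curve(optics, lag_grid, bfi=1e-8, beta=0.5, sep_mm=5.0):
    g1 = g1_semi_infinite(lag_grid, optics, sep_mm / 10.0, FlowModel(bfi=bfi))
    meta = CurveMeta("m1", "autograft", 0, "P4", sep_mm)
    return AutocorrCurve(lag_grid, g2_siegert(g1, beta), meta)


class TestFitCurve:
    def test_inverse_crime_recovery(self, optics, lag_grid):
        """Refitting the generating model's own noiseless output is exact to <0.1%."""
        curve = _noiseless_curve(optics, lag_grid)
        est = fit_curve(curve, optics)
        assert est.converged
        assert est.bfi == pytest.approx(1e-8, rel=1e-3)
        assert est.beta == pytest.approx(0.5, rel=1e-3)

    def test_noisy_recovery_median_within_5_percent(self, optics, lag_grid):
        """Gaussian noise sigma=0.005 per lag: median |relative error| over 100 seeds.

        Monte-Carlo calibration of this setup observed a median of ~0.6%.
        """
        noise = NoiseModel(sigma0=0.005, profile="constant")
        errs = []
        for seed in range(100):
            curve = simulate_curve(1e-8, optics, 0.5, noise, seed=seed, lags=lag_grid)
            est = fit_curve(curve, optics)
            errs.append(abs(est.bfi - 1e-8) / 1e-8)
        med = float(np.median(errs))
        assert med < 0.05
        assert med == pytest.approx(0.0062, abs=0.004)  # frozen calibration

    def test_flat_curve_reports_no_signal(self, optics, lag_grid):
        meta = CurveMeta("m1", "autograft", 0, "P4", 5.0)
        curve = AutocorrCurve(lag_grid, np.ones(len(lag_grid)), meta)
        with pytest.warns(NoSignalWarning):
            est = fit_curve(curve, optics)
        assert not est.converged
        assert est.bfi == FitOptions().min_bfi

    def test_too_few_lags_rejected(self, optics):
        lags = LagGrid(np.geomspace(1e-6, 1e-5, 5))
        meta = CurveMeta("m1", "autograft", 0, "P4", 5.0)
        curve = AutocorrCurve(lags, np.full(5, 1.4), meta)
        with pytest.raises(DegenerateInputError):
            fit_curve(curve, optics)

    @pytest.mark.parametrize("scale", [0.1, 10.0])
    def test_scale_equivariance(self, optics, lag_grid, scale):
        """Scaling the true BFI by c scales the fitted BFI by c."""
        base = fit_curve(_noiseless_curve(optics, lag_grid, bfi=1e-8), optics)
        scaled = fit_curve(_noiseless_curve(optics, lag_grid, bfi=1e-8 * scale), optics)
        assert scaled.bfi / base.bfi == pytest.approx(scale, rel=1e-3)

    def test_idempotent_refit(self, optics, lag_grid):
        """Refitting the model curve reconstructed from a fit reproduces the fit."""
        noise = NoiseModel(sigma0=0.005, profile="constant")
        noisy = simulate_curve(2e-8, optics, 0.5, noise, seed=3, lags=lag_grid)
        est1 = fit_curve(noisy, optics)
        recon = _noiseless_curve(optics, lag_grid, bfi=est1.bfi, beta=est1.beta)
        est2 = fit_curve(recon, optics)
        assert est2.bfi == pytest.approx(est1.bfi, rel=1e-4)
        assert est2.beta == pytest.approx(est1.beta, rel=1e-4)

    def test_agrees_with_reference_simplex(self, optics, lag_grid):
        """The compiled simplex reproduces scipy's Nelder-Mead minimum."""
        from dcsflow._kernels import sse_objective

        rng = np.random.default_rng(5)
        opts = FitOptions()
        for _ in range(5):
            bfi = 10 ** rng.uniform(-8.5, -7.5)
            noise = NoiseModel(sigma0=0.003)
            curve = simulate_curve(bfi, optics, 0.5, noise,
                                   seed=int(rng.integers(2**31)), lags=lag_grid)
            mask = lag_grid.lags_s <= opts.max_lag_s
            tau, y = lag_grid.lags_s[mask], curve.g2[mask]
            a, b, r1, r2 = semi_infinite_geometry(optics, 0.5)
            beta0 = min(max(float(np.mean(y[:3]) - 1.0), 0.05), 1.0)
            ref = minimize(
                lambda p: sse_objective(p[0], p[1], tau, y, a, b, r1, r2),
                [np.log(opts.init_bfi), beta0],
                method="Nelder-Mead",
                options=dict(xatol=1e-10, fatol=1e-12, maxiter=5000),
            )
            est = fit_curve(curve, optics, opts)
            assert est.bfi == pytest.approx(np.exp(ref.x[0]), rel=1e-4)
            assert est.beta == pytest.approx(ref.x[1], rel=1e-4)


class TestGridOracle:
    def test_exact_truth_on_grid(self, optics, lag_grid):
        curve = _noiseless_curve(optics, lag_grid, bfi=1e-8, beta=0.5)
        est = grid_oracle(curve, optics, np.array([1e-9, 1e-8, 1e-7]),
                          np.array([0.3, 0.5, 0.7]))
        assert est.bfi == 1e-8 and est.beta == 0.5
        assert est.sse == pytest.approx(0.0, abs=1e-20)

    def test_single_point_grid(self, optics, lag_grid):
        curve = _noiseless_curve(optics, lag_grid)
        est = grid_oracle(curve, optics, np.array([3e-8]), np.array([0.4]))
        assert (est.bfi, est.beta) == (3e-8, 0.4) and est.sse > 0

    def test_empty_grid_rejected(self, optics, lag_grid):
        with pytest.raises(ValueError):
            grid_oracle(_noiseless_curve(optics, lag_grid), optics,
                        np.array([]), np.array([0.5]))

    def test_tie_breaks_toward_smaller_parameters(self, optics, lag_grid):
        curve = _noiseless_curve(optics, lag_grid)
        # duplicated grid values create exact ties
        est = grid_oracle(curve, optics, np.array([1e-8, 1e-8]), np.array([0.5, 0.5]))
        assert est.bfi == 1e-8 and est.beta == 0.5


class TestAverageRepeats:
    meta = CurveMeta("m1", "allograft", 3, "P4", 5.0)

    def _est(self, bfi, converged=True, sse=1e-6):
        from dcsflow import BFIEstimate

        return BFIEstimate(bfi=bfi, beta=0.5, sse=sse, converged=converged, n_lags_used=89)

    def test_plain_mean(self):
        rec = average_repeats([self._est(b) for b in (1e-8, 2e-8, 3e-8)], self.meta)
        assert rec.bfi == pytest.approx(2e-8)
        assert rec.n_used == 3 and rec.n_total == 3
        assert (rec.mouse, rec.week, rec.position) == ("m1", 3, "P4")

    def test_non_converged_excluded(self):
        ests = [self._est(2e-8)] * 25 + [self._est(9e-8, converged=False)] * 5
        rec = average_repeats(ests, self.meta)
        assert rec.bfi == pytest.approx(2e-8)
        assert rec.n_used == 25 and rec.n_total == 30

    def test_all_failed_returns_missing(self):
        assert average_repeats([self._est(1e-8, converged=False)], self.meta) is None

    def test_outlier_drop_optional(self):
        ests = [self._est(2e-8, sse=1e-6)] * 10 + [self._est(9e-8, sse=1e-3)]
        assert average_repeats(ests, self.meta).bfi > 2e-8
        assert average_repeats(ests, self.meta, drop_outliers=True).bfi == pytest.approx(2e-8)


class TestMuaSensitivity:
    def test_zero_bias_zero_error(self, optics):
        err = mua_sensitivity(FlowModel(1e-8, 0.5), optics, 0.5, 0.0)
        assert err == pytest.approx(0.0, abs=1e-4)

    def test_negative_bias_underestimates_bfi(self, optics):
        err = mua_sensitivity(FlowModel(1e-8, 0.5), optics, 0.5, -0.10)
        assert err < -0.5  # clearly negative, a few percent

    def test_bias_symmetry_within_one_point(self, optics):
        lo = mua_sensitivity(FlowModel(1e-8, 0.5), optics, 0.5, -0.10)
        hi = mua_sensitivity(FlowModel(1e-8, 0.5), optics, 0.5, +0.10)
        assert hi > 0
        assert abs(abs(lo) - abs(hi)) < 1.0

    def test_bias_bounds_enforced(self, optics):
        with pytest.raises(ValueError):
            mua_sensitivity(FlowModel(1e-8, 0.5), optics, 0.5, -1.0)
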
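"""NLS/WNLS Hill fits, neighbor weights, F-test, outlier detection."""

import numpy as np
import pytest
from scipy import optimize, stats

from qhtscall import (
    HillParams,
    Profile,
    Weights,
    concentration_grid,
    detect_outliers,
    fit_constant,
    fit_hill_nls,
    fit_hill_wnls,
    hill_response,
    neighbor_weights,
    overall_f_test,
)


def _profile(R, grid):
    return Profile("x", grid, np.asarray(R, float))


class TestNeighborWeights:
    def test_flat_profile_gives_equal_weights(self, grid14):
        w = neighbor_weights(_profile(np.full(14, 7.0), grid14))
        assert np.allclose(w.w, 1.0)

    def test_isolated_spike_gets_smallest_weight(self):
        grid = concentration_grid(4)
        w = neighbor_weights(_profile([0, 0, 0, 100], grid)).w
        assert w[3] == min(w)
        assert w[3] < w[0]
        # hand-computed disagreements d = (0, 0, 50, 100)
        raw = 1.0 / (1.0 + np.array([0.0, 0.0, 50.0, 100.0]))
        assert np.allclose(w, 4 * raw / raw.sum())

    def test_normalization(self, grid14, make_profile):
        w = neighbor_weights(make_profile(sigma=25, seed=3)).w
        assert abs(w.sum() - 14) < 1e-12

    def test_needs_two_points(self):
        p = Profile("x", np.array([1.0, 2.0]), np.zeros(2), np.array([True, False]))
        with pytest.raises(ValueError):
            neighbor_weights(p)

    def test_weights_skip_masked_points(self, grid14):
        R = np.zeros(14)
        R[7] = 100.0
        mask = np.ones(14, bool)
        mask[7] = False
        w = neighbor_weights(Profile("x", grid14, R, mask))
        assert np.allclose(w.w, 1.0)  # remaining points all agree


class TestHillFits:
    @pytest.mark.parametrize("ac50,rmax,slope", [(0.1, 100, 1), (1e-3, 50, 2), (10, -100, 0.5)])
    def test_noiseless_recovery(self, grid14, ac50, rmax, slope):
        truth = HillParams(0, rmax, ac50, slope)
        prof = _profile(hill_response(truth, grid14), grid14)
        fit = fit_hill_nls(prof)
        assert fit.sse < 1e-6
        got = fit.params
        assert got.rmax == pytest.approx(rmax, rel=1e-3)
        assert got.ac50 == pytest.approx(ac50, rel=1e-3)
        assert got.slope == pytest.approx(slope, rel=1e-3)

    def test_equal_weights_reduce_wnls_to_nls(self, make_profile):
        prof = make_profile(rmax=80, ac50=0.05, sigma=25, seed=5)
        a = fit_hill_nls(prof)
        b = fit_hill_wnls(prof, Weights.equal(14))
        assert np.allclose(a.params.as_array(), b.params.as_array(), atol=1e-6)
        assert a.sse == pytest.approx(b.sse, abs=1e-9)

    def test_weighted_fit_ignores_downweighted_spike(self, grid14):
        # noisy spike-driven profile; weights concentrated on the flat
        # subset make the weighted fit ignore the spike entirely
        rng = np.random.default_rng(21)
        R = rng.normal(0, 5, 14)
        R[-1] = 120.0
        prof = _profile(R, grid14)
        nls = fit_hill_nls(prof)
        raw = np.r_[np.ones(13), 1e-6]
        wnls = fit_hill_wnls(prof, Weights(14 * raw / raw.sum()))
        span_nls = abs(nls.params.rmax - nls.params.r0)
        span_wnls = abs(wnls.params.rmax - wnls.params.r0)
        assert span_nls > 100.0
        assert span_wnls < span_nls

    def test_noiseless_recovery_is_weight_invariant(self, grid14):
        truth = HillParams(0, 100, 0.1, 1)
        prof = _profile(hill_response(truth, grid14), grid14)
        rng = np.random.default_rng(0)
        raw = rng.uniform(0.2, 3.0, 14)
        fit = fit_hill_wnls(prof, Weights(14 * raw / raw.sum()))
        assert fit.sse < 1e-6
        assert fit.params.ac50 == pytest.approx(0.1, rel=1e-3)

    def test_nesting_of_sse(self, make_profile):
        for seed in range(5):
            prof = make_profile(rmax=40, sigma=25, seed=seed)
            hill = fit_hill_nls(prof)
            flat = fit_constant(prof)
            assert hill.sse <= flat.sse + 1e-8

    def test_direction_symmetry(self, make_profile, grid14):
        prof = make_profile(rmax=60, ac50=0.2, sigma=25, seed=9)
        neg = Profile("x", grid14, -prof.responses)
        a, b = fit_hill_nls(prof), fit_hill_nls(neg)
        assert a.sse == pytest.approx(b.sse, rel=1e-9)
        assert a.params.r0 == pytest.approx(-b.params.r0, abs=1e-6)
        assert a.params.rmax == pytest.approx(-b.params.rmax, abs=1e-6)

    def test_matches_independent_optimizer(self, make_profile):
        """Dense grid + simplex refinement as an independent minimizer."""
        prof = make_profile(rmax=70, ac50=0.03, sigma=25, seed=11)
        C, R = prof.used()
        logC = np.log10(C)

        def sse(x):
            r0, rmax, la, s = x
            f = 1.0 / (1.0 + 10 ** (np.clip(s * (la - logC), -300, 300)))
            return float(np.sum((R - r0 - (rmax - r0) * f) ** 2))

        best = None
        for la in np.linspace(-5, 3, 33):
            for s in (0.25, 0.5, 1, 2, 4, 8):
                for r0 in np.linspace(R.min(), R.max(), 7):
                    for rmax in np.linspace(R.min(), R.max(), 7):
                        v = sse((r0, rmax, la, s))
                        if best is None or v < best[0]:
                            best = (v, (r0, rmax, la, s))
        res = optimize.minimize(
            sse, best[1], method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
        )
        ours = fit_hill_nls(prof).sse
        assert ours == pytest.approx(res.fun, rel=1e-3)

    def test_parameter_recovery_under_noise(self, grid14):
        """Median |log10 AC50 error| < 0.2 at sigma = 10%, |RMAX| = 100."""
        truth = HillParams(0, 100, 0.1, 1)
        mu = hill_response(truth, grid14)
        rng = np.random.default_rng(2024)
        errs = []
        for _ in range(200):
            prof = _profile(mu + rng.normal(0, 10, 14), grid14)
            fit = fit_hill_nls(prof)
            errs.append(abs(np.log10(fit.params.ac50) - np.log10(0.1)))
        assert np.median(errs) < 0.2


class TestConstantFit:
    def test_unweighted_mean_and_sse(self, grid14):
        prof = _profile(np.r_[10.0, 20.0, 30.0], concentration_grid(3))
        fit = fit_constant(prof)
        assert fit.params == pytest.approx(20.0)
        assert fit.sse == pytest.approx(200.0)

    def test_equal_weights_identical_to_unweighted(self, grid14):
        prof = _profile(np.r_[10.0, 20.0, 30.0], concentration_grid(3))
        fit = fit_constant(prof, Weights.equal(3))
        assert fit.params == pytest.approx(20.0)
        assert fit.sse == pytest.approx(200.0)

    def test_hand_computed_weighted_mean(self):
        # w = (2, 1, 0), renormalized to sum 3; level = (2*10 + 1*20)/3
        prof = _profile(np.r_[10.0, 20.0, 30.0], concentration_grid(3))
        w = Weights(np.array([2.0, 1.0, 0.0]))
        fit = fit_constant(prof, w)
        level = (2 * 10 + 1 * 20) / 3.0
        assert fit.params == pytest.approx(level)
        assert fit.sse == pytest.approx(2 * (10 - level) ** 2 + (20 - level) ** 2)


class TestOverallFTest:
    def _pair(self, grid, R, n=None):
        prof = _profile(R, grid)
        return fit_hill_nls(prof), fit_constant(prof)

    def test_closed_form_value(self):
        # printed toy: sse_null = 1000, sse_full = 100, n = 14
        # F = ((1000 - 100)/3) / (100/10) = 30
        from qhtscall.fitting import FitResult

        full = FitResult("hill", False, HillParams(0, 1, 1, 1), 100.0, 14, 4, True)
        null = FitResult("constant", False, 0.0, 1000.0, 14, 1, True)
        ft = overall_f_test(full, null)
        assert ft.F == pytest.approx(30.0)
        assert ft.df1 == 3 and ft.df2 == 10
        assert ft.p == pytest.approx(stats.f.sf(30.0, 3, 10))

    def test_no_improvement_clamps_to_zero(self):
        from qhtscall.fitting import FitResult

        full = FitResult("hill", False, HillParams(0, 1, 1, 1), 500.0, 14, 4, True)
        null = FitResult("constant", False, 0.0, 500.0, 14, 1, True)
        ft = overall_f_test(full, null)
        assert ft.F == 0.0 and ft.p == 1.0

    def test_undefined_at_four_points(self):
        from qhtscall.fitting import FitResult

        full = FitResult("hill", False, HillParams(0, 1, 1, 1), 1.0, 4, 4, True)
        null = FitResult("constant", False, 0.0, 50.0, 4, 1, True)
        ft = overall_f_test(full, null)
        assert not ft.defined
        assert not ft.rejects(0.05)

    def test_mismatched_fits_error(self):
        from qhtscall.fitting import FitResult

        full = FitResult("hill", True, HillParams(0, 1, 1, 1), 1.0, 14, 4, True)
        null = FitResult("constant", False, 0.0, 5.0, 14, 1, True)
        with pytest.raises(ValueError):
            overall_f_test(full, null)


class TestOutlierDetection:
    def test_clean_curve_untouched(self, grid14):
        prof = _profile(hill_response(HillParams(0, 100, 0.1, 1), grid14), grid14)
        assert detect_outliers(prof).all()

    def test_gross_spike_flagged(self, grid14):
        R = hill_response(HillParams(0, 100, 0.1, 1), grid14).copy()
        R[7] = 500.0
        mask = detect_outliers(_profile(R, grid14))
        assert not mask[7]
        assert mask.sum() == 13

    def test_small_profiles_untouched(self):
        grid = concentration_grid(5)
        R = np.array([0.0, 0.0, 500.0, 0.0, 0.0])
        assert detect_outliers(_profile(R, grid)).all()

    def test_gaussian_noise_rarely_flagged(self, grid14):
        rng = np.random.default_rng(7)
        removed = 0
        for _ in range(50):
            prof = _profile(rng.normal(0, 25, 14), grid14)
            removed += 14 - detect_outliers(prof).sum()
        assert removed / (50 * 14) < 0.02
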
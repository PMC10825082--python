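import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bjtvd.denoise import (DenoiseResult, MovingAverageSmoother, TVDConfig,
                           TotalVariationDenoiser, lambda_sweep,
                           moving_average, tv_objective, tvd_admm, tvd_exact)
from bjtvd.simulate import generate_trace


def tv(x):
    return float(np.sum(np.abs(np.diff(x))))


class TestObjective:
    @pytest.mark.parametrize("raw,rec,lam,expected", [
        ([0.0, 1.0], [0.0, 1.0], 1.0, 1.0),
        ([0.0, 1.0], [0.3, 0.7], 0.3, 0.21),
        ([5.0, 5.0, 5.0], [5.0, 5.0, 5.0], 7.0, 0.0),
    ])
    def test_hand_computed_values(self, raw, rec, lam, expected):
        assert tv_objective(raw, rec, lam) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tv_objective([0, 1], [0, 1, 2], 1.0)


class TestExactSolver:
    @pytest.mark.parametrize("raw,lam,expected", [
        ([0.0, 1.0], 0.3, [0.3, 0.7]),      # endpoints move lam together
        ([0.0, 1.0], 0.6, [0.5, 0.5]),      # lam >= half-gap: collapse to mean
        ([2.0, 2.0, 2.0], 5.0, [2.0, 2.0, 2.0]),
    ])
    def test_closed_forms(self, raw, lam, expected):
        np.testing.assert_allclose(tvd_exact(raw, lam), expected, atol=1e-12)

    def test_large_lambda_collapses_to_mean(self, rng):
        y = rng.normal(size=80)
        x = tvd_exact(y, 1e6)
        np.testing.assert_allclose(x, np.full_like(y, y.mean()), atol=1e-9)

    def test_kkt_certificate_on_random_signals(self, rng):
        """The dual variables u_k = cumsum(y - x) of the minimizer must stay
        inside [-lam, lam], vanish at the end, and sit on the boundary at
        every jump of x: stationarity gives u_k = -lam * sign(x_{k+1}-x_k)."""
        for lam in (0.1, 1.0, 5.0):
            for _ in range(20):
                y = rng.normal(size=int(rng.integers(2, 200))) * 2
                x = tvd_exact(y, lam)
                u = np.cumsum(y - x)
                assert abs(u[-1]) < 1e-9
                assert np.all(np.abs(u[:-1]) <= lam + 1e-9)
                jumps = np.diff(x)
                for k, j in enumerate(jumps):
                    if j > 1e-9:
                        assert u[k] == pytest.approx(-lam, abs=1e-9)
                    elif j < -1e-9:
                        assert u[k] == pytest.approx(lam, abs=1e-9)

    def test_agrees_with_dual_box_least_squares(self, rng):
        """Independent route: x = y - D^T u* with u* the box-constrained
        least-squares solution of min ||D^T u - y|| s.t. |u| <= lam."""
        from scipy.optimize import lsq_linear
        for n, lam in ((12, 0.5), (40, 1.0), (25, 0.2)):
            y = rng.normal(size=n) * 2
            dt = np.zeros((n, n - 1))
            idx = np.arange(n - 1)
            dt[idx, idx] = -1.0
            dt[idx + 1, idx] = 1.0
            res = lsq_linear(dt, y, bounds=(-lam, lam), method="bvls",
                             tol=1e-14)
            x_dual = y - dt @ res.x
            np.testing.assert_allclose(tvd_exact(y, lam), x_dual, atol=1e-8)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            tvd_exact([0.0, np.nan], 1.0)


class TestADMM:
    def test_lambda_zero_returns_raw(self, rng):
        y = rng.normal(size=50)
        res = tvd_admm(y, TVDConfig(lam=0.0))
        np.testing.assert_array_equal(res.reconstructed, y)

    def test_two_point_closed_form(self):
        res = tvd_admm([0.0, 1.0], TVDConfig(lam=0.3))
        np.testing.assert_allclose(res.reconstructed, [0.3, 0.7], atol=1e-5)

    def test_matches_exact_oracle_on_random_signals(self, rng):
        """Optimality: at default settings ADMM agrees with the direct exact
        solver within 1e-5 max-norm; run to a tight tolerance its objective
        exceeds the exact optimum by at most 1e-6."""
        tight = dict(max_iter=20000, tol=1e-9)
        for _ in range(100):
            n = int(rng.integers(50, 501))
            y = rng.normal(size=n) * 2
            lam = float(rng.choice([0.1, 1.0, 5.0]))
            res = tvd_admm(y, TVDConfig(lam=lam))
            exact = tvd_exact(y, lam)
            assert np.max(np.abs(res.reconstructed - exact)) < 1e-5
            res_tight = tvd_admm(y, TVDConfig(lam=lam, **tight))
            assert (tv_objective(y, res_tight.reconstructed, lam)
                    <= tv_objective(y, exact, lam) + 1e-6)

    def test_objective_history_decreases(self, class1_trace):
        res = tvd_admm(class1_trace.log_g, TVDConfig(lam=1.0))
        hist = res.objective_history
        assert res.converged
        assert len(hist) == res.n_iter
        assert hist[-1] <= hist[0]
        assert hist[-1] < hist[0]  # noisy trace: TV loss must actually drop

    def test_offset_equivariance(self, rng):
        y = rng.normal(size=120)
        base = tvd_admm(y, TVDConfig(lam=1.0)).reconstructed
        shifted = tvd_admm(y + 5.0, TVDConfig(lam=1.0)).reconstructed
        np.testing.assert_allclose(shifted, base + 5.0, atol=1e-5)

    def test_tv_contraction(self, rng):
        y = rng.normal(size=200)
        for lam in (0.1, 1.0, 5.0, 50.0):
            rec = tvd_admm(y, TVDConfig(lam=lam)).reconstructed
            assert tv(rec) <= tv(y) + 1e-9

    def test_max_iter_reached_flags_not_converged(self, rng):
        y = rng.normal(size=100)
        res = tvd_admm(y, TVDConfig(lam=1.0, max_iter=3))
        assert not res.converged and res.n_iter == 3

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            tvd_admm([np.inf, 0.0], TVDConfig())


class TestMovingAverage:
    def test_window_one_is_identity(self, rng):
        y = rng.normal(size=30)
        np.testing.assert_array_equal(moving_average(y, 1), y)

    def test_constant_series_unchanged(self):
        y = np.full(20, 3.3)
        np.testing.assert_allclose(moving_average(y, 7), y)

    def test_edge_truncation(self):
        np.testing.assert_allclose(moving_average([0.0, 1.0, 2.0], 3),
                                   [0.5, 1.0, 1.5])

    @pytest.mark.parametrize("window", [0, 2, -3])
    def test_invalid_window_rejected(self, window):
        with pytest.raises(ValueError):
            moving_average(np.zeros(5), window)


class TestLambdaSweep:
    def test_tv_non_increasing_in_lambda(self, class1_trace):
        results = lambda_sweep(class1_trace.log_g, [0.1, 1.0, 5.0, 20.0])
        tvs = [tv(r.reconstructed) for r in results]
        assert all(a >= b - 1e-9 for a, b in zip(tvs, tvs[1:]))

    def test_lambda_zero_returns_raw(self, class1_trace):
        (res,) = lambda_sweep(class1_trace.log_g, [0.0])
        np.testing.assert_array_equal(res.reconstructed, class1_trace.log_g)

    def test_molecular_region_stable_for_moderate_lambda(self, class1_trace):
        """The recovered molecular conductance is insensitive to lambda in
        0.5-3: the mean reconstructed level over each molecular plateau
        agrees pairwise within 0.05 (pointwise values differ at staircase
        edges, but the conductance they report does not)."""
        results = lambda_sweep(class1_trace.log_g, [0.5, 1.0, 3.0])
        for state in ("plateau_1", "plateau_2"):
            mol = class1_trace.truth_state == state
            means = [r.reconstructed[mol].mean() for r in results]
            assert max(means) - min(means) < 0.05

    def test_empty_lambda_list_rejected(self, class1_trace):
        with pytest.raises(ValueError):
            lambda_sweep(class1_trace.log_g, [])


class TestEstimators:
    def test_transformer_roundtrip_2d(self, rng):
        X = rng.normal(size=(3, 60))
        est = TotalVariationDenoiser(lam=1.0).fit(X)
        out = est.transform(X)
        assert out.shape == X.shape
        for row_in, row_out in zip(X, out):
            np.testing.assert_allclose(
                row_out, tvd_exact(row_in, 1.0), atol=1e-5)

    def test_transformer_list_of_varying_lengths(self, rng):
        X = [rng.normal(size=30), rng.normal(size=55)]
        out = TotalVariationDenoiser(lam=0.5).fit().transform(X)
        assert [len(o) for o in out] == [30, 55]

    def test_denoise_returns_result_object(self, rng):
        res = TotalVariationDenoiser().denoise(rng.normal(size=40))
        assert isinstance(res, DenoiseResult)

    def test_get_params_roundtrip(self):
        est = TotalVariationDenoiser(lam=2.0, rho=0.5)
        params = est.get_params()
        assert params["lam"] == 2.0 and params["rho"] == 0.5
        est2 = TotalVariationDenoiser(**params)
        assert est2.get_params() == params

    def test_moving_average_smoother(self, rng):
        X = rng.normal(size=(2, 31))
        out = MovingAverageSmoother(window=5).fit(X).transform(X)
        np.testing.assert_allclose(out[0], moving_average(X[0], 5))

    def test_smoother_blurs_steps_more_than_tvd(self, class1_trace):
        """The moving average smears the high->low step while TVD keeps it
        sharp: max consecutive jump in the molecular region is larger for
        TVD than for the smoother."""
        tvd = TotalVariationDenoiser(lam=1.0).denoise(
            class1_trace.log_g).reconstructed
        ma = moving_average(class1_trace.log_g, 11)
        mol = np.isin(class1_trace.truth_state, ["plateau_1", "plateau_2"])
        assert np.max(np.abs(np.diff(tvd[mol]))) > np.max(
            np.abs(np.diff(ma[mol])))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.lists(st.floats(-10, 10), min_size=2, max_size=60),
       st.sampled_from([0.05, 0.5, 2.0]))
def test_exact_solver_objective_never_beaten_by_perturbations(raw, lam):
    """Property: the direct solver's output cannot be improved by small
    perturbations in any coordinate (local optimality of a convex problem
    implies global optimality)."""
    y = np.asarray(raw)
    x = tvd_exact(y, lam)
    base = tv_objective(y, x, lam)
    for i in range(0, len(y), max(1, len(y) // 7)):
        for eps in (1e-4, -1e-4):
            x2 = x.copy()
            x2[i] += eps
            assert tv_objective(y, x2, lam) >= base - 1e-12
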
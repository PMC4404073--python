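"""Semiparametric geographically weighted Poisson regression."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from gwcommute import (
    KernelSpec,
    SemiparametricSpec,
    bandwidth_grid,
    bandwidth_search,
    compare_models,
    fit_gwpr,
    fit_local_poisson,
    fit_poisson_glm,
    kernel_weights,
    pseudo_t,
    summarize_local,
)
from gwcommute.gwpr import GwprFit, effective_parameters

from conftest import make_spec, pooled_design


class TestFitLocalPoisson:
    def test_uniform_weights_equal_global_glm(self):
        rng = np.random.default_rng(1)
        n = 60
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.poisson(np.exp(0.5 + 0.3 * X[:, 1]))
        lf = fit_local_poisson(0, y, X, weights=np.ones(n))
        gf = fit_poisson_glm(y, X)
        np.testing.assert_allclose(lf.coefficients, gf.coefficients, atol=1e-10)

    def test_degenerate_kernel_single_point(self):
        # all weight on one observation with y=2, intercept-only design
        y = np.array([2, 7, 9])
        X = np.ones((3, 1))
        w = np.array([1.0, 0.0, 0.0])
        lf = fit_local_poisson(0, y, X, weights=w)
        assert lf.coefficients[0] == pytest.approx(np.log(2.0), abs=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_numeric_maximizer(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.poisson(np.exp(0.4 + 0.5 * X[:, 1]))
        pts = rng.uniform(0, 1000, size=(n, 2))
        d = np.hypot(*(pts - pts[0]).T)
        b = np.sort(d)[35]
        w = kernel_weights(d, b, "bisquare")
        off = rng.normal(0, 0.2, n)
        lf = fit_local_poisson(0, y, X, offset=off, weights=w)

        def nwll(beta):
            eta = X @ beta + off
            return -np.sum(w * (y * eta - np.exp(eta)))

        res = minimize(nwll, lf.coefficients + 0.1, method="Nelder-Mead",
                       options=dict(xatol=1e-10, fatol=1e-13, maxiter=20000))
        np.testing.assert_allclose(lf.coefficients, res.x, atol=1e-6)

    def test_rank_deficient_flagged_unstable(self):
        y = np.array([1, 2, 3, 4])
        X = np.column_stack([np.ones(4), [1.0, 1.0, 1.0, 1.0]])
        lf = fit_local_poisson(0, y, X, weights=np.ones(4))
        assert not lf.stable


class TestFitGwpr:
    def test_empty_local_set_equals_global_glm(self, cohort_design):
        y, Xl, Xg, pts = cohort_design
        Xg1 = pooled_design(Xl.iloc[:, :0], Xg)  # intercept + global only
        spec = SemiparametricSpec((), tuple(Xg1.columns),
                                  KernelSpec("bisquare", "adaptive", neighbor_count=50),
                                  local_intercept=False)
        fit = fit_gwpr(y, None, Xg1, pts, spec)
        ref = fit_poisson_glm(y, Xg1)
        np.testing.assert_allclose(fit.gamma, ref.coefficients, atol=1e-10)
        assert fit.aicc == pytest.approx(ref.deviance + 2 * ref.p, abs=1e-10)
        assert fit.degenerate

    def test_global_limit_recovers_global_fit(self, cohort_design):
        y, Xl, Xg, pts = cohort_design
        spec = make_spec(mode="fixed", family="gaussian", bandwidth_m=1e9)
        fit = fit_gwpr(y, Xl, Xg, pts, spec)
        ref = fit_poisson_glm(y, pooled_design(Xl, Xg))
        p_local = Xl.shape[1] + 1
        assert np.max(np.abs(fit.local_coefficients - ref.coefficients[:p_local])) < 1e-4
        np.testing.assert_allclose(fit.gamma, ref.coefficients[p_local:], atol=1e-4)

    def test_local_fits_match_weighted_likelihood_maximizer(self, cohort_design):
        """Each converged local fit maximizes its geographically weighted
        log-likelihood given the fixed-term offset."""
        y, Xl, Xg, pts = cohort_design
        n = len(y)
        idx = np.arange(0, n, 37)  # a handful of locations
        spec = make_spec(neighbor_count=80)
        fit = fit_gwpr(y, Xl, Xg, pts, spec)
        Xlm = np.column_stack([np.ones(n), Xl.to_numpy()])
        off = Xg.to_numpy() @ fit.gamma
        from gwcommute.kernels import adaptive_bandwidths

        bw = adaptive_bandwidths(pts, 80)
        for i in idx:
            d = np.hypot(*(pts - pts[i]).T)
            w = kernel_weights(d, bw[i], "bisquare")

            def nwll(beta):
                eta = Xlm @ beta + off
                return -np.sum(w * (y * eta - np.exp(eta)))

            res = minimize(nwll, fit.local_coefficients[i], method="Nelder-Mead",
                           options=dict(xatol=1e-10, fatol=1e-13, maxiter=50000))
            np.testing.assert_allclose(fit.local_coefficients[i], res.x, atol=1e-5)

    def test_backfitting_deviance_monotone(self, cohort_design):
        y, Xl, Xg, pts = cohort_design
        fit = fit_gwpr(y, Xl, Xg, pts, make_spec(neighbor_count=100))
        diffs = np.diff(fit.deviance_trace)
        assert np.all(diffs <= 1e-3)  # non-increasing up to solver tolerance

    def test_effective_parameters_bounds_and_limits(self, cohort_design):
        y, Xl, Xg, pts = cohort_design
        n = len(y)
        p_local, p_global = Xl.shape[1] + 1, Xg.shape[1]
        fit = fit_gwpr(y, Xl, Xg, pts, make_spec(neighbor_count=100))
        assert p_global <= fit.k <= n * p_local + p_global
        assert effective_parameters(fit) == fit.k

    def test_trace_s_monotone_in_bandwidth(self, cohort_design):
        y, Xl, Xg, pts = cohort_design
        traces = []
        for N in [40, 60, 100, 150, 199]:
            fit = fit_gwpr(y, Xl, Xg, pts, make_spec(neighbor_count=N))
            traces.append(fit.trace_S)
        assert np.all(np.diff(traces) <= 1e-6)

    def test_near_global_gaussian_intercept_trace_near_one(self):
        """Huge bandwidth with a single local intercept: the local smoother
        collapses to the global intercept hat matrix, trace -> 1."""
        rng = np.random.default_rng(8)
        n = 120
        pts = rng.uniform(0, 1000, size=(n, 2))
        y = rng.poisson(2.0, size=n)
        spec = SemiparametricSpec((), (), KernelSpec("gaussian", "fixed", bandwidth_m=1e9))
        fit = fit_gwpr(y, None, None, pts, spec)
        assert fit.trace_S == pytest.approx(1.0, abs=1e-4)


class TestPseudoT:
    def test_zero_coefficient_not_significant(self, cohort_design):
        y, Xl, Xg, pts = cohort_design
        fit = fit_gwpr(y, Xl, Xg, pts, make_spec(neighbor_count=100))
        tab = pseudo_t(fit)
        t = fit.pseudo_t_values
        # strict inequality at the threshold
        assert not tab["env_built_sig"].to_numpy()[np.abs(t[:, 1]) <= 1.96].any()
        assert tab["env_built_sig"].to_numpy()[np.abs(t[:, 1]) > 1.96].all()

    def test_boundary_value_not_flagged(self):
        fit = _tiny_fit(beta=np.array([[1.96]]), se=np.array([[1.0]]))
        tab = pseudo_t(fit)
        assert not tab["b0_sig"].iloc[0]
        fit2 = _tiny_fit(beta=np.array([[0.0]]), se=np.array([[1.0]]))
        assert pseudo_t(fit2)["b0_t"].iloc[0] == 0.0
        assert not pseudo_t(fit2)["b0_sig"].iloc[0]

    def test_zero_se_undefined(self):
        fit = _tiny_fit(beta=np.array([[1.0]]), se=np.array([[0.0]]))
        tab = pseudo_t(fit)
        assert tab["b0_undefined"].iloc[0]
        assert not tab["b0_sig"].iloc[0]


def _tiny_fit(beta, se):
    n = beta.shape[0]
    return GwprFit(
        coords=np.zeros((n, 2)), local_labels=["b0"], global_labels=[],
        local_coefficients=beta, local_se=se, gamma=np.zeros(0),
        gamma_se=np.zeros(0), fitted=np.ones(n), deviance=0.0,
        null_deviance=1.0, loglik=0.0, null_loglik=0.0, trace_S=1.0, k=1.0,
        aicc=2.0, kernel=KernelSpec("bisquare", "adaptive", neighbor_count=2),
        n_cycles=1, converged=True, stable=np.ones(n, bool),
    )


class TestBandwidthSearch:
    def test_default_grid_descends_every_50(self):
        grid = bandwidth_grid(4164, p_local=1)
        assert grid[0] == 4000 and grid[-1] == 50
        assert np.all(np.diff(grid) == -50)
        assert len(grid) == 80

    def test_grid_clipped_to_sample_size(self):
        grid = bandwidth_grid(130, p_local=4)
        assert max(grid) <= 129 and min(grid) >= 50

    def test_single_value_grid_returned(self, cohort_design):
        y, Xl, Xg, pts = cohort_design
        res = bandwidth_search(y, Xl, Xg, pts, make_spec(), grid=[120])
        assert res["selected"] == 120
        assert len(res["trace"]) == 1

    def test_selected_minimizes_aicc_trace(self, cohort_design):
        y, Xl, Xg, pts = cohort_design
        res = bandwidth_search(y, Xl, Xg, pts, make_spec(), grid=[80, 140, 199])
        tr = res["trace"]
        assert res["selected"] == tr.loc[tr.aicc.idxmin(), "N"]


class TestCompareModels:
    def test_identical_fits_not_substantial(self, cohort_design):
        y, Xl, Xg, pts = cohort_design
        fit = fit_gwpr(y, Xl, Xg, pts, make_spec(neighbor_count=100))
        out = compare_models(fit, fit)
        assert out["delta_aicc"] == 0.0 and not out["substantial"]

    def test_table_style_difference_substantial(self):
        out = compare_models(_stub_aicc(6556.0), _stub_aicc(6757.0),
                             names=("GWPR", "GPR"))
        assert out["delta_aicc"] == pytest.approx(-201.0)
        assert out["substantial"] and out["preferred"] == "GWPR"

    def test_delta_two_exactly_not_substantial(self):
        out = compare_models(_stub_aicc(100.0), _stub_aicc(102.0))
        assert not out["substantial"] and out["preferred"] is None

    def test_mismatched_data_refused(self, cohort_design):
        y, Xl, Xg, pts = cohort_design
        fit = fit_gwpr(y, Xl, Xg, pts, make_spec(neighbor_count=100))
        y2 = y.copy()
        y2[0] += 1
        fit2 = fit_gwpr(y2, Xl, Xg, pts, make_spec(neighbor_count=100))
        with pytest.raises(ValueError, match="identical data"):
            compare_models(fit, fit2)


def _stub_aicc(aicc):
    f = _tiny_fit(np.zeros((1, 1)), np.ones((1, 1)))
    f.aicc = aicc
    return f


class TestSummarizeLocal:
    def test_constant_coefficients_zero_spread(self):
        fit = _tiny_fit(np.full((5, 1), 0.7), np.ones((5, 1)))
        tab = summarize_local(fit)
        assert tab["std_log_odds"].iloc[0] == 0.0
        assert tab["range_OR"].iloc[0] == 0.0
        assert tab["mean_OR"].iloc[0] == pytest.approx(np.exp(0.7))

    def test_two_location_arithmetic(self):
        fit = _tiny_fit(np.array([[-0.1], [0.1]]), np.ones((2, 1)))
        tab = summarize_local(fit)
        assert tab["min_OR"].iloc[0] == pytest.approx(np.exp(-0.1))
        assert tab["max_OR"].iloc[0] == pytest.approx(np.exp(0.1))
        assert tab["range_OR"].iloc[0] == pytest.approx(np.exp(0.1) - np.exp(-0.1))

    def test_all_unstable_raises(self):
        fit = _tiny_fit(np.zeros((3, 1)), np.ones((3, 1)))
        fit.stable = np.zeros(3, bool)
        with pytest.raises(ValueError, match="unstable"):
            summarize_local(fit)


class TestSpecValidation:
    def test_overlapping_column_sets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SemiparametricSpec(("a",), ("a", "b"),
                               KernelSpec("bisquare", "adaptive", neighbor_count=10))
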
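"""Design matrix, likelihood, derivatives, and model fitting."""

import numpy as np
import pytest

from hawkestre.data import MarkedPointDataset, Window
from hawkestre.model import (
    ETA_MAX,
    HawkesParams,
    HawkesPointProcess,
    build_design,
    g_function,
    hessian,
    linear_predictor,
    loglik,
    score,
)
from hawkestre.splines import SplineSpec, evaluate_h


def _poisson_dataset(n=20, length=1000.0, marks=("A",), seed=5):
    rng = np.random.default_rng(seed)
    ds = MarkedPointDataset([Window("c", 0.0, length, 0)], tuple(marks))
    for m in marks:
        ds.points[(0, m)] = np.sort(rng.uniform(1.0, length, size=n))
    return ds


class TestDesign:
    def test_grid_row_count_empty_dataset(self):
        ds = MarkedPointDataset([Window("c", 0.0, 1000.0, 0)], ("A",))
        ds.points[(0, "A")] = np.empty(0)
        d = build_design(ds, "A", resolution=10.0)
        assert d.n_rows == 100
        assert d.event_rows.size == 0
        assert d.w.sum() == pytest.approx(1000.0)

    def test_truncated_last_cell_weights_sum_to_length(self):
        ds = MarkedPointDataset([Window("c", 0.0, 995.0, 0)], ("A",))
        ds.points[(0, "A")] = np.empty(0)
        d = build_design(ds, "A", resolution=10.0)
        assert d.n_rows == 100
        assert d.w.sum() == pytest.approx(995.0)
        assert d.w[-1] == pytest.approx(5.0)

    def test_column_count_encode_configuration(self):
        # 44 per-region baselines + 2 covariates + 8 marks x 4 basis = 78
        windows = [Window("c", i * 10_000.0, (i + 1) * 10_000.0, i) for i in range(44)]
        marks = tuple(f"m{i}" for i in range(8))
        ds = MarkedPointDataset(windows, marks, covariate_names=("h1", "h2"))
        for i in range(44):
            for m in marks:
                ds.points[(i, m)] = np.empty(0)
        d = build_design(ds, "m0", resolution=1000.0, baseline_mode="per_window")
        assert d.X.shape[1] == 44 + 2 + 32

    def test_event_row_spline_entries_equal_basis_at_lag(self, default_spec):
        ds = MarkedPointDataset([Window("c", 0.0, 2000.0, 0)], ("A", "B"))
        ds.points[(0, "A")] = np.array([100.0])
        ds.points[(0, "B")] = np.array([600.0])
        d = build_design(ds, "B", resolution=10.0)
        row = d.X[d.event_rows[0]].toarray().ravel()
        cols = d.layout.beta_cols("A")
        np.testing.assert_allclose(row[cols], default_spec.basis_matrix(500.0)[0])

    def test_no_entries_beyond_support(self, default_spec):
        ds = MarkedPointDataset([Window("c", 0.0, 3000.0, 0)], ("A", "B"))
        ds.points[(0, "A")] = np.array([100.0])
        ds.points[(0, "B")] = np.array([1500.0])  # lag 1400 > 1000
        d = build_design(ds, "B", resolution=10.0)
        row = d.X[d.event_rows[0]].toarray().ravel()
        assert np.all(row[d.layout.beta_cols("A")] == 0.0)

    def test_resolution_larger_than_window_rejected(self):
        ds = MarkedPointDataset([Window("c", 0.0, 100.0, 0)], ("A",))
        ds.points[(0, "A")] = np.empty(0)
        with pytest.raises(ValueError, match="resolution"):
            build_design(ds, "A", resolution=500.0)


class TestLinearPredictor:
    def test_no_history_gives_baseline(self, default_spec):
        ds = MarkedPointDataset([Window("c", 0.0, 1000.0, 0)], ("A",))
        ds.points[(0, "A")] = np.empty(0)
        p = HawkesParams.zeros(("A",), default_spec, log_baseline=np.log(2e-4))
        assert linear_predictor(500.0, "A", 0, ds, p) == pytest.approx(np.log(2e-4))

    def test_single_upstream_point_multiplies_by_g(self, default_spec, rng):
        ds = MarkedPointDataset([Window("c", 0.0, 2000.0, 0)], ("A", "B"))
        ds.points[(0, "A")] = np.array([200.0])
        ds.points[(0, "B")] = np.empty(0)
        p = HawkesParams.zeros(("A", "B"), default_spec, log_baseline=np.log(1e-3))
        p.beta[("A", "B")] = rng.normal(size=4)
        lam = np.exp(linear_predictor(500.0, "B", 0, ds, p))
        g = g_function("A", "B", 300.0, p)[0]
        assert lam == pytest.approx(1e-3 * g)

    def test_two_upstream_points_multiply(self, default_spec, rng):
        ds = MarkedPointDataset([Window("c", 0.0, 2000.0, 0)], ("A", "B"))
        ds.points[(0, "A")] = np.array([200.0, 450.0])
        ds.points[(0, "B")] = np.empty(0)
        p = HawkesParams.zeros(("A", "B"), default_spec, log_baseline=np.log(1e-3))
        p.beta[("A", "B")] = rng.normal(size=4)
        lam = np.exp(linear_predictor(500.0, "B", 0, ds, p))
        expected = 1e-3 * g_function("A", "B", 300.0, p)[0] * g_function("A", "B", 50.0, p)[0]
        assert lam == pytest.approx(expected)

    def test_point_does_not_excite_itself(self, default_spec):
        ds = MarkedPointDataset([Window("c", 0.0, 2000.0, 0)], ("A",))
        ds.points[(0, "A")] = np.array([500.0])
        p = HawkesParams.zeros(("A",), default_spec, log_baseline=0.0)
        p.beta[("A", "A")] = np.ones(4)
        # at the point's own position only strictly-earlier points count
        assert linear_predictor(500.0, "A", 0, ds, p) == pytest.approx(0.0)

    def test_g_is_one_when_beta_zero_or_beyond_support(self, default_spec):
        p = HawkesParams.zeros(("A",), default_spec)
        assert g_function("A", "A", 300.0, p)[0] == 1.0
        p.beta[("A", "A")] = np.ones(4)
        assert g_function("A", "A", 1200.0, p)[0] == 1.0


class TestLikelihood:
    def test_homogeneous_poisson_closed_form(self):
        ds = _poisson_dataset(n=20, length=1000.0)
        d = build_design(ds, "A", resolution=10.0)
        theta = np.zeros(d.layout.n_params)
        alpha0 = np.log(0.02)
        theta[0] = alpha0
        # no interactions in theta -> l = n alpha0 - |C| e^{alpha0}
        assert loglik(theta, d) == pytest.approx(20 * alpha0 - 1000 * 0.02)

    def test_poisson_mle_recovered_exactly(self):
        ds = _poisson_dataset(n=20, length=1000.0)
        model = HawkesPointProcess(ds, resolution=10.0)
        res = model.fit(fixed_zero=[("A", "A")])
        assert np.exp(res.params.log_baseline["A"][0]) == pytest.approx(
            20 / 1000.0, rel=1e-6
        )

    def test_gradient_matches_finite_differences(self, rng):
        ds = _poisson_dataset(n=15, length=2000.0, marks=("A", "B"), seed=7)
        d = build_design(ds, "B", resolution=20.0)
        theta = rng.normal(scale=0.3, size=d.layout.n_params)
        theta[0] = np.log(15 / 2000.0)
        g = score(theta, d)
        eps = 1e-6
        for j in range(theta.size):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += eps
            tm[j] -= eps
            fd = (loglik(tp, d) - loglik(tm, d)) / (2 * eps)
            assert g[j] == pytest.approx(fd, rel=1e-6, abs=1e-8)

    def test_hessian_negative_semidefinite(self, rng):
        ds = _poisson_dataset(n=15, length=2000.0, marks=("A", "B"), seed=7)
        d = build_design(ds, "B", resolution=20.0)
        for _ in range(3):
            theta = rng.normal(scale=0.5, size=d.layout.n_params)
            H = hessian(theta, d)
            np.testing.assert_allclose(H, H.T, atol=1e-10)
            assert np.linalg.eigvalsh(H).max() <= 1e-8

    def test_additivity_over_windows(self):
        w1 = Window("c1", 0.0, 1000.0, 0)
        w2 = Window("c2", 0.0, 1500.0, 1)
        rng = np.random.default_rng(3)
        pts1 = np.sort(rng.uniform(0, 1000, 8))
        pts2 = np.sort(rng.uniform(0, 1500, 12))
        both = MarkedPointDataset([w1, w2], ("A",))
        both.points[(0, "A")] = pts1
        both.points[(1, "A")] = pts2
        single1 = MarkedPointDataset([w1], ("A",))
        single1.points[(0, "A")] = pts1
        single2 = MarkedPointDataset([Window("c2", 0.0, 1500.0, 0)], ("A",))
        single2.points[(0, "A")] = pts2
        theta = np.array([np.log(0.01), 0.2, -0.1, 0.3, 0.1])
        ll_both = loglik(theta, build_design(both, "A", resolution=10.0))
        ll_1 = loglik(theta, build_design(single1, "A", resolution=10.0))
        ll_2 = loglik(theta, build_design(single2, "A", resolution=10.0))
        assert ll_both == pytest.approx(ll_1 + ll_2, rel=1e-12)

    def test_translation_invariance(self):
        rng = np.random.default_rng(8)
        pts = np.sort(rng.uniform(0, 5000, 25))
        ds = MarkedPointDataset([Window("c", 0.0, 5000.0, 0)], ("A",))
        ds.points[(0, "A")] = pts
        shifted = MarkedPointDataset([Window("c", 1e6, 1e6 + 5000.0, 0)], ("A",))
        shifted.points[(0, "A")] = pts + 1e6
        theta = np.array([np.log(0.005), 0.3, -0.2, 0.1, 0.0])
        ll = loglik(theta, build_design(ds, "A", resolution=5.0))
        ll_shift = loglik(theta, build_design(shifted, "A", resolution=5.0))
        assert ll == pytest.approx(ll_shift, rel=1e-9)

    def test_discretization_error_shrinks_with_resolution(self):
        ds = _poisson_dataset(n=30, length=5000.0, seed=11)
        theta = np.array([np.log(30 / 5000.0), 0.5, -0.4, 0.3, 0.2])
        ll = {
            r: loglik(theta, build_design(ds, "A", resolution=r)) for r in (1.0, 2.0, 20.0)
        }
        assert abs(ll[2.0] - ll[1.0]) < abs(ll[20.0] - ll[1.0])

    def test_overflow_clamp_warns(self):
        ds = _poisson_dataset(n=5, length=1000.0)
        d = build_design(ds, "A", resolution=10.0)
        theta = np.zeros(d.layout.n_params)
        theta[0] = ETA_MAX + 10
        with pytest.warns(RuntimeWarning, match="clamped"):
            loglik(theta, d)


class TestFit:
    def test_concave_optimum_reached_from_perturbed_start(self):
        from scipy.optimize import minimize

        ds = _poisson_dataset(n=40, length=8000.0, marks=("A", "B"), seed=2)
        model = HawkesPointProcess(ds, resolution=10.0)
        res = model.fit(marks=["B"])
        d = model.design("B")
        rng = np.random.default_rng(0)
        start = rng.normal(scale=0.5, size=d.layout.n_params)
        alt = minimize(
            lambda th: -loglik(th, d),
            start,
            jac=lambda th: -score(th, d),
            method="L-BFGS-B",
            options={"maxiter": 1000, "gtol": 1e-8},
        )
        assert -alt.fun == pytest.approx(res.loglik["B"], abs=1e-5)

    def test_joint_fit_separates_by_mark(self):
        ds = _poisson_dataset(n=25, length=5000.0, marks=("A", "B"), seed=6)
        model = HawkesPointProcess(ds, resolution=10.0)
        res = model.fit()
        res_a = model.fit(marks=["A"])
        assert res.loglik["A"] == pytest.approx(res_a.loglik["A"], abs=1e-8)

    def test_params_roundtrip_json(self, default_spec):
        p = HawkesParams.zeros(("A", "B"), default_spec, covariate_names=("c1",))
        p.beta[("A", "B")] = np.array([0.1, -0.2, 0.3, 0.0])
        q = HawkesParams.from_dict(p.to_dict())
        np.testing.assert_allclose(q.beta[("A", "B")], p.beta[("A", "B")])
        assert q.marks == p.marks and q.covariate_names == p.covariate_names
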
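"""Priors, Legendre chaos expansions, sparse grids and Sobol indices."""

import itertools
import math

import numpy as np
import pytest

from eeguq.surrogate import (
    ConductivityPrior,
    PCEModel,
    basis_matrix,
    fit_pce,
    gauss_legendre_rule,
    rescale,
    sample_prior,
    sobol_indices,
    sparse_grid_nodes,
    total_degree_indices,
    unrescale,
)


class TestPrior:
    def test_default_bounds_mSm(self, prior):
        expected = {
            "skin": (280.0, 870.0, 430.0),
            "skull": (1.6, 33.0, 10.0),
            "csf": (1769.6, 1810.4, 1790.0),
            "gm": (220.0, 670.0, 330.0),
            "wm": (90.0, 290.0, 140.0),
        }
        for tissue, (lo, hi, std) in expected.items():
            assert prior.lower(tissue) * 1e3 == pytest.approx(lo)
            assert prior.upper(tissue) * 1e3 == pytest.approx(hi)
            assert prior.standard(tissue) * 1e3 == pytest.approx(std)

    def test_invalid_prior_rejected(self):
        with pytest.raises(ValueError):
            ConductivityPrior({"skin": (0.5, 0.4, 0.45)})


class TestRescale:
    def test_endpoints_and_midpoint(self, prior):
        lo, hi = prior.lower("gm"), prior.upper("gm")
        assert rescale([lo], prior, ["gm"])[0] == pytest.approx(-1.0)
        assert rescale([hi], prior, ["gm"])[0] == pytest.approx(1.0)
        assert rescale([(lo + hi) / 2], prior, ["gm"])[0] == pytest.approx(0.0, abs=1e-14)

    def test_skull_standard_value_affine_map(self, prior):
        """σ_skull = 10.0 mS/m with bounds [1.6, 33.0] → ξ = (10.0-17.3)/15.7."""
        xi = rescale({"skull": 0.010}, prior, ["skull"])[0]
        assert xi == pytest.approx((10.0 - 17.3) / 15.7, abs=1e-12)

    def test_round_trip(self, prior):
        rng = np.random.default_rng(0)
        tissues = ["skin", "skull", "gm"]
        sig = np.array(
            [rng.uniform(prior.lower(t), prior.upper(t)) for t in tissues]
        )
        back = unrescale(rescale(sig, prior, tissues), prior, tissues)
        np.testing.assert_allclose(back, sig, rtol=1e-14)

    def test_out_of_bounds_names_tissue(self, prior):
        with pytest.raises(ValueError, match="skull"):
            rescale({"skull": 0.050}, prior, ["skull"])

    def test_degenerate_prior_rejected(self):
        p = ConductivityPrior({"x": (0.1, 0.1, 0.1)})
        with pytest.raises(ValueError, match="degenerate"):
            rescale({"x": 0.1}, p, ["x"])


class TestSamplePrior:
    def test_within_bounds_and_deterministic(self, prior):
        s1 = sample_prior(prior, ["skull"], 500, seed=11)
        s2 = sample_prior(prior, ["skull"], 500, seed=11)
        np.testing.assert_array_equal(s1, s2)
        assert s1.min() >= 1.6e-3 and s1.max() <= 33.0e-3

    def test_degenerate_prior_constant_samples(self):
        p = ConductivityPrior({"x": (0.2, 0.2, 0.2)})
        s = sample_prior(p, ["x"], 50, seed=0)
        assert np.all(s == 0.2)

    def test_mean_within_standard_error(self, prior):
        n = 4000
        s = sample_prior(prior, ["gm"], n, seed=3)[:, 0]
        lo, hi = prior.lower("gm"), prior.upper("gm")
        se = (hi - lo) / math.sqrt(12 * n)
        assert abs(s.mean() - (lo + hi) / 2) < 3 * se


class TestSparseGrid:
    def test_1d_is_gauss_legendre(self):
        nodes, weights = sparse_grid_nodes(1, 4)
        x, w = gauss_legendre_rule(5)
        np.testing.assert_allclose(np.sort(nodes[:, 0]), np.sort(x), atol=1e-13)
        # integrates monomials up to degree 9 exactly under the uniform measure
        for k in range(10):
            exact = 0.0 if k % 2 else 1.0 / (k + 1)
            assert np.sum(weights * nodes[:, 0] ** k) == pytest.approx(exact, abs=1e-14)

    @pytest.mark.parametrize("d", [1, 2, 4])
    def test_weights_sum_to_one(self, d):
        _, weights = sparse_grid_nodes(d, 4)
        assert weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_2d_nodes_subset_of_tensor_union(self):
        """Every Smolyak node lies in the union of the contributing tensor
        Gauss-Legendre grids (independent enumeration)."""
        nodes, _ = sparse_grid_nodes(2, 3)
        union = set()
        L, d = 3, 2
        for l1 in range(L + 1):
            for l2 in range(L + 1 - l1):
                x1, _ = gauss_legendre_rule(l1 + 1)
                x2, _ = gauss_legendre_rule(l2 + 1)
                for a in x1:
                    for b in x2:
                        union.add((round(a, 10), round(b, 10)))
        for row in nodes:
            assert (round(row[0], 10), round(row[1], 10)) in union

    def test_2d_integrates_like_dense_tensor_rule(self):
        """Quadrature agrees with a dense Gauss-Legendre tensor rule on
        random polynomials of total degree ≤ 7."""
        rng = np.random.default_rng(1)
        nodes, weights = sparse_grid_nodes(2, 3)
        xg, wg = gauss_legendre_rule(10)
        X, Y = np.meshgrid(xg, xg, indexing="ij")
        W = np.outer(wg, wg)
        for _ in range(5):
            coeffs = {(i, j): rng.normal() for i in range(8) for j in range(8 - i)}
            f = lambda x, y: sum(c * x**i * y**j for (i, j), c in coeffs.items())
            dense = np.sum(W * f(X, Y))
            sparse = np.sum(weights * f(nodes[:, 0], nodes[:, 1]))
            assert sparse == pytest.approx(dense, abs=1e-12)

    def test_d4_exact_for_total_degree_8(self):
        nodes, weights = sparse_grid_nodes(4, 4)
        rng = np.random.default_rng(2)
        for _ in range(30):
            a = rng.multinomial(8, np.ones(4) / 4)
            exact = math.prod(0.0 if k % 2 else 1.0 / (k + 1) for k in a)
            quad = np.sum(weights * np.prod(nodes**a, axis=1))
            assert quad == pytest.approx(exact, abs=1e-12)


class TestMultiIndices:
    @pytest.mark.parametrize("d,p", [(1, 4), (2, 3), (4, 4)])
    def test_count_and_uniqueness(self, d, p):
        mi = total_degree_indices(d, p)
        assert mi.shape == (math.comb(d + p, p), d)
        assert len({tuple(r) for r in mi}) == mi.shape[0]
        assert np.all(mi.sum(axis=1) <= p)
        assert np.any(np.all(mi == 0, axis=1))

    def test_basis_orthonormal_under_quadrature(self):
        nodes, weights = sparse_grid_nodes(2, 3)
        Psi = basis_matrix(nodes, total_degree_indices(2, 3))
        G = (Psi * weights[:, None]).T @ Psi
        np.testing.assert_allclose(G, np.eye(G.shape[0]), atol=1e-12)


class TestFitAndEvaluate:
    def _fit_1d(self, f, degree=4):
        nodes, weights = sparse_grid_nodes(1, degree)
        evals = np.atleast_2d(f(nodes[:, 0])).T
        return fit_pce(evals, nodes, weights, ["x"], degree, [[-1.0, 1.0]])

    def test_constant_function(self):
        model = self._fit_1d(lambda x: np.full_like(x, 3.25))
        assert model.coefficients[0, 0] == pytest.approx(3.25)
        assert np.abs(model.coefficients[1:]).max() < 1e-12

    def test_xi_squared_analytic_coefficients(self):
        """ξ² = 1/3·Ψ0 + (2/(3√5))·Ψ2 in the orthonormal Legendre basis."""
        model = self._fit_1d(lambda x: x**2)
        coef = {tuple(a): c for a, c in zip(model.multi_indices, model.coefficients[:, 0])}
        assert coef[(0,)] == pytest.approx(1 / 3, abs=1e-14)
        assert coef[(1,)] == pytest.approx(0.0, abs=1e-14)
        assert coef[(2,)] == pytest.approx(2 / (3 * np.sqrt(5)), abs=1e-14)
        assert coef[(3,)] == pytest.approx(0.0, abs=1e-14)
        assert coef[(4,)] == pytest.approx(0.0, abs=1e-14)

    def test_degree4_polynomial_reproduced_exactly(self):
        rng = np.random.default_rng(3)
        c = {tuple(a): rng.normal() for a in total_degree_indices(2, 4)}

        def f(x, y):
            return sum(ci * x**a[0] * y**a[1] for a, ci in c.items())

        nodes, weights = sparse_grid_nodes(2, 4)
        evals = f(nodes[:, 0], nodes[:, 1])[:, None]
        model = fit_pce(evals, nodes, weights, ["x", "y"], 4, [[-1, 1], [-1, 1]])
        pts = rng.uniform(-1, 1, size=(1000, 2))
        pred = model.predict_xi(pts)[:, 0]
        truth = f(pts[:, 0], pts[:, 1])
        assert np.abs(pred - truth).max() < 1e-10

    def test_nan_evaluation_names_node(self):
        nodes, weights = sparse_grid_nodes(1, 2)
        evals = np.ones((nodes.shape[0], 1))
        evals[2, 0] = np.nan
        with pytest.raises(ValueError, match="2"):
            fit_pce(evals, nodes, weights, ["x"], 2, [[-1, 1]])

    def test_predict_rejects_out_of_bounds(self, prior):
        nodes, weights = sparse_grid_nodes(1, 2)
        model = fit_pce(
            nodes[:, :1] ** 2, nodes, weights, ["skull"],
            2, prior.interval_array(["skull"]),
        )
        with pytest.raises(ValueError, match="skull"):
            model.predict({"skull": 0.9}, prior)

    def test_degree0_model_is_constant_term(self, prior):
        nodes, weights = sparse_grid_nodes(1, 0)
        model = fit_pce(
            np.full((nodes.shape[0], 2), 7.0), nodes, weights, ["skull"],
            0, prior.interval_array(["skull"]),
        )
        out = model.predict({"skull": prior.standard("skull")}, prior)
        np.testing.assert_allclose(out, [7.0, 7.0])

    def test_hdf5_roundtrip(self, tmp_path):
        model = self._fit_1d(lambda x: x**3 - x)
        model.to_hdf5(tmp_path / "pce.h5")
        back = PCEModel.from_hdf5(tmp_path / "pce.h5")
        np.testing.assert_array_equal(back.multi_indices, model.multi_indices)
        np.testing.assert_allclose(back.coefficients, model.coefficients)
        assert back.tissues == model.tissues


def fit_analytic_2d(f, degree=4):
    nodes, weights = sparse_grid_nodes(2, degree)
    evals = f(nodes[:, 0], nodes[:, 1])[:, None]
    return fit_pce(evals, nodes, weights, ["x", "y"], degree, [[-1, 1], [-1, 1]])


class TestSobol:
    def test_single_variable_function(self):
        model = fit_analytic_2d(lambda x, y: 2.0 * x)
        t = sobol_indices(model)
        assert t.indices[("x",)][0] == pytest.approx(1.0, abs=1e-13)
        assert t.indices[("y",)][0] == pytest.approx(0.0, abs=1e-13)
        assert t.indices[("x", "y")][0] == pytest.approx(0.0, abs=1e-13)

    def test_analytic_interaction_function(self):
        """f = ξ1 + ξ2 + ξ1ξ2: V=7/9, S1=S2=3/7, S12=1/7."""
        model = fit_analytic_2d(lambda x, y: x + y + x * y)
        t = sobol_indices(model)
        assert t.total_variance[0] == pytest.approx(7 / 9, abs=1e-13)
        assert t.indices[("x",)][0] == pytest.approx(3 / 7, abs=1e-10)
        assert t.indices[("y",)][0] == pytest.approx(3 / 7, abs=1e-10)
        assert t.indices[("x", "y")][0] == pytest.approx(1 / 7, abs=1e-10)

    def test_sum_over_all_subsets_is_one(self):
        rng = np.random.default_rng(4)
        c = {tuple(a): rng.normal() for a in total_degree_indices(2, 3)}
        model = fit_analytic_2d(
            lambda x, y: sum(ci * x**a[0] * y**a[1] for a, ci in c.items())
        )
        t = sobol_indices(model)
        assert t.sum_of_indices()[0] == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_output_flagged(self):
        model = fit_analytic_2d(lambda x, y: np.full_like(x, 5.0))
        t = sobol_indices(model)
        assert t.zero_variance[0]
        assert np.isnan(t.indices[("x",)][0])

    def test_parseval_variance_matches_sampling(self):
        model = fit_analytic_2d(lambda x, y: x + 0.5 * y**2 + 0.2 * x * y)
        rng = np.random.default_rng(5)
        xi = rng.uniform(-1, 1, size=(40_000, 2))
        vals = model.predict_xi(xi)[:, 0]
        block_vars = [v.var(ddof=1) for v in np.split(vals, 10)]
        sem = np.std(block_vars, ddof=1) / np.sqrt(10)
        coef_var = sobol_indices(model).total_variance[0]
        assert abs(np.mean(block_vars) - coef_var) < 4 * sem


def test_sobol_coefficients_agree_with_saltelli_oracle():
    from conftest import saltelli_indices

    f = lambda X: X[:, 0] + X[:, 1] + X[:, 0] * X[:, 1]
    model = fit_analytic_2d(lambda x, y: x + y + x * y)
    t = sobol_indices(model)
    S1, S2 = saltelli_indices(f, 2, 100_000, np.random.default_rng(6), pairs=[(0, 1)])
    for i, name in enumerate(["x", "y"]):
        est, se = S1[i]
        assert abs(t.indices[(name,)][0] - est) < 3 * se
    est, se = S2[(0, 1)]
    assert abs(t.indices[("x", "y")][0] - est) < 3 * se
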
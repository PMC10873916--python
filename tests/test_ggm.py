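"""Graphical lasso, EBIC selection and the partial-correlation conversion."""

import numpy as np
import pytest

from netpsych import (ebic, ebic_glasso_select, estimate_network,
                      gaussian_loglik, glasso_fit, lambda_grid,
                      precision_to_partial, sample_ordinal_responses,
                      make_random_sparse_ggm)
from netpsych.ggm import ZERO_TOL, GlassoError, glasso_objective

from conftest import random_correlation


class TestGlassoFit:
    def test_lambda_zero_is_unpenalized_mle(self):
        rng = np.random.default_rng(0)
        S = random_correlation(rng, p=5, n=200)
        K = glasso_fit(S, 0.0)
        assert np.abs(K - np.linalg.inv(S)).max() < 1e-8

    def test_penalty_above_threshold_empties_network(self):
        rng = np.random.default_rng(1)
        S = random_correlation(rng)
        lam = np.abs(S - np.eye(4)).max()
        K = glasso_fit(S, lam)
        off = K - np.diag(np.diag(K))
        assert np.all(off == 0)

    def test_objective_not_worse_than_sklearn_oracle(self):
        sklearn_cov = pytest.importorskip("sklearn.covariance")
        rng = np.random.default_rng(2)
        for _ in range(10):
            S = random_correlation(rng)
            for lam in (0.05, 0.1, 0.3):
                K = glasso_fit(S, lam)
                with np.errstate(all="ignore"):
                    import warnings
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        _, K_o = sklearn_cov.graphical_lasso(S, alpha=lam,
                                                             tol=1e-10, max_iter=500)
                assert (glasso_objective(K, S, lam)
                        <= glasso_objective(K_o, S, lam) + 1e-6)
                assert np.array_equal(np.abs(K) > 1e-6, np.abs(K_o) > 1e-6)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            glasso_fit(np.eye(3), -0.1)


class TestLambdaGrid:
    def test_log_spacing_closed_form(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        g = lambda_grid(S, n_lambda=3, min_ratio=0.01)
        assert np.allclose(g, [0.5, 0.05, 0.005])

    def test_single_lambda(self):
        S = np.array([[1.0, 0.4], [0.4, 1.0]])
        assert np.allclose(lambda_grid(S, n_lambda=1), [0.4])

    def test_all_zero_offdiagonal_warns_single_zero(self):
        with pytest.warns(UserWarning):
            g = lambda_grid(np.eye(3))
        assert np.array_equal(g, [0.0])

    def test_endpoints(self):
        rng = np.random.default_rng(4)
        S = random_correlation(rng)
        g = lambda_grid(S, n_lambda=100, min_ratio=0.01)
        lam_max = np.abs(S - np.eye(4)).max()
        assert g[0] == pytest.approx(lam_max)
        assert g[-1] == pytest.approx(lam_max * 0.01)
        assert np.all(np.diff(g) < 0)


class TestLikelihoodAndEBIC:
    def test_loglik_at_mle_closed_form(self):
        rng = np.random.default_rng(5)
        S = random_correlation(rng)
        n = 100
        L = gaussian_loglik(S, np.linalg.inv(S), n)
        _, logdetS = np.linalg.slogdet(S)
        assert L == pytest.approx(0.5 * n * (-logdetS - 4))

    def test_loglik_identity(self):
        assert gaussian_loglik(np.eye(3), np.eye(3), 50) == pytest.approx(-0.5 * 50 * 3)

    def test_ebic_arithmetic(self):
        K = np.eye(3)
        K[0, 1] = K[1, 0] = 0.2
        K[1, 2] = K[2, 1] = 0.1
        assert ebic(0.0, K, n=100, p=3, gamma=0.5) == pytest.approx(
            2 * np.log(100) + 4 * np.log(3))

    def test_gamma_zero_is_bic(self):
        K = np.eye(3)
        K[0, 1] = K[1, 0] = 0.2
        assert ebic(0.0, K, n=50, p=3, gamma=0.0) == pytest.approx(np.log(50))

    def test_empty_support_is_minus_two_L(self):
        assert ebic(-12.5, np.eye(4), n=10, p=4) == pytest.approx(25.0)


class TestPrecisionToPartial:
    def test_diagonal_precision_zero_partials(self):
        assert np.all(precision_to_partial(np.diag([2.0, 3.0, 1.0])) == 0)

    def test_two_by_two_formula(self):
        K = np.array([[2.0, -1.0], [-1.0, 2.0]])
        assert precision_to_partial(K)[0, 1] == pytest.approx(0.5)

    def test_agrees_with_nodewise_regression_oracle(self):
        # population check: partial corr of (i, j) = correlation of the
        # residuals of i and j regressed on all other variables
        rng = np.random.default_rng(6)
        A = rng.standard_normal((4, 4)) * 0.3 + np.eye(4)
        K = A @ A.T
        S = np.linalg.inv(K)
        P = precision_to_partial(K)
        for i, j in [(0, 1), (1, 3), (2, 3)]:
            others = [k for k in range(4) if k not in (i, j)]
            Soo = S[np.ix_(others, others)]
            Sio = S[np.ix_([i, j], others)]
            cond = S[np.ix_([i, j], [i, j])] - Sio @ np.linalg.solve(Soo, Sio.T)
            r = cond[0, 1] / np.sqrt(cond[0, 0] * cond[1, 1])
            assert P[i, j] == pytest.approx(r, abs=1e-10)

    def test_nonpositive_diagonal_rejected(self):
        with pytest.raises(ValueError):
            precision_to_partial(np.array([[1.0, 0.0], [0.0, -2.0]]))


class TestEBICSelection:
    def test_selected_index_minimizes_ebic(self, sparse_table):
        net, path = estimate_network(sparse_table.values)
        assert path.selected_index == int(np.argmin(path.ebics))
        assert path.ebics[path.selected_index] <= path.ebics.min() + 1e-12

    def test_monotone_shrinkage_along_path(self, sparse_table):
        _, path = estimate_network(sparse_table.values)
        sums = [np.abs(precision_to_partial(K)).sum() for K in path.precisions]
        assert np.all(np.diff(sums) >= -1e-6)

    def test_provenance_records_selection(self, sparse_table):
        net, path = estimate_network(sparse_table.values, gamma=0.5)
        assert net.provenance["gamma"] == 0.5
        assert net.provenance["lambda"] == pytest.approx(
            path.lambdas[path.selected_index])

    def test_weights_are_valid_partials(self, sparse_table):
        net, _ = estimate_network(sparse_table.values)
        assert np.all(np.abs(net.weights) < 1)
        assert np.all(np.diag(net.weights) == 0)
        assert np.allclose(net.weights, net.weights.T)

    def test_sparsity_pattern_matches_selected_precision(self, sparse_table):
        net, path = estimate_network(sparse_table.values)
        K = path.precisions[path.selected_index]
        iu = np.triu_indices(net.p, k=1)
        assert np.array_equal(np.abs(net.weights[iu]) > ZERO_TOL,
                              np.abs(K[iu]) > ZERO_TOL)

    def test_near_empty_truth_selects_near_empty_network(self):
        spec = make_random_sparse_ggm(p=8, edge_density=0.0, seed=12,
                                      n_respondents=2000)
        t = sample_ordinal_responses(spec)
        net, _ = estimate_network(t.values)
        assert net.n_edges <= 1

    def test_recovery_on_sparse_truth(self):
        spec = make_random_sparse_ggm(p=10, edge_density=0.2, seed=13,
                                      n_respondents=3000)
        t = sample_ordinal_responses(spec)
        net, _ = estimate_network(t.values)
        iu = np.triu_indices(10, k=1)
        true = np.abs(spec.true_partial[iu]) > 0
        est = np.abs(net.weights[iu]) > ZERO_TOL
        sens = (true & est).sum() / true.sum()
        assert sens >= 0.7

    def test_edge_list_export(self, sparse_table):
        net, _ = estimate_network(sparse_table.values)
        el = net.edge_list()
        assert len(el) == net.n_edges
        assert {"node_i", "node_j", "weight"} == set(el.columns)

    def test_graphml_export_round_trip(self, sparse_table, tmp_path):
        import igraph as ig
        net, _ = estimate_network(
            sparse_table.values,
            node_groups={c: "OTHER" for c in sparse_table.values.columns})
        f = tmp_path / "net.graphml"
        net.to_graphml(f, partition={l: 0 for l in net.labels})
        g = ig.Graph.Read_GraphML(str(f))
        assert g.vcount() == net.p
        assert g.ecount() == net.n_edges
        assert "weight" in g.es.attributes()
        assert "group" in g.vs.attributes()
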
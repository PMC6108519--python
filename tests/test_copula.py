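"""Skeptic correlation, graphical lasso and network extraction."""

import numpy as np
import pytest
from scipy import stats

from mealnets.copula import (
    GlassoConvergenceError,
    cv_select_lambda,
    default_lambda_grid,
    estimate_network,
    glasso_fit,
    kendall_to_latent,
    nearest_psd_correlation,
    spearman_to_latent,
    partial_correlations,
    rank_correlation_matrix,
    skeptic_from_data,
    skeptic_transform,
)
from conftest import ista_glasso, single_meal_cohort
from mealnets.synthetic import GraphSpec


class TestRankCorrelation:
    def test_hand_computed_midrank_spearman(self):
        # ranks (1..5) vs (1,2,3,5,4): sum d^2 = 2 -> 1 - 12/120 = 0.9
        X = np.array([[1, 1], [2, 2], [3, 3], [4, 5], [5, 4]], dtype=float)
        R, const = rank_correlation_matrix(X, "spearman")
        assert R[0, 1] == pytest.approx(0.9)
        assert const == ()

    def test_hand_computed_midrank_spearman_with_ties(self):
        # x ranks: 1, 2.5, 2.5, 4, 5; y ranks: 1, 2, 3, 4, 5
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0])
        y = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        R, _ = rank_correlation_matrix(np.column_stack([x, y]))
        rx = np.array([1, 2.5, 2.5, 4, 5])
        ry = np.array([1, 2, 3, 4, 5])
        expected = np.corrcoef(rx, ry)[0, 1]
        assert R[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_identical_and_antimonotone_columns(self):
        x = np.arange(10.0)
        R, _ = rank_correlation_matrix(np.column_stack([x, x, -x]))
        assert R[0, 1] == pytest.approx(1.0)
        assert R[0, 2] == pytest.approx(-1.0)

    def test_constant_column_flagged_with_zero_correlation(self):
        X = np.column_stack([np.arange(6.0), np.full(6, 3.0)])
        R, const = rank_correlation_matrix(X)
        assert const == (1,)
        assert R[0, 1] == 0.0
        assert R[1, 1] == 1.0

    def test_all_constant_errors(self):
        with pytest.raises(ValueError):
            rank_correlation_matrix(np.ones((5, 3)))

    def test_kendall_tau_b_under_ties(self):
        x = np.array([1.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 2.0, 3.0, 5.0, 5.0])
        R, _ = rank_correlation_matrix(np.column_stack([x, y]), "kendall")
        assert R[0, 1] == pytest.approx(stats.kendalltau(x, y).statistic)


class TestSkepticTransform:
    @pytest.mark.parametrize("rho, expected", [
        (-1.0, -1.0), (-0.5, -2 * np.sin(np.pi / 12)), (0.0, 0.0),
        (0.5, 2 * np.sin(np.pi / 12)), (1.0, 1.0),
    ])
    def test_spearman_sine_map_closed_form(self, rho, expected):
        assert spearman_to_latent(rho) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("tau, expected", [
        (-1.0, -1.0), (-0.5, -np.sin(np.pi / 4)), (0.0, 0.0),
        (0.5, np.sin(np.pi / 4)), (1.0, 1.0),
    ])
    def test_kendall_sine_map_closed_form(self, tau, expected):
        assert kendall_to_latent(tau) == pytest.approx(expected, abs=1e-12)

    def test_transform_applies_sine_map_off_diagonal(self):
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        S = skeptic_transform(R, "spearman", n_obs=10)
        assert S.matrix[0, 1] == pytest.approx(2 * np.sin(np.pi / 12), abs=1e-12)
        assert not S.psd_corrected

    def test_odd_monotone_and_sign_preserving(self):
        grid = np.linspace(-1, 1, 201)
        sp = 2 * np.sin(np.pi * grid / 6)
        kd = np.sin(np.pi * grid / 2)
        for vals in (sp, kd):
            assert np.all(np.diff(vals) > 0)
            assert np.allclose(vals + vals[::-1], 0.0)  # odd
            assert np.all(np.sign(vals) == np.sign(grid))

    def test_estimator_consistency_against_pearson_on_gaussian_data(self):
        rng = np.random.default_rng(5)
        corr = np.eye(5)
        corr[0, 1] = corr[1, 0] = 0.6
        corr[2, 3] = corr[3, 2] = -0.4
        X = rng.multivariate_normal(np.zeros(5), corr, size=10000)
        for method in ("spearman",):
            S = skeptic_from_data(X, method)
            pearson = np.corrcoef(X, rowvar=False)
            assert np.max(np.abs(S.matrix - pearson)) < 0.03


class TestNearestPSD:
    def test_psd_input_returned_unchanged(self):
        S = np.eye(3)
        assert nearest_psd_correlation(S) is S

    def test_indefinite_matrix_is_floored_with_unit_diagonal(self):
        S = np.full((3, 3), -0.9)
        np.fill_diagonal(S, 1.0)
        out = nearest_psd_correlation(S, 1e-4)
        assert np.linalg.eigvalsh(out)[0] >= 1e-4 * (1 - 1e-9)
        assert np.allclose(np.diag(out), 1.0)

    def test_correction_flag_set_on_tied_zero_heavy_data(self):
        # two near-duplicate heavy-tie columns force an indefinite skeptic
        rng = np.random.default_rng(0)
        base = rng.standard_normal(300)
        X = np.column_stack([base, base + 1e-12, rng.standard_normal(300),
                             (rng.random(300) > 0.9) * rng.random(300)])
        S = skeptic_from_data(X)
        assert S.matrix.shape == (4, 4)
        assert np.linalg.eigvalsh(S.matrix)[0] >= 1e-4 * (1 - 1e-9)


class TestGlasso:
    def test_large_penalty_gives_exact_empty_graph(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        fit = glasso_fit(S, 0.5)
        assert fit.precision[0, 1] == 0.0
        # off-diagonal penalty: diagonal of the covariance stays at s_ii
        assert np.allclose(np.diag(fit.covariance), 1.0)
        assert np.allclose(np.diag(fit.precision), 1.0)

    def test_vanishing_penalty_recovers_inverse(self):
        rng = np.random.default_rng(2)
        A = rng.standard_normal((80, 4))
        S = np.corrcoef(A, rowvar=False)
        fit = glasso_fit(S, 1e-8)
        assert np.max(np.abs(fit.precision - np.linalg.inv(S))) < 1e-4

    def test_two_by_two_kkt_closed_form(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        fit = glasso_fit(S, 0.1)
        assert fit.precision[0, 1] < 0
        assert abs(fit.covariance[0, 1] - 0.5) == pytest.approx(0.1, abs=1e-6)

    def test_kkt_residual_on_random_pd_inputs(self):
        rng = np.random.default_rng(7)
        for p in (5, 10, 20):
            A = rng.standard_normal((3 * p, p))
            S = np.corrcoef(A, rowvar=False)
            for lam in (0.4, 0.1, 0.02):
                fit = glasso_fit(S, lam)
                assert fit.kkt_residual <= 1e-5

    @pytest.mark.parametrize("p", [2, 3, 4])
    def test_agreement_with_independent_convex_oracle(self, p):
        rng = np.random.default_rng(30 + p)
        for lam in (0.3, 0.1, 0.02):
            A = rng.standard_normal((60, p))
            S = np.corrcoef(A, rowvar=False)
            fit = glasso_fit(S, lam)
            oracle = ista_glasso(S, lam)
            assert np.max(np.abs(fit.precision - oracle)) < 1e-5

    def test_nonpositive_penalty_rejected(self):
        with pytest.raises(ValueError):
            glasso_fit(np.eye(2), 0.0)


class TestCVSelection:
    def test_more_folds_than_rows_errors(self):
        X = np.random.default_rng(0).standard_normal((5, 3))
        with pytest.raises(ValueError):
            cv_select_lambda(X, k=10)

    def test_independent_columns_yield_few_false_edges(self):
        # oracle-computed over fixed seeds: the 1SE-selected graph is empty
        # or nearly so on independent data
        counts = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = rng.standard_normal((1000, 10))
            cv = cv_select_lambda(X, k=10, seed=seed)
            fit = glasso_fit(skeptic_from_data(X).matrix, cv.lambda_star)
            off = ~np.eye(10, dtype=bool)
            counts.append(int((fit.precision[off] != 0).sum() // 2))
        assert np.median(counts) == 0
        assert np.mean([c <= 2 for c in counts]) >= 0.9

    def test_chain_graph_edges_fully_recovered(self):
        graph = GraphSpec.chain(10, 0.4, seed=1)
        ds, groups = single_meal_cohort(graph, n_obs=2000,
                                        zero_probability=0.0, seed=41)
        from mealnets.intake import build_meal_table
        X = build_meal_table(ds, "lunch").matrix()
        est = estimate_network(X, groups, k=10, seed=41)
        found = {(e.u, e.v) for e in est.network.edges}
        true = {(groups[i], groups[j]) for i, j, _ in graph.edges}
        assert true <= found  # recall 1

    def test_edge_count_monotone_along_descending_path(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((300, 8))
        cv = cv_select_lambda(X, k=5, seed=9)
        assert np.all(np.diff(cv.edge_counts, axis=1) >= 0)

    def test_selection_rules_and_grid(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((200, 6))
        cv_min = cv_select_lambda(X, k=5, seed=1, selection_rule="min")
        cv_1se = cv_select_lambda(X, k=5, seed=1, selection_rule="1se")
        assert cv_min.lambda_star == cv_min.lambda_min
        assert cv_1se.lambda_star >= cv_1se.lambda_min
        grid = default_lambda_grid(skeptic_from_data(X).matrix)
        assert len(grid) == 30
        assert np.all(np.diff(grid) < 0)
        assert grid[-1] == pytest.approx(grid[0] * 0.01)


class TestPartialCorrelations:
    def test_two_by_two_formula(self):
        fit = glasso_fit(np.array([[1.0, 0.4], [0.4, 1.0]]), 1e-8)
        omega = np.array([[2.0, -1.0], [-1.0, 2.0]])
        net = partial_correlations(
            type(fit)(precision=omega, covariance=np.linalg.inv(omega),
                      lam=fit.lam, objective=0.0, kkt_residual=0.0, n_iter=1),
            ("a", "b"))
        assert net.edges[0].pcor == pytest.approx(0.5)

    def test_matches_regression_residual_oracle(self):
        # partial correlation given all other variables, from the recursive
        # correlation formula at p = 3
        rng = np.random.default_rng(11)
        A = rng.standard_normal((500, 3))
        A[:, 1] += 0.7 * A[:, 0]
        A[:, 2] -= 0.4 * A[:, 1]
        S = np.corrcoef(A, rowvar=False)
        fit = glasso_fit(S, 1e-9)
        net = partial_correlations(fit, ("a", "b", "c"))
        r = S
        expected_ab = (r[0, 1] - r[0, 2] * r[1, 2]) / np.sqrt(
            (1 - r[0, 2] ** 2) * (1 - r[1, 2] ** 2))
        got = {frozenset((e.u, e.v)): e.pcor for e in net.edges}
        assert got[frozenset(("a", "b"))] == pytest.approx(expected_ab, abs=1e-4)

    def test_diagonal_precision_means_no_edges_no_networks(self):
        from mealnets.copula import GlassoFit
        fit = GlassoFit(precision=np.eye(4), covariance=np.eye(4), lam=0.1,
                        objective=0.0, kkt_residual=0.0, n_iter=1)
        net = partial_correlations(fit, tuple("abcd"))
        assert net.edges == ()
        assert net.networks == ()
        assert len(net.components) == 4

    def test_strong_flag_is_inclusive_at_threshold(self):
        from mealnets.copula import GlassoFit
        omega = np.array([[1.0, -0.30], [-0.30, 1.0]])
        fit = GlassoFit(precision=omega, covariance=np.linalg.inv(omega),
                        lam=0.1, objective=0.0, kkt_residual=0.0, n_iter=1)
        net = partial_correlations(fit, ("a", "b"))
        assert net.edges[0].pcor == pytest.approx(0.30)
        assert net.edges[0].strong
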
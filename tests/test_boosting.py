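import numpy as np
import pytest
from scipy.integrate import simpson

import genestab as gs
from genestab.boosting import (natural_basis, natural_basis_d2,
                               second_derivative_gram, _gene_learners)

from conftest import make_expr, make_phen


@pytest.fixture(scope="module")
def noisy_fixture():
    """Non-separable two-class data (keeps weighted errors interior)."""
    study = gs.generate_study(gs.SyntheticConfig(
        n_samples=50, n_genes=8, block_sizes=(4,), n_informative=3,
        effect_size=0.8, seed=33))
    return study.expression, study.phenotypes


class TestStumpDictionary:
    def test_midpoint_cuts(self):
        expr = make_expr(np.array([[1.0], [2.0], [3.0]]))
        stumps = gs.build_stump_dictionary(expr)
        assert [s.cut for s in stumps] == [1.5, 2.5]

    def test_constant_gene_contributes_none(self, caplog):
        expr = make_expr(np.array([[1.0, 7.0], [2.0, 7.0], [3.0, 7.0]]))
        with caplog.at_level("WARNING"):
            stumps = gs.build_stump_dictionary(expr)
        assert {s.gene_id for s in stumps} == {"g0"}
        assert "g1" in caplog.text

    def test_count_is_genes_times_cuts(self, rng):
        values = rng.integers(0, 5, size=(10, 4)).astype(float)
        expr = make_expr(values)
        stumps = gs.build_stump_dictionary(expr)
        expected = sum(len(np.unique(values[:, j])) - 1 for j in range(4))
        assert len(stumps) == expected

    def test_stump_evaluates_heaviside(self):
        s = gs.DecisionStump("g0", 1.5)
        np.testing.assert_array_equal(s.evaluate([1.0, 1.5, 2.0]), [-1, 1, 1])


class TestAdaBoost:
    def test_first_round_coefficient_from_quarter_error(self):
        # engineered so the best first stump has weighted error 1/4
        expr = make_expr(np.array([[1.0], [2.0], [3.0], [4.0]]))
        phen = make_phen([1, -1, 1, 1])
        res = gs.AdaBoost(expr, phen).fit(T=1)
        assert res.history[0]["eps"] == pytest.approx(0.25)
        assert res.rounds[0][1] == pytest.approx(0.5 * np.log(3))

    def test_reweighted_error_of_chosen_stump_is_half(self, noisy_fixture):
        res = gs.AdaBoost(*noisy_fixture).fit(T=15)
        for h in res.history:
            assert h["reweighted_error"] == pytest.approx(0.5, abs=1e-10)

    def test_separable_toy_reaches_zero_error(self):
        expr = make_expr(np.array([[0.0], [1.0], [2.0], [3.0]]))
        phen = make_phen([-1, -1, 1, 1])
        res = gs.AdaBoost(expr, phen).fit(T=5)
        assert res.train_report.error_rate == 0.0

    def test_loss_non_increasing(self, noisy_fixture):
        res = gs.AdaBoost(*noisy_fixture).fit(T=20)
        losses = [h["loss"] for h in res.history]
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))

    def test_loss_recurrence_per_round(self, noisy_fixture):
        """L_t = L_{t-1} * (e^beta eps + e^-beta (1 - eps)) each round."""
        res = gs.AdaBoost(*noisy_fixture).fit(T=12)
        prev = 1.0  # loss of F = 0
        for h in res.history:
            eps, beta = h["eps"], h["beta"]
            predicted = prev * (np.exp(beta) * eps + np.exp(-beta) * (1 - eps))
            assert h["loss"] == pytest.approx(predicted, abs=1e-10)
            prev = h["loss"]

    def test_sample_order_invariance(self, noisy_fixture):
        expr, phen = noisy_fixture
        res = gs.AdaBoost(expr, phen).fit(T=8)
        perm = np.random.default_rng(1).permutation(expr.n_samples)
        ids = [expr.sample_ids[i] for i in perm]
        res_p = gs.AdaBoost(expr.subset_samples(ids), phen.subset(ids)).fit(T=8)
        assert [(s.gene_id, s.cut) for s, _ in res.rounds] == \
               [(s.gene_id, s.cut) for s, _ in res_p.rounds]
        np.testing.assert_allclose([b for _, b in res.rounds],
                                   [b for _, b in res_p.rounds], atol=1e-12)


class TestExpLoss:
    def test_zero_function_gives_one(self):
        assert gs.exp_loss(np.zeros(5), np.ones(5)) == pytest.approx(1.0)

    def test_log_two_margin_gives_half(self):
        y = np.array([1, -1, 1])
        F = y * np.log(2)
        assert gs.exp_loss(F, y) == pytest.approx(0.5)

    def test_extreme_margins_do_not_produce_nan(self):
        huge = gs.exp_loss([-800.0], [1])
        assert not np.isnan(huge) and huge > 0
        tiny = gs.exp_loss([800.0], [1])
        assert tiny == pytest.approx(0.0)


class TestSplineBasis:
    def test_basis_spans_m_dimensions(self, rng):
        knots = np.array([0.0, 1.0, 2.5, 4.0, 5.0])
        x = rng.uniform(-1, 6, size=50)
        N = natural_basis(x, knots)
        assert N.shape == (50, 5)
        assert np.linalg.matrix_rank(N) == 5

    def test_linear_beyond_boundary_knots(self):
        knots = np.array([0.0, 1.0, 2.0, 3.0])
        outside = np.array([-5.0, -1.0, 3.0, 4.0, 10.0])
        D = natural_basis_d2(outside, knots)
        np.testing.assert_allclose(D, 0.0, atol=1e-10)

    def test_learners_standardized_to_unit_sd(self, rng):
        values = rng.normal(size=40)
        learners = _gene_learners(values, "g", 5)
        assert len(learners) == 4  # m knots -> m - 1 non-constant learners
        for lr in learners:
            assert lr.evaluate(values).std() == pytest.approx(1.0, abs=1e-12)

    def test_few_distinct_values_fall_back_to_linear(self, caplog):
        values = np.array([0.0, 1.0, 0.0, 1.0, 1.0])
        with caplog.at_level("WARNING"):
            learners = _gene_learners(values, "g", 5)
        assert len(learners) == 1 and learners[0].basis_index == 1
        assert "fallback" in caplog.text

    def test_dictionary_size(self, rng):
        expr = make_expr(rng.normal(size=(30, 3)))
        learners = gs.build_spline_dictionary(expr, n_knots=5)
        assert len(learners) == 3 * 4


class TestRoughnessPenalty:
    def test_linear_component_is_zero(self, rng):
        values = rng.normal(size=30)
        learners = _gene_learners(values, "g", 5)
        linear = [lr for lr in learners if lr.basis_index == 1]
        assert gs.roughness_penalty(linear, [2.5]) == pytest.approx(0.0)

    def test_quadratic_in_coefficients(self, rng):
        values = rng.normal(size=30)
        learners = _gene_learners(values, "g", 5)
        p1 = gs.roughness_penalty(learners, [1.0, 0.5, -0.25, 2.0])
        p3 = gs.roughness_penalty(learners, [3.0, 1.5, -0.75, 6.0])
        assert p3 == pytest.approx(9 * p1, rel=1e-12)

    def test_matches_numeric_quadrature(self, rng):
        values = rng.normal(size=50)
        learners = _gene_learners(values, "g", 5)
        lr = learners[2]  # a curved basis function
        knots = np.asarray(lr.knots)
        grid = np.linspace(knots[0], knots[-1], 10001)
        numeric = simpson(lr.d2(grid) ** 2, x=grid)
        closed = gs.roughness_penalty([lr], [1.0])
        assert closed == pytest.approx(numeric, rel=1e-6)

    def test_gram_matrix_symmetric_psd(self):
        knots = np.array([0.0, 0.7, 1.1, 2.0, 3.3])
        omega = second_derivative_gram(knots)
        np.testing.assert_allclose(omega, omega.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(omega) > -1e-10)


class TestAucBoost:
    def test_huge_lambda_forces_linear_components(self, noisy_fixture):
        expr, phen = noisy_fixture
        res = gs.AUCBoost(expr, phen).fit(lambda_grid=(1e6,), T_max=5,
                                          cv_folds=1, seed=0)
        assert res.total_roughness() == pytest.approx(0.0, abs=1e-6)

    def test_objective_non_decreasing_without_penalty(self):
        expr = make_expr(np.array([[0.0], [1.0], [2.0], [3.0], [4.0], [5.0]]))
        phen = make_phen([-1, -1, -1, 1, 1, 1])
        res = gs.AUCBoost(expr, phen).fit(lambda_grid=(0.0,), T_max=6,
                                          cv_folds=1, seed=0)
        path = res.objective_path
        assert all(b >= a - 1e-9 for a, b in zip(path, path[1:]))

    def test_deterministic_under_seed(self, noisy_fixture):
        expr, phen = noisy_fixture
        kw = dict(lambda_grid=(0.01, 1.0), T_max=4, cv_folds=3, seed=5)
        a = gs.AUCBoost(expr, phen).fit(**kw)
        b = gs.AUCBoost(expr, phen).fit(**kw)
        assert a.lambda_ == b.lambda_ and a.n_rounds == b.n_rounds
        assert a.threshold == b.threshold
        np.testing.assert_array_equal(a.train_scores, b.train_scores)

    def test_improves_on_chance_for_signal(self, noisy_fixture):
        expr, phen = noisy_fixture
        res = gs.AUCBoost(expr, phen).fit(lambda_grid=(0.1,), T_max=5,
                                          cv_folds=2, seed=0)
        assert res.train_report.auc > 0.7
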
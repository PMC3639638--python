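import numpy as np
import pytest

import genestab as gs

from conftest import make_expr, make_phen


class TestRankGenes:
    def test_outcome_replica_ranks_first(self, rng):
        y = np.array([-1, -1, 1, 1, -1, 1])
        values = rng.normal(size=(6, 5))
        values[:, 3] = y  # gene identical to the outcome
        ranking = gs.rank_genes(make_expr(values), make_phen(y))
        assert ranking.gene_ids[0] == "g3"
        assert ranking.scores["g3"] == pytest.approx(1.0)

    def test_independent_gene_scores_near_zero(self, rng):
        n = 400
        y = np.where(rng.random(n) < 0.5, 1, -1)
        values = rng.normal(size=(n, 2))
        values[:, 0] = y
        ranking = gs.rank_genes(make_expr(values), make_phen(y))
        assert ranking.scores["g1"] < 0.2
        assert ranking.gene_ids[-1] == "g1"

    def test_ties_keep_input_order(self):
        y = [-1, 1, -1, 1]
        col = np.array([0.0, 1.0, 0.0, 1.0])
        values = np.column_stack([col, col, col])
        ranking = gs.rank_genes(make_expr(values), make_phen(y))
        assert ranking.gene_ids == ["g0", "g1", "g2"]

    def test_constant_gene_scores_zero(self, caplog):
        values = np.array([[1.0, 5.0], [1.0, 6.0], [1.0, 7.0], [1.0, 8.0]])
        with caplog.at_level("WARNING"):
            ranking = gs.rank_genes(make_expr(values), make_phen([-1, 1, -1, 1]))
        assert ranking.scores["g0"] == 0.0

    def test_auc_method_folds_both_directions(self):
        y = [-1, -1, 1, 1]
        values = np.column_stack([[1.0, 2, 3, 4], [4.0, 3, 2, 1]])
        ranking = gs.rank_genes(make_expr(values), make_phen(y), method="auc")
        assert ranking.scores["g0"] == ranking.scores["g1"] == 1.0

    def test_permutation_equivariance(self, rng):
        values = rng.normal(size=(20, 6))
        y = [-1] * 10 + [1] * 10
        base = gs.rank_genes(make_expr(values), make_phen(y))
        perm = rng.permutation(6)
        expr_p = gs.ExpressionMatrix(values[:, perm],
                                     [f"s{i}" for i in range(20)],
                                     [f"g{j}" for j in perm])
        permuted = gs.rank_genes(expr_p, make_phen(y))
        assert permuted.gene_ids == base.gene_ids


class TestBuildWindows:
    def test_study_family_dimensions(self):
        family = gs.build_windows(230, width=70, step=5)
        assert len(family.windows) == 33
        assert family.windows[0] == (1, 70)
        assert family.windows[-1] == (161, 230)

    def test_single_full_window(self):
        family = gs.build_windows(50, width=50, step=7)
        assert family.windows == [(1, 50)]

    def test_zero_step_rejected(self):
        with pytest.raises(ValueError):
            gs.build_windows(100, width=10, step=0)

    def test_overrun_rejected(self):
        with pytest.raises(ValueError):
            gs.build_windows(100, width=70, step=5, n_windows=10)

    def test_step_equals_width_tiles_without_overlap(self):
        family = gs.build_windows(60, width=20, step=20)
        covered = []
        for start, end in family.windows:
            covered.extend(range(start, end + 1))
        assert covered == list(range(1, 61))


class TestEvaluateWindows:
    def test_informative_window_beats_distant_window(self):
        cfg = gs.SyntheticConfig(n_samples=120, n_genes=30, block_sizes=(),
                                 n_informative=10, effect_size=1.5,
                                 subtype_effect=0.0, seed=17)
        study = gs.generate_study(cfg)
        tr, te = gs.train_test_split(study.expression, study.phenotypes, 80, 3)
        ranking = gs.rank_genes(*tr)
        family = gs.build_windows(ranking, width=10, step=10)
        evs = gs.evaluate_windows(family, ranking, tr, te, methods=("dlda",))
        aucs = [e.test.auc for e in evs]
        assert aucs[0] > aucs[-1]
        assert aucs[0] > 0.8

    def test_failures_recorded_not_fatal(self, small_split):
        ranking = gs.rank_genes(*small_split[0])
        family = gs.build_windows(ranking, width=10, step=10, n_windows=2)
        evs = gs.evaluate_windows(family, ranking, small_split[0],
                                  small_split[1], methods=("nope", "dlda"))
        failed = [e for e in evs if e.method == "nope"]
        worked = [e for e in evs if e.method == "dlda"]
        assert all(e.error is not None and e.test is None for e in failed)
        assert all(e.error is None and e.test is not None for e in worked)

    def test_train_metrics_beat_test_for_boosting(self, small_split):
        ranking = gs.rank_genes(*small_split[0])
        family = gs.build_windows(ranking, width=10, step=15, n_windows=2)
        evs = gs.evaluate_windows(family, ranking, small_split[0],
                                  small_split[1], methods=("adaboost",),
                                  method_kwargs={"adaboost": {"T": 30}})
        mean_train = np.mean([e.train.auc for e in evs])
        mean_test = np.mean([e.test.auc for e in evs])
        assert mean_train >= mean_test


class TestResampleStability:
    def test_degenerate_full_subsample(self, small_study):
        expr, phen = small_study.expression, small_study.phenotypes
        rep = gs.resample_stability(expr, phen, expr.n_samples, 5, top_k=10,
                                    seed=0)
        assert set(np.unique(rep.inclusion_rate)) <= {0.0, 1.0}

    def test_rates_sum_to_top_k(self, small_study):
        expr, phen = small_study.expression, small_study.phenotypes
        rep = gs.resample_stability(expr, phen, 30, 25, top_k=12, seed=1)
        assert rep.inclusion_rate.sum() == pytest.approx(12.0)

    def test_strong_gene_nearly_always_included(self, rng):
        n = 100
        y = np.where(rng.random(n) < 0.5, 1, -1)
        values = rng.normal(size=(n, 20))
        values[:, 0] += 1.8 * y  # |r| ~ 0.9 marker gene
        rep = gs.resample_stability(make_expr(values), make_phen(y), 60, 50,
                                    top_k=5, seed=2)
        assert rep.inclusion_rate["g0"] >= 0.95

    def test_exchangeable_null_rates_average_to_ratio(self, rng):
        n, p, k = 80, 30, 6
        y = np.where(rng.random(n) < 0.5, 1, -1)
        rep = gs.resample_stability(make_expr(rng.normal(size=(n, p))),
                                    make_phen(y), 50, 40, top_k=k, seed=3)
        assert rep.inclusion_rate.mean() == pytest.approx(k / p)

    def test_deterministic(self, small_study):
        expr, phen = small_study.expression, small_study.phenotypes
        a = gs.resample_stability(expr, phen, 30, 10, top_k=8, seed=9)
        b = gs.resample_stability(expr, phen, 30, 10, top_k=8, seed=9)
        assert (a.inclusion_rate == b.inclusion_rate).all()

    def test_impossible_subsample_errors(self):
        y = [-1] * 10 + [1] * 10
        expr = make_expr(np.random.default_rng(0).normal(size=(20, 5)))
        with pytest.raises(ValueError, match="single-class"):
            gs.resample_stability(expr, make_phen(y), 1, 5, top_k=2, seed=0)


class TestResamplePrediction:
    def test_null_signal_stays_at_chance(self, rng):
        n = 120
        y = np.where(rng.random(n) < 0.5, 1, -1)
        expr = make_expr(rng.normal(size=(n, 25)))
        reports = gs.resample_prediction(expr, make_phen(y), 70, 25, top_k=8,
                                         seed=4)
        mean_auc = np.mean([r.auc for r in reports])
        assert 0.35 <= mean_auc <= 0.65

    def test_subsample_ranking_degrades_paired_fits(self):
        """Ranking genes on the subsample (selection noise) performs worse on
        the complement, on average, than ranking them on the full data."""
        cfg = gs.SyntheticConfig(n_samples=140, n_genes=60, block_sizes=(8,),
                                 n_informative=8, effect_size=0.8, seed=27)
        study = gs.generate_study(cfg)
        expr, phen = study.expression, study.phenotypes
        full_genes = gs.rank_genes(expr, phen).top(10)
        rng = np.random.default_rng(6)
        y = phen.labels_for(expr.sample_ids)
        noisy, stable = [], []
        for _ in range(25):
            idx = rng.choice(expr.n_samples, size=60, replace=False)
            if len(np.unique(y[idx])) < 2:
                continue
            ids = [expr.sample_ids[i] for i in np.sort(idx)]
            rest = [s for s in expr.sample_ids if s not in set(ids)]
            sub = (expr.subset_samples(ids), phen.subset(ids))
            comp = (expr.subset_samples(rest), phen.subset(rest))
            sub_genes = gs.rank_genes(*sub).top(10)
            noisy.append(gs.DiagonalLDA(*sub, genes=sub_genes).fit()
                         .evaluate(*comp).auc)
            stable.append(gs.DiagonalLDA(*sub, genes=full_genes).fit()
                          .evaluate(*comp).auc)
        assert np.mean(noisy) <= np.mean(stable)

    def test_deterministic(self, small_study):
        expr, phen = small_study.expression, small_study.phenotypes
        a = gs.resample_prediction(expr, phen, 35, 8, top_k=8, seed=11)
        b = gs.resample_prediction(expr, phen, 35, 8, top_k=8, seed=11)
        assert [r.auc for r in a] == [r.auc for r in b]
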
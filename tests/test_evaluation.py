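import numpy as np
import pytest

from _oracles import oracle_auc, oracle_aupr
from gatcda.evaluation import (
    cross_validate,
    grid_search,
    make_folds,
    pr_aupr,
    rank_candidates,
    roc_auc,
    threshold_metrics,
)
from gatcda.predictor import GatcdaPredictor


class TestMakeFolds:
    def test_even_split(self, rng):
        y = np.zeros((5, 4), dtype=int)
        y.flat[rng.choice(20, 10, replace=False)] = 1
        plan = make_folds(y, seed=0, k=5)
        assert [len(f) for f in plan.folds] == [2] * 5

    def test_uneven_split_sizes_differ_by_at_most_one(self, rng):
        y = np.zeros((30, 30), dtype=int)
        y.flat[rng.choice(900, 13, replace=False)] = 1
        sizes = sorted(len(f) for f in make_folds(y, seed=1, k=5).folds)
        assert sizes == [2, 2, 3, 3, 3]

    def test_partition_covers_every_positive_exactly_once(self, rng):
        y = (rng.random((12, 9)) < 0.3).astype(int)
        plan = make_folds(y, seed=2, k=5)
        seen = np.vstack(plan.folds)
        assert len(seen) == y.sum()
        assert len({(i, j) for i, j in seen}) == y.sum()
        assert all(y[i, j] == 1 for i, j in seen)

    def test_same_seed_same_plan(self, rng):
        y = (rng.random((10, 10)) < 0.3).astype(int)
        a = make_folds(y, seed=7, k=5)
        b = make_folds(y, seed=7, k=5)
        for fa, fb in zip(a.folds, b.folds):
            np.testing.assert_array_equal(fa, fb)

    def test_more_folds_than_positives_rejected(self):
        y = np.eye(2, dtype=int)
        with pytest.raises(ValueError):
            make_folds(y, seed=0, k=5)

    def test_training_matrix_zeroes_exactly_the_test_fold(self, rng):
        y = (rng.random((8, 8)) < 0.4).astype(int)
        plan = make_folds(y, seed=3, k=4)
        ytr = plan.training_matrix(y, 0)
        test = plan.folds[0]
        assert (ytr[test[:, 0], test[:, 1]] == 0).all()
        assert ytr.sum() == y.sum() - len(test)


class TestRankingMetrics:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert roc_auc(scores, labels)[0] == 1.0
        assert pr_aupr(scores, labels)[0] == 1.0

    def test_four_point_example(self):
        scores = np.array([0.9, 0.8, 0.7, 0.6])
        labels = np.array([1, 0, 1, 0])
        assert roc_auc(scores, labels)[0] == pytest.approx(0.75)
        assert pr_aupr(scores, labels)[0] == pytest.approx(
            oracle_aupr(scores, labels)
        )

    def test_constant_scores_give_prevalence_aupr(self):
        scores = np.full(10, 0.5)
        labels = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        assert pr_aupr(scores, labels)[0] == pytest.approx(0.3)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))
        with pytest.raises(ValueError):
            pr_aupr(np.array([0.1, 0.2]), np.array([0, 0]))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracles_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 50))
        scores = np.round(rng.random(n), 1)  # rounding forces ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert roc_auc(scores, labels)[0] == pytest.approx(
            oracle_auc(scores, labels), abs=1e-12
        )
        assert pr_aupr(scores, labels)[0] == pytest.approx(
            oracle_aupr(scores, labels), abs=1e-12
        )

    def test_random_scores_near_half_auc(self):
        rng = np.random.default_rng(0)
        n = 4000
        scores = rng.random(n)
        labels = rng.integers(0, 2, n)
        # 3 sigma of the Mann-Whitney null
        n1, n0 = labels.sum(), n - labels.sum()
        sigma = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
        assert abs(roc_auc(scores, labels)[0] - 0.5) < 3 * sigma


class TestThresholdMetrics:
    def test_contingency_arithmetic(self):
        # TP=3, FP=1, TN=5, FN=1
        scores = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        labels = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 1])
        acc, prec = threshold_metrics(scores, labels, threshold=0.5)
        assert acc == pytest.approx(0.8)
        assert prec == pytest.approx(0.75)

    def test_calling_everything_positive_gives_prevalence_precision(self):
        scores = np.ones(10)
        labels = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        acc, prec = threshold_metrics(scores, labels, threshold=0.0)
        assert prec == pytest.approx(0.2)
        assert acc == pytest.approx(0.2)

    def test_perfect_scores(self):
        scores = np.array([5.0, 4.0, -4.0, -5.0])
        labels = np.array([1, 1, 0, 0])
        assert threshold_metrics(scores, labels, 0.0) == (1.0, 1.0)


class TestCrossValidate:
    def test_report_aggregate_is_exact_mean_of_folds(self, small_dataset, quick_params):
        est = GatcdaPredictor(**quick_params)
        rep = cross_validate(
            est,
            small_dataset.y,
            circ_mirna=small_dataset.circ_mirna,
            dis_mrna=small_dataset.dis_mrna,
            symptom_sim=small_dataset.dss,
            k=3,
            seed=0,
        )
        assert len(rep.folds) == 3
        for key in ("auc", "aupr", "accuracy", "precision"):
            assert rep.aggregate[key] == pytest.approx(
                np.mean([f[key] for f in rep.folds])
            )
            assert 0.0 <= rep.aggregate[key] <= 1.0

    def test_same_seed_gives_identical_report(self, small_dataset, quick_params):
        est = GatcdaPredictor(**quick_params)
        kw = dict(
            circ_mirna=small_dataset.circ_mirna,
            dis_mrna=small_dataset.dis_mrna,
            symptom_sim=small_dataset.dss,
            k=3,
            seed=5,
        )
        r1 = cross_validate(est, small_dataset.y, **kw)
        r2 = cross_validate(est, small_dataset.y, **kw)
        assert r1.aggregate == r2.aggregate

    def test_sampled_negative_mode_runs(self, small_dataset, quick_params):
        rep = cross_validate(
            GatcdaPredictor(**quick_params),
            small_dataset.y,
            k=3,
            seed=0,
            negatives="sampled",
        )
        # 1:1 sampling: each fold scored on ~2x its positives
        for f in rep.folds:
            assert 0.0 <= f["auc"] <= 1.0

    def test_no_leakage_into_training_or_features(self, small_dataset, quick_params):
        from gatcda.similarity import entropy_similarity
        from gatcda.data import BipartiteNetwork

        y = small_dataset.y
        rep = cross_validate(
            GatcdaPredictor(**quick_params),
            y,
            k=3,
            seed=1,
            return_estimators=True,
        )
        nc = y.shape[0]
        for fold, est in enumerate(rep.estimators_):
            test = rep.fold_plan.folds[fold]
            ytr = rep.fold_plan.training_matrix(y.matrix, fold)
            # the attention graph contains no test edge
            edges = set(zip(est.graph_.dst.tolist(), est.graph_.src.tolist()))
            for i, j in test:
                assert (i, nc + j) not in edges
            # the entropy similarities were computed from the training matrix
            net = BipartiteNetwork(y.row_index, y.col_index, ytr)
            np.testing.assert_array_equal(
                est.ces_.matrix, entropy_similarity(net, axis="rows").matrix
            )


class TestGridSearch:
    def test_single_point_grid_equals_plain_cv(self, small_dataset, quick_params):
        est = GatcdaPredictor(**quick_params)
        kw = dict(k=3, seed=0)
        auc, best_a, best_b = grid_search(est, small_dataset.y, [0.1], [0.1], **kw)
        plain = cross_validate(est, small_dataset.y, **kw)
        assert auc.shape == (1, 1)
        assert auc[0, 0] == pytest.approx(plain.aggregate["auc"])
        assert (best_a, best_b) == (0.1, 0.1)

    def test_heatmap_shape_matches_grids(self, small_dataset, quick_params):
        est = GatcdaPredictor(**{**quick_params, "epochs": 5})
        auc, _, _ = grid_search(
            est, small_dataset.y, [0.1, 0.9], [0.2, 0.5, 0.8], k=3, seed=0
        )
        assert auc.shape == (2, 3)

    def test_empty_grid_rejected(self, small_dataset, quick_params):
        with pytest.raises(ValueError):
            grid_search(GatcdaPredictor(**quick_params), small_dataset.y, [], [0.1])


class TestRankCandidates:
    def test_returns_k_sorted_candidates(self, small_dataset, quick_params):
        top = rank_candidates(
            GatcdaPredictor(**quick_params),
            small_dataset.y,
            disease=0,
            circ_mirna=small_dataset.circ_mirna,
            k=10,
        )
        assert len(top) == 10
        scores = [s for _, s in top]
        assert scores == sorted(scores, reverse=True)

    def test_k_larger_than_population_returns_everyone(self, small_dataset, quick_params):
        top = rank_candidates(
            GatcdaPredictor(**quick_params), small_dataset.y, disease=0, k=10_000
        )
        assert len(top) == small_dataset.y.shape[0]

    def test_deterministic_under_fixed_seed(self, small_dataset, quick_params):
        args = (GatcdaPredictor(**quick_params), small_dataset.y)
        assert rank_candidates(*args, disease=1, k=5) == rank_candidates(
            *args, disease=1, k=5
        )
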
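"""Ensemble kNN: grid predictions, majority voting, greedy selection."""

import numpy as np
import pytest

from soxfe import tknn
from soxfe.cross_validation import make_partition
from .conftest import make_separable


def brute_force_knn(train_x, train_y, test_row, k, metric, weight):
    """Independent oracle: explicit distance list, explicit weighted vote."""
    from scipy.stats import spearmanr

    dists = []
    for row in train_x:
        if metric == "cityblock":
            d = np.abs(test_row - row).sum()
        elif metric == "euclidean":
            d = np.sqrt(((test_row - row) ** 2).sum())
        elif metric == "cosine":
            na, nb = np.linalg.norm(test_row), np.linalg.norm(row)
            d = 1 - (test_row @ row) / (na * nb) if na > 0 and nb > 0 else 1.0
        else:
            rho = spearmanr(test_row, row).statistic
            d = 1 - (0.0 if np.isnan(rho) else rho)
        dists.append(d)
    order = np.argsort(dists, kind="stable")[:k]
    nd = np.array(dists)[order]
    nl = train_y[order]
    if weight != "equal" and np.any(nd == 0):
        nl, w = nl[nd == 0], np.ones(np.sum(nd == 0))
    elif weight == "equal":
        w = np.ones(k)
    elif weight == "inverse":
        w = 1 / nd
    else:
        w = 1 / nd**2
    classes = np.unique(train_y)
    scores = [w[nl == c].sum() for c in classes]
    return classes[int(np.argmax(scores))]


class TestKnnPredict:
    def test_k1_returns_nearest_label(self):
        x, y = make_separable(20, 3, seed=0)
        cfg = tknn.KNNConfig("euclidean", "equal", 1)
        pred = tknn.knn_predict(x, y, x + 1e-6, cfg)
        assert np.array_equal(pred, y)

    def test_zero_distance_dominates_inverse_weighting(self):
        train = np.array([[0.0, 0], [0, 0.1], [0, 0.2], [0, 0.3]])
        y = np.array([2, 1, 1, 1])
        cfg = tknn.KNNConfig("cityblock", "inverse", 4)
        pred = tknn.knn_predict(train, y, np.array([[0.0, 0]]), cfg)
        assert pred[0] == 2  # the coincident row's label decides alone

    @pytest.mark.parametrize("metric", tknn.DISTANCES)
    @pytest.mark.parametrize("weight", tknn.WEIGHTS)
    def test_matches_brute_force_on_toys(self, metric, weight):
        rng = np.random.default_rng(11)
        for trial in range(5):
            train = rng.normal(size=(6, 4))
            y = np.array([1, 2, 1, 2, 1, 2])
            test = rng.normal(size=(3, 4))
            cfg = tknn.KNNConfig(metric, weight, 3)
            pred = tknn.knn_predict(train, y, test, cfg)
            expected = [
                brute_force_knn(train, y, row, 3, metric, weight) for row in test
            ]
            assert pred.tolist() == expected

    def test_agrees_with_sklearn_on_standard_settings(self):
        """Cross-check against an independent kNN implementation where the
        conventions coincide (no distance ties, no zero distances)."""
        from sklearn.neighbors import KNeighborsClassifier

        rng = np.random.default_rng(12)
        x_train = rng.normal(size=(40, 5))
        y_train = np.repeat([1, 2], 20)
        x_test = rng.normal(size=(15, 5))
        for metric in ("cityblock", "euclidean"):
            for k in (1, 3, 5):
                skl = KNeighborsClassifier(n_neighbors=k, metric=metric)
                skl.fit(x_train, y_train)
                ours = tknn.knn_predict(
                    x_train, y_train, x_test, tknn.KNNConfig(metric, "equal", k)
                )
                # sklearn breaks exact vote ties differently; avoid them
                if k % 2 == 1:
                    assert np.array_equal(ours, skl.predict(x_test))

    def test_spearman_zero_variance_row(self):
        train = np.array([[1.0, 1, 1], [1, 2, 3]])
        y = np.array([1, 2])
        d = tknn.pairwise_distances(np.array([[3.0, 2, 1]]), train, "spearman")
        assert d[0, 0] == pytest.approx(1.0)  # flat row: correlation 0
        assert d[0, 1] == pytest.approx(2.0)  # perfectly anti-correlated

    def test_k_larger_than_training_rejected(self):
        with pytest.raises(ValueError):
            tknn.knn_predict(
                np.zeros((2, 2)), [1, 2], np.zeros((1, 2)),
                tknn.KNNConfig("euclidean", "equal", 5),
            )


class TestParameterOutcomes:
    def test_grid_has_120_deterministic_configs(self):
        grid = tknn.config_grid()
        assert len(grid) == 120
        assert grid[0] == tknn.KNNConfig("cityblock", "squared_inverse", 1)
        assert grid[9].k == 10 and grid[10].weight == "equal"
        assert grid[-1] == tknn.KNNConfig("spearman", "inverse", 10)

    def test_separable_data_reaches_perfect_config(self):
        x, y = make_separable(40, 4, seed=13, gap=12)
        folds = make_partition(y, None, "tenfold", seed=0)
        _, outcomes, accs = tknn.generate_parameter_outcomes(x, y, folds)
        assert outcomes.shape == (120, 40)
        assert accs.max() == 100.0


class TestIterativeMajorityVote:
    def test_produces_118_votes_from_120(self):
        rng = np.random.default_rng(14)
        outcomes = rng.integers(1, 3, size=(120, 30))
        accs = rng.uniform(40, 90, size=120)
        _, voted, vacc = tknn.iterative_majority_vote(outcomes, accs, outcomes[0])
        assert voted.shape == (118, 30) and len(vacc) == 118

    def test_identical_outcomes_vote_to_themselves(self):
        base = np.array([1, 2, 1, 2, 2])
        outcomes = np.tile(base, (10, 1))
        _, voted, _ = tknn.iterative_majority_vote(outcomes, np.full(10, 80.0), base)
        assert np.all(voted == base)

    def test_top3_majority(self):
        outcomes = np.array([[1], [1], [2]])
        accs = np.array([90.0, 80.0, 70.0])
        _, voted, _ = tknn.iterative_majority_vote(outcomes, accs, np.array([1]))
        assert voted[0, 0] == 1

    def test_mode_tie_goes_to_smallest_label(self):
        outcomes = np.array([[2], [1], [1], [2]])
        assert tknn.elementwise_mode(outcomes)[0] == 1

    def test_vote_of_accurate_configs_beats_median(self):
        """One strong config among noisy ones: the top-3 vote should not be
        worse than the median single outcome."""
        rng = np.random.default_rng(15)
        y = rng.integers(1, 3, size=60)
        strong = y.copy()
        strong[:3] = 3 - strong[:3]  # 95% accurate
        noisy = rng.integers(1, 3, size=(9, 60))
        outcomes = np.vstack([strong, noisy])
        accs = np.array([100.0 * np.mean(o == y) for o in outcomes])
        _, voted, vacc = tknn.iterative_majority_vote(outcomes, accs, y)
        assert vacc[0] >= np.median(accs)


class TestGreedyAndComposition:
    def test_greedy_best_tie_to_smallest_index(self):
        outcomes = np.array([[1, 2], [1, 2], [2, 1]])
        accs = np.array([80.0, 80.0, 60.0])
        best, idx = tknn.greedy_best(outcomes, accs)
        assert idx == 0

    def test_full_ensemble_counts_and_determinism(self, small_planted):
        from soxfe import dmpat

        f1, _, _ = dmpat.extract_all(small_planted.segments)
        y = small_planted.labels
        folds = make_partition(y, small_planted.record_ids, "loro", seed=0)
        a = tknn.tknn(f1[:, :30], y, folds)
        assert a.parameter_outcomes.shape[0] == 120
        assert a.voted_outcomes.shape[0] == 118
        assert len(a.accuracies) == 238
        assert a.best_accuracy == a.accuracies.max()
        assert a.best_accuracy >= a.accuracies[:120].max()
        b = tknn.tknn(f1[:, :30], y, folds)
        assert a.to_json() == b.to_json()
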
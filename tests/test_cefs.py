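"""Correlation clustering, trace criteria and the embedded selection loop."""

import numpy as np
import pytest

from chmcs.cefs import (
    auto_threshold,
    class_separability,
    cluster_quality,
    dependency_partition,
    pearson,
    run_cefs,
)
from chmcs.featurebank import FeatureBank
from chmcs.synthdata import PlantedBankRecipe, make_planted_bank


class TestPearson:
    def test_self_and_sign_flip(self, rng):
        x = rng.standard_normal(20)
        assert pearson(x, x) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_frozen_value(self):
        assert pearson(np.array([1.0, 2, 3]), np.array([1.0, 2, 4])) == pytest.approx(
            0.9819805, abs=1e-6)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson(np.ones(5), np.arange(5.0))


class TestPartition:
    def test_identical_columns_cluster_together(self, rng):
        a = rng.standard_normal(30)
        X = np.column_stack([a, a, rng.standard_normal(30)])
        clusters = dependency_partition(X, 0.9)
        lookup = {int(k): i for i, c in enumerate(clusters) for k in c}
        assert lookup[0] == lookup[1] != lookup[2]

    def test_long_dependency_chains_merge(self, rng):
        """a-b and b-c edges put a, b, c in one cluster even if rho(a,c) < t."""
        a = rng.standard_normal(400)
        b = a + 0.28 * rng.standard_normal(400)
        c = b + 0.28 * rng.standard_normal(400)
        X = np.column_stack([a, b, c])
        corr = np.corrcoef(X, rowvar=False)
        t = 0.93
        assert abs(corr[0, 1]) > t and abs(corr[1, 2]) > t and abs(corr[0, 2]) < t
        clusters = dependency_partition(X, t)
        assert len(clusters) == 1 and set(clusters[0]) == {0, 1, 2}

    def test_independent_columns_are_singletons(self, rng):
        X = rng.standard_normal((500, 10))
        clusters = dependency_partition(X, 0.95)
        assert len(clusters) == 10


class TestClusterQuality:
    def test_single_cluster_is_zero(self, rng):
        X = rng.standard_normal((8, 5))
        assert cluster_quality(X, [np.arange(5)]) == pytest.approx(0.0, abs=1e-9)

    def test_duplicated_columns_give_rank_of_between_scatter(self, rng):
        """W = 0 for clusters of exact duplicates; Tr -> rank(B) = 1 on a toy."""
        a = np.array([0.0, 1.0, 2.0])
        b = np.array([5.0, -1.0, 0.5])
        X = np.column_stack([a, a, b, b])
        tr = cluster_quality(X, [np.array([0, 1]), np.array([2, 3])])
        assert tr == pytest.approx(1.0, abs=1e-6)

    def test_bounded_by_sample_count(self, rng):
        X = rng.standard_normal((6, 12))
        clusters = dependency_partition(X, 0.75)
        tr = cluster_quality(X, clusters)
        assert -1e-9 <= tr <= 6 + 1e-9

    def test_uncovered_features_rejected(self, rng):
        with pytest.raises(ValueError, match="partition"):
            cluster_quality(rng.standard_normal((5, 4)), [np.array([0, 1])])


class TestAutoThreshold:
    def test_two_block_structure_recovered(self, rng):
        """Two perfectly separated correlation blocks win at every threshold."""
        base1 = rng.standard_normal(120)
        base2 = rng.standard_normal(120)
        X = np.column_stack([base1 + 0.05 * rng.standard_normal(120) for _ in range(3)]
                            + [base2 + 0.05 * rng.standard_normal(120) for _ in range(3)])
        part = auto_threshold(X)
        assert part.n_clusters == 2
        assert {frozenset(map(int, c)) for c in part.clusters} == {
            frozenset({0, 1, 2}), frozenset({3, 4, 5})}

    def test_all_singletons_tie_breaks_to_largest_threshold(self, rng):
        X = rng.standard_normal((400, 6))
        part = auto_threshold(X)
        if part.n_clusters == 6:  # every threshold yields the same partition
            assert part.t_hat == 0.95

    def test_scores_recorded_for_whole_grid(self, rng):
        part = auto_threshold(rng.standard_normal((50, 8)))
        assert set(part.scores) == {0.75, 0.80, 0.85, 0.90, 0.95}


class TestClassSeparability:
    def test_equal_class_means_zero(self, rng):
        X = rng.standard_normal((40, 3))
        y = np.repeat(["a", "b"], 20)
        Xc = X.copy()
        for cls in ("a", "b"):
            Xc[y == cls] -= Xc[y == cls].mean(axis=0)  # force identical (zero) means
        assert class_separability(Xc, y) == pytest.approx(0.0, abs=1e-9)

    def test_perfectly_separated_scalar_is_one(self):
        X = np.array([[-1.0], [-1.0], [1.0], [1.0]])
        y = np.array(["a", "a", "b", "b"])
        assert class_separability(X, y) == pytest.approx(1.0, abs=1e-6)

    def test_invariance_under_invertible_transform(self, rng):
        X = rng.standard_normal((60, 4)) + np.repeat(rng.standard_normal((3, 4)), 20, axis=0)
        y = np.repeat(["a", "b", "c"], 20)
        A = rng.standard_normal((4, 4)) + 4 * np.eye(4)
        tr1 = class_separability(X, y)
        tr2 = class_separability(X @ A, y)
        assert tr1 == pytest.approx(tr2, abs=1e-6)

    def test_bounds(self, rng):
        X = rng.standard_normal((30, 5))
        y = np.repeat(["a", "b", "c"], 10)
        tr = class_separability(X, y)
        assert -1e-9 <= tr <= 5 + 1e-9

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="2 classes"):
            class_separability(rng.standard_normal((5, 2)), np.repeat("a", 5))


class TestRunCefs:
    def test_planted_informative_feature_selected_first(self):
        bank, truth = make_planted_bank(PlantedBankRecipe(seed=11))
        trace = run_cefs(bank, dmax=8, seed=11)
        assert trace.selected[0] in truth["informative_block"]

    def test_selected_features_in_distinct_clusters(self):
        bank, _ = make_planted_bank(PlantedBankRecipe(seed=5))
        trace = run_cefs(bank, dmax=10, seed=5)
        sd = bank.X.std(axis=0)
        keep = np.flatnonzero(sd > 0)
        Xz = (bank.X[:, keep] - bank.X[:, keep].mean(0)) / sd[keep]
        part = auto_threshold(Xz)
        cid = part.cluster_of()
        pos = {int(k): i for i, k in enumerate(keep)}
        ids = [cid[pos[j]] for j in trace.selected]
        assert len(ids) == len(set(ids))

    def test_single_cluster_selects_exactly_one(self, rng):
        a = rng.standard_normal(30)
        X = np.column_stack([a + 0.01 * rng.standard_normal(30) for _ in range(5)])
        bank = FeatureBank.from_matrix(X, np.repeat(["a", "b"], 15))
        trace = run_cefs(bank, dmax=10, k_folds=2, repetitions=2, seed=0)
        assert len(trace.selected) == 1

    def test_deterministic(self):
        bank, _ = make_planted_bank(PlantedBankRecipe(seed=2))
        t1 = run_cefs(bank, dmax=6, seed=9)
        t2 = run_cefs(bank, dmax=6, seed=9)
        assert t1.selected == t2.selected
        assert t1.r_bar == t2.r_bar
        assert t1.d_hat == t2.d_hat

    def test_dmax_one(self):
        bank, _ = make_planted_bank(PlantedBankRecipe(seed=3))
        trace = run_cefs(bank, dmax=1, seed=3)
        assert len(trace.selected) == 1 and trace.d_hat == 1

    def test_class_smaller_than_k_rejected(self, rng):
        X = rng.standard_normal((5, 4))
        bank = FeatureBank.from_matrix(X, np.array(["a", "a", "a", "b", "b"]))
        with pytest.raises(ValueError, match="fewer than K"):
            run_cefs(bank, k_folds=3)

    def test_greedy_steps_match_exhaustive_search(self):
        """On a small bank every greedy step equals the exhaustive argmax."""
        recipe = PlantedBankRecipe(n_samples=30, n_informative=2, n_copies=1,
                                   n_noise=6, seed=21)  # D = 10
        bank, _ = make_planted_bank(recipe)
        trace = run_cefs(bank, dmax=8, seed=21)

        X = bank.X
        sd = X.std(axis=0)
        keep = np.flatnonzero(sd > 0)
        Xz = (X[:, keep] - X[:, keep].mean(0)) / sd[keep]
        part = auto_threshold(Xz)
        cid = part.cluster_of()
        y = bank.labels
        remaining = set(range(Xz.shape[1]))
        chosen: list[int] = []
        for step_sel in trace.selected:
            scores = {k: class_separability(Xz[:, chosen + [k]], y)
                      for k in sorted(remaining)}
            best = max(sorted(scores), key=lambda k: (scores[k], -k))
            assert int(keep[best]) == step_sel
            chosen.append(best)
            remaining -= {int(m) for m in part.clusters[cid[best]]}
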
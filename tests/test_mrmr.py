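"""mRMR relevance/redundancy scoring and the incremental ranking search."""

import numpy as np
import pytest

from mr2dnm.mrmr import (
    MRMRSelector,
    PairwiseMICache,
    discretize_features,
    exhaustive_best_subset,
    incremental_rank,
    phi_score,
    redundancy_R,
    relevance_D,
)
from mr2dnm.mutual_info import as_nominal, entropy, mutual_information


def brute_force_rank(data, cls):
    """Independent oracle: re-evaluate the incremental objective by explicit
    loops at every step, no caching, no shared code with the implementation."""
    n = len(data)
    relevance = [mutual_information(data[i], cls) for i in range(n)]
    order = []
    remaining = list(range(n))
    while remaining:
        best, best_score = None, -np.inf
        for r in remaining:
            if not order:
                score = relevance[r]
            else:
                red = sum(mutual_information(data[r], data[i]) for i in order) / len(order)
                score = relevance[r] - red
            if score > best_score + 1e-12 or (
                abs(score - best_score) <= 1e-12 and (best is None or r < best)
            ):
                best, best_score = r, score
        order.append(best)
        remaining.remove(best)
    return order


def random_discrete_dataset(rng, n_samples=40, n_features=6):
    data = [as_nominal(rng.integers(0, 3, n_samples)) for _ in range(n_features)]
    cls = as_nominal(rng.integers(0, 2, n_samples))
    return data, cls


@pytest.fixture
def planted(rng):
    """F1 == class, F2 exact copy of F1, F3 noise."""
    n = 80
    y = rng.integers(0, 2, n)
    f1 = y.copy()
    f2 = f1.copy()
    f3 = rng.integers(0, 2, n)
    data = [as_nominal(v) for v in (f1, f2, f3)]
    return data, as_nominal(y)


class TestRelevanceRedundancy:
    def test_singleton_relevance_is_class_mi(self, planted):
        data, cls = planted
        assert relevance_D([0], cls, data) == pytest.approx(
            mutual_information(data[0], cls), abs=1e-12
        )

    def test_independent_features_have_zero_relevance(self, rng):
        cls = as_nominal(np.repeat([0, 1], 20))
        data = [as_nominal(np.tile([0, 1], 20))]  # independent of cls
        assert relevance_D([0], cls, data) == pytest.approx(0.0, abs=1e-12)

    def test_three_feature_relevance_is_mean_of_mis(self, rng):
        data, cls = random_discrete_dataset(rng)
        expected = np.mean([mutual_information(data[i], cls) for i in (0, 2, 4)])
        assert relevance_D([0, 2, 4], cls, data) == pytest.approx(expected, abs=1e-12)

    def test_singleton_redundancy_is_entropy(self, planted):
        data, _ = planted
        assert redundancy_R([0], data) == pytest.approx(entropy(data[0]), abs=1e-12)

    def test_two_identical_features_redundancy_is_entropy(self, planted):
        data, _ = planted
        # all four ordered-pair MIs equal H(x): (1/4)(4 H) = H
        assert redundancy_R([0, 1], data) == pytest.approx(entropy(data[0]), abs=1e-12)

    def test_redundancy_matches_nine_term_double_loop(self, rng):
        data, _ = random_discrete_dataset(rng)
        subset = [1, 3, 5]
        total = sum(
            mutual_information(data[i], data[r]) for i in subset for r in subset
        )
        assert redundancy_R(subset, data) == pytest.approx(total / 9, abs=1e-12)

    def test_empty_subset_rejected(self, planted):
        data, cls = planted
        with pytest.raises(ValueError, match="nonempty"):
            relevance_D([], cls, data)
        with pytest.raises(ValueError, match="nonempty"):
            redundancy_R([], data)

    def test_phi_is_relevance_minus_redundancy(self, rng):
        data, cls = random_discrete_dataset(rng)
        s = [0, 1, 4]
        assert phi_score(s, cls, data) == pytest.approx(
            relevance_D(s, cls, data) - redundancy_R(s, data), abs=1e-12
        )

    def test_phi_of_class_copy_singleton(self, planted):
        data, cls = planted
        expected = mutual_information(data[0], cls) - entropy(data[0])
        assert phi_score([0], cls, data) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.0, abs=1e-12)  # I(x;c)=H(x) when x==c

    def test_noise_only_subset_has_nonpositive_phi(self, rng):
        cls = as_nominal(np.repeat([0, 1], 30))
        noise = [as_nominal(np.tile(np.arange(2), 30)) for _ in range(2)]
        assert phi_score([0, 1], cls, noise) <= 1e-12


class TestIncrementalRank:
    def test_single_feature_dataset(self, planted):
        data, cls = planted
        ranking = incremental_rank(data[:1], cls)
        assert ranking.order == (0,)

    def test_planted_fixture_ranks_informative_first(self, planted):
        data, cls = planted
        ranking = incremental_rank(data, cls)
        assert ranking.order[0] == 0  # F1 == class (ties to F2 break low)
        # step 2 by hand: F2 objective = I(F2;c) - I(F2;F1) = H - H = 0;
        # F3 objective = I(F3;c) - I(F3;F1) which can exceed 0 only by noise
        h = entropy(data[1])
        obj_f2 = mutual_information(data[1], cls) - mutual_information(data[1], data[0])
        assert obj_f2 == pytest.approx(0.0, abs=1e-12) and h > 0
        obj_f3 = mutual_information(data[2], cls) - mutual_information(data[2], data[0])
        expected_second = 1 if obj_f2 >= obj_f3 else 2
        assert ranking.order[1] == expected_second

    def test_matches_brute_force_on_random_datasets(self):
        for trial in range(20):
            rng = np.random.default_rng(1000 + trial)
            data, cls = random_discrete_dataset(rng)
            assert list(incremental_rank(data, cls).order) == brute_force_rank(data, cls)

    def test_prefix_m_matches_full_ranking_prefix(self, rng):
        data, cls = random_discrete_dataset(rng)
        full = incremental_rank(data, cls, m="all")
        top3 = incremental_rank(data, cls, m=3)
        assert full.order[:3] == top3.order

    def test_log_base_invariance(self, rng):
        data, cls = random_discrete_dataset(rng)
        nat = incremental_rank(data, cls, log_base=None)
        bits = incremental_rank(data, cls, log_base=2)
        assert nat.order == bits.order

    def test_column_order_invariance(self, rng):
        data, cls = random_discrete_dataset(rng)
        perm = [3, 0, 5, 1, 4, 2]
        permuted = [data[i] for i in perm]
        orig = incremental_rank(data, cls).order
        shuf = incremental_rank(permuted, cls).order
        assert [perm[i] for i in shuf] == list(orig)

    def test_step_scores_step1_is_pure_relevance(self, rng):
        data, cls = random_discrete_dataset(rng)
        ranking = incremental_rank(data, cls)
        assert ranking.step_scores[0] == pytest.approx(
            max(ranking.relevance_per_feature), abs=1e-12
        )

    def test_zero_features_rejected(self, planted):
        _, cls = planted
        with pytest.raises(ValueError):
            incremental_rank([], cls)

    def test_pairwise_mi_cache_evaluates_each_pair_once(self, rng):
        data, cls = random_discrete_dataset(rng)
        cache = PairwiseMICache(data)
        for i in range(6):
            for r in range(6):
                cache.pair_mi(i, r)
        assert cache.n_pair_evaluations == 6 * 7 // 2  # unordered incl. self


class TestExhaustiveOracle:
    def test_k1_is_max_relevance_feature(self, planted):
        data, cls = planted
        best = exhaustive_best_subset(data, cls, k=1)
        rel = [phi_score([i], cls, data) for i in range(3)]
        assert best == (int(np.argmax(rel)),)
        assert incremental_rank(data, cls).order[0] in best or len(best) == 1

    def test_k_equals_n_is_full_set(self, planted):
        data, cls = planted
        assert exhaustive_best_subset(data, cls, k=3) == (0, 1, 2)

    def test_n6_k2_matches_15_way_enumeration(self, rng):
        from itertools import combinations

        data, cls = random_discrete_dataset(rng)
        best = exhaustive_best_subset(data, cls, k=2)
        scores = {s: phi_score(s, cls, data) for s in combinations(range(6), 2)}
        assert len(scores) == 15
        assert phi_score(best, cls, data) == pytest.approx(max(scores.values()), abs=1e-12)

    def test_refuses_large_instances(self, rng):
        data = [as_nominal(rng.integers(0, 2, 10)) for _ in range(20)]
        cls = as_nominal(rng.integers(0, 2, 10))
        with pytest.raises(ValueError, match="too large"):
            exhaustive_best_subset(data, cls, k=3)

    def test_incremental_first_pick_equals_exhaustive_k1_equal_entropy(self):
        """Agreement of the two search routes at size 1.

        With self-pairs in the redundancy sum, Phi({i}) = I(x_i; c) - H(x_i),
        while the incremental step 1 maximizes pure relevance; the two argmaxes
        coincide when all features share the same entropy, so the fixture
        uses shuffled copies of one balanced code vector.
        """
        base = np.tile([0, 1, 2], 12)
        for trial in range(5):
            rng = np.random.default_rng(50 + trial)
            data = [as_nominal(rng.permutation(base)) for _ in range(6)]
            cls = as_nominal(rng.integers(0, 2, base.size))
            assert (incremental_rank(data, cls).order[0],) == exhaustive_best_subset(
                data, cls, k=1
            )


class TestMRMRSelectorEstimator:
    def test_fit_transform_selects_top_k_columns(self, rng):
        n = 120
        y = rng.integers(0, 2, n)
        X = np.column_stack([y, rng.integers(0, 2, n), rng.integers(0, 2, n)]).astype(float)
        sel = MRMRSelector(k=1, nominal_columns=(0, 1, 2)).fit(X, y)
        assert sel.order_[0] == 0
        Xt = sel.transform(X)
        assert Xt.shape == (n, 1)
        np.testing.assert_array_equal(Xt[:, 0], X[:, 0])

    def test_sklearn_clone_and_params_roundtrip(self):
        from sklearn.base import clone

        sel = MRMRSelector(k=2, discretizer="equal_width", n_bins=5)
        cloned = clone(sel)
        assert cloned.get_params() == sel.get_params()

    def test_pipeline_composition(self, rng):
        from sklearn.pipeline import Pipeline

        from mr2dnm.training import DendriticNeuronClassifier

        n = 80
        y = rng.integers(0, 2, n)
        X = np.column_stack([y, rng.integers(0, 2, n)]).astype(float)
        # seed picked from a recorded converging run; BP on this model has
        # seed-dependent local minima, which is why the protocol averages runs
        pipe = Pipeline(
            [
                ("select", MRMRSelector(k=1, nominal_columns=(0, 1))),
                ("dnm", DendriticNeuronClassifier(n_branches=3, k=5, eta=0.5,
                                                  iterations=200, seed=0)),
            ]
        )
        pipe.fit(X, y)
        assert (pipe.predict(X) == y).mean() > 0.9
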
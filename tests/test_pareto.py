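import numpy as np
import pytest

from molgrow import (
    assign_rewards,
    dominates,
    non_dominated_sort,
    order_within_frontier,
    pareto_ranking,
)
from molgrow.pareto import ParetoRanking


def brute_force_frontiers(scores):
    """O(N^2 n) reference implementation by repeated maximal-set removal."""
    n = len(scores)
    remaining = set(range(n))
    fronts = []
    while remaining:
        front = [
            i
            for i in remaining
            if not any(dominates(scores[j], scores[i]) for j in remaining if j != i)
        ]
        fronts.append(sorted(front))
        remaining -= set(front)
    return fronts


class TestDominance:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ((0.8, 0.9), (0.7, 0.9), True),
            ((0.7, 0.9), (0.8, 0.9), False),
            ((0.5, 0.5), (0.5, 0.5), False),  # no strict improvement
            ((0.8, 0.5), (0.5, 0.8), False),  # mutually non-dominated
            ((0.5, 0.8), (0.8, 0.5), False),
        ],
    )
    def test_definition(self, x, y, expected):
        assert dominates(x, y) is expected

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dominates((1, 2), (1, 2, 3))


class TestNonDominatedSort:
    def test_mutually_non_dominated_is_one_frontier(self):
        scores = np.array([[1.0, 0.0], [0.5, 0.5], [0.0, 1.0]])
        fronts = non_dominated_sort(scores)
        assert len(fronts) == 1 and len(fronts[0]) == 3

    def test_strict_chain_gives_singletons(self):
        scores = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        fronts = non_dominated_sort(scores)
        assert [sorted(f.tolist()) for f in fronts] == [[2], [1], [0]]

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 61))
            d = int(rng.integers(1, 5))
            scores = np.round(rng.random((n, d)), 2)
            got = [sorted(f.tolist()) for f in non_dominated_sort(scores)]
            assert got == brute_force_frontiers(scores)

    def test_union_is_population(self, rng):
        scores = rng.random((40, 3))
        fronts = non_dominated_sort(scores)
        assert sorted(np.concatenate(fronts).tolist()) == list(range(40))


class TestWithinFrontierOrdering:
    def test_singleton_unchanged(self):
        assert order_within_frontier([3], [frozenset()] * 4) == [3]

    def test_duplicates_are_most_crowded(self):
        fps = [frozenset({1, 2}), frozenset({1, 2}), frozenset({7, 8, 9})]
        ordered = order_within_frontier([0, 1, 2], fps, labels=["a", "a", "b"])
        assert set(ordered[:2]) == {0, 1}  # identical pair first (lowest rank)
        assert ordered[2] == 2

    def test_permutation_invariant(self, rng):
        fps = [frozenset(map(int, rng.choice(50, 8, replace=False))) for _ in range(6)]
        labels = [f"m{i}" for i in range(6)]
        a = order_within_frontier([0, 1, 2, 3, 4, 5], fps, labels)
        b = order_within_frontier([5, 3, 1, 0, 4, 2], fps, labels)
        assert a == b


class TestRewards:
    def test_worked_example_two_undesired_three_desired(self):
        ranking = ParetoRanking(
            frontier=np.ones(5, dtype=int),
            rank=np.arange(1, 6),
            desired=np.array([False, False, True, True, True]),
            n_desired=3,
            n_undesired=2,
        )
        np.testing.assert_allclose(
            assign_rewards(ranking), [0.25, 0.5, 2 / 3, 5 / 6, 1.0]
        )

    def test_all_desired_branch(self):
        ranking = ParetoRanking(
            frontier=np.ones(4, dtype=int),
            rank=np.arange(1, 5),
            desired=np.ones(4, dtype=bool),
            n_desired=4,
            n_undesired=0,
        )
        np.testing.assert_allclose(assign_rewards(ranking), [0.625, 0.75, 0.875, 1.0])

    def test_reward_intervals_on_random_populations(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 61))
            scores = rng.random((n, 2))
            desired = rng.random(n) < rng.random()
            fps = [
                frozenset(map(int, rng.choice(64, 8, replace=False)))
                for _ in range(n)
            ]
            ranking = pareto_ranking(scores, desired, fps)
            rewards = assign_rewards(ranking)
            assert (rewards > 0).all() and (rewards <= 1).all()
            if ranking.n_undesired:
                assert rewards[~ranking.desired].max() <= 0.5
            if ranking.n_desired:
                assert rewards[ranking.desired].min() > 0.5

    def test_rank_is_a_bijection(self, rng):
        n = 50
        ranking = pareto_ranking(
            rng.random((n, 3)),
            rng.random(n) < 0.5,
            [frozenset({i}) for i in range(n)],
        )
        assert sorted(ranking.rank.tolist()) == list(range(1, n + 1))

    def test_ranking_consistent_with_dominance(self, rng):
        """Within a desirability class, a molecule never outranks one that
        dominates it."""
        n = 30
        scores = rng.random((n, 2))
        desired = rng.random(n) < 0.5
        ranking = pareto_ranking(
            scores, desired, [frozenset({i}) for i in range(n)]
        )
        for i in range(n):
            for j in range(n):
                if desired[i] == desired[j] and dominates(scores[i], scores[j]):
                    assert ranking.rank[i] > ranking.rank[j]

    def test_invalid_molecules_rank_below_valid_undesired(self, rng):
        n = 20
        scores = rng.random((n, 2))
        valid = np.ones(n, dtype=bool)
        valid[:5] = False
        ranking = pareto_ranking(
            scores,
            np.zeros(n, dtype=bool),
            [frozenset({i}) for i in range(n)],
            valid=valid,
        )
        assert ranking.rank[:5].max() < ranking.rank[5:].min()
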
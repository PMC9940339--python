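"""Pareto dominance, non-dominated sorting and rank-based reward shaping.

A population of score vectors (all objectives oriented larger-is-better) is
sorted into Pareto frontiers.  Within a frontier, molecules are ordered by
their mean Tanimoto distance to the other frontier members, crowded
molecules (small mean distance) first, which pushes reward toward diverse
solutions.  Undesired molecules occupy global ranks 1..N_undesired and
desired molecules the ranks above; the final reward

    R* = k / (2 N_und)                      for undesired,
    R* = 1/2 + (k - N_und) / (2 N_des)      for desired,

with 1-based rank k, lands undesired rewards in (0, 0.5] and desired ones
in (0.5, 1].
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .metrics import tanimoto_distance


def dominates(x, y) -> bool:
    """True iff x >= y on every objective and x > y on at least one."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("score vectors differ in length")
    return bool(np.all(x >= y) and np.any(x > y))


def non_dominated_sort(scores: np.ndarray) -> list[np.ndarray]:
    """Fast non-dominated sorting into frontiers (frontier 1 first).

    Vectorized pairwise dominance; frontier f+1 is the non-dominated set
    after removing frontiers <= f.  The union of frontiers is 0..N-1.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError("scores must be an N x n matrix")
    n = scores.shape[0]
    ge = np.all(scores[:, None, :] >= scores[None, :, :], axis=2)
    gt = np.any(scores[:, None, :] > scores[None, :, :], axis=2)
    dom = ge & gt  # dom[i, j]: i dominates j
    n_dominators = dom.sum(axis=0)
    frontiers = []
    assigned = np.zeros(n, dtype=bool)
    while not assigned.all():
        current = np.flatnonzero((n_dominators == 0) & ~assigned)
        if current.size == 0:  # pragma: no cover - defensive
            raise RuntimeError("non-dominated sort failed to progress")
        frontiers.append(current)
        assigned[current] = True
        n_dominators = n_dominators - dom[current].sum(axis=0)
    return frontiers


def order_within_frontier(
    frontier: Sequence[int],
    fingerprints: Sequence[frozenset],
    labels: Optional[Sequence[str]] = None,
) -> list[int]:
    """Order frontier members ascending by mean Tanimoto distance to the rest.

    The most crowded molecules (smallest mean distance) come first and so
    receive the lowest ranks/rewards.  Ties break deterministically on the
    provided labels (canonical SMILES) then the index.
    """
    frontier = list(frontier)
    if len(frontier) <= 1:
        return frontier
    fps = [fingerprints[i] for i in frontier]
    mean_dist = []
    for a in range(len(frontier)):
        d = [tanimoto_distance(fps[a], fps[b]) for b in range(len(frontier)) if b != a]
        mean_dist.append(float(np.mean(d)))
    keys = labels if labels is not None else [str(i) for i in frontier]
    order = sorted(
        range(len(frontier)),
        key=lambda a: (mean_dist[a], keys[frontier[a]] if labels is not None else keys[a], frontier[a]),
    )
    return [frontier[a] for a in order]


@dataclass
class ParetoRanking:
    """Frontier assignment and global 1-based rank k per molecule."""

    frontier: np.ndarray  # frontier number per molecule (1 = non-dominated)
    rank: np.ndarray  # global 1-based rank k; permutation of 1..N
    desired: np.ndarray  # boolean
    n_desired: int
    n_undesired: int


def pareto_ranking(
    scores: np.ndarray,
    desired: Sequence[bool],
    fingerprints: Sequence[frozenset],
    valid: Optional[Sequence[bool]] = None,
    labels: Optional[Sequence[str]] = None,
) -> ParetoRanking:
    """Rank a population: all undesired below all desired, each group ordered
    by frontier (worse frontiers lower) and, within a frontier, by mean
    Tanimoto distance (crowded first).

    Invalid molecules (``valid`` false) count as undesired and take the
    lowest ranks of all.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    desired = np.asarray(desired, dtype=bool)
    valid = np.ones(n, dtype=bool) if valid is None else np.asarray(valid, dtype=bool)
    desired = desired & valid

    frontier_no = np.zeros(n, dtype=np.int64)
    ordered_valid: list[int] = []
    valid_idx = np.flatnonzero(valid)
    if valid_idx.size:
        frontiers = non_dominated_sort(scores[valid_idx])
        for f, members in enumerate(frontiers, start=1):
            global_members = [int(valid_idx[m]) for m in members]
            frontier_no[global_members] = f
            ordered_valid.append((f, global_members))
    # ranks are assigned bottom-up: invalid first, then valid undesired from
    # the worst frontier upward, then desired likewise
    rank = np.zeros(n, dtype=np.int64)
    k = 0
    for i in sorted(np.flatnonzero(~valid)):
        k += 1
        rank[i] = k
    for want_desired in (False, True):
        for f, members in sorted(ordered_valid, key=lambda t: -t[0]):
            group = [i for i in members if desired[i] == want_desired]
            ordered = order_within_frontier(group, fingerprints, labels)
            for i in ordered:
                k += 1
                rank[i] = k
    assert k == n
    return ParetoRanking(
        frontier=frontier_no,
        rank=rank,
        desired=desired,
        n_desired=int(desired.sum()),
        n_undesired=int(n - desired.sum()),
    )


def assign_rewards(ranking: ParetoRanking) -> np.ndarray:
    """Final reward R* in (0, 1]; desired strictly above 0.5."""
    k = ranking.rank.astype(float)
    n_und, n_des = ranking.n_undesired, ranking.n_desired
    rewards = np.empty_like(k)
    und = ~ranking.desired
    if n_und:
        rewards[und] = k[und] / (2.0 * n_und)
    if n_des:
        rewards[ranking.desired] = 0.5 + (k[ranking.desired] - n_und) / (2.0 * n_des)
    return rewards
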
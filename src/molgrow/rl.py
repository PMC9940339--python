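"""Pareto-ranked policy-gradient reinforcement learning.

REINFORCE over complete generation episodes: the exploitation net G_theta
samples molecules for a batch of scaffolds (a fraction epsilon of the batch
is answered by a frozen exploration net G_phi), the environment scores
them, the population is Pareto-ranked into rewards R* in (0, 1], and only
G_theta is updated by ascending

    J(theta) = sum_t log G(y_t | y_{1:t-1}) * R*(y_{1:T}).

For the graph model each step contributes the log-probabilities of all
four decisions (atom, bond, connected index, current index).
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem

from . import nn
from .environment import Environment, ecfp6_bitset
from .generators import GraphTransformerGenerator
from .metrics import solow_polasky_diversity
from .pareto import assign_rewards, pareto_ranking

logger = logging.getLogger("molgrow")


@dataclass
class RLConfig:
    """Exploration rate epsilon in [0, 1], epoch/batch sizes and the seed."""

    epsilon: float = 0.0
    epochs: int = 30
    batch_size: int = 64
    lr: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError(f"epsilon must lie in [0, 1], got {self.epsilon}")


def policy_gradient_step(logprob: nn.Tensor, rewards: np.ndarray, optimizer) -> bool:
    """One REINFORCE ascent step on -(mean of logprob * reward).

    Returns False (batch skipped) when the gradient is non-finite.
    """
    rewards = np.asarray(rewards, dtype=np.float32)
    loss = -(logprob * nn.Tensor(rewards)).mean()
    optimizer.zero_grad()
    loss.backward()
    if not optimizer.grads_finite():
        logger.warning("skipping policy-gradient batch: non-finite gradient")
        return False
    optimizer.step()
    return True


def _sample_grouped(gen, scaffolds: list[str], seed: int):
    """Sample one molecule per scaffold entry, batching duplicate scaffolds.

    Returns (smiles list, episode payloads) aligned with ``scaffolds``.
    The payload is what ``episode_logprob`` needs: graph matrices for the
    graph model, (x, y) index rows for sequence models.
    """
    counts = Counter(scaffolds)
    by_scaffold: dict[str, list] = {}
    is_graph = isinstance(gen, GraphTransformerGenerator)
    for i, (scaffold, k) in enumerate(sorted(counts.items())):
        if is_graph:
            df = gen.sample([scaffold], k=k, seed=seed + i, return_matrices=True)
            by_scaffold[scaffold] = list(zip(df.smiles, df.matrix))
        else:
            df = gen.sample([scaffold], k=k, seed=seed + i)
            payloads = []
            x = gen.vocab_.encode(scaffold, gen.max_len)
            for s in df.smiles:
                try:
                    y = gen.vocab_.encode(s, gen.max_len)
                except ValueError:
                    y = None
                payloads.append((s, (x, y)))
            by_scaffold[scaffold] = payloads
    smiles, payloads = [], []
    for scaffold in scaffolds:
        s, payload = by_scaffold[scaffold].pop()
        smiles.append(s)
        payloads.append(payload)
    return smiles, payloads


def _agent_logprob(agent, payloads):
    if isinstance(agent, GraphTransformerGenerator):
        return agent.episode_logprob(payloads), np.ones(len(payloads), bool)
    usable = np.array([p[1] is not None for p in payloads])
    xs = np.stack([p[0] for p, u in zip(payloads, usable) if u])
    ys = np.stack([p[1] for p, u in zip(payloads, usable) if u])
    return agent.episode_logprob(xs, ys), usable


def rl_train(
    agent,
    frozen,
    scaffold_pool: list[str],
    env: Environment,
    cfg: RLConfig,
) -> pd.DataFrame:
    """Train the exploitation net in place; returns per-epoch metrics.

    Each epoch draws ``batch_size`` scaffolds with replacement; a fraction
    epsilon is answered by the frozen exploration net and the rest by the
    agent.  All generated molecules are scored, Pareto-ranked and rewarded,
    and only the agent's parameters are updated; the frozen net's
    parameters are untouched throughout.
    """
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(agent.net_.parameters(), lr=cfg.lr, clip_norm=5.0)
    history = []
    for epoch in range(1, cfg.epochs + 1):
        batch = [
            scaffold_pool[i]
            for i in rng.integers(0, len(scaffold_pool), size=cfg.batch_size)
        ]
        explore = rng.random(cfg.batch_size) < cfg.epsilon
        agent_scaffolds = [s for s, e in zip(batch, explore) if not e]
        frozen_scaffolds = [s for s, e in zip(batch, explore) if e]
        seed = int(rng.integers(0, 2**31 - 1))
        smiles, payloads = [], []
        with nn.no_grad():
            if agent_scaffolds:
                s, p = _sample_grouped(agent, agent_scaffolds, seed)
                smiles += s
                payloads += p
            if frozen_scaffolds:
                s, p = _sample_grouped(frozen, frozen_scaffolds, seed + 1)
                smiles += s
                payloads += p

        scored = env.score_population(smiles)
        objectives = env.objective_matrix(scored)
        valid = scored["valid"].to_numpy()
        desired = scored["desired"].to_numpy()
        canon = [
            Chem.CanonSmiles(s) if v else "" for s, v in zip(smiles, valid)
        ]
        fps = [ecfp6_bitset(c) if c else frozenset() for c in canon]
        ranking = pareto_ranking(objectives, desired, fps, valid=valid, labels=canon)
        rewards = assign_rewards(ranking)

        logprob, usable = _agent_logprob(agent, payloads)
        policy_gradient_step(logprob, rewards[usable], opt)

        distinct = {c for c in canon if c}
        history.append(
            {
                "epoch": epoch,
                "desirability": float(desired.mean()),
                "uniqueness": len(distinct) / len(smiles),
                "diversity": solow_polasky_diversity(
                    [ecfp6_bitset(c) for c in distinct]
                )
                if distinct
                else 0.0,
                "mean_reward": float(rewards.mean()),
            }
        )
        logger.info(
            "rl epoch %d: desirability %.3f mean_reward %.3f",
            epoch, history[-1]["desirability"], history[-1]["mean_reward"],
        )
    return pd.DataFrame(history)
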
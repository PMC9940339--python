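import copy

import numpy as np
import pytest

from molgrow import RLConfig, policy_gradient_step, rl_train
from molgrow import nn
from molgrow.nn import Tensor


class TestPolicyGradientStep:
    def test_toy_bandit_converges_to_rewarded_token(self):
        """REINFORCE on a 2-token bandit: reward 1 for token 0, 0 otherwise.

        The probability of the rewarded token must approach 1; this is the
        analytic REINFORCE behaviour on a single-step episode.
        """
        rng = np.random.default_rng(0)
        logits = Tensor(np.zeros(2, dtype=np.float32), requires_grad=True)
        opt = nn.Adam([logits], lr=0.05, clip_norm=None)
        for _ in range(200):
            probs = np.exp(logits.data) / np.exp(logits.data).sum()
            actions = rng.choice(2, size=16, p=probs)
            rewards = (actions == 0).astype(np.float32)
            logprob = nn.gather_last(
                nn.log_softmax(
                    logits.reshape(1, 2) * Tensor(np.ones((16, 1), np.float32)),
                    axis=-1,
                ),
                actions,
            )
            policy_gradient_step(logprob, rewards, opt)
        final = np.exp(logits.data) / np.exp(logits.data).sum()
        assert final[0] > 0.95

    def test_zero_reward_episodes_contribute_no_gradient(self):
        logits = Tensor(np.zeros((4, 3), dtype=np.float32), requires_grad=True)
        opt = nn.Adam([logits], lr=0.1)
        lp = nn.gather_last(nn.log_softmax(logits, axis=-1), np.zeros(4, np.int64))
        loss = -(lp * Tensor(np.zeros(4, np.float32))).mean()
        opt.zero_grad()
        loss.backward()
        assert np.allclose(logits.grad, 0.0)

    def test_constant_reward_is_reward_weighted_likelihood(self):
        """With all rewards equal the update direction equals the scaled
        likelihood gradient (degenerate REINFORCE)."""
        base = np.random.default_rng(1).normal(size=(5, 3)).astype(np.float32)
        targets = np.array([0, 1, 2, 0, 1])

        def grad_with_rewards(r):
            logits = Tensor(base.copy(), requires_grad=True)
            lp = nn.gather_last(nn.log_softmax(logits, axis=-1), targets)
            loss = -(lp * Tensor(np.full(5, r, np.float32))).mean()
            loss.backward()
            return logits.grad.copy()

        np.testing.assert_allclose(
            grad_with_rewards(2.0), 2.0 * grad_with_rewards(1.0), atol=1e-6
        )

    def test_non_finite_gradient_skips_batch(self):
        logits = Tensor(np.zeros(2, np.float32), requires_grad=True)
        opt = nn.Adam([logits], lr=0.1)
        bad = Tensor(np.array([np.inf, 0.0], np.float32), requires_grad=True)
        lp = bad * logits.sum()
        assert policy_gradient_step(lp, np.ones(2), opt) is False
        assert np.allclose(logits.data, 0.0)


class TestRLConfig:
    @pytest.mark.parametrize("eps", [-0.1, 1.5])
    def test_epsilon_out_of_range_rejected(self, eps):
        with pytest.raises(ValueError):
            RLConfig(epsilon=eps)


class TestRlTrain:
    def test_epsilon_zero_never_queries_frozen_net(
        self, trained_graph_generator, affinity_env, small_scaffold_pool
    ):
        agent = copy.deepcopy(trained_graph_generator)
        frozen = copy.deepcopy(trained_graph_generator)
        calls = {"n": 0}
        original = frozen.sample

        def counting_sample(*args, **kwargs):
            calls["n"] += 1
            return original(*args, **kwargs)

        frozen.sample = counting_sample
        rl_train(
            agent, frozen, small_scaffold_pool, affinity_env,
            RLConfig(epsilon=0.0, epochs=2, batch_size=8, seed=0),
        )
        assert calls["n"] == 0

    def test_frozen_net_parameters_bit_identical(
        self, trained_graph_generator, affinity_env, small_scaffold_pool
    ):
        agent = copy.deepcopy(trained_graph_generator)
        frozen = copy.deepcopy(trained_graph_generator)
        before = {k: v.copy() for k, v in frozen.net_.state_dict().items()}
        rl_train(
            agent, frozen, small_scaffold_pool, affinity_env,
            RLConfig(epsilon=0.5, epochs=3, batch_size=8, seed=0),
        )
        after = frozen.net_.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_agent_parameters_do_change(
        self, trained_graph_generator, affinity_env, small_scaffold_pool
    ):
        agent = copy.deepcopy(trained_graph_generator)
        frozen = copy.deepcopy(trained_graph_generator)
        before = {k: v.copy() for k, v in agent.net_.state_dict().items()}
        history = rl_train(
            agent, frozen, small_scaffold_pool, affinity_env,
            RLConfig(epsilon=0.2, epochs=2, batch_size=8, seed=0),
        )
        after = agent.net_.state_dict()
        assert any(not np.array_equal(before[k], after[k]) for k in before)
        assert {"epoch", "desirability", "uniqueness", "diversity", "mean_reward"} <= set(
            history.columns
        )
        assert len(history) == 2
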
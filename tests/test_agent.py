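"""Q-learning machinery: targets, schedules, exploration, replay, training."""

import numpy as np
import pytest

from genetriage.agent import (
    AgentConfig,
    DQNAgent,
    QNetwork,
    ReplayBuffer,
    Transition,
    bellman_target,
    epsilon_at,
    q_values,
    select_action,
    sync_target,
    train_step,
)


def tabular_q_target(r, done, gamma, max_next_q):
    """Independent re-statement of the tabular Q-learning backup."""
    if done:
        return r
    return r + gamma * max_next_q


class TestBellman:
    def test_matches_independent_tabular_backup_on_random_inputs(self, rng):
        for _ in range(1000):
            r = float(rng.normal())
            gamma = float(rng.uniform(0, 1))
            q = float(rng.normal())
            done = bool(rng.random() < 0.5)
            assert bellman_target(r, done, gamma, q) == tabular_q_target(r, done, gamma, q)

    @pytest.mark.parametrize(
        "r,done,gamma,q,expected",
        [(1.0, False, 0.8, 2.0, 2.6), (0.199, True, 0.8, 5.0, 0.199), (1.5, False, 0.0, 9.0, 1.5)],
    )
    def test_hand_cases(self, r, done, gamma, q, expected):
        assert bellman_target(r, done, gamma, q) == pytest.approx(expected)


class TestEpsilonSchedule:
    def test_exact_values(self):
        cfg = AgentConfig()
        assert epsilon_at(0, cfg) == 1.0
        assert epsilon_at(500_000, cfg) == pytest.approx(0.1)
        assert epsilon_at(250_000, cfg) == pytest.approx(0.55)
        assert epsilon_at(750_000, cfg) == pytest.approx(0.1)

    def test_linearity_everywhere(self):
        cfg = AgentConfig(epsilon_anneal_steps=1000)
        for step in range(0, 1000, 37):
            assert epsilon_at(step, cfg) == pytest.approx(1.0 - 0.9 * step / 1000)


class TestSelectAction:
    def test_greedy_takes_argmax_and_ties_break_low(self, rng):
        q = np.array([0.1, 0.9, 0.9, -1.0])
        assert select_action(q, [0, 1, 2, 3], epsilon=0.0, rng=rng) == 1
        tied = np.array([0.5, 0.5, 0.5])
        assert select_action(tied, [0, 1, 2], epsilon=0.0, rng=rng) == 0
        assert select_action(tied, [2, 1], epsilon=0.0, rng=rng) == 1

    def test_full_exploration_is_uniform(self):
        rng = np.random.default_rng(42)
        q = np.array([5.0, 0.0, -5.0])
        counts = np.zeros(3)
        n = 10_000
        for _ in range(n):
            counts[select_action(q, [0, 1, 2], epsilon=1.0, rng=rng)] += 1
        # each within 4 binomial SDs of n/3
        sd = np.sqrt(n * (1 / 3) * (2 / 3))
        assert np.all(np.abs(counts - n / 3) < 4 * sd)

    def test_empty_legal_set_rejected(self, rng):
        with pytest.raises(ValueError):
            select_action(np.array([1.0]), [], 0.0, rng)


class TestReplayBuffer:
    def make_transition(self, tag):
        s = np.array([float(tag)])
        return Transition(s, 0, 0.0, s, False)

    def test_fifo_eviction(self):
        buf = ReplayBuffer(2)
        for i in range(3):
            buf.push(self.make_transition(i))
        assert len(buf) == 2
        assert sorted(t.state[0] for t in buf._items) == [1.0, 2.0]

    def test_sample_from_singleton_and_empty(self, rng):
        buf = ReplayBuffer(5)
        with pytest.raises(ValueError):
            buf.sample(1, rng)
        buf.push(self.make_transition(7))
        batch = buf.sample(4, rng)
        assert len(batch) == 4 and all(t.state[0] == 7.0 for t in batch)

    def test_sampling_is_uniform(self):
        rng = np.random.default_rng(1)
        buf = ReplayBuffer(10)
        for i in range(10):
            buf.push(self.make_transition(i))
        counts = np.zeros(10)
        n = 20_000
        for t in buf.sample(n, rng):
            counts[int(t.state[0])] += 1
        chi2 = ((counts - n / 10) ** 2 / (n / 10)).sum()
        assert chi2 < 27.88  # chi-square df=9, p=0.001

    def test_capacity_never_exceeded_under_random_pushes(self, rng):
        buf = ReplayBuffer(17)
        for i in range(int(rng.integers(50, 200))):
            buf.push(self.make_transition(i))
            assert len(buf) <= 17


class TestQNetwork:
    def test_zeroed_output_heads_give_zero_q(self, rng):
        net = QNetwork(4, head_sizes=(3, 2), seed=0)
        for i in range(2):
            net.params[f"Wh{i}"][:] = 0.0
            net.params[f"bh{i}"][:] = 0.0
        heads = q_values(rng.normal(size=4), net)
        assert all(np.all(h == 0.0) for h in heads)

    def test_forward_is_deterministic(self):
        net = QNetwork(3, head_sizes=(2,), seed=5)
        state = np.array([0.3, -0.2, 1.0])
        assert np.array_equal(q_values(state, net)[0], q_values(state, net)[0])

    def test_hand_computed_two_layer_relu_forward(self):
        net = QNetwork(2, head_sizes=(2,), hidden_units=1, seed=0)
        net.params["W1"] = np.array([[2.0], [-1.0]])
        net.params["b1"] = np.array([0.5])
        net.params["W2"] = np.array([[3.0]])
        net.params["b2"] = np.array([-1.0])
        net.params["Wh0"] = np.array([[1.0, -2.0]])
        net.params["bh0"] = np.array([0.25, 0.5])
        state = np.array([1.0, 1.0])
        # h1 = relu(2 - 1 + 0.5) = 1.5 ; h2 = relu(4.5 - 1) = 3.5
        # q = [3.5 + 0.25, -7 + 0.5]
        assert q_values(state, net)[0] == pytest.approx([3.75, -6.5])
        assert q_values(np.array([-1.0, 2.0]), net)[0] == pytest.approx([0.25, 0.5])

    def test_dimension_mismatch_rejected(self):
        net = QNetwork(4, seed=0)
        with pytest.raises(ValueError):
            net.forward(np.zeros(5))


class TestTrainStep:
    def test_fixed_point_has_zero_loss_and_unchanged_parameters(self):
        net = QNetwork(2, head_sizes=(2,), seed=0)
        for k in ("Wh0", "bh0"):
            net.params[k][:] = 0.0
        tgt = net.clone()
        batch = [Transition(np.zeros(2), 0, 0.0, np.zeros(2), True)] * 4
        before = {k: v.copy() for k, v in net.params.items()}
        loss = train_step(net, tgt, batch, AgentConfig(batch_size=4))
        assert loss == 0.0
        for k in before:
            assert np.array_equal(net.params[k], before[k])

    def test_single_transition_regression_converges(self):
        cfg = AgentConfig(learning_rate=0.02, gamma=0.8)
        net = QNetwork(2, head_sizes=(2,), seed=1)
        tgt = net.clone()
        tr = Transition(np.array([1.0, -1.0]), 1, 0.7, np.zeros(2), True)
        losses = [train_step(net, tgt, [tr], cfg) for _ in range(400)]
        assert losses[-1] < 1e-6
        assert losses[-1] < losses[0]

    def test_loss_finite_on_random_minibatches(self, rng):
        cfg = AgentConfig(learning_rate=1e-3)
        net = QNetwork(3, head_sizes=(3, 2), seed=2)
        tgt = net.clone()
        batch = [
            Transition(rng.normal(size=3), int(rng.integers(0, 5)), float(rng.normal()),
                       rng.normal(size=3), bool(rng.random() < 0.3),
                       next_legal=(0, 1, 4))
            for _ in range(16)
        ]
        loss = train_step(net, tgt, batch, cfg)
        assert np.isfinite(loss) and loss >= 0

    def test_empty_minibatch_rejected(self):
        net = QNetwork(2, seed=0)
        with pytest.raises(ValueError):
            train_step(net, net.clone(), [], AgentConfig())


class TestTargetSync:
    def test_sync_copies_and_then_decouples(self, rng):
        net = QNetwork(3, head_sizes=(2,), seed=0)
        tgt = QNetwork(3, head_sizes=(2,), seed=99)
        state = rng.normal(size=3)
        sync_target(net, tgt)
        assert np.array_equal(q_values(state, net)[0], q_values(state, tgt)[0])
        frozen = q_values(state, tgt)[0].copy()
        net.params["W1"] += 0.5  # online update after sync
        assert np.array_equal(q_values(state, tgt)[0], frozen)

    def test_architecture_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            sync_target(QNetwork(3, head_sizes=(2,), seed=0), QNetwork(3, head_sizes=(3,), seed=0))

    def test_sync_schedule_count(self):
        cfg = AgentConfig(target_sync_every=50, batch_size=10 ** 9)  # batch too big: no training
        agent = DQNAgent(state_dim=2, config=cfg, seed=0)
        rng = np.random.default_rng(0)
        T = 1234
        tr = Transition(np.zeros(2), 0, 0.0, np.zeros(2), False)
        for _ in range(T):
            agent.observe(tr, rng)
        assert agent.sync_count == T // 50


def test_agent_checkpoint_round_trip(tmp_path, rng):
    agent = DQNAgent(state_dim=5, config=AgentConfig(batch_size=2), seed=3)
    state = rng.normal(size=5)
    agent.save(tmp_path / "agent.npz")
    loaded = DQNAgent.load(tmp_path / "agent.npz")
    for a, b in zip(q_values(state, agent.network), q_values(state, loaded.network)):
        assert np.array_equal(a, b)
    assert loaded.config == agent.config
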
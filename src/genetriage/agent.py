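"""Deep Q-network decision maker for article triage.

A small feed-forward approximator of Q(s, a): two hidden ReLU layers of 20
units, followed by two separate linear output heads — one scoring the
per-article decisions {select, reject, read}, the other the continuation
decision (stop). The agent issues one action per environment step, chosen
ε-greedily over the concatenation of the heads restricted to the legal
actions; training uses standard Q-learning targets
(r + γ·max Q_target(s′) over the next state's legal actions, no bootstrap
at terminals), experience replay, a linear ε anneal, and periodic
target-network synchronisation.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .nn import SGD, softmax

__all__ = [
    "AgentConfig",
    "Transition",
    "ReplayBuffer",
    "QNetwork",
    "DQNAgent",
    "q_values",
    "bellman_target",
    "epsilon_at",
    "select_action",
    "train_step",
    "sync_target",
]


@dataclass
class AgentConfig:
    """Q-learning hyper-parameters. Defaults are the full-scale settings.

    ``learning_rate`` is the SGD step for the Q-network; ``step_penalty``
    is the per-action cost added to every reward; ε anneals linearly from
    ``epsilon_start`` to ``epsilon_end`` over ``epsilon_anneal_steps``
    transitions and stays constant afterwards.
    """

    gamma: float = 0.8
    learning_rate: float = 2.5e-5
    replay_capacity: int = 500_000
    epsilon_start: float = 1.0
    epsilon_end: float = 0.1
    epsilon_anneal_steps: int = 500_000
    target_sync_every: int = 5_000
    hidden_units: int = 20
    hidden_layers: int = 2
    step_penalty: float = -0.001
    batch_size: int = 64

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must be in [0, 1]")
        if self.epsilon_end > self.epsilon_start:
            raise ValueError("epsilon_end must not exceed epsilon_start")
        if self.replay_capacity <= 0:
            raise ValueError("replay_capacity must be positive")


@dataclass
class Transition:
    """One replay record (s, a, r, s′, done).

    ``action`` indexes the network's concatenated action space (all output
    heads laid end to end). ``next_legal`` lists the actions legal in
    ``s′``; the Bellman bootstrap maximises over it (irrelevant at
    terminals, where no bootstrap happens). ``None`` means all actions.
    """

    state: np.ndarray
    action: int
    reward: float
    next_state: np.ndarray
    done: bool
    next_legal: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.state.shape != self.next_state.shape:
            raise ValueError("state and next_state must share a dimension")


class ReplayBuffer:
    """Bounded FIFO of transitions; uniform sampling with replacement."""

    def __init__(self, capacity: int):
        self._items: deque[Transition] = deque(maxlen=capacity)
        self.capacity = capacity

    def __len__(self) -> int:
        return len(self._items)

    def push(self, transition: Transition) -> None:
        self._items.append(transition)

    def sample(self, n: int, rng: np.random.Generator) -> list[Transition]:
        if not self._items:
            raise ValueError("cannot sample from an empty replay buffer")
        idx = rng.integers(0, len(self._items), size=n)
        return [self._items[i] for i in idx]


class QNetwork:
    """2-hidden-layer ReLU MLP with multiple linear output heads."""

    def __init__(
        self,
        state_dim: int,
        head_sizes: tuple[int, ...] = (3, 2),
        hidden_units: int = 20,
        seed: int = 0,
    ):
        self.state_dim = state_dim
        self.head_sizes = tuple(head_sizes)
        self.hidden_units = hidden_units
        rng = np.random.default_rng(seed)
        h = hidden_units
        self.params: dict[str, np.ndarray] = {
            "W1": rng.normal(0.0, 1.0 / np.sqrt(state_dim), (state_dim, h)),
            "b1": np.zeros(h),
            "W2": rng.normal(0.0, 1.0 / np.sqrt(h), (h, h)),
            "b2": np.zeros(h),
        }
        for i, size in enumerate(self.head_sizes):
            self.params[f"Wh{i}"] = rng.normal(0.0, 1.0 / np.sqrt(h), (h, size))
            self.params[f"bh{i}"] = np.zeros(size)

    def forward(self, states: np.ndarray):
        """Q-values per head for a (B, state_dim) batch, with cache."""
        if states.ndim == 1:
            states = states[None, :]
        if states.shape[1] != self.state_dim:
            raise ValueError(f"state dimension {states.shape[1]} != {self.state_dim}")
        z1 = states @ self.params["W1"] + self.params["b1"]
        h1 = np.maximum(z1, 0.0)
        z2 = h1 @ self.params["W2"] + self.params["b2"]
        h2 = np.maximum(z2, 0.0)
        heads = [h2 @ self.params[f"Wh{i}"] + self.params[f"bh{i}"] for i in range(len(self.head_sizes))]
        cache = {"states": states, "h1": h1, "h2": h2, "z1": z1, "z2": z2}
        return heads, cache

    def backward(self, dheads: list[np.ndarray], cache: dict) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        h1, h2, states = cache["h1"], cache["h2"], cache["states"]
        dh2 = np.zeros_like(h2)
        for i, dq in enumerate(dheads):
            grads[f"Wh{i}"] = h2.T @ dq
            grads[f"bh{i}"] = dq.sum(axis=0)
            dh2 += dq @ self.params[f"Wh{i}"].T
        dz2 = dh2 * (cache["z2"] > 0)
        grads["W2"] = h1.T @ dz2
        grads["b2"] = dz2.sum(axis=0)
        dh1 = dz2 @ self.params["W2"].T
        dz1 = dh1 * (cache["z1"] > 0)
        grads["W1"] = states.T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        return grads

    def clone(self) -> "QNetwork":
        other = QNetwork(self.state_dim, self.head_sizes, self.hidden_units, seed=0)
        other.params = {k: v.copy() for k, v in self.params.items()}
        return other


def q_values(state: np.ndarray, network: QNetwork) -> list[np.ndarray]:
    """Per-head Q-value vectors for a single state."""
    heads, _ = network.forward(np.asarray(state, dtype=np.float64))
    return [h[0] for h in heads]


def bellman_target(r: float, done: bool, gamma: float, max_next_q: float) -> float:
    """Q-learning target: ``r`` at terminals, else ``r + γ·max_a′ Q(s′, a′)``."""
    return r if done else r + gamma * max_next_q


def epsilon_at(step: int, config: AgentConfig) -> float:
    """Linear anneal from ε_start (step 0) to ε_end (anneal end), then flat."""
    if step >= config.epsilon_anneal_steps:
        return config.epsilon_end
    frac = step / config.epsilon_anneal_steps
    return config.epsilon_start + frac * (config.epsilon_end - config.epsilon_start)


def select_action(
    q: np.ndarray,
    legal_actions: list[int],
    epsilon: float,
    rng: np.random.Generator,
) -> int:
    """ε-greedy over one head's Q-vector, restricted to legal actions.

    Greedy ties break toward the lowest action index, for determinism.
    """
    if not legal_actions:
        raise ValueError("legal_actions must be non-empty")
    if rng.random() < epsilon:
        return int(legal_actions[rng.integers(0, len(legal_actions))])
    legal = sorted(legal_actions)
    best = legal[0]
    for a in legal[1:]:
        if q[a] > q[best]:
            best = a
    return int(best)


def train_step(
    network: QNetwork,
    target_network: QNetwork,
    minibatch: list[Transition],
    config: AgentConfig,
) -> float:
    """One SGD step on the squared Bellman error.

    Actions index the concatenated action space across heads. Targets come
    from the frozen target network, maximised over each transition's legal
    next actions; terminal transitions do not bootstrap. Returns the
    scalar loss before the update.
    """
    if not minibatch:
        raise ValueError("minibatch must be non-empty")
    B = len(minibatch)
    states = np.stack([t.state for t in minibatch])
    next_states = np.stack([t.next_state for t in minibatch])
    rewards = np.array([t.reward for t in minibatch])
    dones = np.array([t.done for t in minibatch])
    actions = np.array([t.action for t in minibatch])

    target_heads, _ = target_network.forward(next_states)
    target_q = np.concatenate(target_heads, axis=1)
    n_actions = target_q.shape[1]
    legal_mask = np.zeros((B, n_actions), dtype=bool)
    for i, t in enumerate(minibatch):
        if t.next_legal is None:
            legal_mask[i] = True
        else:
            legal_mask[i, list(t.next_legal)] = True
    masked = np.where(legal_mask, target_q, -np.inf)
    max_next = masked.max(axis=1)
    max_next = np.where(np.isfinite(max_next), max_next, 0.0)
    targets = np.where(dones, rewards, rewards + config.gamma * max_next)

    heads, cache = network.forward(states)
    q_all = np.concatenate(heads, axis=1)
    q_sel = q_all[np.arange(B), actions]
    err = q_sel - targets
    loss = float(np.mean(err**2))

    dq_all = np.zeros_like(q_all)
    dq_all[np.arange(B), actions] = 2.0 * err / B
    dheads = []
    offset = 0
    for size in network.head_sizes:
        dheads.append(dq_all[:, offset : offset + size])
        offset += size
    grads = network.backward(dheads, cache)
    SGD(config.learning_rate).step(network.params, grads)
    return loss


def sync_target(network: QNetwork, target_network: QNetwork) -> None:
    """Copy online parameters into the target network (bit-equal)."""
    for k, v in network.params.items():
        if k not in target_network.params or target_network.params[k].shape != v.shape:
            raise ValueError(f"architecture mismatch at parameter {k!r}")
    for k, v in network.params.items():
        target_network.params[k] = v.copy()


# Concatenated action indices for the triage network (heads of size 3+2).
# The decision head ranks per-article actions; the continuation head owns
# the stop action. Index 3 ("continue") is the continuation head's no-op
# slot: deferring to the decision head is expressed by simply not stopping,
# so that slot is never selected or trained.
A_SELECT, A_REJECT, A_READ, A_CONTINUE, A_STOP = 0, 1, 2, 3, 4


class DQNAgent:
    """Online + target Q-networks, replay buffer, and step bookkeeping."""

    def __init__(self, state_dim: int, config: AgentConfig | None = None, seed: int = 0):
        self.config = config or AgentConfig()
        self.network = QNetwork(
            state_dim, head_sizes=(3, 2), hidden_units=self.config.hidden_units, seed=seed
        )
        self.target_network = self.network.clone()
        self.buffer = ReplayBuffer(self.config.replay_capacity)
        self.step_count = 0
        self.sync_count = 0

    def act(
        self,
        state: np.ndarray,
        legal_actions: list[int],
        epsilon: float,
        rng: np.random.Generator,
    ) -> tuple[int, float]:
        """Pick one action ε-greedily over the legal concatenated-action
        subset; also return the softmax margin (top1 − top2 over legal
        actions), used downstream as the selection-confidence feature."""
        q = np.concatenate(q_values(state, self.network))
        a = select_action(q, legal_actions, epsilon, rng)
        legal_q = softmax(np.array([q[i] for i in sorted(legal_actions)]))
        if len(legal_q) > 1:
            top = np.sort(legal_q)[::-1]
            margin = float(top[0] - top[1])
        else:
            margin = 1.0
        return a, margin

    def observe(self, transition: Transition, rng: np.random.Generator) -> float | None:
        """Push a transition, take one training step (once the buffer can
        fill a batch), and sync the target network on schedule."""
        self.buffer.push(transition)
        self.step_count += 1
        loss = None
        if len(self.buffer) >= self.config.batch_size:
            batch = self.buffer.sample(self.config.batch_size, rng)
            loss = train_step(self.network, self.target_network, batch, self.config)
        if self.step_count % self.config.target_sync_every == 0:
            sync_target(self.network, self.target_network)
            self.sync_count += 1
        return loss

    def epsilon(self) -> float:
        return epsilon_at(self.step_count, self.config)

    def save(self, path: str | Path) -> None:
        meta = {
            "config": asdict(self.config),
            "state_dim": self.network.state_dim,
            "step_count": self.step_count,
            "sync_count": self.sync_count,
        }
        arrays = {f"online_{k}": v for k, v in self.network.params.items()}
        arrays.update({f"target_{k}": v for k, v in self.target_network.params.items()})
        np.savez(path, __meta__=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "DQNAgent":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        agent = cls(meta["state_dim"], AgentConfig(**meta["config"]), seed=0)
        agent.step_count = meta["step_count"]
        agent.sync_count = meta["sync_count"]
        for k in agent.network.params:
            agent.network.params[k] = data[f"online_{k}"]
            agent.target_network.params[k] = data[f"target_{k}"]
        return agent
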
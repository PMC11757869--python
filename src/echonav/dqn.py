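"""Deep Q-network for probe-search behaviour generation.

The action-value function is a small dense network mapping the normalized
XYC state — probe grid coordinates scaled to [0, 1] plus the detection
confidence — to one value per action (eight moves and STOP).  The network has
``D`` hidden layers of 100 rectifier units and a linear 9-unit output, and is
trained with epsilon-greedy exploration, a replay buffer sampled in
minibatches, temporal-difference targets from a periodically synced target
network, and Adam updates.  Everything is driven by explicit
``numpy.random.Generator`` streams so a training run is bit-reproducible from
its seed.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .confmap import ConfidenceMap, GridGeometry
from .environment import (
    ACTIONS,
    Action,
    EnvState,
    RewardParams,
    reset,
    step,
)

__all__ = [
    "QNetworkConfig",
    "TrainConfig",
    "Transition",
    "QNetwork",
    "ReplayBuffer",
    "DQNAgent",
    "encode_state",
    "select_action_epsilon_greedy",
    "td_target",
    "train",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class QNetworkConfig:
    """Architecture: 3 inputs (X, Y, C normalized), ``depth_d`` hidden layers
    of ``width`` rectifier units, 9 linear outputs (one per action)."""

    depth_d: int = 2
    width: int = 100
    input_dim: int = 3
    output_dim: int = 9
    activation: str = "relu"
    init_seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_d < 1:
            raise ValueError("need at least one hidden layer")
        if self.activation != "relu":
            raise ValueError("only the rectifier nonlinearity is supported")


@dataclass(frozen=True)
class Transition:
    state_features: np.ndarray
    action: int
    reward: float
    next_state_features: np.ndarray
    done: bool


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (conservative small-scale DQN practice).

    Epsilon decays linearly from ``epsilon_start`` to ``epsilon_end`` over
    ``epsilon_decay_episodes`` (default: 60% of ``episodes``).  One gradient
    step is taken every ``learn_every`` environment steps once the buffer
    holds ``min_replay_before_learning`` transitions; the target network is
    synced every ``target_sync_interval`` learner steps.
    """

    episodes: int = 5000
    discount_gamma: float = 0.95
    learning_rate: float = 5e-4
    batch_size: int = 32
    replay_capacity: int = 10000
    min_replay_before_learning: int = 500
    epsilon_start: float = 1.0
    epsilon_end: float = 0.05
    epsilon_decay_episodes: int | None = None
    target_sync_interval: int = 200
    learn_every: int = 4
    episode_cap: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.discount_gamma <= 1.0:
            raise ValueError("discount_gamma must lie in [0, 1]")
        for e in (self.epsilon_start, self.epsilon_end):
            if not 0.0 <= e <= 1.0:
                raise ValueError("epsilon values must lie in [0, 1]")
        for name in ("episodes", "batch_size", "replay_capacity", "episode_cap",
                     "target_sync_interval", "learn_every"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def decay_episodes(self) -> int:
        if self.epsilon_decay_episodes is not None:
            return self.epsilon_decay_episodes
        return max(1, int(0.6 * self.episodes))

    def epsilon_at(self, episode: int) -> float:
        frac = min(1.0, episode / self.decay_episodes)
        return self.epsilon_start + frac * (self.epsilon_end - self.epsilon_start)


def encode_state(
    position: tuple[int, int], c_here: float, geometry: GridGeometry
) -> np.ndarray:
    """Normalize the XYC state to ``[0, 1]^3``: grid indices divided by the
    maximal index (0 on a degenerate single-cell axis), confidence as is."""
    x = position[0] / (geometry.n_x - 1) if geometry.n_x > 1 else 0.0
    y = position[1] / (geometry.n_y - 1) if geometry.n_y > 1 else 0.0
    return np.array([x, y, c_here], dtype=float)


def select_action_epsilon_greedy(
    q: np.ndarray, epsilon: float, rng: np.random.Generator
) -> Action:
    """Uniform random action with probability epsilon, else greedy argmax
    (ties broken by the fixed action order)."""
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    if rng.random() < epsilon:
        return ACTIONS[int(rng.integers(len(ACTIONS)))]
    return ACTIONS[int(np.argmax(q))]


def td_target(reward: float, next_q: np.ndarray, done: bool, gamma: float) -> float:
    """One-step temporal-difference target: r, or r + gamma * max_a' Q'."""
    if done:
        return float(reward)
    return float(reward + gamma * np.max(next_q))


class QNetwork:
    """Dense rectifier network with Adam; plain numpy, float64."""

    def __init__(self, config: QNetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.init_seed)
        dims = [config.input_dim] + [config.width] * config.depth_d + [config.output_dim]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            scale = np.sqrt(2.0 / fan_in)
            self.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self._adam_m = [np.zeros_like(w) for w in self.weights + self.biases]
        self._adam_v = [np.zeros_like(w) for w in self.weights + self.biases]
        self._adam_t = 0

    @property
    def n_params(self) -> int:
        return sum(w.size for w in self.weights) + sum(b.size for b in self.biases)

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = np.atleast_2d(x)
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ w + b, 0.0)
        out = h @ self.weights[-1] + self.biases[-1]
        return out[0] if np.ndim(x) == 1 else out

    def _forward_cached(self, x: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        acts = [x]
        h = x
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ w + b, 0.0)
            acts.append(h)
        return h @ self.weights[-1] + self.biases[-1], acts

    def sgd_step(
        self, x: np.ndarray, action_idx: np.ndarray, targets: np.ndarray, lr: float
    ) -> float:
        """One Adam step on the half-MSE of the selected actions' Q-values."""
        n = x.shape[0]
        out, acts = self._forward_cached(x)
        idx = np.arange(n)
        err = np.zeros_like(out)
        err[idx, action_idx] = (out[idx, action_idx] - targets) / n
        loss = float(0.5 * np.sum((out[idx, action_idx] - targets) ** 2) / n)

        grads_w: list[np.ndarray] = [np.empty(0)] * len(self.weights)
        grads_b: list[np.ndarray] = [np.empty(0)] * len(self.biases)
        delta = err
        for layer in range(len(self.weights) - 1, -1, -1):
            grads_w[layer] = acts[layer].T @ delta
            grads_b[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ self.weights[layer].T) * (acts[layer] > 0.0)

        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        params = self.weights + self.biases
        grads = grads_w + grads_b
        for i, (p, g) in enumerate(zip(params, grads)):
            self._adam_m[i] = b1 * self._adam_m[i] + (1 - b1) * g
            self._adam_v[i] = b2 * self._adam_v[i] + (1 - b2) * g * g
            m_hat = self._adam_m[i] / (1 - b1**self._adam_t)
            v_hat = self._adam_v[i] / (1 - b2**self._adam_t)
            p -= lr * m_hat / (np.sqrt(v_hat) + eps)
        return loss

    def copy_weights_from(self, other: "QNetwork") -> None:
        for mine, theirs in zip(self.weights, other.weights):
            mine[...] = theirs
        for mine, theirs in zip(self.biases, other.biases):
            mine[...] = theirs


class ReplayBuffer:
    """Fixed-capacity circular transition store; evicts oldest first."""

    def __init__(self, capacity: int, feature_dim: int = 3):
        self.capacity = capacity
        self._s = np.zeros((capacity, feature_dim))
        self._a = np.zeros(capacity, dtype=np.int64)
        self._r = np.zeros(capacity)
        self._s2 = np.zeros((capacity, feature_dim))
        self._d = np.zeros(capacity, dtype=bool)
        self._n = 0
        self._head = 0

    def __len__(self) -> int:
        return self._n

    def push(self, t: Transition) -> None:
        i = self._head
        self._s[i] = t.state_features
        self._a[i] = t.action
        self._r[i] = t.reward
        self._s2[i] = t.next_state_features
        self._d[i] = t.done
        self._head = (i + 1) % self.capacity
        self._n = min(self._n + 1, self.capacity)

    def sample(self, batch_size: int, rng: np.random.Generator):
        idx = rng.integers(self._n, size=batch_size)
        return self._s[idx], self._a[idx], self._r[idx], self._s2[idx], self._d[idx]


@dataclass
class DQNAgent:
    """A trained (or initialized) Q-network bound to its grid geometry.

    Exposes the planner-facing protocol ``action_values(position, c)``.
    """

    network: QNetwork
    geometry: GridGeometry

    def q_values(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        if features.shape != (self.network.config.input_dim,):
            raise ValueError(f"expected {self.network.config.input_dim} features")
        return self.network.forward(features)

    def action_values(self, position: tuple[int, int], c_here: float) -> np.ndarray:
        return self.q_values(encode_state(position, c_here, self.geometry))


def train(
    maps: Sequence[ConfidenceMap],
    start: tuple[int, int],
    reward_params: RewardParams,
    net_config: QNetworkConfig,
    train_config: TrainConfig,
) -> tuple[DQNAgent, list[dict]]:
    """Train one Q-network across a cohort of subject maps.

    Maps are scheduled round-robin by episode index so a run is reproducible
    from its seeds alone.  Returns the agent and a per-episode log of
    ``{"episode", "return", "epsilon", "moves"}``.
    """
    if len(maps) == 0:
        raise ValueError("cohort must be non-empty")
    geometry = maps[0].geometry
    net = QNetwork(replace(net_config, init_seed=net_config.init_seed))
    target = QNetwork(net_config)
    target.copy_weights_from(net)
    rng = np.random.default_rng(train_config.seed)
    buffer = ReplayBuffer(train_config.replay_capacity, net_config.input_dim)

    learner_steps = 0
    env_steps = 0
    curve: list[dict] = []
    for episode in range(train_config.episodes):
        cmap = maps[episode % len(maps)]
        state: EnvState = reset(cmap, start)
        epsilon = train_config.epsilon_at(episode)
        ep_return = 0.0
        while not state.done:
            features = encode_state(state.position, state.c_here, geometry)
            q = net.forward(features)
            action = select_action_epsilon_greedy(q, epsilon, rng)
            rec = step(state, action, cmap, reward_params, train_config.episode_cap)
            next_features = encode_state(
                rec.state_after.position, rec.state_after.c_here, geometry
            )
            buffer.push(
                Transition(features, ACTIONS.index(action), rec.reward,
                           next_features, rec.state_after.done)
            )
            ep_return += rec.reward
            state = rec.state_after
            env_steps += 1

            if (
                len(buffer) >= train_config.min_replay_before_learning
                and env_steps % train_config.learn_every == 0
            ):
                s, a, r, s2, d = buffer.sample(train_config.batch_size, rng)
                next_q = target.forward(s2)
                targets = np.where(
                    d, r, r + train_config.discount_gamma * next_q.max(axis=1)
                )
                net.sgd_step(s, a, targets, train_config.learning_rate)
                learner_steps += 1
                if learner_steps % train_config.target_sync_interval == 0:
                    target.copy_weights_from(net)

        curve.append(
            {
                "episode": episode,
                "return": ep_return,
                "epsilon": epsilon,
                "moves": state.moves_taken,
            }
        )
    return DQNAgent(network=net, geometry=geometry), curve


# ---------------------------------------------------------------------------
# Checkpoints: JSON header (configs) + base64-encoded float64 weight blocks.


def save_checkpoint(agent: DQNAgent, path: str | Path) -> None:
    net = agent.network
    blob = {
        "net_config": {
            "depth_d": net.config.depth_d,
            "width": net.config.width,
            "input_dim": net.config.input_dim,
            "output_dim": net.config.output_dim,
            "activation": net.config.activation,
            "init_seed": net.config.init_seed,
        },
        "geometry": {"n_x": agent.geometry.n_x, "n_y": agent.geometry.n_y},
        "weights": [base64.b64encode(w.tobytes()).decode() for w in net.weights],
        "biases": [base64.b64encode(b.tobytes()).decode() for b in net.biases],
    }
    Path(path).write_text(json.dumps(blob) + "\n")


def load_checkpoint(path: str | Path) -> DQNAgent:
    blob = json.loads(Path(path).read_text())
    config = QNetworkConfig(**blob["net_config"])
    net = QNetwork(config)
    for i, enc in enumerate(blob["weights"]):
        net.weights[i] = np.frombuffer(
            base64.b64decode(enc), dtype=float
        ).reshape(net.weights[i].shape).copy()
    for i, enc in enumerate(blob["biases"]):
        net.biases[i] = np.frombuffer(base64.b64decode(enc), dtype=float).copy()
    return DQNAgent(network=net, geometry=GridGeometry(**blob["geometry"]))
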
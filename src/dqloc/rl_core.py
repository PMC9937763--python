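"""The Markov decision process and value networks of the boundary-point agent.

The agent is a point moving one pixel at a time (up/down/left/right) inside
an 80-pixel active region centered on the initializer's estimate.  Its
state is a 4-deep stack of 32x32 intensity patches centered on its current
and three previous positions.  The reward for a move is the clipped change
in Euclidean distance to the target point, positive when the move brought
the agent closer.  Training episodes end when the agent is within one
pixel of the target or a step budget (100) runs out; at test time, where no
target exists, the episode ends when the recorded Q values flatten out —
the difference between the means of the first and last eight of the most
recent 16 Q values stays below 0.3 on two checks — or after 60 steps.

Value networks come in four variants: plain DQN, double DQN (action chosen
by the online network, evaluated by the target network), and the dueling
forms of each (a shared trunk splitting into a state-value head and a
mean-centered advantage head).
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np

from . import _nn
from .phantom import BScan

__all__ = [
    "Action", "ActiveRegion", "AgentState", "Transition", "ExperienceMemory",
    "TrainTermination", "TestTermination", "QNetwork",
    "euclidean", "compute_reward", "extract_patch", "reset", "step_env",
    "train_terminated", "delta_q", "select_action", "td_target", "dqn_loss",
    "sync_target", "PATCH_SIZE", "STACK_DEPTH",
]

PATCH_SIZE = 32
STACK_DEPTH = 4


class Action(IntEnum):
    UP = 0
    DOWN = 1
    LEFT = 2
    RIGHT = 3


# (dx, dy) per action; UP decreases y in the top-left-origin convention.
_DISPLACEMENT = {
    Action.UP: (0, -1),
    Action.DOWN: (0, 1),
    Action.LEFT: (-1, 0),
    Action.RIGHT: (1, 0),
}


def euclidean(p: tuple[int, int], q: tuple[int, int]) -> float:
    """Euclidean distance D(p, q) in pixels."""
    return float(np.hypot(p[0] - q[0], p[1] - q[1]))


def compute_reward(pos_before, pos_after, target) -> float:
    """Clipped distance improvement: clip(D(before,T) - D(after,T), -1, 1).

    Positive when the action moved the agent toward the target.  For unit
    steps the raw value already lies in [-1, 1] (triangle inequality), so
    clipping only matters for hypothetical multi-pixel jumps.
    """
    raw = euclidean(pos_before, target) - euclidean(pos_after, target)
    return float(np.clip(raw, -1.0, 1.0))


@dataclass(frozen=True)
class ActiveRegion:
    """Axis-aligned box of side ``side`` centered on the initial point,
    clipped to the image; only the agent's *position* is confined to it."""

    center: tuple[int, int]
    side: int = 80
    image_shape: tuple[int, int] = (0, 0)  # (height, width)
    x_min: int = field(init=False)
    x_max: int = field(init=False)
    y_min: int = field(init=False)
    y_max: int = field(init=False)

    def __post_init__(self):
        h, w = self.image_shape
        if h < 1 or w < 1:
            raise ValueError("image_shape must be positive")
        half = self.side // 2
        cx, cy = self.center
        object.__setattr__(self, "x_min", max(0, cx - half))
        object.__setattr__(self, "x_max", min(w - 1, cx + half))
        object.__setattr__(self, "y_min", max(0, cy - half))
        object.__setattr__(self, "y_max", min(h - 1, cy + half))
        if self.x_min > self.x_max or self.y_min > self.y_max:
            raise ValueError("active region does not intersect the image")

    def contains(self, pos: tuple[int, int]) -> bool:
        x, y = pos
        return self.x_min <= x <= self.x_max and self.y_min <= y <= self.y_max

    def clamp(self, pos: tuple[int, int]) -> tuple[int, int]:
        x, y = pos
        return (int(np.clip(x, self.x_min, self.x_max)),
                int(np.clip(y, self.y_min, self.y_max)))


@dataclass
class AgentState:
    """Agent position plus its 4-deep stack of 32x32 patches, newest last."""

    position: tuple[int, int]
    patches: np.ndarray  # float32, (STACK_DEPTH, PATCH_SIZE, PATCH_SIZE)

    def __post_init__(self):
        self.patches = np.asarray(self.patches, dtype=np.float32)
        if self.patches.shape != (STACK_DEPTH, PATCH_SIZE, PATCH_SIZE):
            raise ValueError(
                f"patch stack must be {STACK_DEPTH}x{PATCH_SIZE}x{PATCH_SIZE}, "
                f"got {self.patches.shape}"
            )

    def features(self) -> np.ndarray:
        return self.patches.ravel()


@dataclass
class Transition:
    state: np.ndarray       # flattened feature vector of s
    action: int
    reward: float
    next_state: np.ndarray  # flattened feature vector of s'
    terminal: bool

    def __post_init__(self):
        if not -1.0 <= self.reward <= 1.0:
            raise ValueError("reward must lie in [-1, 1]")


class ExperienceMemory:
    """FIFO replay memory of transitions with a fixed capacity."""

    def __init__(self, capacity: int = 10000):
        if capacity < 1:
            raise ValueError("capacity must be positive")
        self.capacity = capacity
        self._records: deque[Transition] = deque(maxlen=capacity)

    def push(self, transition: Transition) -> None:
        self._records.append(transition)

    def sample(self, batch_size: int, rng: np.random.Generator):
        idx = rng.integers(0, len(self._records), size=batch_size)
        return [self._records[i] for i in idx]

    def clear(self) -> None:
        self._records.clear()

    def __len__(self) -> int:
        return len(self._records)


@dataclass
class TrainTermination:
    """Training stop rule: within ``distance_threshold`` px of the target
    (inclusive by default; Eq-style strict mode selectable) or budget."""

    distance_threshold: float = 1.0
    inclusive: bool = True
    n_train: int = 100


@dataclass
class TestTermination:
    """Test-time stop rule driven by the flattening of recorded Q values."""

    tr: float = 0.3
    t_q: int = 2
    n_test: int = 60
    q_history: list = field(default_factory=list)
    q: int = 0
    step: int = 0

    def update(self, new_q: float) -> bool:
        """Record one Q value (one agent step); return the terminate flag."""
        self.q_history.append(float(new_q))
        self.step += 1
        dq = delta_q(self.q_history)
        if dq is not None and dq < self.tr and self.step < self.n_test:
            self.q += 1
        terminate = (dq is not None and dq < self.tr and self.q >= self.t_q)
        return bool(terminate or self.step >= self.n_test)


def delta_q(q_history) -> float | None:
    """|mean of first 8 - mean of last 8| over the most recent 16 Q values.

    Returns None ("not ready") with fewer than 16 recorded values.  The
    statistic is invariant to adding a constant to every Q value.
    """
    if len(q_history) < 16:
        return None
    last16 = np.asarray(q_history[-16:], dtype=np.float64)
    return float(abs(last16[:8].mean() - last16[8:].mean()))


def train_terminated(pos, target, step: int,
                     cfg: TrainTermination | None = None) -> bool:
    cfg = cfg or TrainTermination()
    d = euclidean(pos, target)
    hit = d <= cfg.distance_threshold if cfg.inclusive else d < cfg.distance_threshold
    return bool(hit or step >= cfg.n_train)


# ---------------------------------------------------------------------------
# environment dynamics

def extract_patch(scan: BScan, pos: tuple[int, int],
                  size: int = PATCH_SIZE) -> np.ndarray:
    """``size`` x ``size`` patch centered at ``pos``, scaled to [0, 1].

    For even sizes the position maps to the floor-center index
    (size/2 - 1, size/2 - 1).  Out-of-image pixels are edge-replicated.
    """
    x, y = pos
    if not (0 <= x < scan.width and 0 <= y < scan.height):
        raise ValueError(f"position {pos} outside image "
                         f"{scan.width}x{scan.height}")
    lo = size // 2 - 1 if size % 2 == 0 else size // 2
    rows = np.clip(np.arange(y - lo, y - lo + size), 0, scan.height - 1)
    cols = np.clip(np.arange(x - lo, x - lo + size), 0, scan.width - 1)
    patch = scan.pixels[np.ix_(rows, cols)].astype(np.float32) / 255.0
    return patch


def reset(scan: BScan, region: ActiveRegion,
          start: tuple[int, int]) -> AgentState:
    """Initial state at ``start``: the start patch replicated 4 deep."""
    if not region.contains(start):
        raise ValueError(f"start {start} outside active region")
    patch = extract_patch(scan, start)
    stack = np.repeat(patch[None], STACK_DEPTH, axis=0)
    return AgentState(position=tuple(start), patches=stack)


def step_env(scan: BScan, region: ActiveRegion, state: AgentState,
             action: Action, target: tuple[int, int] | None = None
             ) -> tuple[AgentState, float | None]:
    """One environment step: unit move clamped to the region, stack shift.

    With ``target`` given (training) the clipped distance-change reward is
    returned; at test time (``target=None``) the reward slot is None.  A
    move blocked by the region edge leaves the position unchanged, which
    makes its reward exactly 0.
    """
    dx, dy = _DISPLACEMENT[Action(action)]
    old_pos = state.position
    new_pos = region.clamp((old_pos[0] + dx, old_pos[1] + dy))
    patch = extract_patch(scan, new_pos)
    stack = np.concatenate([state.patches[1:], patch[None]], axis=0)
    new_state = AgentState(position=new_pos, patches=stack)
    reward = None if target is None else compute_reward(old_pos, new_pos, target)
    return new_state, reward


def select_action(qvec, epsilon: float, rng: np.random.Generator) -> Action:
    """Epsilon-greedy action; greedy ties break toward the lowest index."""
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must be in [0, 1]")
    if epsilon > 0 and rng.random() < epsilon:
        return Action(int(rng.integers(0, len(Action))))
    return Action(int(np.argmax(qvec)))


# ---------------------------------------------------------------------------
# value networks

_VARIANTS = ("DQN", "DDQN", "DuelDQN", "DuelDDQN")


class QNetwork:
    """Online + target value networks for one side's agent.

    A dense trunk on the flattened 32x32x4 patch stack feeds either a
    single 4-way head (plain variants) or a dueling pair of heads whose
    aggregation ``Q = V + (A - mean A)`` satisfies ``mean_a Q = V``
    exactly.  The double variants differ only in how TD targets bootstrap
    (see :func:`td_target`), not in architecture.

    Parameters
    ----------
    variant : one of DQN, DDQN, DuelDQN, DuelDDQN (case-insensitive).
    hidden : trunk widths; default a single 256-unit layer.
    gamma : discount factor, 0.95.
    seed : weight-initialization seed.
    """

    def __init__(self, variant: str = "DQN", hidden: tuple = (256,),
                 gamma: float = 0.95, seed: int = 0,
                 input_dim: int = STACK_DEPTH * PATCH_SIZE * PATCH_SIZE):
        canon = {v.lower(): v for v in _VARIANTS}
        if variant.lower() not in canon:
            raise ValueError(f"unknown variant {variant!r}; "
                             f"choose from {_VARIANTS}")
        self.variant = canon[variant.lower()]
        self.hidden = tuple(hidden)
        self.gamma = float(gamma)
        self.seed = int(seed)
        self.input_dim = int(input_dim)
        self.dueling = self.variant.startswith("Duel")
        self.double = "DDQN" in self.variant
        rng = np.random.default_rng(seed)
        self._online = self._build(rng)
        self._target = self._build(np.random.default_rng(seed))
        self.sync_target()

    def _build(self, rng):
        dims = [self.input_dim, *self.hidden]
        layers = []
        for a, b in zip(dims, dims[1:]):
            layers += [_nn.Dense(a, b, rng), _nn.ReLU()]
        trunk = _nn.Sequential(layers)
        if self.dueling:
            heads = {"value": _nn.Dense(dims[-1], 1, rng),
                     "advantage": _nn.Dense(dims[-1], len(Action), rng)}
        else:
            heads = {"q": _nn.Dense(dims[-1], len(Action), rng)}
        return {"trunk": trunk, "heads": heads}

    # forward ------------------------------------------------------------
    def _forward(self, net, X: np.ndarray) -> np.ndarray:
        h = net["trunk"].forward(X)
        if self.dueling:
            v = net["heads"]["value"].forward(h)
            a = net["heads"]["advantage"].forward(h)
            return v + (a - a.mean(axis=1, keepdims=True))
        return net["heads"]["q"].forward(h)

    def q_values(self, state, use_target: bool = False) -> np.ndarray:
        """4-vector of Q values, ordered (UP, DOWN, LEFT, RIGHT)."""
        if isinstance(state, AgentState):
            x = state.features()
        else:
            x = np.asarray(state, dtype=np.float32).ravel()
        if x.size != self.input_dim:
            raise ValueError(f"state has {x.size} features, "
                             f"expected {self.input_dim}")
        net = self._target if use_target else self._online
        return self._forward(net, x[None])[0]

    def q_values_batch(self, X: np.ndarray, use_target: bool = False
                       ) -> np.ndarray:
        net = self._target if use_target else self._online
        return self._forward(net, np.asarray(X, dtype=np.float32))

    # parameters ---------------------------------------------------------
    def _params(self, net):
        ps = list(net["trunk"].params)
        for head in net["heads"].values():
            ps += head.params
        return ps

    def _grads(self, net):
        gs = list(net["trunk"].grads)
        for head in net["heads"].values():
            gs += head.grads
        return gs

    def parameters(self):
        return self._params(self._online)

    def sync_target(self) -> None:
        """Copy online weights into the target network (idempotent)."""
        for p_t, p_o in zip(self._params(self._target),
                            self._params(self._online)):
            p_t[...] = p_o

    def make_optimizer(self, lr: float) -> _nn.Adam:
        return _nn.Adam(self.parameters(), lr=lr)

    def train_step(self, states: np.ndarray, actions: np.ndarray,
                   targets: np.ndarray, optimizer: _nn.Adam) -> float:
        """One squared-TD-error gradient step; returns the batch loss.

        The gradient flows only through the online network's Q(s, a).
        """
        X = np.asarray(states, dtype=np.float32)
        q = self._forward(self._online, X)
        n = len(actions)
        picked = q[np.arange(n), actions]
        err = picked - np.asarray(targets, dtype=np.float32)
        loss = float(np.mean(err ** 2))
        dq = np.zeros_like(q)
        dq[np.arange(n), actions] = 2.0 * err / n
        # backward through aggregation and trunk
        if self.dueling:
            dv = dq.sum(axis=1, keepdims=True)
            da = dq - dq.mean(axis=1, keepdims=True)
            heads = self._online["heads"]
            dh = heads["value"].backward(dv) + heads["advantage"].backward(da)
        else:
            dh = self._online["heads"]["q"].backward(dq)
        self._online["trunk"].backward(dh)
        optimizer.step(self._grads(self._online))
        return loss

    # persistence --------------------------------------------------------
    def save(self, path) -> None:
        """Single-file checkpoint: weights plus the network descriptor."""
        spec = {"variant": self.variant, "hidden": list(self.hidden),
                "gamma": self.gamma, "seed": self.seed,
                "input_dim": self.input_dim}
        arrays = {f"w{i}": p for i, p in enumerate(self.parameters())}
        np.savez(path, spec=json.dumps(spec), **arrays)

    @classmethod
    def load(cls, path) -> "QNetwork":
        with np.load(path, allow_pickle=False) as data:
            spec = json.loads(str(data["spec"]))
            net = cls(**{**spec, "hidden": tuple(spec["hidden"])})
            weights = [data[f"w{i}"] for i in range(len(net.parameters()))]
        for p, w in zip(net.parameters(), weights):
            if p.shape != w.shape:
                raise ValueError("checkpoint weight shape mismatch")
            p[...] = w
        net.sync_target()
        return net


def td_target(batch, gamma: float, net: QNetwork) -> np.ndarray:
    """TD targets for a batch of transitions under the network's variant.

    Terminal transitions contribute the bare reward.  Non-terminal:
    plain variants bootstrap with ``max_a' Q(s', a'; theta')`` from the
    target network; double variants evaluate the online network's argmax
    action under the target network.
    """
    if len(batch) == 0:
        raise ValueError("batch must be non-empty")
    rewards = np.array([t.reward for t in batch], dtype=np.float64)
    terminal = np.array([t.terminal for t in batch], dtype=bool)
    targets = rewards.copy()
    live = ~terminal
    if live.any():
        S2 = np.stack([batch[i].next_state for i in range(len(batch))])[live]
        q_tgt = net.q_values_batch(S2, use_target=True).astype(np.float64)
        if net.double:
            q_on = net.q_values_batch(S2, use_target=False)
            pick = np.argmax(q_on, axis=1)
            boot = q_tgt[np.arange(len(pick)), pick]
        else:
            boot = q_tgt.max(axis=1)
        targets[live] = rewards[live] + gamma * boot
    return targets


def dqn_loss(batch, targets, net: QNetwork) -> float:
    """Mean squared TD error of the online network on a batch (no update)."""
    if len(batch) != len(targets):
        raise ValueError("batch and targets must be aligned")
    X = np.stack([t.state for t in batch])
    actions = np.array([t.action for t in batch])
    q = net.q_values_batch(X)
    picked = q[np.arange(len(batch)), actions].astype(np.float64)
    return float(np.mean((np.asarray(targets) - picked) ** 2))


def sync_target(net: QNetwork) -> None:
    net.sync_target()
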
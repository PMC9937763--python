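"""Agent training and the cascaded initializer-to-agent location pipeline.

The left and right boundary points get independent agents: identical
architecture, separately trained weights.  Training episodes start at the
ground-truth point plus a margin pair drawn per axis from
[-4,-6,-8,-10,-12,-14,4,6,8,10,12,14], so initial distances span roughly
5.7 to 19.8 pixels — the spread the test-time initializer is expected to
leave behind.  At test time the initializer's point fixes an 80-pixel
active region, the agent starts there, acts greedily, and stops on the
Q-flattening rule or the 60-step budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator

from .initializer import InitialPoints, predict_initial
from .phantom import Annotation, BScan, PatientSeries
from .rl_core import (
    Action, ActiveRegion, ExperienceMemory, QNetwork, TestTermination,
    TrainTermination, Transition, euclidean, reset, select_action, step_env,
    td_target, train_terminated,
)

__all__ = [
    "TRAIN_MARGINS", "GRID_MARGINS", "Side", "AgentTrainConfig",
    "SideResult", "LocationResult", "BoundaryAgent", "train_boundary_agent",
    "evaluate_grid", "locate_side", "locate_joint", "run_patient",
]

#: Per-axis training-start margins (pixels from the ground-truth point).
TRAIN_MARGINS = (-4, -6, -8, -10, -12, -14, 4, 6, 8, 10, 12, 14)

#: Per-axis validation-grid margins; the Cartesian product gives 16 starts.
GRID_MARGINS = (-4, -14, 4, 14)


class Side:
    LEFT = "left"
    RIGHT = "right"


@dataclass
class AgentTrainConfig:
    """Training schedule for one side's agent (full-scale defaults)."""

    epochs: int = 80
    learning_rate: float = 1e-4
    batch_size: int = 32           # B
    max_episode: int = 25          # P, episodes per image
    update_frequency: int = 50     # L, optimizer steps between target syncs
    sample_step: int = 5           # S, memory-size modulus triggering updates
    n_train: int = 100             # per-episode step budget
    gamma: float = 0.95
    train_margins: tuple = TRAIN_MARGINS
    memory_capacity: int = 10000
    epsilon_start: float = 1.0
    epsilon_end: float = 0.1
    seed: int = 0


@dataclass
class SideResult:
    """One side's outcome of the cascaded location."""

    initial: tuple[int, int]
    final: tuple[int, int]
    q_trace: list = field(default_factory=list)
    positions: list = field(default_factory=list)
    steps: int = 0
    terminated_by: str = "budget"   # {"delta_q", "budget"}


@dataclass
class LocationResult:
    """Joint result for one B-scan: both sides plus provenance."""

    left: SideResult
    right: SideResult
    initializer_source: str = "heuristic"
    initializer_warning: bool = False
    patient_id: str = ""
    frame_index: int = 0

    @property
    def final_points(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return self.left.final, self.right.final

    @property
    def initial_points(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return self.left.initial, self.right.initial


def _target_point(ann: Annotation, side: str) -> tuple[int, int]:
    if side == Side.LEFT:
        return ann.left_point
    if side == Side.RIGHT:
        return ann.right_point
    raise ValueError(f"unknown side {side!r}")


def _clamp_to_image(pos, scan: BScan) -> tuple[int, int]:
    return (int(np.clip(pos[0], 0, scan.width - 1)),
            int(np.clip(pos[1], 0, scan.height - 1)))


class BoundaryAgent(BaseEstimator):
    """Single-agent deep-Q boundary-point refiner for one side.

    ``fit`` runs the replay-memory training loop: per epoch the images are
    shuffled; per image the memory is cleared and ``max_episode`` episodes
    are played from randomized starts; a gradient step fires whenever the
    memory size has reached the batch size and is a multiple of
    ``sample_step``; the target network is re-synced every
    ``update_frequency`` optimizer steps.  Exploration is epsilon-greedy
    with a linear decay from ``epsilon_start`` to ``epsilon_end`` over the
    first half of all planned episodes.

    When a validation split is supplied, the per-epoch checkpoint with the
    smallest grid-evaluation error is kept (``best_epoch_``).

    Fitted attributes: ``qnet_`` (value network), ``reward_curve_`` (mean
    episode reward per epoch), ``grid_curve_`` (validation error per epoch,
    when validated), ``best_epoch_``.
    """

    def __init__(self, side: str = Side.LEFT, variant: str = "DQN",
                 hidden: tuple = (256,), epochs: int = 80,
                 learning_rate: float = 1e-4, batch_size: int = 32,
                 max_episode: int = 25, update_frequency: int = 50,
                 sample_step: int = 5, n_train: int = 100,
                 gamma: float = 0.95, region_side: int = 80,
                 train_margins: tuple = TRAIN_MARGINS,
                 memory_capacity: int = 10000, epsilon_start: float = 1.0,
                 epsilon_end: float = 0.1, tr: float = 0.3, t_q: int = 2,
                 n_test: int = 60, seed: int = 0):
        self.side = side
        self.variant = variant
        self.hidden = hidden
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_episode = max_episode
        self.update_frequency = update_frequency
        self.sample_step = sample_step
        self.n_train = n_train
        self.gamma = gamma
        self.region_side = region_side
        self.train_margins = train_margins
        self.memory_capacity = memory_capacity
        self.epsilon_start = epsilon_start
        self.epsilon_end = epsilon_end
        self.tr = tr
        self.t_q = t_q
        self.n_test = n_test
        self.seed = seed

    # -- training --------------------------------------------------------
    def fit(self, scans, annotations, validation=None):
        """Train on aligned scans/annotations.

        ``validation`` is an optional ``(scans, annotations)`` pair used
        for per-epoch grid evaluation and best-checkpoint selection.
        """
        if len(scans) == 0:
            raise ValueError("training set must be non-empty")
        if len(scans) != len(annotations):
            raise ValueError("scans and annotations must be aligned")
        rng = np.random.default_rng(self.seed)
        net = QNetwork(variant=self.variant, hidden=self.hidden,
                       gamma=self.gamma,
                       seed=int(rng.integers(0, 2**31 - 1)))
        opt = net.make_optimizer(self.learning_rate)
        memory = ExperienceMemory(self.memory_capacity)
        term_cfg = TrainTermination(n_train=self.n_train)
        margins = np.asarray(self.train_margins)

        pairs = []
        for scan, ann in zip(scans, annotations):
            if ann is None:
                continue  # skip silently-unusable images, keep going
            pairs.append((scan, _target_point(ann, self.side)))
        if not pairs:
            raise ValueError(f"no usable annotations for side {self.side}")

        total_episodes = self.epochs * len(pairs) * self.max_episode
        half = max(1, total_episodes // 2)
        episode_counter = 0
        update_counter = 0
        reward_curve = []
        grid_curve = []
        best_weights = None
        best_err = np.inf
        best_epoch = -1
        start_log = []

        for epoch in range(self.epochs):
            order = rng.permutation(len(pairs))
            episode_rewards = []
            for j in order:
                scan, target = pairs[j]
                memory.clear()
                for _ in range(self.max_episode):
                    frac = min(1.0, episode_counter / half)
                    eps = (self.epsilon_start
                           + (self.epsilon_end - self.epsilon_start) * frac)
                    episode_counter += 1
                    dx = int(margins[rng.integers(0, len(margins))])
                    dy = int(margins[rng.integers(0, len(margins))])
                    start = _clamp_to_image((target[0] + dx, target[1] + dy),
                                            scan)
                    start_log.append((dx, dy))
                    region = ActiveRegion(center=start, side=self.region_side,
                                          image_shape=scan.pixels.shape)
                    state = reset(scan, region, start)
                    step = 0
                    total_r = 0.0
                    done = train_terminated(state.position, target, step,
                                            term_cfg)
                    while not done:
                        qvec = net.q_values(state)
                        action = select_action(qvec, eps, rng)
                        nxt, reward = step_env(scan, region, state, action,
                                               target=target)
                        step += 1
                        done = train_terminated(nxt.position, target, step,
                                                term_cfg)
                        memory.push(Transition(state.features(), int(action),
                                               reward, nxt.features(), done))
                        total_r += reward
                        state = nxt
                        if (len(memory) >= self.batch_size
                                and len(memory) % self.sample_step == 0):
                            batch = memory.sample(self.batch_size, rng)
                            targets = td_target(batch, self.gamma, net)
                            S = np.stack([t.state for t in batch])
                            A = np.array([t.action for t in batch])
                            net.train_step(S, A, targets, opt)
                            update_counter += 1
                            if update_counter % self.update_frequency == 0:
                                net.sync_target()
                    episode_rewards.append(total_r)
            reward_curve.append(float(np.mean(episode_rewards)))
            if validation is not None:
                err = evaluate_grid(net, validation[0], validation[1],
                                    self.side, region_side=self.region_side,
                                    tr=self.tr, t_q=self.t_q,
                                    n_test=self.n_test)
                grid_curve.append(err)
                if err < best_err:
                    best_err = err
                    best_epoch = epoch
                    best_weights = [p.copy() for p in net.parameters()]

        if best_weights is not None:
            for p, w in zip(net.parameters(), best_weights):
                p[...] = w
            net.sync_target()
        self.qnet_ = net
        self.reward_curve_ = reward_curve
        self.grid_curve_ = grid_curve
        self.best_epoch_ = best_epoch if best_weights is not None else self.epochs - 1
        self.episode_starts_ = start_log
        return self

    # -- inference -------------------------------------------------------
    def refine(self, scan: BScan, start: tuple[int, int]) -> SideResult:
        """Greedy rollout from ``start`` with the test-time stop rule."""
        if not hasattr(self, "qnet_"):
            raise RuntimeError("BoundaryAgent is not fitted")
        return locate_side(self.qnet_, scan, start,
                           region_side=self.region_side, tr=self.tr,
                           t_q=self.t_q, n_test=self.n_test)

    def predict(self, scans, starts) -> list[tuple[int, int]]:
        """Final point per (scan, start) pair."""
        return [self.refine(s, p).final for s, p in zip(scans, starts)]


def train_boundary_agent(scans, annotations, side: str,
                cfg: AgentTrainConfig | None = None, variant: str = "DQN",
                validation=None, **overrides) -> BoundaryAgent:
    """Functional wrapper over :class:`BoundaryAgent`."""
    cfg = cfg or AgentTrainConfig()
    params = asdict(cfg)
    params.pop("memory_capacity", None)
    agent = BoundaryAgent(side=side, variant=variant,
                          memory_capacity=cfg.memory_capacity,
                          **{**params, **overrides})
    return agent.fit(scans, annotations, validation=validation)


def locate_side(net: QNetwork, scan: BScan, start: tuple[int, int],
                region_side: int = 80, tr: float = 0.3, t_q: int = 2,
                n_test: int = 60) -> SideResult:
    """Pure-greedy rollout inside the active region centered on ``start``.

    The recorded per-step Q value is the maximum of the 4-vector (the
    value driving the greedy action); the rollout stops when the
    Q-flattening rule fires or at the step budget.
    """
    start = _clamp_to_image(start, scan)
    region = ActiveRegion(center=start, side=region_side,
                          image_shape=scan.pixels.shape)
    state = reset(scan, region, start)
    tt = TestTermination(tr=tr, t_q=t_q, n_test=n_test)
    positions = [state.position]
    rng = np.random.default_rng(0)  # unused at epsilon=0
    terminated_by = "budget"
    while True:
        qvec = net.q_values(state)
        action = select_action(qvec, 0.0, rng)
        state, _ = step_env(scan, region, state, action, target=None)
        positions.append(state.position)
        if tt.update(float(np.max(qvec))):
            terminated_by = "delta_q" if tt.step < tt.n_test else "budget"
            break
    return SideResult(initial=start, final=state.position,
                      q_trace=list(tt.q_history), positions=positions,
                      steps=tt.step, terminated_by=terminated_by)


def evaluate_grid(net: QNetwork, scans, annotations, side: str,
                  grid_margins: tuple = GRID_MARGINS, region_side: int = 80,
                  tr: float = 0.3, t_q: int = 2, n_test: int = 60) -> float:
    """Mean final distance to the truth over the 16-offset validation grid.

    Each scan is probed from every (dx, dy) in the Cartesian product of
    ``grid_margins`` with itself, starting at ground truth + offset.
    """
    errors = []
    for scan, ann in zip(scans, annotations):
        target = _target_point(ann, side)
        for dx in grid_margins:
            for dy in grid_margins:
                start = _clamp_to_image((target[0] + dx, target[1] + dy),
                                        scan)
                res = locate_side(net, scan, start, region_side=region_side,
                                  tr=tr, t_q=t_q, n_test=n_test)
                errors.append(euclidean(res.final, target))
    return float(np.mean(errors))


def locate_joint(scan: BScan, initializer, left_model, right_model,
                 region_side: int = 80, tr: float = 0.3, t_q: int = 2,
                 n_test: int = 60) -> LocationResult:
    """Full cascade on one scan: initial points, then per-side refinement.

    ``initializer`` may be a fitted :class:`MultitaskInitializer`, ``None``
    (the heuristic), or a precomputed :class:`InitialPoints`.  Models may
    be :class:`BoundaryAgent` or bare :class:`QNetwork` objects.
    """
    if isinstance(initializer, InitialPoints):
        init = initializer
    else:
        init = predict_initial(initializer, scan)

    def _net(m):
        return m.qnet_ if isinstance(m, BoundaryAgent) else m

    left = locate_side(_net(left_model), scan, init.left,
                       region_side=region_side, tr=tr, t_q=t_q, n_test=n_test)
    right = locate_side(_net(right_model), scan, init.right,
                        region_side=region_side, tr=tr, t_q=t_q,
                        n_test=n_test)
    return LocationResult(left=left, right=right,
                          initializer_source=init.source,
                          initializer_warning=init.warning,
                          patient_id=scan.patient_id,
                          frame_index=scan.frame_index)


def run_patient(series: PatientSeries, initializer, left_model, right_model,
                **kwargs) -> list[LocationResult]:
    """Cascade every frame of a patient stack, preserving frame order."""
    results = []
    for scan, _ in series.scans:
        results.append(locate_joint(scan, initializer, left_model,
                                    right_model, **kwargs))
    return results
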
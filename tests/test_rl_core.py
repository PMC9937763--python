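"""MDP environment, termination rules and value networks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dqloc import phantom as ph
from dqloc.rl_core import (Action, ActiveRegion, AgentState, ExperienceMemory,
                           QNetwork, TestTermination as QTerminationRule,
                           TrainTermination,
                           Transition, compute_reward, delta_q, dqn_loss,
                           euclidean, extract_patch, reset, select_action,
                           step_env, td_target, train_terminated,
                           PATCH_SIZE, STACK_DEPTH)


def _toy_scan(h=64, w=64, seed=0):
    rng = np.random.default_rng(seed)
    return ph.BScan(rng.integers(0, 256, (h, w), dtype=np.uint8))


def _state_at(scan, region, pos):
    return reset(scan, region, pos)


class TestDistanceAndReward:
    @pytest.mark.parametrize("p,q,d", [((0, 0), (3, 4), 5.0),
                                       ((5, 5), (5, 5), 0.0),
                                       ((1, 1), (2, 1), 1.0)])
    def test_euclidean_examples(self, p, q, d):
        assert euclidean(p, q) == pytest.approx(d)

    @pytest.mark.parametrize("before,after,target,r", [
        ((10, 10), (10, 11), (10, 20), 1.0),     # axial approach
        ((0, 0), (1, 0), (0, 0), -1.0),          # retreat from the target
        ((3, 4), (2, 4), (0, 0), 5 - np.sqrt(20)),
    ])
    def test_reward_examples(self, before, after, target, r):
        assert compute_reward(before, after, target) == pytest.approx(r)

    @given(st.integers(0, 200), st.integers(0, 200),
           st.integers(0, 200), st.integers(0, 200),
           st.sampled_from(list(Action)))
    @settings(max_examples=300, deadline=None)
    def test_unit_step_reward_never_clips(self, x, y, tx, ty, action):
        """|D(before,T) - D(after,T)| <= 1 for unit moves (triangle
        inequality), so clipping is the identity on legal moves."""
        dx, dy = {Action.UP: (0, -1), Action.DOWN: (0, 1),
                  Action.LEFT: (-1, 0), Action.RIGHT: (1, 0)}[action]
        before, after, target = (x, y), (x + dx, y + dy), (tx, ty)
        raw = euclidean(before, target) - euclidean(after, target)
        assert abs(raw) <= 1.0 + 1e-12
        assert compute_reward(before, after, target) == pytest.approx(raw)


class TestPatchesAndEnvironment:
    def test_patch_is_constant_on_constant_image(self):
        scan = ph.BScan(np.full((64, 64), 100, dtype=np.uint8))
        patch = extract_patch(scan, (32, 32))
        assert patch.shape == (PATCH_SIZE, PATCH_SIZE)
        assert np.allclose(patch, 100 / 255.0)

    def test_corner_patch_edge_replicates(self):
        scan = _toy_scan()
        patch = extract_patch(scan, (0, 0))
        assert patch.shape == (PATCH_SIZE, PATCH_SIZE)
        assert patch[0, 0] == pytest.approx(scan.pixels[0, 0] / 255.0)
        # the replicated corner block is constant
        assert np.all(patch[:15, :15] == patch[0, 0])

    def test_position_maps_to_floor_center_index(self):
        scan = _toy_scan(seed=3)
        patch = extract_patch(scan, (30, 20))
        assert patch[15, 15] == pytest.approx(scan.pixels[20, 30] / 255.0)

    def test_neighboring_positions_give_shifted_patches(self):
        scan = ph.BScan(np.tile(np.arange(64, dtype=np.uint8), (64, 1)))
        a = extract_patch(scan, (30, 32))
        b = extract_patch(scan, (31, 32))
        assert np.array_equal(a[:, 1:], b[:, :-1])

    def test_patch_outside_image_rejected(self):
        with pytest.raises(ValueError, match="outside image"):
            extract_patch(_toy_scan(), (64, 0))

    def test_reset_replicates_start_patch(self):
        scan = _toy_scan()
        region = ActiveRegion(center=(32, 32), side=80,
                              image_shape=scan.pixels.shape)
        state = reset(scan, region, (32, 32))
        assert state.patches.shape == (STACK_DEPTH, PATCH_SIZE, PATCH_SIZE)
        for k in range(1, STACK_DEPTH):
            assert np.array_equal(state.patches[0], state.patches[k])

    def test_reset_outside_region_rejected(self):
        scan = _toy_scan(128, 128)
        region = ActiveRegion(center=(20, 20), side=10,
                              image_shape=scan.pixels.shape)
        with pytest.raises(ValueError, match="outside active region"):
            reset(scan, region, (100, 100))

    def test_step_shifts_stack_and_moves_one_pixel(self):
        scan = _toy_scan()
        region = ActiveRegion(center=(32, 32), side=80,
                              image_shape=scan.pixels.shape)
        state = reset(scan, region, (32, 32))
        nxt, _ = step_env(scan, region, state, Action.UP, target=(32, 10))
        assert nxt.position == (32, 31)  # UP decreases y
        assert np.array_equal(nxt.patches[:3], state.patches[1:])

    def test_blocked_move_at_edge_gives_zero_reward(self):
        scan = _toy_scan()
        region = ActiveRegion(center=(5, 5), side=8,
                              image_shape=scan.pixels.shape)
        state = reset(scan, region, (region.x_min, 5))
        nxt, reward = step_env(scan, region, state, Action.LEFT,
                               target=(40, 40))
        assert nxt.position == state.position
        assert reward == 0.0

    def test_agent_confined_to_region_under_random_actions(self):
        scan = _toy_scan(128, 128)
        region = ActiveRegion(center=(60, 60), side=80,
                              image_shape=scan.pixels.shape)
        rng = np.random.default_rng(0)
        state = reset(scan, region, (60, 60))
        for _ in range(500):
            action = Action(int(rng.integers(0, 4)))
            state, _ = step_env(scan, region, state, action, target=None)
            assert region.contains(state.position)


class TestTerminationRules:
    def test_at_target_terminates_immediately(self):
        assert train_terminated((10, 10), (10, 10), step=0)

    def test_budget_exhaustion_terminates(self):
        assert train_terminated((0, 0), (5, 0), step=100)

    def test_midway_does_not_terminate(self):
        assert not train_terminated((0, 0), (5, 0), step=10)

    def test_inclusive_vs_strict_distance_rule(self):
        inc = TrainTermination(inclusive=True)
        strict = TrainTermination(inclusive=False)
        assert train_terminated((10, 10), (11, 10), 0, inc)
        assert not train_terminated((10, 10), (11, 10), 0, strict)

    def test_delta_q_examples(self):
        assert delta_q([1.0] * 16) == 0.0
        assert delta_q(list(range(1, 17))) == pytest.approx(8.0)
        assert delta_q([1.0] * 15) is None

    def test_delta_q_shift_invariance(self):
        rng = np.random.default_rng(1)
        hist = list(rng.normal(size=30))
        shifted = [h + 123.4 for h in hist]
        assert delta_q(hist) == pytest.approx(delta_q(shifted))

    def test_constant_q_terminates_on_second_subthreshold_check(self):
        tt = QTerminationRule()
        flags = [tt.update(2.5) for _ in range(17)]
        assert flags[:16] == [False] * 16   # q reaches 1 at step 16
        assert flags[16] is True            # q reaches 2 at step 17
        assert tt.q == 2

    def test_never_flattening_q_runs_to_the_60_step_budget(self):
        # steadily drifting Q keeps delta-Q at 80, far above the threshold
        tt = QTerminationRule()
        step = 0
        terminate = False
        while not terminate:
            step += 1
            terminate = tt.update(step * 10.0)
        assert step == 60 and tt.q == 0

    def test_short_history_never_terminates(self):
        tt = QTerminationRule()
        assert not any(tt.update(1.0) for _ in range(15))


class TestActionSelection:
    def test_greedy_tie_breaks_to_lowest_index(self):
        rng = np.random.default_rng(0)
        assert select_action(np.zeros(4), 0.0, rng) == Action.UP
        assert select_action(np.array([0, 1, 0, 0]), 0.0, rng) == Action.DOWN

    def test_full_exploration_is_uniform(self):
        """Empirical frequencies within 3 sigma of uniform over 1e4 draws."""
        rng = np.random.default_rng(7)
        counts = np.zeros(4)
        n = 10_000
        for _ in range(n):
            counts[select_action(np.array([9, 0, 0, 0]), 1.0, rng)] += 1
        expected = n / 4
        sigma = np.sqrt(n * 0.25 * 0.75)
        assert np.all(np.abs(counts - expected) < 3 * sigma)

    def test_invalid_epsilon_rejected(self):
        with pytest.raises(ValueError):
            select_action(np.zeros(4), 1.5, np.random.default_rng(0))


class TestQNetwork:
    @pytest.fixture(scope="class")
    def nets(self):
        return {v: QNetwork(variant=v, hidden=(32,), seed=1)
                for v in ("DQN", "DDQN", "DuelDQN", "DuelDDQN")}

    def test_output_is_a_4_vector_on_a_32x32x4_state(self, nets):
        scan = _toy_scan()
        region = ActiveRegion(center=(32, 32), side=80,
                              image_shape=scan.pixels.shape)
        state = reset(scan, region, (32, 32))
        for net in nets.values():
            q = net.q_values(state)
            assert q.shape == (4,)
            assert np.all(np.isfinite(q))

    def test_forward_pass_is_deterministic(self, nets):
        x = np.random.default_rng(2).random(4 * 32 * 32).astype(np.float32)
        for net in nets.values():
            assert np.array_equal(net.q_values(x), net.q_values(x))

    def test_wrong_state_shape_rejected(self, nets):
        with pytest.raises(ValueError, match="features"):
            nets["DQN"].q_values(np.zeros(10))

    def test_dueling_aggregation_identity(self):
        """mean_a Q(s, a) equals the value head output exactly, and with a
        zeroed advantage head every entry equals V(s)."""
        net = QNetwork(variant="DuelDQN", hidden=(32,), seed=1)
        x = np.random.default_rng(3).random(4 * 32 * 32).astype(np.float32)
        q = net.q_values(x)
        h = net._online["trunk"].forward(x[None])
        v = net._online["heads"]["value"].forward(h)[0, 0]
        assert np.mean(q) == pytest.approx(v, rel=1e-5)
        adv = net._online["heads"]["advantage"]
        adv.W[...] = 0
        adv.b[...] = 0
        q0 = net.q_values(x)
        assert np.allclose(q0, q0[0])
        assert q0[0] == pytest.approx(
            net._online["heads"]["value"].forward(
                net._online["trunk"].forward(x[None]))[0, 0], rel=1e-5)

    def test_sync_makes_target_equal_online_and_is_idempotent(self):
        net = QNetwork(hidden=(16,), seed=4)
        opt = net.make_optimizer(1e-3)
        x = np.random.default_rng(5).random((8, 4 * 32 * 32)).astype(np.float32)
        net.train_step(x, np.zeros(8, dtype=int), np.ones(8), opt)
        probe = x[0]
        assert not np.allclose(net.q_values(probe),
                               net.q_values(probe, use_target=True))
        net.sync_target()
        a = net.q_values(probe, use_target=True)
        assert np.allclose(net.q_values(probe), a)
        net.sync_target()
        assert np.array_equal(net.q_values(probe, use_target=True), a)

    def test_checkpoint_roundtrip(self, tmp_path):
        net = QNetwork(variant="DuelDDQN", hidden=(16,), seed=6)
        path = tmp_path / "net.npz"
        net.save(path)
        back = QNetwork.load(path)
        x = np.random.default_rng(8).random(4 * 32 * 32).astype(np.float32)
        assert np.array_equal(net.q_values(x), back.q_values(x))
        assert back.variant == "DuelDDQN"

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            QNetwork(variant="rainbow")


def _fake_transition(rng, reward, terminal, n_features=4 * 32 * 32):
    return Transition(rng.random(n_features).astype(np.float32), 1, reward,
                      rng.random(n_features).astype(np.float32), terminal)


class TestTDTargets:
    def test_terminal_target_is_bare_reward(self):
        net = QNetwork(hidden=(8,), seed=0)
        rng = np.random.default_rng(0)
        batch = [_fake_transition(rng, 1.0, True)]
        assert td_target(batch, 0.95, net) == pytest.approx([1.0])

    def test_plain_dqn_bootstraps_with_target_max(self):
        """Known target-net row (0.1, 0.5, -0.2, 0.0), R=1, gamma=0.95
        gives 1 + 0.95 * 0.5 = 1.475."""
        net = QNetwork(hidden=(8,), seed=0)
        rng = np.random.default_rng(1)
        batch = [_fake_transition(rng, 1.0, False)]
        row = np.array([0.1, 0.5, -0.2, 0.0])
        net.q_values_batch = lambda X, use_target=False: np.tile(row, (len(X), 1))
        assert td_target(batch, 0.95, net) == pytest.approx([1.475])

    def test_double_dqn_evaluates_online_argmax_under_target(self):
        """Online argmax index 2, target row value -0.2 there:
        1 + 0.95 * (-0.2) = 0.81."""
        net = QNetwork(variant="DDQN", hidden=(8,), seed=0)
        rng = np.random.default_rng(2)
        batch = [_fake_transition(rng, 1.0, False)]
        t_row = np.array([0.1, 0.5, -0.2, 0.0])
        o_row = np.array([0.0, 0.1, 0.9, 0.2])   # argmax -> index 2

        def fake(X, use_target=False):
            row = t_row if use_target else o_row
            return np.tile(row, (len(X), 1))

        net.q_values_batch = fake
        assert td_target(batch, 0.95, net) == pytest.approx([0.81])

    def test_empty_batch_rejected(self):
        net = QNetwork(hidden=(8,), seed=0)
        with pytest.raises(ValueError):
            td_target([], 0.95, net)


class TestLossAndMemory:
    def test_loss_zero_when_targets_equal_predictions(self):
        net = QNetwork(hidden=(8,), seed=3)
        rng = np.random.default_rng(3)
        batch = [_fake_transition(rng, 0.5, False) for _ in range(4)]
        X = np.stack([t.state for t in batch])
        q = net.q_values_batch(X)
        targets = q[np.arange(4), [t.action for t in batch]]
        assert dqn_loss(batch, targets, net) == pytest.approx(0.0, abs=1e-10)

    def test_single_transition_unit_error(self):
        net = QNetwork(hidden=(8,), seed=3)
        rng = np.random.default_rng(4)
        batch = [_fake_transition(rng, 0.0, False)]
        X = np.stack([t.state for t in batch])
        q0 = float(net.q_values_batch(X)[0, batch[0].action])
        assert dqn_loss(batch, [q0 + 1.0], net) == pytest.approx(1.0)

    def test_loss_is_reproducible(self):
        net = QNetwork(hidden=(8,), seed=3)
        rng = np.random.default_rng(5)
        batch = [_fake_transition(rng, 0.2, False) for _ in range(3)]
        t = td_target(batch, 0.95, net)
        assert dqn_loss(batch, t, net) == dqn_loss(batch, t, net)

    def test_training_step_reduces_batch_loss(self):
        net = QNetwork(hidden=(32,), seed=9)
        opt = net.make_optimizer(1e-2)
        rng = np.random.default_rng(9)
        X = rng.random((16, 4 * 32 * 32)).astype(np.float32)
        A = rng.integers(0, 4, 16)
        targets = rng.random(16)
        first = net.train_step(X, A, targets, opt)
        for _ in range(30):
            last = net.train_step(X, A, targets, opt)
        assert last < first

    def test_memory_is_fifo_with_capacity(self):
        rng = np.random.default_rng(0)
        mem = ExperienceMemory(capacity=5)
        for r in range(8):
            mem.push(_fake_transition(rng, r / 10.0, False, n_features=4))
        assert len(mem) == 5
        rewards = {t.reward for t in mem.sample(50, rng)}
        assert rewards <= {0.3, 0.4, 0.5, 0.6, 0.7}

    def test_reward_outside_clip_bounds_rejected(self):
        with pytest.raises(ValueError, match="reward"):
            Transition(np.zeros(4, np.float32), 0, 1.5,
                       np.zeros(4, np.float32), False)
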
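"""The package's reproducible phantom study.

One call trains the full cascade at phantom scale and measures everything
the method is about: the joint framework's endpoint error (AED) against
the perturbed initializer it starts from, the successful-correction rate,
the 16-offset validation-grid error of the trained agents, and the lesion
diameter recovered on a held-out patient stack.

Study conditions (the defaults): 40 training, 10 validation and 10
held-out test phantoms at 128x128 with multiplicative speckle (sigma
0.15); left and right DQN agents trained for 8 epochs with 5 episodes
per image and a 64-unit trunk, keeping each side's best epoch by
validation-grid error; at test time the heuristic initializer's points are
perturbed by 8-14 px per axis (random sign) to emulate a coarse first
stage, and each agent refines greedily inside its 80-px active region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import phantom as ph
from .initializer import InitialPoints, heuristic_initializer
from .metrics import aed, correction_rate, diameter, patient_summary
from .rl_core import euclidean
from .train_infer import (GRID_MARGINS, BoundaryAgent, Side, evaluate_grid,
                          locate_joint, run_patient)

__all__ = ["PhantomStudyConfig", "PhantomStudyResult", "run_phantom_study",
           "perturb_points", "mean_grid_offset_norm"]


@dataclass
class PhantomStudyConfig:
    """Frozen conditions of the scaled phantom study."""

    image_size: int = 128
    n_train_patients: int = 8     # x 5 frames = 40 training images
    n_val_patients: int = 2       # x 5 frames = 10 validation images
    n_test_patients: int = 2      # x 5 frames = 10 test images
    frames_per_patient: int = 5
    speckle_sigma: float = 0.15
    epochs: int = 8
    max_episode: int = 5
    hidden: tuple = (64,)
    learning_rate: float = 3e-4
    variant: str = "DQN"
    perturb_range: tuple[int, int] = (8, 14)
    diameter_series_frames: int = 9


@dataclass
class PhantomStudyResult:
    init_aed: float
    joint_aed: float
    correction_rate: float
    correction_count: int
    n_test_images: int
    grid_final_distance: float
    grid_initial_offset: float
    diameter_true_max: float
    diameter_measured_max: float
    reward_curves: dict = field(default_factory=dict)
    agents: dict = field(default_factory=dict)


def perturb_points(points: InitialPoints, scan: ph.BScan,
                   rng: np.random.Generator,
                   lo: int = 8, hi: int = 14) -> InitialPoints:
    """Offset both points by lo..hi px per axis with random signs."""

    def _one(p):
        dx = int(rng.integers(lo, hi + 1)) * (1 if rng.random() < 0.5 else -1)
        dy = int(rng.integers(lo, hi + 1)) * (1 if rng.random() < 0.5 else -1)
        return (int(np.clip(p[0] + dx, 0, scan.width - 1)),
                int(np.clip(p[1] + dy, 0, scan.height - 1)))

    return InitialPoints(left=_one(points.left), right=_one(points.right),
                         source=points.source, warning=points.warning)


def mean_grid_offset_norm(margins=GRID_MARGINS) -> float:
    """Mean Euclidean norm of the 16 validation-grid offsets (13.644 px)."""
    return float(np.mean([np.hypot(dx, dy)
                          for dx in margins for dy in margins]))


def run_phantom_study(seed: int = 0,
                      cfg: PhantomStudyConfig | None = None
                      ) -> PhantomStudyResult:
    """Run the whole study from scratch under one seed."""
    cfg = cfg or PhantomStudyConfig()
    root = np.random.default_rng(seed)
    gen_seed = int(root.integers(0, 2**31 - 1))
    test_seed = int(root.integers(0, 2**31 - 1))
    agent_seed = int(root.integers(0, 2**31 - 1))
    perturb_seed = int(root.integers(0, 2**31 - 1))
    val_seed = int(root.integers(0, 2**31 - 1))

    pcfg = ph.PhantomConfig(image_height=cfg.image_size,
                            image_width=cfg.image_size,
                            n_frames_per_patient=cfg.frames_per_patient,
                            speckle_sigma=cfg.speckle_sigma, seed=gen_seed)
    train_scans, train_anns = ph.flatten(
        ph.generate_dataset(pcfg, cfg.n_train_patients, seed=gen_seed))
    test_scans, test_anns = ph.flatten(
        ph.generate_dataset(pcfg, cfg.n_test_patients, seed=test_seed))
    val_scans, val_anns = ph.flatten(
        ph.generate_dataset(pcfg, cfg.n_val_patients, seed=val_seed))

    # per-epoch grid evaluation on the validation split selects the
    # best checkpoint (minimum grid error) for each side
    agents = {}
    curves = {}
    for i, side in enumerate((Side.LEFT, Side.RIGHT)):
        agent = BoundaryAgent(side=side, variant=cfg.variant,
                              epochs=cfg.epochs,
                              max_episode=cfg.max_episode,
                              hidden=cfg.hidden,
                              learning_rate=cfg.learning_rate,
                              seed=agent_seed + i)
        agent.fit(train_scans, train_anns,
                  validation=(val_scans, val_anns))
        agents[side] = agent
        curves[side] = agent.reward_curve_

    # cascaded location from a deliberately degraded initializer
    prng = np.random.default_rng(perturb_seed)
    init_list, joint_list = [], []
    for scan in test_scans:
        init = perturb_points(heuristic_initializer(scan), scan, prng,
                              *cfg.perturb_range)
        res = locate_joint(scan, init, agents[Side.LEFT], agents[Side.RIGHT])
        init_list.append(res.initial_points)
        joint_list.append(res)
    init_aed = aed(init_list, test_anns)
    joint_aed = aed(joint_list, test_anns)
    rate, count = correction_rate(init_list, joint_list, test_anns)

    # 16-offset validation grid, averaged over both sides
    grid_err = float(np.mean([
        evaluate_grid(agents[s].qnet_, test_scans, test_anns, s)
        for s in (Side.LEFT, Side.RIGHT)]))

    # lesion diameter on a fresh patient stack, located by the cascade
    dcfg = ph.PhantomConfig(image_height=cfg.image_size,
                            image_width=cfg.image_size,
                            n_frames_per_patient=cfg.diameter_series_frames,
                            speckle_sigma=cfg.speckle_sigma,
                            seed=test_seed + 1)
    series = ph.generate_patient_series(dcfg, np.random.default_rng(
        test_seed + 1), patient_id="PD")
    results = run_patient(series, None, agents[Side.LEFT],
                          agents[Side.RIGHT])
    measured = [diameter(*r.final_points) for r in results]
    true_d = [euclidean(ann.left_point, ann.right_point)
              for _, ann in series.scans]
    d_max_meas, _, _ = patient_summary(measured)
    d_max_true, _, _ = patient_summary(true_d)

    return PhantomStudyResult(
        init_aed=init_aed, joint_aed=joint_aed, correction_rate=rate,
        correction_count=count, n_test_images=len(test_scans),
        grid_final_distance=grid_err,
        grid_initial_offset=mean_grid_offset_norm(),
        diameter_true_max=d_max_true, diameter_measured_max=d_max_meas,
        reward_curves=curves, agents=agents)
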
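# Methods

`dqloc` locates the two lateral extreme points ("key boundary points") of a
dark serous-fluid pocket in a grayscale OCT-style B-scan and reports their
separation as the lesion diameter. It does so with a two-stage cascade: a
coarse initializer proposes one point per side, and a per-side
reinforcement-learning agent refines that point inside a local active
region. This note records the model, its assumptions, the parameters that
matter, and the design choices made where the design was genuinely open.

## The Markov decision process

Each side's refinement is a deterministic MDP on the image grid
(x = column, y = row, origin top-left).

- **State.** The agent's position plus a stack of the four most recent
  32×32 intensity patches centered on it (newest last), intensities scaled
  to [0, 1]. The stack gives the value network short-term motion context.
  On reset the start patch is replicated four times. Because 32 is even,
  the center pixel maps to patch index (15, 15) (floor-center), used
  consistently everywhere. Patches extending past the image are
  edge-replicated.
- **Actions.** Four unit moves: up, down, left, right, with "up"
  decreasing y (screen convention). Moves are clamped to the active
  region: a blocked move leaves the position unchanged.
- **Reward (training only).** The clipped change in Euclidean distance to
  the target point, `R = clip(D(before, T) − D(after, T), −1, 1)`,
  positive when the move approached the target. For unit steps the raw
  value already lies in [−1, 1] by the triangle inequality, so the clip
  only guards hypothetical multi-pixel jumps; a blocked move scores
  exactly 0. The sign convention is positive-for-approach — the
  alternative orientation would reward walking away from the target and
  cannot train a useful policy.
- **Active region.** An 80-pixel axis-aligned box centered on the
  initializer's point, clipped to the image. Only the agent's *position*
  is confined; its patches may look past the box. The region keeps
  test-time rollouts cheap and local. The region is centered on whatever
  point the first stage supplies, even when that point is poor — the
  cascade honestly inherits initializer failures rather than hiding them.
- **Termination, training.** Distance to the target ≤ 1 px (the default;
  a strict `< 1` variant is selectable — on the integer grid the
  inclusive rule admits the four neighbors, the strict rule only the
  target itself) or a budget of `N_train = 100` steps.
- **Termination, testing.** No target is available, so the rollout stops
  when the recorded Q values flatten: after at least 16 steps, compute
  δQ = |mean of the first 8 − mean of the last 8| over the most recent 16
  recorded Q values; each step with δQ < 0.3 (while under the step budget)
  increments a counter q, and the rollout stops when q reaches 2, or
  unconditionally at `N_test = 60` steps. δQ is invariant to shifting all
  Q values by a constant. The recorded per-step Q value is the maximum of
  the 4-vector — the value that drives the greedy action.

## Value networks

Four variants share one architecture family: a dense trunk on the
flattened 32×32×4 stack (default one 256-unit ReLU layer; the phantom
study uses 64 units), followed by either a single 4-way linear head
(DQN, DDQN) or a dueling pair — a scalar state-value head V and a 4-way
advantage head A aggregated as `Q = V + (A − mean_a A)`, which makes
`mean_a Q = V` hold exactly (DuelDQN, DuelDDQN). A compact
fully-connected trunk is an appropriate capacity for piecewise-constant
phantom patches and keeps CPU training fast; the trunk layout is
configurable through `QNetwork(hidden=...)` for anyone wanting a deeper
model. The networks and their Adam optimizer are implemented directly on
numpy (`dqloc._nn`), float32 throughout, He-normal initialization.

TD targets: terminal transitions contribute the bare reward; otherwise
plain variants bootstrap with `R + γ max_a' Q(s', a'; θ′)` from the target
network θ′, and double variants evaluate the online network's argmax
action under the target network, `R + γ Q(s', argmax_a' Q(s', a'; θ); θ′)`.
γ = 0.95. The loss is the mean squared TD error with gradient flowing only
through the online Q(s, a).

## Training protocol

Per epoch the images are shuffled. Per image the replay memory is cleared
(so no sampled batch ever mixes images) and `P` episodes are played, each
starting at the ground-truth point offset per axis by a margin drawn
uniformly from ±{4, 6, 8, 10, 12, 14} — initial distances between √32 ≈
5.7 and √392 ≈ 19.8 px, the error range a coarse first stage realistically
leaves. Starts are clamped into the image rather than resampled. A
gradient step fires whenever the memory size has reached the batch size
and is a multiple of the sample step `S`; the target network is re-synced
every `L` optimizer steps. Exploration is ε-greedy with ε decaying
linearly from 1.0 to 0.1 over the first half of all planned episodes, then
constant; greedy ties break toward the lowest action index
(up < down < left < right). Left and right agents are trained
independently and never share weights.

Full-scale defaults follow the regime the method was designed for:
80 epochs, learning rate 1e-4, batch 32, P = 25 episodes per image,
target sync every L = 50 updates, sample step S = 5, Adam. When a
validation split is provided, each epoch is scored by the 16-offset grid
protocol below and the best checkpoint (minimum error) is kept.

## Initializers

- **Heuristic.** Otsu threshold → dark mask → drop components touching
  the border (the vitreous background is dark and border-connected) →
  largest remaining component with centroid in the central half of the
  image → its extreme columns (bottom pixel per extreme, since the dome is
  widest at its base). If nothing qualifies it returns image-center ±
  quarter-width with a warning flag that propagates into the location
  result. On the phantoms this detector is nearly exact by construction,
  because the lesion is the only enclosed dark blob.
- **Multitask network.** A small dense trunk (default one 96-unit layer on
  a 32×32 downsampled image) with two heads: a lesion-presence logit
  (binary cross-entropy) and four normalized coordinates
  (x_L, y_L, x_R, y_R) under a smooth-L1 loss, summed with 1:1 weights
  (the weights are configuration; nothing in the problem fixes them).
  Defaults: 40 epochs, learning rate 0.001, batch 20, Adam. Coordinates
  are normalized by image size, so a model transfers across resolutions.
  Anything that yields two points can play the first-stage role; the
  cascade only consumes coordinates.

## Evaluation

- **AED** (average Euclidean distance): `(1/2N) Σ (‖left error‖ + ‖right
  error‖)` over N images — the mean per-side endpoint error in pixels.
  Reports carry both an image-weighted and a patient-weighted (mean of
  per-patient AEDs) aggregate; the patient-weighted number is the
  headline, since patients contribute different frame counts.
- **Diameter**: the 2-norm between the located left and right points;
  per-patient max/min/mean summaries over frames. Units are pixels; a
  micron conversion is a single configuration scalar.
- **Successful-correction rate**: the fraction of images whose
  single-image AED under the cascade is *strictly* below the
  initializer's; ties count as non-corrections.
- **16-offset grid protocol**: each validation image is probed from every
  offset in {−4, −14, 4, 14}² around the ground truth (mean offset norm
  ≈ 13.64 px, maximum √392 ≈ 19.8 px) and the mean final distance to the
  truth is reported.

## The phantom generator

Real clinical stacks of this kind are not publicly distributable, so the
package ships a generator whose defaults define the study conditions.
A phantom is: horizontal bright bands (grayscale means 200/150/220/170
over a background of 35) emulating the layered retina; a dark half-ellipse
dome (fluid level 15) sitting on a band, chord endpoints annotated as
ground truth; multiplicative speckle `I·(1 + σ·ε), ε ~ N(0,1)`, clipped to
[0, 255] — the standard first-order OCT speckle surrogate, with σ = 0.15
as the default study condition. Within a patient stack the band layout and
dome anchor are fixed while the chord follows a chord-of-sphere profile
`d_k = D_max·√(1 − (2k/(n−1) − 1)²)` (rounded, floored at 4 px), because a
serous detachment is approximately dome-shaped in 3-D: central frames cut
near the equator. D_max is drawn from 40–90 px at the default 128×128
size. Augmentation offers horizontal flips (which must swap the
left/right labels — annotations are side-specific) and edge-replicated
shifts; rotations and scalings are deliberately not offered.

What the phantom does *not* emulate: A-scan physics, depth-dependent
signal decay, shadowing under the detachment, vessel artifacts, other
fluid types (PED, cystoid edema), curved retinal geometry. Passing tests
therefore show that the MDP formulation, networks, training loop and
metrics are correct and that the cascade refines a degraded initializer
under speckle — not that the trained weights transfer to clinical scans,
which would require retraining on real annotated data through the same
interfaces.

## The scaled phantom study

`dqloc.experiments.run_phantom_study` is the package's reproducible
end-to-end experiment, and the sizes below are its fixed conditions:
40 training, 10 validation and 10 held-out test images (8 + 2 + 2
patients × 5 frames) at 128×128, σ = 0.15; left and right DQN agents with
a 64-unit trunk trained for 8 epochs, P = 5, learning rate 3e-4 (a
short-schedule rate; the 80-epoch full-scale default uses 1e-4), batch
32, L = 50, S = 5, with each side's best epoch selected by the
validation-grid error. At test
time the heuristic initializer's points are deliberately perturbed by
8–14 px per axis (random sign) to emulate a coarse first stage, and the
study measures: initializer-only AED, cascade AED, correction rate, the
16-offset grid error against the ≈13.64 px mean initial offset, and the
maximum-diameter recovery on a fresh 9-frame stack. All randomness derives
from a single seed.

## Numerical and degenerate-input choices

- Seeded `numpy.random.Generator` everywhere; identical (config, seed) →
  bit-identical phantoms, training trajectories and results.
- Images are 8-bit; every emitted intensity is rounded then clipped to
  [0, 255].
- `delta_q` returns a distinct "not ready" signal (None) below 16 values
  rather than a number.
- Whether the sub-threshold counter q counts consecutive or cumulative
  events is ambiguous in principle; it is cumulative here (the counter
  only ever increments), matching the unconditional increment of the
  testing loop it implements.
- The replay-update trigger compares the memory *size* (`len(M) ≥ B and
  len(M) % S == 0`), which grows by one per step until capacity — the
  literal reading of the training loop; an every-S-th-step trigger would
  behave identically until the memory wraps.
- Denoising: non-local means (strength = noise-sigma estimate in gray
  levels) and median filtering are built in; block-matching collaborative
  filtering (BM3D) is available through the optional `bm3d` extra, and the
  API rejects it with an informative error when the package is absent.
  `strength = 0` is the identity.
- Empty dataset directories read as empty lists; malformed manifest rows
  fail with their row number; a shift augmentation that would push an
  annotation out of bounds is rejected rather than clamped.

## Known limitations

- The dense trunk underperforms a convolutional one on textured real
  images; swap in a stronger function approximator before clinical use.
- The heuristic initializer is phantom-shaped: on real scans, where other
  dark structures abound, the multitask network (retrained) or any
  external detector should supply the first stage.
- The test-time stop rule can fire early when the agent starts near a
  local Q plateau; the step budget bounds, but does not eliminate, the
  resulting error.
- Single lesion per image; multi-lesion scans would need a detection
  stage ahead of the cascade.
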
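# Methods

`landmarkrl` localizes a point landmark in a 3D scalar volume with a deep
Q-learning agent that observes 2.5D patches and walks the voxel grid. This
note records the model, the default parameters and why they are what they
are, the synthetic data the package is validated on, and the numerical and
design choices that were genuinely open.

## The decision process

The volume is the environment; the agent's state at time *t* is a stack of
`H+1` *frames*, each frame holding the three orthogonal `N x N` slices
(normals along x, y, z) through the agent's position at time `t-h`,
`h = 0..H`. The default history order is `H = 3`, so the state is a
`4 x 3 x N x N` tensor; at episode start all frames replicate the current
position. Keeping a short trajectory in the state gives it a higher-order
Markov character: the agent can infer its direction of travel, which
discourages cycling. Intensities are windowed linearly to `[0, 1]`
(configurable window; for CT data a `[-200, 800]` HU window is the natural
choice, phantoms use `[0, 1]`), and samples outside the grid take the window
minimum — an air-equivalent neutral background.

The action set has seven elements: one voxel-step along each signed axis,
scaled by a step size `rho` (default 3 voxels), plus a stationary action.
The reward for a move from `p_i` to `p_{i+1}` with target `g` is the
decrease in distance to the target. Two variants are implemented:

* `squared` (default): `||p_i - g||^2 - ||p_{i+1} - g||^2`, integer-exact in
  voxel units; over any trajectory the rewards telescope to
  `d^2(p_0, g) - d^2(p_T, g)`.
* `plain`: the same difference of unsquared Euclidean distances, bounded by
  `±rho` per step.

The squared form is the default definition; the plain form is exposed
because the two differ materially for learning dynamics (see the
desk-scale protocol below). Episodes terminate when the agent comes within
`reach_tol` voxels of the target (default 3, one coarse step — a stricter
tolerance is unreachable at `rho = 3`), leaves the grid, or exhausts the
step cap (default 1500).

## The Q-network

The approximator factorizes exactly along the state's structure:

* Per-axis convolutional encoders `xi_j` (parameters `theta_j`): shared
  across frames, *not* shared across the three image axes — the three
  orthogonal views carry different anatomy and deserve separate filters.
  Reference encoder: three 3x3 stride-2 convolutions (1→8→16→32 channels,
  'same' padding) and a linear layer to 64 features per plane, ReLU
  throughout.
* Per-frame local inference `psi_h` (parameters `omega_h`): one fully
  connected layer per frame (192→64), *not* shared across frames, fusing
  the three plane codes of that frame.
* Global inference: one fully connected layer (256→128) over the
  concatenated frame codes `s_bar`.
* Heads: either a dueling pair — state value `V` (128→1, parameters `beta`)
  and advantage `A` (128→7, parameters `alpha`) aggregated as
  `Q = V + (A - mean(A))`, which makes `mean(Q) = V` exactly and removes
  the shared-offset unidentifiability — or a single plain linear head
  (128→7). Plain and dueling modes share the encoder exactly; only the
  heads differ.

The network and its reverse-mode gradients are implemented directly in
NumPy (im2col convolutions lowered to BLAS matrix products); gradient
correctness is verified against central finite differences in float64 in
the test suite. Initialization is He-uniform with zero biases.

### FLOPs accounting

`count_flops` computes the cost of one forward pass from the architecture
description alone: one multiply-accumulate per conv/FC output element
counts as one FLOP; biases, activations, and the dueling mean-subtraction
are excluded; the per-axis encoder cost is incurred once per plane pass
(`(H+1) x 3 = 12` passes). Under this convention the reference dueling
network at `N = 32` totals 2,466,816 FLOPs (≈ 2.47 M). The convention is
stated in the `flops` CLI output; other conventions (counting
multiply+add as 2, including biases) scale the number but not the
architecture comparison it supports.

## Training

Standard experience-replay deep Q-learning: a FIFO replay buffer (default
capacity 1.5e5) sampled uniformly, an epsilon-greedy behavior policy with
epsilon decaying linearly 0.9 → 0.1 (default over 5e4 steps; the endpoints
are the protocol, the decay length is ours), a frozen target network
re-synced every `target_sync_every` steps (default 2500; "periodically" is
the protocol, the number is ours), and the loss

    L(theta) = E[(r + gamma * max_a' Q(s', a'; theta^-) - Q(s, a; theta))^2]

with `gamma = 0.9`, bootstrapping masked on terminal transitions (the
standard stable reading). Optimization is Adam (default lr 1e-4, ours) with
global gradient-norm clipping at 10 (ours, a stability guard). One
gradient step is taken per `update_every` environment steps (default 1)
after a warm-up of `max(batch_size, 1000)` stored transitions. Each
episode draws a volume uniformly and starts at a uniform voxel within the
central 80% of each dimension.

### Fine-rehearsal episodes

The test-time procedure (below) runs a refinement phase with unit steps in
the immediate neighborhood of the target — a state distribution that
ordinary training barely visits, because episodes terminate on arrival and
use the coarse step size. `TrainConfig.fine_fraction` therefore lets a
fraction of episodes rehearse that regime: start 2–12 voxels from the
target, step size 1, reach tolerance 1, short cap. Default 0 (off); the
desk-scale protocol uses it. This is a training-distribution choice, not a
change to the learning rule.

## Coarse-to-fine localization

At test time the agent cannot be trusted to stop at the target, so the
procedure is two fixed-iteration phases with a step-size decay:

1. **Coarse:** one greedy (`epsilon = 0`) rollout from the start point
   (default: the volume center) with `rho = 3` for ~100 steps. Out-of-grid
   moves are clamped to the boundary rather than terminating, so the phase
   always completes.
2. **Fine:** five agents spawned uniformly in an L2 ball (default radius 6
   voxels = 2 coarse steps) around the coarse endpoint, each rolled out
   greedily with `rho = 1` for ~50 steps. The prediction is a weighted
   average of the five endpoints, rounded half-away-from-zero.

The weights are uniform by default. A `value_softmax` option weights each
agent by the softmax of its final state value `V`. Caveat: with
distance-difference rewards, `V` estimates the *remaining collectible
reward*, which grows with distance to the target, so softmax-over-V tends
to upweight agents that end far away; with reward structures where `V`
peaks at the goal the option behaves as its name suggests. Uniform is the
default and is what the package's own evaluations use.

Reported errors are Euclidean distances in mm via the voxel spacing;
internal rewards are voxel-based.

## Synthetic phantoms

Each phantom is a bright spheroid (radius 10–14 voxels, "aortic root")
with a tube (radius 2, length 18, "coronary artery") attached at a random
surface point and pointing radially outward, over a dark background
(intensity means 0.8 / 0.15, Gaussian noise sd 0.03, clipped to [0, 1],
64^3 voxels at 0.33 mm isotropic). The landmark is the tube–sphere
junction, the analogue of a coronary ostium. Geometry is rejection-sampled
so the junction is at least 8 voxels from every face (observations at the
target are padding-free at `N = 16`) and the tube fits inside the grid.

The spheroid carries an angular intensity shading (strength 0.35): voxels
on the junction side of the sphere are at the full foreground intensity and
the far side is dimmed by 35%. This is the phantom's analogue of the
consistent surrounding structure that makes a real landmark learnable — a
target whose surroundings carry no directional information cannot be found
by a local-patch agent except by exhaustive search. With `shading = 0` the
tube itself is the only cue, and it is invisible from most directions at
slice thickness 1.

What the phantoms do **not** emulate: anatomical shape variability, HU
calibration, contrast inhomogeneity, neighboring structures (heart
chambers, valves), motion or reconstruction artifacts. Passing the
end-to-end tests therefore shows that the machinery — state encoding,
value learning, coarse-to-fine search — works as designed on a consistent
target; it does not certify accuracy on clinical CT.

Suites default to a 24/8 train/test split at 32 phantoms (`generate_suite`),
with seeds `base_seed + i` per phantom.

## Desk-scale end-to-end protocol

The full-scale defaults above are sized for long training runs. The
package's own end-to-end tests (and the numbers in the README) use a
desk-scale protocol chosen to fit a single CPU:

* observations `N = 16`, `H = 3`; phantoms 64^3;
* 96 training phantoms, 8 held-out test phantoms from a disjoint seed
  range (held-out generalization is the binding constraint at this scale:
  with 24 training phantoms the learned move-direction field generalizes
  markedly worse than with 96);
* 300 episodes of at most 150 steps; replay capacity 2e4; batch 32;
* one gradient step per 4 environment steps; Adam lr 3e-3; epsilon decay
  over 3000 steps; target sync every 500 steps;
* `plain` reward: at this training budget the squared reward's dynamic
  range (state values spanning three orders of magnitude) dominates the
  squared-error loss and starves the per-action differences the policy
  needs; the bounded plain reward conditions the regression much better,
  and is the package's documented reading for desk-scale runs;
* fine-rehearsal episodes at fraction 0.65 (start 2–12 voxels out, unit
  steps, tolerance 1, cap 60).

Under this protocol the 30-episode moving-average reward reliably rises
from the first to the last quartile of training, and held-out localization
reaches median errors of roughly 4–8 voxels (seed-dependent). A reference
experiment locates the remaining gap squarely in value-learning quality
rather than in the search procedure: a direction classifier trained with
clean geometric labels on the same architecture and phantoms (held-out
top-1 accuracy ≈ 0.77) drives the identical coarse-to-fine procedure to a
median error of ≈ 1.4 voxels. Closing that gap with Q-learning requires
substantially more episodes and gradient steps than a desk-scale budget
admits; consistently, training runs at full scale report reliable
localization only after several hundred episodes on GPU-class budgets.

## Numerical choices and degenerate inputs

* Patch centering covers `c - floor(N/2) … c - floor(N/2) + N - 1`; even
  `N` is left-biased by one voxel, fixed and documented.
* Greedy ties (equal Q) break to the lowest action index in the fixed
  order `+x, -x, +y, -y, +z, -z, stay`.
* `weighted_average` rounds half away from zero, component-wise.
* Rewards in `squared` mode are computed in integer arithmetic and are
  exact; the telescoping identity is asserted exactly in tests.
* Replay sampling is uniform without replacement within a batch; sampling
  more than the buffer holds is an error (callers wait out the warm-up).
* A terminal environment refuses further steps; observations at
  out-of-grid positions are fully padded rather than errors.
* Checkpoints are `.npz` archives with a JSON architecture header; loading
  verifies the architecture (and optionally the head mode) and fails
  loudly on mismatch.
* All randomness flows from per-run integer seeds through named
  `numpy.random.SeedSequence` substreams (network init / environment /
  replay); training, phantom generation and localization are bit-
  reproducible given their seeds.

## Known limitations

* The reward is isotropic in voxel units; with anisotropic spacing the
  distance being minimized is not metric distance (no correction is
  applied; inputs are assumed near-isotropic).
* Volumes are assumed axis-aligned; no resampling or reorientation is
  performed and DICOM is not ingested.
* One landmark per run; multi-landmark search would need one agent per
  landmark or a shared backbone, neither of which is implemented.
* The NumPy backend is single-threaded BLAS-bound; it is sized for the
  desk-scale protocol, not for full-scale training.
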
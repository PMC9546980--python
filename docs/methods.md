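# Methods

## Problem and scope

Semantic segmentation of mitochondria in volume EM is a per-voxel binary
classification task with heavy class imbalance (foreground is typically a
few percent of voxels) and annotation noise at object borders. This package
implements a family of deliberately lightweight encoder–decoder networks and
— just as importantly — the surrounding machinery that determines the final
number: how patches are sampled, how tiled predictions are stitched, which
post-processing operators run, how the Jaccard score is defined, and how
run-to-run variance is reported. Competing architectures and full-scale GPU
training on the public EM datasets are out of scope; the package ships a
CPU-scale profile and a synthetic data generator instead.

## Networks

All presets share one construction grammar:

* **Processing block**: two same-padded 3×3 (3×3×3) convolutions with
  biases, each followed by the activation (ELU, α = 1, by default) and
  dropout. The residual variant uses full pre-activation ordering
  (activation before each convolution) with an identity shortcut, replaced
  by a 1×1 projection whenever the channel count changes.
* **Downsampling**: 2× max pooling per level; 3D presets can disable the Z
  factor per level (`z_down`), which the anisotropic presets do everywhere.
* **Upsampling**: transposed convolution with kernel 2 and stride 2 — the
  exact shape-mirror of the pooling, and the convention under which the
  3D preset counts reproduce the published figures exactly.
* **Feature merge**: concatenation; with attention gates enabled the skip
  features are first modulated by an additive gate (1×1 projections of skip
  and gating signal, add, ReLU, 1×1 → 1 channel, sigmoid, multiply). The
  gating signal is the decoder feature map after upsampling at the same
  level, and the internal projection width equals the skip channel count —
  the published material does not fix these two numbers, so they were chosen
  as the simplest option and validated against the printed 1.99 M total.
* **Squeeze-excitation**: global-average-pool squeeze, two dense layers
  (ReLU then sigmoid) with reduction ratio r = 8, channel-wise rescale;
  placed after every processing block except the bottleneck
  (`all_but_bottleneck`) or after every convolution (`every_conv`).
* **Head**: 1×1 convolution to one channel + sigmoid.
* **Batch norm** is off by default (it degraded performance in the original
  ablation) but available as a flag; its running statistics are
  non-trainable and excluded from parameter counts.

Parameter counting is exact enumeration of the constructed weight tensors.
Under these conventions the presets count 788,817 (3D U-Net → 0.79 M) and
1,501,293 (3D residual → 1.50 M), matching the published figures exactly,
as do the 2D SE (1.95 M), attention (1.99 M) and residual (2.03 M) variants.
The basic 2D U-Net comes to 1,940,817 → 1.94 M against a printed 1.95 M
(0.47% difference); since four of six figures reproduce exactly, the
conventions are kept and the 1% band covers the remainder.

Dropout rates ramp linearly from 0.1 at the first level to 0.3 in the
bottleneck and back down in the decoder. The 2D schedule is
(0.1, 0.1, 0.2, 0.2, 0.3); for 3D depths where only the endpoints are
specified, the ramp is linearly interpolated.

### The compute core

No deep-learning framework is assumed: the networks run on a small tape-based
reverse-mode autodiff engine (`mitoseg.nn`) written on numpy, with
convolutions expressed as per-kernel-offset channel-mixing matmuls (BLAS
does the heavy lifting) and hand-written vector–Jacobian products verified
against central finite differences in the test suite. Inference runs in a
no-grad mode that frees activations eagerly, so full 80³ 3D patches fit
comfortably in memory. Weight initialisation (He normal by default, Glorot
uniform optionally) is driven by a seed sequence in construction order:
same spec + same seed ⇒ bit-identical weights.

## Sampling

Random patch centers are drawn from a probability map in which every
foreground voxel carries a common weight chosen so total foreground mass is
0.5 (background weight 1, then normalised) — a direct class-balancing
reading of "prioritise patches containing mitochondria"; the map degrades to
uniform on all-background volumes. Patches below a foreground-fraction
threshold can be rejected and redrawn (bounded retries, with a warning
fallback when unattainable); the default threshold when discarding is
enabled is 0.5% foreground, a value the source material leaves open.
Validation splits take `round_half_up(0.10 · n)` slices (minimum 1), random
or trailing-consecutive. Augmentation applies identical in-plane right-angle
rotations and flips to image and label; elastic deformation (default
amplitude 10 voxels, Gaussian correlation length 4) warps images bilinearly
and labels nearest-neighbour, sharing one in-plane field across Z so 3D
patches stay coherent.

Systematic grids use half-open boxes in lexicographic (Z,Y,X) order. Two
border policies exist: *shift-inward* (sampling; the last box per axis moves
flush with the border, guaranteeing bit-exact flat-merge round trips) and
*reflect-padding* (inference; the volume is padded to a whole number of
strides so blending windows apply cleanly, and the merge crops back).

## Reconstruction

Merging computes `out[v] = Σ w_i(v)·p_i(v) / Σ w_i(v)` in float64 and casts
to float32. The blending window is the separable squared-sine taper
`s(t) = sin(π(t+0.5)/n)^power` with `power = 2` — a standard realisation of
a "second-order spline window" — floored at 10⁻³ at the outermost voxels so
no voxel ever has zero weight. TTA enumerates the in-plane dihedral group
(8 elements) and, in 3D, its product with the Z-flip (16 elements); each
variant carries an exact inverse descriptor, and averaging happens in
probability space (the standard ensemble choice; the source is silent on
averaging before vs after binarisation). 3D spline blending is disabled by
default on cost grounds and must be forced explicitly. Full-image 3D
inference above a voxel budget raises with advice to use overlap mode,
mirroring the accelerator-memory limitation it stands in for.

## Post-processing

Binarisation thresholds at 0.5 with ties going to foreground. Spurious
removal drops connected components below `min_area` (default 100 voxels;
8-connectivity per slice in 2D mode, 26 in 3D). Watershed refinement erodes
the mask (disk radius 2) for foreground markers, dilates it (radius 5) for
the background complement, and floods the in-plane morphological gradient;
slices whose markers vanish pass through unchanged. These parameters are
explicit configuration, not a claimed faithful reproduction of the original
pipeline they are inspired by (whose exact criteria are not published).
Z-filtering is a per-column sliding median (default window 3, reflected
edges). All operators return strictly binary masks; `run_chain` logs voxels
changed per step and exposes a metric hook for incremental score tables.

## Metrics

`IoU_F = TP/(TP+FP+FN)`, `IoU_B` with classes swapped, `IoU_O` their exact
mean. Empty-union convention: 1.0 when both masks are empty, 0.0 when
exactly one is — required for averaging over background-only patches.
Per-patch aggregation is the unweighted mean, and shifted border patches are
cropped to the valid region rather than double-counting padding. The
perturbation probe reports foreground IoU of 1-pixel dilated and eroded
ground truth against the original, using a 3×3 in-plane square element per
slice by default (annotations are per-slice); the published real-data values
(0.885/0.904 on the Lucchi annotations) require downloading that dataset and
are covered by an opt-in test only.

## Stability harness

`train_model` minimises BCE with SGD (momentum 0.99, no decay, constant
lr 0.002, batch 6), early-stops after 100 epochs without validation-loss
improvement and restores the best-validation weights. `repeat_runs` executes
the same configuration with seeds `base_seed + i`; a failed run is recorded
as missing, never dropped from the count. `summarize` reports per-cell mean,
sample standard deviation (n−1; NaN for a single run) and max, with cells
ordered as in the reference tables. The "maximum" is taken per cell
independently (one possible reading of the published tables, chosen and
documented here). CPU determinism is the reproducibility reference: with a
fixed base seed the whole harness is bit-identical, which is this package's
answer to accelerator non-determinism.

### Desk profile

The shipped `desk` profile is the CPU-scale stand-in for the full protocol:
a 2-level 2D network (16→32 filters), 64×64 patches, ≤30 epochs, 3 runs on
synthetic fixtures, with the published optimiser settings unchanged. One
epoch covers 96 patches — chosen so the fixture volume is sampled about as
densely per epoch as the full-scale setup samples its training stack; with
a much sparser epoch the network is still descending when the epoch budget
ends. Each run takes ~80 s on one CPU and reaches foreground IoU ≈ 0.95 on
held-out fixtures. This establishes that the pipeline trains, stitches and
evaluates correctly — not that any real-data score is reproduced; full-scale
results additionally need the real datasets, GPU-scale training and 10-run
statistics, which the harness supports structurally but the tests do not
execute.

## Synthetic fixtures

`make_volume` places rotated ellipsoids (in-plane major semi-axis 5–12
voxels, elongation 0.45–0.85, Z semi-axis divided by the anisotropy factor)
fully inside the volume, rejecting candidates overlapping existing
foreground by more than half their own volume. Intensities: background
Gaussian (mean 0.55, σ 0.06), darker interiors (0.22), a bright 2-voxel
in-plane rim (0.80) as the membrane analogue, light in-plane smoothing,
clipped to [0,1]. Labels are the exact ellipsoid interiors. The fixtures are
intensity-separable by design (an Otsu threshold already recovers the labels
with foreground IoU > 0.5), which guarantees tiny networks can learn them in
minutes; they deliberately lack cristae, membrane contacts, staining
gradients and imaging artefacts, so green tests validate machinery, not
real-world accuracy. `corrupt_labels` simulates an imperfect prediction
(boundary-band flips, uniform salt-and-pepper flips, small spurious blobs,
all seeded; with all rates zero it is the identity), enabling post-processing
and metric tests without any training.

## Numerical choices

* Patch merging accumulates in float64, outputs float32; flat-weight round
  trips are bit-exact.
* Millions of parameters are rounded half-up to two decimals.
* Dropout is inverted (scale 1/(1−p) at train time); evaluation is
  dropout-free.
* BCE clips probabilities at 10⁻⁷ for the log; the gradient is zeroed in
  the clipped region.
* Thresholds, radii, window sizes and connectivities are all exposed as
  keyword arguments or config keys; the defaults stated above are the ones
  the tests pin.

## Known limitations

* No GPU path; full-scale (256² × hundreds of slices, 360 epochs) training
  is impractical on CPU and is not attempted.
* The watershed and spurious-detection parameters are plausible defaults,
  not a validated reproduction of the pipeline that inspired them.
* Elastic augmentation shares one displacement field across Z rather than
  warping in 3D.
* The attention-gate projection widths are inferred from the parameter
  budget, not from a published table.
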
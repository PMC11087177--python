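# Methods

This note documents the models, numerical choices and study conditions the
package implements, and what its synthetic experiments can and cannot
show.

## Paired-course phantom

Every stage is exercised on synthetic paired-course cases. A case is an
analytic pelvis surrogate on an air background (−1000 HU): an elliptic
soft-tissue cylinder (≈0 HU) with a mild axial taper, two axially
truncated bone rods (+700 HU) whose end caps anchor the slice direction
(like femoral heads), several mid-contrast organ surrogates (±60–120 HU
ellipsoids standing in for bladder/rectum/bowel) scattered around the
target, and a smooth random cosine texture (±40 HU) that gives
registration metrics gradient structure inside otherwise uniform soft
tissue.

The target is modelled the way clinical CTVs are actually constructed:
a CT-visible gross lesion (+80 HU ellipsoid) expanded by a
*suspected-spread margin* that is isointense with soft tissue. The margin
width is a per-case clinical judgement (drawn from 4–12 mm across a
cohort) with no intensity correlate, so its extent is knowable only from
the delineated contour. This single property sets the information balance
the whole comparison rests on: direct segmentation can find the lesion but
must guess the margin; registration propagates the full contour but is
limited by its warp estimate; the guided networks see both. (An earlier
design with a fully visible target inverted the clinical ordering — a
sufficiently wide direct-segmentation network out-scored deformable
propagation and the guidance channels degenerated into a shortcut — which
is why the margin construction is load-bearing, not decorative.)

Course 1 renders this anatomy on the grid; course 2 renders the *same*
anatomy at `T(x) = R(x) + u(x)` where `R` is a rigid motion (default
offset ≈6 mm, rotation 3° about the slice axis) and `u` a smooth random
warp. Both courses receive independent Gaussian intensity noise
(σ = 12 HU) and are clipped to the CT window (−1000, 1500) HU.

Because course 2 is re-rendered analytically at warped coordinates rather
than resampled from the course-1 raster, the inter-course transform is
known *exactly* and is stored with the case as a dense displacement field
on the course-2 grid. Propagating CTV1 through the stored field therefore
recovers CTV2 up to a one-voxel resampling shell at the mask boundary —
the test suite asserts exactly that.

The warp is a low-resolution random vector lattice (one knot per
correlation length, default 60 mm) upsampled by cubic spline, rescaled so
the maximum displacement equals `deform_amplitude_mm` and capped below
half the correlation length, which keeps the map invertible. The default
amplitude is 20 mm. This is a deliberate calibration, not a clinical
estimate: inter-course deformation magnitudes are not identifiable from
the summary statistics the package targets, and the defaults are chosen so
that the qualitative method ordering (deformable > rigid propagation;
guided > unguided segmentation) is *observable* on cohorts of a few dozen
cases. With gentle warps (≤8 mm) rigid propagation is near-ceiling on this
phantom and all methods collapse together. Cohorts draw per-case
magnitudes from fixed ranges (offsets ±6 mm lateral / ±2 mm axial,
rotation ±5°, warp amplitude 16–26 mm, target radii ±10%, margin width
4–12 mm) via per-case seeds derived from the cohort seed by a counter.

What the phantom does **not** model: organ-filling changes that move the
CTV relative to its surroundings (the transform moves everything
consistently), CBCT artifacts, couch/table structures, multi-organ
context, and observer variability in the reference contours. Passing the
ordering experiment here shows the pipeline's machinery and the relative
information content of its inputs behave as designed — not that the
clinical effect sizes transfer.

## Registration

Both stages use SimpleITK's `ImageRegistrationMethod` on a four-level
image pyramid (shrink factors capped so no level drops below ~4 voxels per
axis).

**Rigid (RB).** Mattes mutual information (32 bins), random 25% metric
sampling with a fixed seed, regular-step gradient descent with initial
step 8, minimum step 10⁻³, at most 500 iterations, scales from physical
shift, geometric-centre initialization. These settings follow the stated
ITK protocol for the rigid stage.

**Deformable (DIR).** A cubic B-spline refined coarse-to-fine: the
control-point mesh starts coarse and doubles at every pyramid level,
reaching a control-point spacing of `grid_spacing_voxels` at the finest
level (default 16 voxels; the desk-scale study uses 6 on its 4-mm grids so
the physical knot spacing stays comparable, over its own 3-level pyramid).
The coefficients are optimized by L-BFGS with *mean squares* as the
similarity metric and deterministic regular-grid sampling, initialized
from the rigid stage, and the composite map is materialized as a dense
voxel displacement field on the fixed grid.

Two deviations from a literal reading of the protocol, both forced by
experiment. First, a regular-step gradient step sized for a 6-parameter
rigid transform is far too large in a dense coefficient space — the
quasi-Newton optimizer replaces it for the B-spline stage only. Second,
driving an *unregularized* B-spline with mutual information consistently
degraded a good rigid initialization on this phantom (DSC drops of
0.05–0.15 with >30 mm coefficient excursions): MI can be increased by
histogram compaction without anatomical correspondence, a pathology that
dedicated deformable stacks suppress with explicit regularization. Both
courses are CT with a shared intensity scale, so mean squares is the
appropriate metric and is stable here; MI is retained for the rigid stage
where the low-dimensional transform cannot exploit it.

Propagation resamples images with linear interpolation and masks with
nearest neighbour (outputs strictly binary); voxels mapping outside the
moving image are filled with −1000 HU (images) or 0 (masks).

## Preprocessing

Slab → crop → resample → normalize, applied identically to every channel
of a case. The axial slab keeps `slab_slices` (default 48) contiguous
slices containing every positive slice of the available contours, centred
on their axial midpoint when there is slack and clamped to the volume. The
crop is lateral only: the bounding box of the union of the body masks of
CT2 and the aligned CT1, where a body mask is the largest
above-threshold (−300 HU) connected component, morphologically closed
(kept extensive) and hole-filled. Images are resampled linearly and masks
by nearest neighbour onto the training grid (default 192×160×48; the
desk-scale study uses 24×24×16), then intensities are clipped to
(−1000, 1500) HU and mapped affinely to [0, 1]. Whether cropping precedes
slab extraction is not prescribed anywhere; the order here is slab first,
which makes the axial extent independent of the lateral crop.

## Networks

All four variants share one encoder-decoder skeleton built from
convolution modules (3×3×3 convolution, instance normalization,
LReLU α=0.2). Downsampling is a stride-2 convolution that doubles the
channel count; on the first and last downsampling steps only the lateral
dimensions shrink (for a 192×160×48 input the axial sizes run
48→48→24→12→12). Decoder stages mirror the strides with transposed
convolutions (kernel = stride), concatenate the skip tensors from every
encoder path, apply a squeeze-and-excitation channel-attention gate to the
concatenated skip (global average pool → bottleneck with reduction 8 →
sigmoid gates in (0,1), channel-wise rescaling), and run two convolution
modules. 1×1×1 heads produce class logits at the final stage and at the
three coarsest decoder stages; the coarse logits are upsampled to full
resolution by trilinear interpolation, summed with the final head, and
softmaxed over K=2 classes (background included — the Dice average runs
over both). The loss sees only the combined map; per-head auxiliary losses
are the documented alternative and are not used.

`mcmp` gives each input channel its own encoder path with no cross-path
mixing before the decoder (its encoder parameter count is exactly 3× the
single-path build); `mcsp` stacks the three channels into one path;
`scsp` is the single-channel variant; `unet3d` is the plain isotropic
reference without channel attention, deep supervision or the anisotropic
schedule. Depth and width default to 5 levels / base 16 filters and scale
down for desk-scale runs (3 levels / base 4). Channel-attention placement
on the concatenated multi-path skip is a design choice: that is the one
place where re-weighting across paths is meaningful.

The tensor machinery is an in-repo numpy reverse-mode autodiff
(`rgmcmp.nn.autodiff`): im2col convolution with per-axis strides,
non-overlapping transposed convolution, instance norm, separable linear
resampling, channel softmax. Everything is float32, single-sample
(batch 1), CPU-only — adequate for the grid sizes this package targets.

## Training protocol

he_normal initialization from the run seed; Adam, batch size 1; validation
loss once per epoch; LR ×0.2 after 30 consecutive non-improving epochs;
stop after 50; the returned model is the best-validation checkpoint.
"Non-improving" means not strictly below the best value so far (tolerance
0), both patience counters run from the same best epoch, and the LR
reduction may fire repeatedly. `max_epochs` (default 1000) exists only as
a hard stop. Data order is reshuffled each epoch from the seed; no
augmentation. Two runs from the same seed and data are bit-identical.

## Metrics

DSC with the doubly-empty case defined as 1. Surface distances use a
voxel-centre point model: surface voxels are mask voxels with a
face-adjacent background neighbour (grid boundary counts as background);
distances are exact Euclidean in physical mm via distance transforms, and
are validated against an O(n²) all-pairs oracle in the tests. HD95 is the
95th percentile — linear interpolation between order statistics — of the
*pooled symmetric* distance multiset (both directions together), and ASD
its mean; both are therefore symmetric in their arguments. Empty masks
make the surface metrics undefined and raise.

## Comparison harness and statistics

The cohort is split train/validation/test (default fractions
0.6/0.2/0.2, in cohort order — cases are i.i.d. by construction).
Registration guidance and preprocessing are computed once per case and
shared; every deep-learning method is trained with the *same* TrainConfig;
every method, including registration-only propagation, is scored on the
preprocessed network grid so that comparisons are not confounded by grid
resolution. Paired t-tests are two-sided (directions are reported
separately; sidedness is otherwise ambiguous), Pearson is used for the
delta correlation, and no multiple-testing correction is applied (none is
applied in the protocol being followed; the report flags this).

## Desk-scale study conditions

The clinical-scale protocol (hundreds of thousands of parameters,
192×160×48 grids, 60 training cases, thousands of epochs on a GPU) is not
reproducible on one CPU. The package's own study conditions
(`rgmcmp.presets.ScaledStudy`) are: 16-case cohorts (10 train / 3
validation / 3 test) on a 48×48×24 phantom lattice at (4,4,5) mm,
networks at 32×32×16 with 3 resolution levels and base 8 filters, Adam at
LR 2·10⁻³ for up to 30 epochs with best-validation checkpointing, and
B-spline control spacing 6 voxels with 30 L-BFGS iterations per level over
a 3-level pyramid. The higher learning rate and shorter schedule
compensate for the ~100× smaller step budget; the protocol semantics
(shared hyperparameters across all network variants, best-validation
checkpointing) are unchanged. The whole chain is deterministic given the
cohort and training seeds — seeded phantom sampling, seeded metric
sampling in the registration, seeded initialization and data order — so
the study's numbers are exactly reproducible. The acceptance script runs
exactly these conditions and reports per-method mean DSC/HD95/ASD on the
held-out test cases.

At this scale the mean test DSC across three training seeds reproduces
the qualitative structure of the clinical comparison: direct segmentation
lowest, rigid propagation next, deformable propagation above it, the
guided networks on top with the multi-path variant leading. The margins
between the guided networks and between DIR-MCMP and DIR are a few
thousandths to ~0.01 DSC — an order of magnitude smaller than the
clinical deltas, as expected with 10 training cases versus 60 — so the
ordering is meaningful only under the fixed seeds the tests pin down;
nearby configurations can reorder the near-ties.

## Known limitations

* The phantom's single-tissue, single-target geometry makes direct
  intensity segmentation easier than clinical CT; absolute DSC values are
  therefore higher than clinical ones, and only orderings and deltas are
  meaningful.
* The deformable stage has no explicit bending-energy regularization; its
  stability here relies on coarse-to-fine refinement and the capped,
  smooth phantom warps.
* The autodiff engine materializes im2col patch matrices and keeps them
  for the backward pass; memory scales with network size × grid volume and
  is sized for desk-scale grids, not 512³ CT.
* Desk-scale training runs are short; per-seed variance of the learned
  methods is a few DSC points, which is why ordering claims are made on
  means over seeds.
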
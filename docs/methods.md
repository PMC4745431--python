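# Methods

## Problem and model

`spinereg` estimates the rigid transform `T_2d3d` that places a preoperative
CT volume into the coordinate frame of an intraoperative biplanar C-arm
acquisition. The search variable is a 6-vector pose
`(Tx, Ty, Tz, Rx, Ry, Rz)` — translations in mm, rotations in degrees,
applied as intrinsic `Rz·Ry·Rx` about a fixed pivot (the centroid of the
registration region). The pose convention is a free choice: the optimizer
explores the same rigid manifold under any fixed Euler order, so the order
only fixes the meaning of the six numbers, not the reachable transforms.

Each C-arm view is an ideal pinhole: a point source and a planar detector
with orthonormal in-plane axes. Given a pose, a digitally reconstructed
radiograph (DRR) is rendered per view by casting one ray per detector pixel,
clipping it to an axis-aligned region-of-interest (ROI) box around a single
vertebral body in the CT frame, and accumulating `max(HU, 0) · step` at
uniform steps with trilinear interpolation. X-ray physics maps intensity to
the exponential of the attenuation line integral; since the gray level of a
radiograph is proportional to the logarithm of received intensity, the
accumulated Hounsfield sum is used directly as the DRR gray level, then
min-max windowed to 8 bits. The registration objective is a similarity
measure between radiograph and DRR, averaged over the AP and LA views, and
maximized over the pose inside a symmetric box around the initial estimate.

Key modelling choices, all configurable:

- **HU clamping at 0.** Air (negative HU) contributes nothing to the
  integral; letting it contribute negatively would bleach bone contrast.
- **Step size** defaults to half the smallest voxel spacing (a standard
  quadrature/Nyquist compromise); the benchmarks use 1.0 mm (below), which
  on this phantom changes NCC scores only in the 4th decimal.
- **Windowing is per-image min-max**, not a fixed HU window. NCC and GC are
  invariant to this linear map; PI and GD operate on the windowed 8-bit
  images with an inter-image scale factor of 1, so no scale search loop is
  run.
- **Rounding** to 8 bits is floor(x + 0.5) of the scaled float
  (half-away-from-zero on exact halves), so quantization is bit-exactly
  reproducible across runs and platforms.

## Similarity measures

Five measures over an explicit validity mask (instrument shadows and
out-of-field pixels excluded): normalized cross-correlation (Pearson r),
gradient correlation (mean of the u- and v-Sobel-gradient NCCs, mask eroded
1 px), pattern intensity (neighborhood-difference kernel
`σ²/(σ² + Δd²)` over the difference image, σ = 10, radius = 3 px),
gradient difference (`A/(A + (∇d)²)` with A the fixed image's gradient
variances), and mutual information (64-bin joint histogram, log base 2).
All are oriented larger-is-better so one optimizer contract serves all five.
Pattern intensity reflect-pads the difference image (edge-repeating, the
same convention as the Sobel filtering) so every masked center keeps a full
neighborhood; its analytic maximum is then exactly `N·K` and gradient
difference's exactly `2N`, which the tests assert. Each measure is verified
to 1e-9 against an independent nested-loop implementation.

## Instrument masking

Metal instruments (reference-frame clamps, retractors) appear as dark
shadows only in the radiograph. The shadow is segmented by seeded region
growing (4-connected, criterion |I − I_seed| ≤ tolerance against the fixed
seed intensity for determinism; tolerance default 25). The segmented region
is then both painted to 0 in radiograph *and* DRR — so both images carry
identical "noise" — and removed from the similarity mask. Painting alone
would let two identical painted regions inflate the score; exclusion alone
would discard the construction entirely; doing both is the safe superset,
and the tests assert the score is independent of whatever pixels lie under
the mask.

## Optimizers

All three searches are bounded to a symmetric box (default ±5 mm / ±5°)
around the initial pose, enforced by clamping rather than penalties so the
reported score stays a pure similarity. Shared defaults: score tolerance
`ftol = 1e-5`, parameter tolerance 0.01 mm / 0.01°, evaluation budget 2000.

- **Powell** direction-set ascent with bounded line searches
  (scipy's bounded Powell).
- **Downhill simplex** (Nelder–Mead; reflection 1, expansion 2, contraction
  0.5, shrink 0.5) with vertices clamped to the box. The initial simplex
  edge is 50% of each bound half-width, and after each convergence the
  search restarts from the incumbent with a fresh 10%-edge simplex until a
  restart gains less than `ftol` (at most 4 restarts). The large first
  simplex plus restarts is the classical guard against premature collapse;
  with a 10% first edge the simplex frequently stalled several millimetres
  from the optimum when started near the box corners.
- **Real-coded genetic algorithm**: population 40, 30 generations,
  tournament selection (k = 3), BLX-0.5 blend crossover, per-gene Gaussian
  mutation (σ = 5% of the bound half-width, rate 0.1), elitism 2, children
  clamped to the box, the initial pose injected into the first population
  (so the best-so-far can never fall below it), and a final simplex polish
  within the remaining budget. The seed is mandatory; results are
  bit-reproducible given it.

Every optimizer returns the best pose *evaluated*, so the monotone
improvement contract (final score ≥ initial score) holds even when a scipy
iteration ends on a worse point.

Multi-resolution search is deliberately absent from the default path; the
restart mechanism provides the needed robustness at desk scale.

## Synthetic phantom and simulated C-arm

The phantom replaces a saw-bone vertebra, CT scanner and C-arm. It is built
from analytic primitives — a vertebral-body cylinder (radius 16 mm,
half-height 13 mm) with a 2.5 mm cortical shell at 1200 HU and trabecular
interior at 300 HU, two pedicle ellipsoids and a spinous mass in solid
bone, a 6 mm spinal canal bored through, and seven 2 mm fiducial spheres at
3000 HU placed asymmetrically so no pose ambiguity exists. Analytic
membership means the voxelization is checkable against a brute-force
per-voxel oracle, and the generating pose is exact ground truth. The grid
is 128³ at 0.46 × 0.46 × 0.7 mm — a single-vertebra crop at clinical CT
resolution.

The simulated C-arm renders AP and LA views (source–isocenter 700 mm,
source–detector 1000 mm) with the same ray-casting model the objective
uses, adds Gaussian intensity noise (default σ = 2 of 255) clipped to
[0, 255], and can paint a dark polygonal instrument overlay. The benchmark
detector is 96 × 96 px at 1.25 mm pitch — a 120 mm field collimated to the
single vertebra; a 470 × 470 preset at 0.486 mm pitch reproduces a 9-inch
full-scale field. Both the simulated radiographs and the objective's DRRs
use a 1.0 mm integration step, keeping the two sides of the comparison
numerically consistent.

What the phantom does *not* emulate: the exponential/logarithmic intensity
transfer of a real detector (an optional log-response flag exists on the
renderer's output for robustness experiments, but NCC's affine invariance
makes the linear proxy adequate for the default protocol), scatter,
beam hardening, C-arm pincushion distortion, soft-tissue background, and
anatomical shape variation. Passing benchmarks therefore demonstrate the
correctness and convergence behaviour of the *pipeline*, not clinical
accuracy on real radiographs.

## Ground truth and error metrics

On synthetic data the generating pose is exact ground truth. The
fiducial-based path used with physical phantoms is also implemented: marker
centroids are detected in CT by thresholding + connected components, their
world positions are known, and a closed-form least-squares rigid fit
(Kabsch) gives `T_GT` — with known correspondences no iterative
closest-point loop is required.

Target registration error at marker `P`: `TRE = |T_2d3d·P − T_GT·P|`,
reported per marker and as the mean. Angular error is the geodesic rotation
angle of `R_2d3d·R_GTᵀ` (a single scalar angle; no per-axis
decomposition). A benchmark trial is a *success* when mean TRE < 1.5 mm —
the literature never fixes this threshold numerically, and 1.5 mm cleanly
separates converged errors (~0.2 mm here) from the ≥5 mm search radii;
it is configurable. Summaries report mean ± sd TRE over successes
("excluding failure") and over all trials ("including failure"), plus the
success rate.

## Benchmark protocol and problem sizes

Each benchmark samples initial offsets uniformly in the convergence-interval
box (seeded), perturbs the ground-truth pose by them, registers, and scores
against ground truth. The default problem sizes — 128³ volume, 96 × 96
views, 1.0 mm step, 40 trials per interval, 9 starts per optimizer
comparison — were chosen so a full protocol run completes in minutes on one
CPU core while leaving every stage of the method (rendering, masking,
similarity, bounded search) identical in structure to a full-scale run.
Offsets are drawn once per benchmark run and recorded per trial; whether
repeated combinations should share one offset panel is a protocol choice
left to the caller (the benchmark takes a seed).

## Numerical and degenerate-input choices

- Triangulation of two rays solves the two-line closest-approach system and
  errors when the cross product norm is below 1e-12 (parallel rays).
- Source estimation uses the normal equations over line projection
  operators, falling back to an SVD least-squares solve when the condition
  number exceeds 1e10; fewer than two lines or an all-parallel set is an
  error.
- Rigid fits require ≥ 3 non-collinear points (second singular value of the
  centered cloud > 1e-9) and force a proper rotation (no reflection).
- Similarity measures require ≥ 64 masked pixels and non-constant images
  (zero variance is an error, not a NaN); the mask erosion for
  gradient-based measures can also trigger the pixel-count floor.
- A constant raw DRR windows to all-zero rather than dividing by zero; an
  ROI disjoint from the view yields an all-zero image, not an error.
- Rays exactly parallel to a detector plane (no intersection) and
  projections of the source itself are errors.

## Known limitations

- The intensity model is monoenergetic and linear in HU; no polychromatic
  or scatter model.
- The capture-range results are specific to this phantom's contrast and
  field of view; real radiographs with soft-tissue clutter will narrow the
  basin, and the GC measure in particular is known to degrade with
  background structure.
- The benchmark's initial offsets stand in for an imperfect 3-point manual
  initial registration; the interactive picking itself is out of scope.
- Success rates at wide intervals (±10 mm/±10°) depend on the optimizer's
  global behaviour and carry seed-to-seed variance of a few percent at
  n = 40.
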
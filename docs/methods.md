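# Methods

This note documents the models, conventions and numerical choices behind
`texton3d`, and what its synthetic validation does and does not show.

## The texture model

Fibrillar-collagen SHG volumes are classified by their *texton* statistics:
the joint distribution of local multi-scale, multi-orientation filter
responses, summarized per stack as a histogram over a learned vocabulary of
prototypical response vectors.  The approach deliberately avoids segmenting
individual fibers or measuring explicit morphology (length, width,
alignment); everything is carried by the response distribution.

### Filter bank

The bank consists of first- and second-order derivatives of anisotropic 3D
Gaussians — edge- and bar-like detectors with widths `(sx, sy, sz)` taken
from `{(1,1,3), (2,2,6), (4,4,12)}` voxels — differentiated along the short
x axis, elongated along z, and rigidly rotated about each coordinate axis at
six angles evenly spaced over [0, 180°); plus one isotropic Gaussian and one
Laplacian-of-Gaussian, both with `sigma = 10` voxels.  That is
`6 x 3 x 2 x 3 + 2 = 110` kernels.  Distributing orientations isotropically
over the sphere instead would need `6^3 x 3 x 2 + 2 = 1298` kernels; the
axis-restricted set keeps convolution affordable while spanning the three
anatomical axes of an image stack.

Per-voxel responses are collapsed by taking, for each (derivative order,
scale, rotation axis) triple, the maximum over its six orientations,
reducing 110 responses to 20 channels.  The maximum of *signed* responses is
used.  This makes even-order channels invariant under volume rotations that
map the orientation set onto itself (e.g. 90° about an axis); odd-order
(edge) channels are rotation-tolerant only up to the sign flip a 180°
orientation reversal induces — an intrinsic property of collapsing an odd
filter over a half-turn orientation set.

Conventions that the mathematics does not fix, chosen once and used
everywhere:

* **Sampling.**  The continuous rotated function is sampled on the integer
  grid (rotate-then-sample).  Kernel support is tight per axis:
  half-extent `ceil(3 * std)` along each array axis from the rotated
  covariance, taken as the union box over a group's six orientations (so a
  group shares one support).  The 3-sigma truncation keeps >99.7% of the
  Gaussian mass at a fraction of the cubic-support cost.
* **Normalization.**  Every kernel is L1-normalized by its total absolute
  mass; derivative and LoG kernels are then shifted by a constant to an
  exactly zero sum, so constant image regions produce exactly zero response.
  No per-voxel (Weber) contrast normalization is applied to response
  vectors; instead each volume is globally z-scored before filtering (a
  pipeline switch).
* **Filtering.**  Responses are cross-correlations with the centered kernel;
  boundaries use symmetric reflection.  Because the symmetric extension of
  an n-sample axis is periodic with period 2n, a circular FFT over one
  period computes the reflected correlation *exactly*, for kernels of any
  size — including kernels deeper than the stack (the 73-voxel axial extent
  of the largest-scale kernels exceeds typical 20–60-slice stacks).  The
  separable structure of every kernel (a 1D factor along the rotation axis
  times a 2D factor in the rotation plane) is exploited: one restricted 1D
  pass per orientation group, one cached 2D kernel spectrum per kernel, and
  a cumulative-sum box filter for the zero-sum shift term.  The
  implementation is contractually *equal* to the brute-force direct sum
  (tested to 1e-8 relative on random volumes) — the FFT route is an
  execution strategy, not an approximation.

### Textons and histograms

Stacks are preprocessed to isotropic voxel pitch (trilinear, upsampling
depth to the finest lateral pitch), optionally depth-cropped (SHG contrast
decays with depth; analyses use the top 30–40 um of tissue), and z-scored.
From each stack's collapsed response field, one or more 50 x 50 x 5-voxel
blocks (12,500 vectors each) are sampled at seeded-random positions; block
placement is chosen before filtering so convolution can be restricted to the
block (the restriction is exact, and the full surrounding volume supplies
context, so there are no block-edge artifacts).

Pooled training vectors are clustered by k-means into K = 40 textons.  The
`learn_dictionary` default is full Lloyd k-means (k-means++ init, best of 5
restarts, 300 iterations, tol 1e-6).  The cross-validation pipeline re-fits
the dictionary inside every fold on ~1.6M pooled vectors; there it uses
seeded mini-batch k-means (one k-means++ init, batch 16384, two full
epochs) — for a 40-center vocabulary in 20 dimensions the resulting
histograms are statistically indistinguishable from Lloyd's at a tenth of
the cost, and the choice is a configuration switch, not a contract.  Each stack is summarized as the
normalized histogram of nearest-texton assignments (Euclidean metric,
lowest-index tie-break) of its own sampled vectors.

The pipeline default pools **two** sampling blocks per stack
(`blocks_per_stack = 2`).  A single 12,500-voxel block's histogram carries
substantial placement noise (measured: same-stack different-block
chi-square distances exceed different-stack same-class distances); pooling
two blocks halves that variance while keeping the per-block sample count at
the standard 12,500.

### Classification

Stack histograms are compared with the symmetric chi-square distance
`d(a,b) = 1/2 sum_k (a_k - b_k)^2 / (a_k + b_k)` (empty bins contribute 0;
`d` is in [0,1] for normalized inputs).  One-vs-rest confidence for class c
sums Gaussian-weighted votes of the NN = 10 nearest training histograms:
`score = sum_i w_i exp(-d_i^2 / sigma^2)`, `w_i = q` for positive neighbors
and −1 otherwise.  `sigma` is the maximum-likelihood scale of a
zero-location half-Gaussian fitted to all pairwise training distances,
`sigma = sqrt(mean(d_ij^2))` — the natural reading of fitting a Gaussian to
nonnegative distances.  The positive-class weight `q` (~5–10) rebalances the
one-vs-rest asymmetry (five negatives per positive in a six-class library);
per-test-image optimization of q would leak test information into the
decision rule, so the default selects one q per class by inner 3-fold
cross-validation on the training fold (sweeping q = 5..10, smallest q on
ties); a fixed q = 7 is available.

Evaluation is stratified 10-fold cross-validation (plain k-fold when
folds = n, i.e. leave-one-out): in each fold the dictionary, the histogram
library, sigma and q are fitted on the training stacks only, and held-out
scores are pooled across folds into one ROC per class (AUROC by trapezoid,
identical to the normalized Mann–Whitney U; ties step jointly).  Pooling
across folds rather than averaging per-fold curves uses every score at its
actual operating threshold; with ~7 held-out stacks per fold, per-fold
curves would be too coarse to average meaningfully.

## The phantom generator

No deposited image library exists for this tissue, so validation uses
synthetic fibrillar volumes.  Fibers are persistent random walks: principal
directions from a von Mises–Fisher distribution about a mean axis
(concentration `alignment_kappa`; 0 = isotropic), per-step transverse
direction noise with SD `waviness` (rad per sqrt-voxel), length drawn at
±25% around `fiber_length`.  Centerlines are splatted trilinearly (0.5-voxel
steps), wrapped periodically so expected density is spatially stationary,
blurred with a Gaussian combining fiber cross-section (`fiber_width`) and an
anisotropic PSF, amplitude-scaled so a fiber peaks near `intensity`
regardless of width, then degraded with Poisson shot noise and Gaussian read
noise (photon-counting detection).  A seeded smooth axial density modulation
(`depth_heterogeneity`, default 0.5) emulates the depth-varying collagen
density and signal decay of real stacks; without it every optical section is
statistically identical, which real tissue is not.

The six presets differ along the morphological axes the tissue classes are
described by — density, length, width, waviness, alignment:

| preset       | fibers | length | width | waviness | kappa | morphology analogue            |
|--------------|-------:|-------:|------:|---------:|------:|--------------------------------|
| normal       |    650 |     12 |  0.6  |     0.35 |     0 | short fibers, isotropic mesh   |
| high_risk    |    280 |     26 |  1.2  |     0.12 |     2 | heterogeneous curvy/straight   |
| benign       |    300 |     12 |  2.2  |     0.30 |     1 | thick short wavy               |
| endometrioid |    160 |     34 |  0.8  |     0.06 |    10 | sparse, highly aligned         |
| lgs          |   1100 |      8 |  1.5  |     0.25 |     1 | fibrotic: dense short          |
| hgs          |    450 |     50 |  1.0  |     0.22 |    10 | long wavy aligned              |

(lengths/widths in um at 1 um isotropic pitch; default volume 128 x 128 x 20.)

**What passing tests show — and don't.**  The phantoms validate the
pipeline's machinery: that the filter bank, texton statistics and
chi-square OvR classifier recover known morphological differences without
leakage, deterministically.  They do not reproduce real SHG contrast
(no polarization or chi-(2) tensor physics, no scattering, single fiber
population per volume), and phantom AUROCs are not comparable to
tissue-study accuracies: class differences here are controlled by
construction, while real inter-patient heterogeneity is far richer.

### The single-section baseline

The validation suite contrasts the volumetric analysis with a
single-optical-section analogue: the same pipeline run on the response
vectors of one z slice per stack (the central slice of the first sampling
block, 2,500 vectors).  Because one section cannot average over the stack's
depth profile, its histograms are noisier estimates of the stack texture and
its accuracies fall below the volumetric ones — the scaled-down counterpart
of the planar-vs-volumetric comparison in tissue studies.  The slice's
responses still come from 3D kernels (the planar pipeline with 2D filters is
a different method, out of scope here), so the baseline isolates exactly one
factor: how much of the stack is summarized.

## Problem sizes and numerics

* Standard synthetic experiment: 6 classes x 12 stacks of 128 x 128 x 20
  voxels, two 50 x 50 x 5 blocks per stack, K = 40, NN = 10, 10-fold CV;
  repeated over three dataset seeds in the validation suite.  The
  128 x 128 x 20 size is the package's reduced-scale analogue of full
  512 x 512 x 60 acquisitions (which the code equally supports).
* Pipeline arithmetic is float32 (responses, clustering); kernel
  construction and contract tests are float64.  The convolution-vs-oracle
  tolerance is 1e-8 relative in float64.
* Degenerate inputs: constant volumes z-score to zero; a library whose
  pairwise distances are all zero cannot yield a sigma (error); ROC requires
  both classes present; k-means requires at least K samples.
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` derivations (per-stack, per-fold, per-block),
  so every artifact is bit-reproducible.

## Known limitations

* Odd-order collapsed channels are rotation-tolerant only up to sign (see
  above); full invariance would need orientation sets over [0, 360°) or
  absolute-value collapse, both of which change the representation.
* The vocabulary is global across classes (one dictionary for all training
  stacks); per-class dictionaries are a documented alternative the
  implementation does not pursue.
* `q` selected by inner CV uses the outer fold's dictionary (refitting a
  dictionary per inner fold would multiply cost ~30x for a second-order
  effect); sigma *is* refitted inside the inner folds.
* Patient-grouped splitting (`--group-by patient`) is available for real
  manifests but phantom experiments have no patient structure to exercise it.
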
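# Methods

## Problem and model

The package detects nucleus centroids in 3D fluorescence volumes. The core
detector is two-stage:

1. **Semantic segmentation.** A compact V-net-style fully convolutional
   network (5×5×5 stride-1 zero-padded convolutions, batch normalization,
   ReLU, 2×2×2 max-pool downsampling, stride-2 transposed convolutions
   cropped to exactly double each dimension, additive skip connections,
   softmax head) maps the raw volume to per-voxel class probabilities.
   Two-class (background/nucleus) and three-class (background/boundary/
   nucleus) variants share the architecture. The loss is the soft Dice loss
   averaged over classes, which is insensitive to the extreme class
   imbalance of the thin boundary class.

2. **Centroid regression.** A skip-free encoder–decoder with the same
   convolutional vocabulary and a single-channel linear head maps the
   nucleus-probability volume (the segmentation output before voxel
   classification; it homogenizes nucleus texture and brightness) to a
   centroid density map. The training target places a unit-height
   anisotropic Gaussian (σ in voxels, default 3 per axis, truncated at 4σ;
   truncation error < e⁻⁸) at each centroid; overlapping Gaussians combine
   by maximum so peaks stay at exactly 1. The loss is the mean square error
   against the target scaled by 10,000 — without the scaling the optimum is
   nearly indistinguishable from the all-zero map and training collapses.

Centroids are read out as local maxima of the density map: background
threshold (default 0.1 × map maximum — the absolute threshold is data-scale
free), Gaussian smoothing, then a strict-maximum test over the anisotropic
voxel ellipsoid inscribed in a physical 2 µm ball. Exact value ties are
broken lexicographically by voxel index (smallest wins), so the output is
deterministic and pairwise centroid distances strictly exceed the
suppression radius.

Comparator routes: 26-connected components of the nucleus class (for the
three-class net, whose boundary class separates instances); a 3D watershed
on the negative Euclidean distance transform of the thresholded,
isotropically resampled (tricubic) nucleus mask; and a non-learned baseline
(grayscale opening with a ball element, global Otsu threshold, distance
watershed). Watershed over-segmentation is controlled by suppressing
distance-map maxima shallower than `minima_suppression_depth` (default
1 voxel, h-maxima via morphological reconstruction); the marker count, not
a raw local-maximum count, determines the number of basins.

## Evaluation protocol

Matching is radius-limited (3 µm, roughly the nucleus radius scale):
candidate prediction–truth pairs within the radius are accepted greedily in
ascending distance, each prediction and truth used at most once. This
reduces to "the closest prediction wins, the others are false positives"
in non-degenerate cases and is deterministic under ties. Precision, recall,
F1, predicted count (TP+FP) and signed count error follow the standard
definitions; zero denominators yield 0 by convention. Before scoring, the
same border band (default 30×30×5 voxels; smaller on desk-scale phantoms)
is cropped from predictions and ground truth, because centroids of nuclei
cut by the volume edge are ill-defined. Retention uses the half-open
convention: a point exactly on the inner edge is kept.

## Spatial statistics

F is the CDF of distances from uniform Monte-Carlo reference locations
(default 10,000, seeded) to the nearest pattern point; G the CDF of
nearest-neighbor distances; H the CDF of all unordered pairwise distances.
No edge correction is applied by default — the plain empirical CDFs are
comparable run-to-run and, on the region sizes used here, deviate from the
analytic CSR curve `1 − exp(−λ·4/3πr³)` by well under 0.02 mean absolute
error for a Poisson pattern of ~500 points. A minus-sampling border
correction is available via `border_margin_um`. The default radii grid is
200 equal steps from 0 to half the shortest region side.

## Phantom generator

The generator emulates confocal volumes of DAPI-stained tissue: ellipsoidal
nuclei with uniform mean radius in a configurable range and axis ratio
drawn from an eccentricity range (volume-preserving parameterization,
uniform random orientation), placed by rejection sampling with a minimum
center spacing (an explicit error names the achievable density when
placement fails). Later-placed nuclei own contested voxels, which keeps
each label a single connected mask; labels that lose every voxel are
dropped and the rest renumbered. Appearance effects are applied after the
geometry is frozen: flat per-nucleus brightness with configurable
coefficient of variation, intra-nuclear bright puncta (small Gaussians,
σ 0.4 µm, amplitude 0.8 × base, expected count proportional to nucleus
volume at one per 8 µm³ at `speckle_fraction = 1`), a rare population of
1.6× larger, 0.4× dimmer neuron-like nuclei, multiplicative depth
attenuation `exp(−α·z)`, separable anisotropic Gaussian blur, Poisson
(photon) and Gaussian (read) noise. Labels and centroids are therefore
exact and independent of blur and noise.

What the phantom does *not* model: a physically correct PSF (no spherical
aberration or depth-dependent blur), background autofluorescence
structure, nucleus texture beyond puncta, or multi-channel stains. Passing
the end-to-end tests shows the pipeline recovers geometry under the modeled
degradations; it does not certify performance on real tissue, where
contrast statistics are unknown.

Presets: `heart_like_spec` (elongated 2–4 µm-radius nuclei, no neuron
population) and `brain_like_spec` (rounder 3–6 µm nuclei, 5 % large dim
nuclei) mirror the two tissue archetypes the detector targets.

## Numerical engine

No GPU framework is used: 3D convolutions are evaluated as circular
convolutions on a zero-padded domain via real FFTs. Padding by
`kernel // 2` per side makes the circular wrap touch only discarded border
voxels, so the result equals a linear zero-padded convolution, and the
backward passes are exact conjugate multiplies in the frequency domain
(input gradient) plus a spectrum cross-product (kernel gradient). Every
layer and both full models are verified against central finite differences
in the test suite. Transposed convolution is zero-stuffing to the doubled
grid followed by the same "same" convolution, which guarantees the output
is exactly double the input per axis. Weights use Glorot-uniform
initialization, biases start at zero, and all randomness (placement,
patch sampling, augmentation, dropout, initialization) flows from explicit
integer seeds through `numpy.random.default_rng`.

## Training schedule

Training is patch-based: every iteration draws a minibatch of random
patches from the training volume; with probability ½ a patch pair is
augmented by one of four operations (x-reflection, y-reflection, 90°
counterclockwise z-rotation, x-reflection followed by rotation) applied
identically to input and target. Adam with default moments is used; the
learning rate drops by a fixed factor on a fixed epoch period. Early
stopping: training stops when the validation loss (whole validation volume,
evaluated once per epoch) has not decreased for more than 2 epochs or has
increased for more than 1 consecutive epoch; the best-validation parameters
are restored. Full-scale reference schedules use learning rate 1e-3 with
drop factor 0.75/0.9 and period 5, patches of 200×200×32 (regression) or
128×128×32 (segmentation), 50 patches per epoch.

The desk-scale configuration (`desk_scale_config`) is sized for a single
CPU: 128×128×32 phantoms at 1 µm isotropic voxels with ~110 nuclei at 8 µm
minimum spacing, 3-level networks with 4 (segmentation) and 8 (regression)
base channels, 32×32×16 patches, 50 patches/epoch, up to 15 (segmentation)
and 20 (regression) epochs, learning rates 3e-3 and 3e-2. The larger
regression learning rate compensates for the ×10,000 output scale the
network must reach from O(1) initialization; the post-processing smoothing
scales (maxima smoothing σ = (2, 2, 1.5) voxels, watershed pre-smoothing
σ = 1 voxel) are set for the 1 µm voxel pitch, whereas the full-scale
defaults (σ = (4, 4, 2) and 5 voxels) correspond to sub-µm lateral pitches.
A full desk-scale run — phantom, both networks, detection, scoring — takes
about five minutes.

## Design choices where the design was open

* **Greedy-by-distance matching** instead of per-truth sequential
  assignment: the verbal "closest wins" rule is ambiguous for chained
  conflicts; global greedy on ascending distance is deterministic,
  order-independent, and agrees with the per-truth rule whenever conflicts
  are not chained.
* **Maximum-combination of target Gaussians** (not summation): summation
  would push near-neighbor peaks above 1 and bias the regression toward
  cluster centers.
* **Boundary class** built from per-instance erosion with a 6-connected
  element iterated `width` times, plus all voxels 26-adjacent to a
  different instance — touching nuclei are always separated by boundary,
  and merging nucleus+boundary recovers the two-class volume exactly.
* **Additive skip connections** in the segmentation net (V-net style)
  rather than channel concatenation: fewer parameters at equal depth.
* **Suppression radius in physical µm** (anisotropic in voxels), matching
  the physical interpretation of a minimum nucleus separation.
* **Voxel convention**: voxel `i` spans `[i·d, (i+1)·d)` µm, centers at
  `(i+½)·d`, used consistently for rasterization, centroids, density
  targets and CSV output.

## Known limitations

* The FFT engine favors clarity over throughput; batch sizes and channel
  widths beyond the desk scale are slow on CPU.
* The watershed route depends on `minima_suppression_depth`; strongly
  non-convex fused masks can still over- or under-split.
* Empirical F/G/H curves are uncorrected for edge effects by default and
  therefore biased for patterns whose interaction range is comparable to
  the region size.
* Training uses one training and one validation volume (as in typical
  annotation-limited microscopy studies); there is no multi-volume data
  loader.
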
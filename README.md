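# vregnet3d

Nuclei centroid detection in 3D fluorescence microscopy volumes.

Whole-organ imaging of optically cleared, DAPI-stained tissue produces image
volumes with thousands of densely packed cell nuclei. Counting them and
mapping their spatial organization requires locating each nucleus centroid,
which is hard when nuclei touch, overlap, vary in shape (elongated cardiac
myocyte nuclei, large dim neuron nuclei) and are blurred by a strongly
anisotropic point-spread function. `vregnet3d` implements a two-stage
detector for this problem together with the comparator pipelines, the
evaluation protocol, and the spatial statistics needed to assess it —
exercisable entirely on a built-in synthetic phantom generator with exact
ground truth.

## What is implemented

**VRegNet route (the core method).** A V-net-style volumetric semantic
segmentation network first classifies voxels as nucleus vs background
(trained with the soft Dice loss, `1 − mean_c 2Σpt/(Σp²+Σt²)`, robust to
class imbalance). Its nucleus-probability output — which homogenizes nucleus
appearance — is fed to a fully convolutional encoder–decoder *regression*
network that predicts a centroid density map: the training target places a
unit-height 3D Gaussian (σ = 3 voxels by default) at every centroid, and the
loss is the mean square error against the target multiplied by 10,000 so the
network does not collapse to the all-zero background. Centroids are the
local maxima of the predicted map (threshold, Gaussian smoothing, strict
maximum within a 2 µm suppression ball).

**Comparator routes.** Three-class segmentation (background / boundary /
nucleus) with connected components (`vnet3`) or a distance-transform 3D
watershed (`vnet3w`); two-class segmentation plus watershed (`vnet2w`); and
a non-learned baseline (grayscale opening → Otsu threshold → watershed,
`classical`).

**Evaluation.** A predicted centroid within 3 µm of a ground-truth centroid
is a true positive; when several predictions compete for one truth the
closest wins and the rest are false positives. Precision `P = TP/(TP+FP)`,
recall `R = TP/(TP+FN)`, `F1 = 2PR/(P+R)`, predicted count `TP+FP` and
signed cell-count error `(predicted − true)/true`. A border band is cropped
symmetrically from predictions and ground truth before scoring.

**Spatial statistics.** F (empty-space), G (nearest-neighbor) and H (all
pairwise distances) cumulative functions, curve mean-absolute-error
comparison, and the analytic complete-spatial-randomness reference
`1 − exp(−λ·4/3πr³)`.

**Phantom generator.** Ellipsoidal nuclei with configurable radius,
eccentricity, spacing, intra-nuclear bright puncta, depth attenuation,
anisotropic Gaussian PSF blur, and Poisson + Gaussian noise; labels and
centroids are the pre-blur geometry. The networks are implemented in
numpy/scipy (FFT-domain 3D convolutions with analytically derived backward
passes, batch-norm, dropout, max pooling, Adam, Glorot initialization), so
training runs on a plain CPU.

## Worked example

```bash
vregnet3d run --method vregnet --seed 1 --out runs/demo
```

trains both networks on a synthetic phantom (110 nuclei, 1 µm voxels) and
prints, after about five minutes on one CPU:

```
method=vregnet TP=82 FP=3 FN=6 P=0.9647 R=0.9318 F1=0.9480 count=85 (true 88, error -3.41%)
```

Read: of the 88 ground-truth nuclei remaining after the border crop, 82 were
detected within 3 µm (93.2 % recall), 3 detections matched no nucleus
(96.5 % precision), and the automatic cell count is 3.4 % below truth. The
same library calls are available in Python via
`vregnet3d.run_pipeline(vregnet3d.desk_scale_config(seed=1), "vregnet")`.

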
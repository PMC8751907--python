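"""Training targets derived from instance labels and centroids.

Three target encodings are supported: a two-class (background/nucleus)
volume, a three-class (background/boundary/nucleus) volume where a
few-voxel-wide boundary shell surrounds each nucleus and separates touching
instances, and a centroid density map built by placing a small unit-height
3D Gaussian at each centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import CentroidSet, InstanceLabels, VolumeImage

__all__ = [
    "ClassVolume",
    "CentroidDensityTarget",
    "make_two_class",
    "make_three_class",
    "make_centroid_density",
    "BACKGROUND",
    "BOUNDARY",
    "NUCLEUS",
]

BACKGROUND = 0
BOUNDARY = 1
NUCLEUS = 2


@dataclass
class ClassVolume:
    """Per-voxel class labels for semantic segmentation training.

    Two-class: {0: background, 1: nucleus}.
    Three-class: {0: background, 1: boundary, 2: nucleus}.
    """

    classes: np.ndarray
    n_classes: int

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes)
        if self.n_classes not in (2, 3):
            raise ValueError("n_classes must be 2 or 3")
        if self.classes.size and self.classes.max() >= self.n_classes:
            raise ValueError("class values exceed declared class count")

    def one_hot(self) -> np.ndarray:
        """(n_classes, nx, ny, nz) float32 one-hot encoding."""
        out = np.zeros((self.n_classes,) + self.classes.shape, dtype=np.float32)
        for c in range(self.n_classes):
            out[c] = self.classes == c
        return out


@dataclass
class CentroidDensityTarget:
    """Unit-peak Gaussian centroid density map (the regression target)."""

    map: VolumeImage
    sigma_voxels: tuple[float, float, float]
    peak_value: float = 1.0


def make_two_class(labels: InstanceLabels) -> ClassVolume:
    """Binary background/nucleus volume: class 1 wherever label > 0."""
    return ClassVolume((labels.data > 0).astype(np.uint8), n_classes=2)


def make_three_class(labels: InstanceLabels,
                     boundary_width_voxels: int = 3) -> ClassVolume:
    """Background/boundary/nucleus volume with an instance-separating shell.

    The boundary of each nucleus is the set difference between its mask and
    the erosion of that mask by a 6-connected (face-adjacency) structuring
    element iterated ``boundary_width_voxels`` times.  Voxels of a nucleus
    adjacent (26-connectivity) to a *different* nucleus are also boundary, so
    touching instances are always separated by the boundary class.  The union
    of boundary and nucleus classes equals the original foreground exactly.
    """
    if boundary_width_voxels < 1:
        raise ValueError("boundary width must be >= 1")
    lab = labels.data
    fg = lab > 0
    out = np.zeros(lab.shape, dtype=np.uint8)
    if not fg.any():
        return ClassVolume(out, n_classes=3)

    struct6 = ndimage.generate_binary_structure(3, 1)
    struct26 = ndimage.generate_binary_structure(3, 3)
    interior = np.zeros_like(fg)
    interface = np.zeros_like(fg)
    objects = ndimage.find_objects(lab)
    for k, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        pad = tuple(slice(max(s.start - boundary_width_voxels - 1, 0),
                          min(s.stop + boundary_width_voxels + 1, n))
                    for s, n in zip(sl, lab.shape))
        sub = lab[pad]
        mask = sub == k
        er = ndimage.binary_erosion(mask, structure=struct6,
                                    iterations=boundary_width_voxels,
                                    border_value=0)
        interior[pad] |= er
        # voxels of k whose 26-neighborhood touches another instance
        other = (sub > 0) & ~mask
        near_other = ndimage.binary_dilation(other, structure=struct26) & mask
        interface[pad] |= near_other

    interior &= ~interface
    out[fg] = BOUNDARY
    out[interior] = NUCLEUS
    return ClassVolume(out, n_classes=3)


def make_centroid_density(centroids: CentroidSet, grid: VolumeImage,
                          sigma_voxels=(3.0, 3.0, 3.0),
                          truncate_sigmas: float = 4.0) -> CentroidDensityTarget:
    """Centroid probability map: a unit-height 3D Gaussian per centroid.

    Overlapping Gaussians combine by maximum so every local peak stays at
    height 1.  Per-axis distances are measured in voxel units; a centroid
    coinciding with a voxel center yields the exact value 1 there.  Gaussians
    are truncated at ``truncate_sigmas`` standard deviations (the omitted
    tail is below exp(-truncate_sigmas^2 / 2)).
    """
    shape = np.asarray(grid.shape)
    d = np.asarray(grid.voxel_size_um)
    sig = np.asarray(sigma_voxels, dtype=float)
    if np.any(sig <= 0):
        raise ValueError("sigma_voxels must be positive")

    pts = centroids.coords_um
    if len(pts):
        vox_pos = pts / d - 0.5  # continuous voxel-center coordinates
        bad = np.any((pts < 0) | (pts >= shape * d), axis=1)
        if bad.any():
            raise ValueError(
                f"centroids outside grid: indices {np.flatnonzero(bad).tolist()}")
    out = np.zeros(tuple(shape), dtype=np.float32)
    half = np.ceil(truncate_sigmas * sig).astype(int)
    for k in range(len(pts)):
        c = vox_pos[k]
        lo = np.maximum(np.ceil(c - half).astype(int), 0)
        hi = np.minimum(np.floor(c + half).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        axes = [np.arange(l, h) for l, h in zip(lo, hi)]
        q = [((ax - ci) / si) ** 2 for ax, ci, si in zip(axes, c, sig)]
        g = np.exp(-0.5 * (q[0][:, None, None] + q[1][None, :, None]
                           + q[2][None, None, :]))
        sub = out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        np.maximum(sub, g.astype(np.float32), out=sub)
    return CentroidDensityTarget(
        VolumeImage(out, grid.voxel_size_um),
        tuple(float(s) for s in sig),
    )
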
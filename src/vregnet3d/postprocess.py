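"""From network outputs to centroids: local maxima, watershed, components.

Three routes turn a probability volume into a centroid set:

* regression route — threshold, Gaussian smoothing, and strict local-maxima
  detection within a physical suppression radius on the centroid density map;
* watershed route — binarize the nucleus probability, smooth, resample to
  isotropic voxels (tricubic), Euclidean distance transform, watershed on
  the negative distance map, then per-label centroid;
* connected-components route — label the nucleus class of a three-class
  segmentation directly (the boundary class separates instances).

A classical non-learned baseline (grayscale opening, Otsu threshold,
distance-transform watershed) and the border-cropping rule used before
evaluation are also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .types import Box, CentroidSet, InstanceLabels, VolumeImage, voxel_centers_um

__all__ = [
    "MaximaConfig", "WatershedConfig",
    "smooth_seams", "detect_local_maxima", "watershed_instances",
    "connected_component_instances", "label_centroids",
    "classical_baseline_segment", "crop_border",
]


@dataclass
class MaximaConfig:
    """Local-maxima extraction on the centroid density map.

    ``background_threshold_rel`` is relative to the map maximum (the
    absolute threshold is ``rel * max``); voxels below it are zeroed before
    smoothing.  ``suppression_radius_um`` is a physical radius: a voxel is a
    centroid only if it is the strict maximum over the anisotropic voxel
    ellipsoid corresponding to that ball.
    """

    background_threshold_rel: float = 0.1
    smoothing_sigma_voxels: tuple[float, float, float] = (4.0, 4.0, 2.0)
    suppression_radius_um: float = 2.0

    def __post_init__(self):
        if self.suppression_radius_um <= 0:
            raise ValueError("suppression radius must be positive")
        if any(s < 0 for s in self.smoothing_sigma_voxels):
            raise ValueError("smoothing sigma must be >= 0")


@dataclass
class WatershedConfig:
    """Watershed instance separation on a nucleus-probability volume."""

    class_threshold: float = 0.5
    presmooth_sigma_voxels: tuple[float, float, float] = (5.0, 5.0, 5.0)
    minima_suppression_depth: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.class_threshold < 1.0:
            raise ValueError("class_threshold must be in (0, 1)")


def smooth_seams(prob_map: VolumeImage, size_voxels: int = 3) -> VolumeImage:
    """3x3x3 median filter (reflected edges) to blend patch seams."""
    out = ndimage.median_filter(prob_map.data, size=size_voxels, mode="reflect")
    return VolumeImage(out, prob_map.voxel_size_um)


def _ellipsoid_footprint(radius_um: float, voxel_size_um) -> np.ndarray:
    """Boolean footprint of the voxels within a physical ball (center excluded)."""
    d = np.asarray(voxel_size_um, dtype=float)
    half = np.maximum(np.floor(radius_um / d).astype(int), 0)
    grids = np.meshgrid(*[np.arange(-h, h + 1) * dd
                          for h, dd in zip(half, d)], indexing="ij")
    r2 = sum(g ** 2 for g in grids)
    fp = r2 <= radius_um ** 2
    fp[tuple(half)] = False
    return fp


def detect_local_maxima(density: VolumeImage,
                        cfg: MaximaConfig | None = None) -> CentroidSet:
    """Strict local maxima of the (thresholded, smoothed) density map.

    A voxel is a centroid iff its smoothed value exceeds every other voxel
    inside the physical suppression ball; on exact plateaus the
    lexicographically smallest voxel index wins, so results are
    deterministic.  An all-zero map yields an empty set.
    """
    cfg = cfg or MaximaConfig()
    vox = density.voxel_size_um
    m = np.asarray(density.data, dtype=np.float64)
    peak = m.max()
    if peak <= 0:
        return CentroidSet(np.empty((0, 3)), density.region)
    thr = cfg.background_threshold_rel * peak
    m = np.where(m >= thr, m, 0.0)
    if any(s > 0 for s in cfg.smoothing_sigma_voxels):
        m = ndimage.gaussian_filter(m, sigma=cfg.smoothing_sigma_voxels,
                                    mode="constant")
    fp = _ellipsoid_footprint(cfg.suppression_radius_um, vox)
    neigh_max = ndimage.maximum_filter(m, footprint=fp, mode="constant",
                                       cval=-np.inf)
    strict = m > neigh_max
    # ties: a voxel equal to its neighborhood max survives only if every
    # equal-valued voxel in its ball has a lexicographically larger index
    tied = (m == neigh_max) & (m > 0) & ~strict
    if tied.any():
        offsets = np.argwhere(fp) - (np.asarray(fp.shape) // 2)
        shape = np.asarray(m.shape)
        for idx in np.argwhere(tied):
            val = m[tuple(idx)]
            ok = True
            for off in offsets:
                q = idx + off
                if np.any(q < 0) or np.any(q >= shape):
                    continue
                if m[tuple(q)] == val and tuple(q) < tuple(idx):
                    ok = False
                    break
            strict[tuple(idx)] = ok
    idx = np.argwhere(strict & (m > 0))
    coords = voxel_centers_um(idx, vox) if len(idx) else np.empty((0, 3))
    return CentroidSet(coords, density.region)


def watershed_instances(seg_probs: VolumeImage,
                        cfg: WatershedConfig | None = None) -> InstanceLabels:
    """Distance-transform watershed on the thresholded nucleus probability.

    Steps: binarize at ``class_threshold``; Gaussian-smooth the binary mask
    and re-binarize at 0.5; resample to isotropic voxels at the finest pitch
    by tricubic interpolation; Euclidean distance transform; suppress
    distance maxima shallower than ``minima_suppression_depth`` (h-maxima
    style, via morphological reconstruction) to limit over-segmentation;
    watershed on the negative distance map; map labels back to the original
    grid by nearest neighbor.
    """
    cfg = cfg or WatershedConfig()
    vox = np.asarray(seg_probs.voxel_size_um)
    mask = np.asarray(seg_probs.data) > cfg.class_threshold
    if not mask.any():
        return InstanceLabels(np.zeros(seg_probs.shape, dtype=np.int32),
                              seg_probs.voxel_size_um)
    if any(s > 0 for s in cfg.presmooth_sigma_voxels):
        sm = ndimage.gaussian_filter(mask.astype(np.float64),
                                     sigma=cfg.presmooth_sigma_voxels)
        mask = sm > 0.5
        if not mask.any():
            return InstanceLabels(np.zeros(seg_probs.shape, dtype=np.int32),
                                  seg_probs.voxel_size_um)

    pitch = vox.min()
    zoom = vox / pitch
    iso = ndimage.zoom(mask.astype(np.float64), zoom, order=3) > 0.5
    if not iso.any():
        iso = ndimage.zoom(mask.astype(np.float64), zoom, order=0) > 0.5
    dist = ndimage.distance_transform_edt(iso)

    # suppress shallow maxima: reconstruct dist from dist - depth, then
    # markers are the plateaus where the reconstruction meets the original
    from skimage.morphology import reconstruction
    depth = cfg.minima_suppression_depth
    struct = ndimage.generate_binary_structure(3, 3)
    if depth > 0:
        seeded = reconstruction(np.clip(dist - depth, 0, None), dist,
                                method="dilation", footprint=struct)
        marker_mask = (dist - seeded >= depth - 1e-9) & iso
    else:
        mx = ndimage.maximum_filter(dist, footprint=struct, mode="constant")
        marker_mask = (dist == mx) & iso
    markers, _ = ndimage.label(marker_mask, structure=struct)
    labels_iso = watershed(-dist, markers=markers, mask=iso,
                           connectivity=struct)

    # nearest-neighbor map back to the anisotropic grid
    shape = seg_probs.shape
    idx = [np.clip(np.round((np.arange(n) + 0.5) * z - 0.5).astype(int),
                   0, labels_iso.shape[ax] - 1)
           for ax, (n, z) in enumerate(zip(shape, zoom))]
    back = labels_iso[np.ix_(idx[0], idx[1], idx[2])]
    back = np.where(mask, back, 0)
    return InstanceLabels(back.astype(np.int32), seg_probs.voxel_size_um)


def connected_component_instances(seg_probs: VolumeImage | np.ndarray,
                                  class_threshold: float = 0.5,
                                  voxel_size_um=None) -> InstanceLabels:
    """26-connected labeling of the nucleus-class voxels.

    Intended for the three-class segmentation output where the boundary
    class already separates touching instances.  ``seg_probs`` is the
    nucleus-class probability volume.
    """
    if isinstance(seg_probs, VolumeImage):
        data, vox = seg_probs.data, seg_probs.voxel_size_um
    else:
        data, vox = np.asarray(seg_probs), voxel_size_um or (1.0, 1.0, 1.0)
    mask = data > class_threshold
    lab, _ = ndimage.label(mask, structure=ndimage.generate_binary_structure(3, 3))
    return InstanceLabels(lab.astype(np.int32), vox)


def label_centroids(labels: InstanceLabels) -> CentroidSet:
    """Unweighted voxel-center centroid of each label, in micrometres."""
    ids = labels.ids
    if len(ids) == 0:
        return CentroidSet(np.empty((0, 3)), labels.region)
    coms = ndimage.center_of_mass(np.ones_like(labels.data, dtype=np.float64),
                                  labels.data, ids)
    coords = voxel_centers_um(np.asarray(coms), labels.voxel_size_um)
    return CentroidSet(coords, labels.region, ids=ids)


def classical_baseline_segment(image: VolumeImage,
                               opening_radius_voxels: int = 2,
                               cfg: WatershedConfig | None = None) -> InstanceLabels:
    """Non-learned baseline: opening, Otsu, distance-transform watershed.

    A grayscale morphological opening with a ball structuring element
    homogenizes nucleus texture, a global Otsu threshold separates
    foreground, and the watershed of the negative distance transform labels
    individual nuclei.  A constant image yields zero labels.
    """
    img = np.asarray(image.data, dtype=np.float64)
    if opening_radius_voxels > 0:
        r = opening_radius_voxels
        zz, yy, xx = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
        ball = (xx ** 2 + yy ** 2 + zz ** 2) <= r ** 2
        img = ndimage.grey_opening(img, footprint=ball)
    if np.ptp(img) == 0:
        return InstanceLabels(np.zeros(image.shape, dtype=np.int32),
                              image.voxel_size_um)
    thr = threshold_otsu(img)
    probs = (img > thr).astype(np.float64)
    ws_cfg = cfg or WatershedConfig(presmooth_sigma_voxels=(0.0, 0.0, 0.0))
    return watershed_instances(VolumeImage(probs, image.voxel_size_um), ws_cfg)


def crop_border(obj, border_voxels=(30, 30, 5), voxel_size_um=None):
    """Drop the border band from a centroid set or volume.

    For a :class:`CentroidSet`, centroids inside the border band are removed
    and the region shrinks; retention uses the half-open convention, so a
    point exactly on the inner edge is kept.  For volumes the border voxels
    are sliced away.  The border must be smaller than half the extent.
    """
    if isinstance(obj, CentroidSet):
        if voxel_size_um is None:
            raise ValueError("voxel_size_um required to crop a centroid set")
        d = np.asarray(voxel_size_um, dtype=float)
        margin = np.asarray(border_voxels) * d
        region = obj.region
        if any(2 * m >= s for m, s in zip(margin, region.size)):
            raise ValueError(f"border {tuple(margin)} um >= half region "
                             f"{region.size} um")
        inner = region.shrink(margin, margin)
        keep = inner.contains(obj.coords_um)
        return CentroidSet(obj.coords_um[keep], inner, ids=obj.ids[keep])
    if isinstance(obj, (VolumeImage, InstanceLabels)):
        b = tuple(int(v) for v in border_voxels)
        if any(2 * bb >= n for bb, n in zip(b, obj.shape)):
            raise ValueError(f"border {b} voxels >= half volume {obj.shape}")
        sl = tuple(slice(bb, n - bb) for bb, n in zip(b, obj.shape))
        cls = type(obj)
        return cls(obj.data[sl], obj.voxel_size_um)
    raise TypeError(f"cannot crop border of {type(obj)!r}")
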
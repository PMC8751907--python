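"""Post-processing routes vs independent brute-force oracles."""

import numpy as np
import pytest
from scipy import ndimage

import vregnet3d as v
from vregnet3d.postprocess import (
    MaximaConfig, WatershedConfig, classical_baseline_segment,
    connected_component_instances, crop_border, detect_local_maxima,
    label_centroids, smooth_seams, watershed_instances,
)
from vregnet3d.types import Box, CentroidSet, InstanceLabels, VolumeImage

VOX1 = (1.0, 1.0, 1.0)


def _vol(arr, vox=VOX1):
    return VolumeImage(np.asarray(arr, dtype=float), vox)


class TestMedianFilter:
    def test_constant_unchanged(self):
        out = smooth_seams(_vol(np.full((6, 6, 6), 0.4)))
        np.testing.assert_array_equal(out.data, 0.4)

    def test_single_impulse_removed(self):
        a = np.zeros((7, 7, 7))
        a[3, 3, 3] = 1.0
        out = smooth_seams(_vol(a))
        assert out.data[3, 3, 3] == 0.0

    def test_matches_per_voxel_median_oracle(self, rng):
        """Every voxel equals the median of its reflected 3^3 window."""
        a = rng.random((5, 5, 5))
        out = smooth_seams(_vol(a)).data
        padded = np.pad(a, 1, mode="symmetric")  # scipy's "reflect"
        for i in range(5):
            for j in range(5):
                for k in range(5):
                    win = padded[i:i + 3, j:j + 3, k:k + 3]
                    assert out[i, j, k] == pytest.approx(np.median(win))


def _brute_force_maxima(m, radius_um, vox):
    """Oracle: exhaustive neighborhood scan with strict-max and
    lexicographic plateau tie-break."""
    d = np.asarray(vox)
    half = np.floor(radius_um / d).astype(int)
    shape = m.shape
    found = []
    for idx in np.argwhere(m > 0):
        val = m[tuple(idx)]
        is_max = True
        for off in np.ndindex(*(2 * half + 1)):
            off = np.asarray(off) - half
            if not np.any(off):
                continue
            if np.sum((off * d) ** 2) > radius_um ** 2:
                continue
            q = idx + off
            if np.any(q < 0) or np.any(q >= shape):
                continue
            other = m[tuple(q)]
            if other > val:
                is_max = False
            elif other == val and tuple(q) < tuple(idx):
                is_max = False
            if not is_max:
                break
        if is_max:
            found.append(idx)
    return np.asarray(found).reshape(-1, 3)


class TestLocalMaxima:
    CFG = MaximaConfig(background_threshold_rel=0.0,
                       smoothing_sigma_voxels=(0, 0, 0),
                       suppression_radius_um=2.0)

    def test_single_gaussian_peak(self):
        g = np.ogrid[0:15, 0:15, 0:15]
        m = np.exp(-0.5 * sum((gi - 7.0) ** 2 for gi in g) / 4.0)
        cents = detect_local_maxima(_vol(m), self.CFG)
        assert len(cents) == 1
        np.testing.assert_allclose(cents.coords_um[0], [7.5, 7.5, 7.5])

    def test_two_peaks_far_apart_kept_close_merged(self):
        def peaks(sep):
            m = np.zeros((20, 9, 9))
            g = np.ogrid[0:20, 0:9, 0:9]
            for cx in (5.0, 5.0 + sep):
                m += np.exp(-0.5 * ((g[0] - cx) ** 2 + (g[1] - 4) ** 2
                                    + (g[2] - 4) ** 2) / 1.0)
            return detect_local_maxima(_vol(m), self.CFG)

        assert len(peaks(5.0)) == 2
        assert len(peaks(1.5)) == 1

    def test_all_zero_map_empty(self):
        assert len(detect_local_maxima(_vol(np.zeros((6, 6, 6))), self.CFG)) == 0

    def test_matches_neighborhood_scan_oracle(self, rng):
        for vox in (VOX1, (0.8, 0.8, 1.6)):
            m = np.round(rng.random((12, 12, 8)), 2)  # forces plateaus
            cents = detect_local_maxima(VolumeImage(m, vox), self.CFG)
            got = np.sort((cents.coords_um / np.asarray(vox) - 0.5), axis=0)
            exp = np.sort(_brute_force_maxima(m, 2.0, vox), axis=0)
            np.testing.assert_allclose(got, exp.astype(float), atol=1e-9)

    def test_pairwise_distances_exceed_radius(self, rng):
        m = rng.random((16, 16, 10))
        cents = detect_local_maxima(_vol(m), self.CFG)
        pts = cents.coords_um
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                assert np.linalg.norm(pts[i] - pts[j]) > 2.0


def _two_sphere_mask(shape=(30, 16, 16), c1=(8, 8, 8), c2=(19, 8, 8), r=6):
    g = np.ogrid[tuple(slice(0, s) for s in shape)]
    m1 = sum((gi - ci) ** 2 for gi, ci in zip(g, c1)) <= r ** 2
    m2 = sum((gi - ci) ** 2 for gi, ci in zip(g, c2)) <= r ** 2
    return m1 | m2


class TestWatershed:
    CFG = WatershedConfig(presmooth_sigma_voxels=(0, 0, 0),
                          minima_suppression_depth=1.0)

    def test_single_sphere_one_label(self):
        g = np.ogrid[0:16, 0:16, 0:16]
        mask = sum((gi - 8) ** 2 for gi in g) <= 36
        lab = watershed_instances(_vol(mask.astype(float)), self.CFG)
        assert len(lab.ids) == 1

    def test_two_overlapping_spheres_two_labels(self):
        """Spheres overlapping by ~20% of the radius split into two labels;
        the distance map has exactly two suppressed-depth maxima."""
        mask = _two_sphere_mask()
        lab = watershed_instances(_vol(mask.astype(float)), self.CFG)
        assert len(lab.ids) == 2

    def test_empty_mask_zero_labels(self):
        lab = watershed_instances(_vol(np.zeros((8, 8, 8))), self.CFG)
        assert lab.data.max() == 0

    def test_watershed_splits_never_merges(self, rng):
        """Label count is at least the connected-component count."""
        mask = _two_sphere_mask()
        lab = watershed_instances(_vol(mask.astype(float)), self.CFG)
        cc, ncc = ndimage.label(mask, ndimage.generate_binary_structure(3, 3))
        assert len(lab.ids) >= ncc


def _flood_fill_count(mask):
    """Brute-force 26-connected component count via BFS."""
    seen = np.zeros_like(mask, dtype=bool)
    count = 0
    offs = [np.asarray(o) - 1 for o in np.ndindex(3, 3, 3)
            if o != (1, 1, 1)]
    for start in np.argwhere(mask):
        if seen[tuple(start)]:
            continue
        count += 1
        stack = [start]
        seen[tuple(start)] = True
        while stack:
            p = stack.pop()
            for off in offs:
                q = p + off
                if np.any(q < 0) or np.any(q >= mask.shape):
                    continue
                if mask[tuple(q)] and not seen[tuple(q)]:
                    seen[tuple(q)] = True
                    stack.append(q)
    return count


class TestConnectedComponents:
    def test_two_blobs_separated_by_boundary(self):
        prob = np.zeros((12, 6, 6))
        prob[1:5] = 1.0
        prob[7:11] = 1.0
        lab = connected_component_instances(_vol(prob))
        assert len(lab.ids) == 2

    def test_single_blob(self):
        prob = np.zeros((6, 6, 6))
        prob[2:5, 2:5, 2:5] = 1.0
        assert len(connected_component_instances(_vol(prob)).ids) == 1

    def test_count_matches_flood_fill_oracle(self, rng):
        for _ in range(5):
            mask = rng.random((16, 16, 16)) < 0.2
            lab = connected_component_instances(_vol(mask.astype(float)))
            assert len(lab.ids) == _flood_fill_count(mask)


class TestLabelCentroids:
    def test_cube_geometric_center(self):
        lab = np.zeros((10, 10, 10), dtype=np.int32)
        lab[2:6, 2:6, 2:6] = 1
        c = label_centroids(InstanceLabels(lab, VOX1)).coords_um[0]
        np.testing.assert_allclose(c, [4.0, 4.0, 4.0])

    def test_single_voxel_convention(self):
        lab = np.zeros((6, 6, 6), dtype=np.int32)
        lab[2, 3, 4] = 1
        c = label_centroids(InstanceLabels(lab, (0.5, 1.0, 2.0))).coords_um[0]
        np.testing.assert_allclose(c, [(2 + 0.5) * 0.5, (3 + 0.5) * 1.0,
                                       (4 + 0.5) * 2.0])

    def test_random_shapes_match_average_oracle(self, rng):
        from conftest import random_label_volume
        lab = random_label_volume(rng)
        cs = label_centroids(InstanceLabels(lab, (0.7, 1.0, 1.3)))
        for lid, coord in zip(cs.ids, cs.coords_um):
            idx = np.argwhere(lab == lid)
            expected = (idx.mean(axis=0) + 0.5) * np.asarray((0.7, 1.0, 1.3))
            np.testing.assert_allclose(coord, expected)


class TestClassicalBaseline:
    def test_two_sphere_phantom_recovered(self):
        """Noise-free two-sphere image: at least two labels with centroids
        within one voxel of the sphere centers."""
        mask = _two_sphere_mask()
        img = _vol(mask.astype(float))
        lab = classical_baseline_segment(img, opening_radius_voxels=1)
        assert len(lab.ids) >= 2
        cents = label_centroids(lab).coords_um
        for truth in ((8.5, 8.5, 8.5), (19.5, 8.5, 8.5)):
            d = np.linalg.norm(cents - np.asarray(truth), axis=1)
            assert d.min() <= np.sqrt(3)

    def test_constant_image_no_crash(self):
        lab = classical_baseline_segment(_vol(np.full((8, 8, 8), 0.3)))
        assert lab.data.max() == 0  # constant image: no objects

    def test_otsu_split_on_bimodal_image(self):
        from skimage.filters import threshold_otsu
        img = np.zeros((8, 8, 8))
        img[:4] = 1.0
        thr = threshold_otsu(img)
        assert 0.0 < thr < 1.0


class TestCropBorder:
    REGION = Box((0, 0, 0), (64.0, 64.0, 16.0))

    def _set(self, coords):
        return CentroidSet(np.asarray(coords, dtype=float), self.REGION)

    def test_border_centroid_removed(self):
        cs = self._set([[10.5, 10.5, 2.5]])
        out = crop_border(cs, border_voxels=(30, 30, 5), voxel_size_um=VOX1)
        assert len(out) == 0

    def test_inner_edge_retained_half_open(self):
        cs = self._set([[30.0, 30.0, 5.0]])
        out = crop_border(cs, border_voxels=(30, 30, 5), voxel_size_um=VOX1)
        assert len(out) == 1

    def test_retained_count_matches_filter_oracle(self, rng):
        pts = rng.uniform(0, (64, 64, 16), size=(200, 3))
        cs = self._set(pts)
        out = crop_border(cs, border_voxels=(8, 8, 4), voxel_size_um=VOX1)
        keep = np.sum(np.all((pts >= (8, 8, 4))
                             & (pts < (56, 56, 12)), axis=1))
        assert len(out) == keep

    def test_volume_crop_shrinks_shape(self):
        img = VolumeImage(np.zeros((20, 20, 12)), VOX1)
        out = crop_border(img, border_voxels=(4, 4, 2))
        assert out.shape == (12, 12, 8)

    def test_oversized_border_raises(self):
        cs = self._set([[32.0, 32.0, 8.0]])
        with pytest.raises(ValueError):
            crop_border(cs, border_voxels=(40, 40, 8), voxel_size_um=VOX1)
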
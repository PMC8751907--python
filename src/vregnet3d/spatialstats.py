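"""3D point-pattern statistics: F, G and H cumulative functions.

* F (empty-space function): CDF of the distance from uniformly random
  locations in the region to the nearest point of the pattern.
* G: CDF of nearest-neighbor distances among the points.
* H: CDF of all unordered pairwise distances.

For a homogeneous Poisson process of intensity ``lambda`` (complete spatial
randomness), F and G share the closed form ``1 - exp(-lambda * 4/3 pi r^3)``,
provided here as an analytic reference.  No edge correction is applied by
default (plain empirical CDFs); an optional minus-sampling border correction
restricts reference locations / points to an inner sub-region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .types import Box, CentroidSet

__all__ = [
    "SpatialCurve", "default_radii", "f_function", "g_function",
    "h_function", "curve_mae", "csr_reference",
]


@dataclass
class SpatialCurve:
    radii_um: np.ndarray
    values: np.ndarray
    kind: str  # "F" | "G" | "H"
    n_points: int

    def __post_init__(self):
        self.radii_um = np.asarray(self.radii_um, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.radii_um.shape != self.values.shape:
            raise ValueError("radii and values must align")

    def crossing(self, level: float = 0.5) -> float:
        """Smallest radius at which the curve reaches ``level``."""
        idx = np.searchsorted(self.values, level)
        if idx >= len(self.radii_um):
            return float("nan")
        return float(self.radii_um[idx])


def default_radii(region: Box, n: int = 200) -> np.ndarray:
    """200 equal steps from 0 to half the shortest region side."""
    return np.linspace(0.0, min(region.size) / 2.0, n)


def _ecdf(distances: np.ndarray, radii: np.ndarray) -> np.ndarray:
    d = np.sort(np.asarray(distances))
    return np.searchsorted(d, radii, side="right") / len(d)


def _inner_box(region: Box, margin: float) -> Box:
    return region.shrink((margin,) * 3, (margin,) * 3)


def f_function(points: CentroidSet, radii=None, n_reference: int = 10000,
               seed: int = 0, border_margin_um: float = 0.0) -> SpatialCurve:
    """Empty-space function from Monte-Carlo reference locations.

    ``n_reference`` uniform locations are drawn in the region (or, with
    minus-sampling, in the region shrunk by ``border_margin_um``) and the
    empirical CDF of their distance to the nearest pattern point is
    evaluated on ``radii``.
    """
    if len(points) == 0:
        raise ValueError("F-function needs at least one point")
    region = points.region
    if region.volume <= 0:
        raise ValueError("region volume must be positive")
    radii = default_radii(region) if radii is None else np.asarray(radii)
    rng = np.random.default_rng(seed)
    sample_box = _inner_box(region, border_margin_um) if border_margin_um \
        else region
    locs = rng.uniform(np.asarray(sample_box.lo), np.asarray(sample_box.hi),
                       size=(n_reference, 3))
    tree = cKDTree(points.coords_um)
    d, _ = tree.query(locs, k=1)
    return SpatialCurve(radii, _ecdf(d, radii), "F", len(points))


def g_function(points: CentroidSet, radii=None,
               border_margin_um: float = 0.0) -> SpatialCurve:
    """Nearest-neighbor distance CDF.

    With minus-sampling, only points inside the shrunk region contribute
    distances, but neighbors are searched over the full pattern.
    """
    if len(points) < 2:
        raise ValueError("G-function needs at least two points")
    radii = default_radii(points.region) if radii is None else np.asarray(radii)
    tree = cKDTree(points.coords_um)
    d, _ = tree.query(points.coords_um, k=2)
    nn = d[:, 1]
    if border_margin_um:
        keep = _inner_box(points.region, border_margin_um).contains(points.coords_um)
        if not keep.any():
            raise ValueError("border margin removed every point")
        nn = nn[keep]
    return SpatialCurve(radii, _ecdf(nn, radii), "G", len(points))


def h_function(points: CentroidSet, radii=None) -> SpatialCurve:
    """CDF of all unordered pairwise distances."""
    if len(points) < 2:
        raise ValueError("H-function needs at least two points")
    radii = default_radii(points.region) if radii is None else np.asarray(radii)
    d = pdist(points.coords_um)
    return SpatialCurve(radii, _ecdf(d, radii), "H", len(points))


def curve_mae(a: SpatialCurve, b: SpatialCurve) -> float:
    """Mean absolute difference between two curves on the same radii grid."""
    if a.kind != b.kind:
        raise ValueError(f"curve kinds differ: {a.kind} vs {b.kind}")
    if a.radii_um.shape != b.radii_um.shape or \
            not np.allclose(a.radii_um, b.radii_um):
        raise ValueError("radii grids differ")
    return float(np.mean(np.abs(a.values - b.values)))


def csr_reference(intensity_per_um3: float, radii) -> SpatialCurve:
    """Analytic F = G curve for complete spatial randomness.

    ``1 - exp(-lambda * 4/3 pi r^3)`` for a homogeneous Poisson process of
    intensity ``lambda`` per cubic micrometre.
    """
    if intensity_per_um3 <= 0:
        raise ValueError("intensity must be positive")
    r = np.asarray(radii, dtype=float)
    vals = 1.0 - np.exp(-intensity_per_um3 * 4.0 / 3.0 * np.pi * r ** 3)
    return SpatialCurve(r, vals, "F", 0)
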
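"""Core in-memory containers shared across the pipeline.

Conventions used repo-wide:

* Volumes are numpy arrays indexed ``[ix, iy, iz]``; voxel ``i`` along an axis
  with pitch ``d`` (in micrometres) spans the half-open interval
  ``[i*d, (i+1)*d)``, so the voxel *center* sits at ``(i + 0.5) * d``.
* Centroids and all other point coordinates are continuous physical
  coordinates in micrometres, ``(x, y, z)``.
* Instance labels are non-negative integers; 0 is background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VolumeImage",
    "InstanceLabels",
    "CentroidSet",
    "Box",
    "voxel_centers_um",
]


@dataclass(frozen=True)
class Box:
    """Axis-aligned region in physical micrometres, half-open ``[lo, hi)``."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    @property
    def size(self) -> tuple[float, float, float]:
        return tuple(h - l for l, h in zip(self.lo, self.hi))

    @property
    def volume(self) -> float:
        return float(np.prod(self.size))

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the half-open box."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        lo = np.asarray(self.lo)
        hi = np.asarray(self.hi)
        return np.all((points >= lo) & (points < hi), axis=1)

    def shrink(self, margin_lo, margin_hi) -> "Box":
        lo = tuple(l + m for l, m in zip(self.lo, margin_lo))
        hi = tuple(h - m for h, m in zip(self.hi, margin_hi))
        if any(a >= b for a, b in zip(lo, hi)):
            raise ValueError(f"margins {margin_lo}/{margin_hi} collapse box {self}")
        return Box(lo, hi)


@dataclass
class VolumeImage:
    """3D scalar field with anisotropic voxel pitch in micrometres."""

    data: np.ndarray
    voxel_size_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got shape {self.data.shape}")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError(f"voxel size must be positive, got {self.voxel_size_um}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def region(self) -> Box:
        hi = tuple(n * d for n, d in zip(self.data.shape, self.voxel_size_um))
        return Box((0.0, 0.0, 0.0), hi)


@dataclass
class InstanceLabels(VolumeImage):
    """Integer label field: 0 = background, k > 0 = nucleus identity."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError(f"labels must be integer, got {self.data.dtype}")
        if self.data.size and self.data.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def ids(self) -> np.ndarray:
        ids = np.unique(self.data)
        return ids[ids > 0]


@dataclass
class CentroidSet:
    """Point set in physical micrometres plus its bounding region."""

    coords_um: np.ndarray
    region: Box
    ids: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.coords_um = np.asarray(self.coords_um, dtype=float).reshape(-1, 3)
        if self.ids is None:
            self.ids = np.arange(1, len(self.coords_um) + 1)
        else:
            self.ids = np.asarray(self.ids)
            if len(self.ids) != len(self.coords_um):
                raise ValueError("ids and coords length mismatch")

    def __len__(self) -> int:
        return len(self.coords_um)

    def __iter__(self):
        return iter(self.coords_um)


def voxel_centers_um(indices: np.ndarray, voxel_size_um) -> np.ndarray:
    """Physical center coordinates of integer voxel indices (N, 3)."""
    idx = np.atleast_2d(np.asarray(indices, dtype=float))
    d = np.asarray(voxel_size_um, dtype=float)
    return (idx + 0.5) * d
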
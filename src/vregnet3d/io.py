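"""Reading and writing the exchange formats: TIFF stacks, centroid CSVs,
YAML configs and model checkpoints.

Volumes are stored as multi-page TIFF with one page per z-slice (page axis =
z); in memory they are ``(x, y, z)`` arrays, so the transpose happens at the
boundary.  Centroid CSVs carry physical micrometre coordinates with the
header ``id,x_um,y_um,z_um``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import Box, CentroidSet, InstanceLabels, VolumeImage

__all__ = [
    "write_volume_tiff", "read_volume_tiff",
    "write_labels_tiff", "read_labels_tiff",
    "write_centroids_csv", "read_centroids_csv",
    "write_yaml", "read_yaml",
    "save_checkpoint", "load_checkpoint",
]


def write_volume_tiff(path, volume: VolumeImage) -> None:
    # pages = z, rows = y, cols = x
    pages = np.moveaxis(volume.data, (0, 1, 2), (2, 1, 0))
    tifffile.imwrite(str(path), pages, photometric="minisblack",
                     metadata={"voxel_size_um": list(volume.voxel_size_um)})


def _read_voxel_size(tif) -> tuple[float, float, float] | None:
    meta = tif.shaped_metadata or tif.imagej_metadata
    if meta:
        entry = meta[0] if isinstance(meta, (list, tuple)) else meta
        if "voxel_size_um" in entry:
            v = entry["voxel_size_um"]
            if isinstance(v, str):
                v = json.loads(v)
            return tuple(float(x) for x in v)
    return None


def read_volume_tiff(path, voxel_size_um=None) -> VolumeImage:
    with tifffile.TiffFile(str(path)) as tif:
        pages = tif.asarray()
        stored = _read_voxel_size(tif)
    if pages.ndim == 2:
        pages = pages[None]
    data = np.moveaxis(pages, (0, 1, 2), (2, 1, 0))
    vox = voxel_size_um or stored or (1.0, 1.0, 1.0)
    return VolumeImage(data, vox)


def write_labels_tiff(path, labels: InstanceLabels) -> None:
    write_volume_tiff(path, labels)


def read_labels_tiff(path, voxel_size_um=None) -> InstanceLabels:
    v = read_volume_tiff(path, voxel_size_um)
    return InstanceLabels(v.data.astype(np.int32), v.voxel_size_um)


def write_centroids_csv(path, centroids: CentroidSet) -> None:
    df = pd.DataFrame({
        "id": centroids.ids,
        "x_um": centroids.coords_um[:, 0],
        "y_um": centroids.coords_um[:, 1],
        "z_um": centroids.coords_um[:, 2],
    })
    df.to_csv(path, index=False)


def read_centroids_csv(path, region: Box | None = None) -> CentroidSet:
    df = pd.read_csv(path)
    coords = df[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    ids = df["id"].to_numpy() if "id" in df else None
    if region is None:
        hi = tuple(coords.max(axis=0) + 1e-9) if len(coords) else (1.0,) * 3
        region = Box((0.0, 0.0, 0.0), hi)
    return CentroidSet(coords, region, ids=ids)


def write_yaml(path, obj: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_checkpoint(path, model, extra: dict | None = None) -> None:
    """Serialize model parameters + architecture config + metadata (npz)."""
    state = model.state_dict()
    meta = {
        "class": type(model).__name__,
        "config": model.cfg.to_dict(),
        "extra": extra or {},
    }
    if hasattr(model, "n_classes"):
        meta["n_classes"] = model.n_classes
    np.savez_compressed(str(path), __meta__=json.dumps(meta), **state)


def load_checkpoint(path):
    """Rebuild a model from :func:`save_checkpoint` output."""
    from .networks.models import (RegressionNet, RegressionNetConfig,
                                  SegmentationNet, SegmentationNetConfig)
    with np.load(str(path), allow_pickle=False) as npz:
        meta = json.loads(str(npz["__meta__"]))
        state = {k: npz[k] for k in npz.files if k != "__meta__"}
    rng = np.random.default_rng(0)
    if meta["class"] == "RegressionNet":
        model = RegressionNet(RegressionNetConfig(**meta["config"]), rng)
    elif meta["class"] == "SegmentationNet":
        model = SegmentationNet(meta["n_classes"],
                                SegmentationNetConfig(**meta["config"]), rng)
    else:
        raise ValueError(f"unknown checkpoint class {meta['class']}")
    model.load_state_dict(state)
    return model, meta["extra"]
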
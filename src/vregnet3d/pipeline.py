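"""End-to-end orchestration: phantom -> train -> detect -> evaluate -> stats.

Five detection routes are supported:

* ``vregnet``  — two-class segmentation net, median seam smoothing, centroid
  regression net, local-maxima extraction;
* ``vnet3``    — three-class segmentation net, connected components on the
  nucleus class, per-label centroids;
* ``vnet3w``   — three-class segmentation net, distance-transform watershed,
  per-label centroids;
* ``vnet2w``   — two-class segmentation net, distance-transform watershed,
  per-label centroids;
* ``classical``— non-learned opening + Otsu + watershed baseline.

Evaluation crops the same border band from predictions and ground truth, so
nuclei near volume edges are not scored.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import groundtruth, io, postprocess
from .evaluate import detection_metrics, match_centroids
from .networks import (
    RegressionNetConfig, SegmentationNetConfig, TrainingConfig,
    build_regression_net, build_segmentation_net, predict_tiled, train,
)
from .networks.losses import dice_loss_with_grad, scaled_mse_loss_with_grad
from .phantom import PhantomSpec, Phantom, generate_phantom
from .spatialstats import curve_mae, f_function, g_function, h_function
from .types import CentroidSet, VolumeImage

METHODS = ("vregnet", "vnet3", "vnet3w", "vnet2w", "classical")

__all__ = ["RunConfig", "PipelineModels", "run_pipeline", "train_models",
           "detect", "METHODS", "desk_scale_config"]


@dataclass
class RunConfig:
    """Reproducible configuration for a full synthetic-data run."""

    train_phantom: PhantomSpec = field(default_factory=PhantomSpec)
    val_phantom: PhantomSpec = field(
        default_factory=lambda: PhantomSpec(shape_voxels=(64, 64, 32),
                                            n_nuclei=15, seed=1))
    test_phantom: PhantomSpec = field(
        default_factory=lambda: PhantomSpec(seed=2))
    seg_net: SegmentationNetConfig = field(default_factory=SegmentationNetConfig)
    reg_net: RegressionNetConfig = field(default_factory=RegressionNetConfig)
    seg_training: TrainingConfig = field(default_factory=TrainingConfig)
    reg_training: TrainingConfig = field(default_factory=TrainingConfig)
    maxima: postprocess.MaximaConfig = field(default_factory=postprocess.MaximaConfig)
    watershed: postprocess.WatershedConfig = field(
        default_factory=postprocess.WatershedConfig)
    density_sigma_voxels: tuple[float, float, float] = (3.0, 3.0, 3.0)
    match_radius_um: float = 3.0
    border_voxels: tuple[int, int, int] = (30, 30, 5)
    tile_patch: tuple[int, int, int] | None = None  # default: training patch
    tile_overlap: tuple[int, int, int] = (8, 8, 4)
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def desk_scale_config(seed: int = 0, n_nuclei: int = 110,
                      max_epochs: int = 12) -> RunConfig:
    """A CPU-friendly configuration on an easy, well-separated phantom.

    The phantom uses isotropic 1 um voxels, bright nuclei, low noise and a
    generous minimum spacing; networks are compact (3 levels, 4 base
    channels) and the post-processing smoothing scales are set for the
    1 um voxel pitch.
    """
    def spec(shape, n, s):
        return PhantomSpec(
            shape_voxels=shape, voxel_size_um=(1.0, 1.0, 1.0),
            nucleus_radius_range_um=(2.2, 3.5),
            eccentricity_range=(1.1, 1.6), n_nuclei=n,
            min_center_spacing_um=8.0, intensity_cv=0.15,
            speckle_fraction=0.1, psf_sigma_um=(0.5, 0.5, 1.0),
            gaussian_sd=0.02, poisson_scale=400.0,
            attenuation_per_um=0.002, seed=s)
    base = seed * 97
    return RunConfig(
        train_phantom=spec((128, 128, 32), n_nuclei, base + 11),
        val_phantom=spec((64, 64, 32), max(n_nuclei // 5, 8), base + 12),
        test_phantom=spec((128, 128, 32), n_nuclei, base + 13),
        seg_net=SegmentationNetConfig(n_levels=3, base_channels=4),
        reg_net=RegressionNetConfig(n_levels=3, base_channels=8,
                                    dropout_rate=0.05),
        seg_training=TrainingConfig(
            initial_lr=3e-3, lr_drop_factor=0.9, lr_drop_period_epochs=5,
            minibatch_size=2, patch_size_voxels=(32, 32, 16),
            patches_per_epoch=50, max_epochs=max_epochs, seed=base + 21),
        reg_training=TrainingConfig(
            initial_lr=3e-2, lr_drop_factor=0.9, lr_drop_period_epochs=5,
            minibatch_size=2, patch_size_voxels=(32, 32, 16),
            patches_per_epoch=50, max_epochs=max_epochs + 5, seed=base + 22),
        maxima=postprocess.MaximaConfig(
            background_threshold_rel=0.1,
            smoothing_sigma_voxels=(2.0, 2.0, 1.5),
            suppression_radius_um=2.0),
        watershed=postprocess.WatershedConfig(
            class_threshold=0.5, presmooth_sigma_voxels=(1.0, 1.0, 1.0),
            minima_suppression_depth=1.0),
        border_voxels=(8, 8, 4),
        seed=seed,
    )


@dataclass
class PipelineModels:
    seg2: object | None = None   # two-class segmentation net
    seg3: object | None = None   # three-class segmentation net
    reg: object | None = None    # centroid regression net
    histories: dict = field(default_factory=dict)


def _seg_target(phantom: Phantom, n_classes: int) -> np.ndarray:
    if n_classes == 2:
        cv = groundtruth.make_two_class(phantom.labels)
    else:
        cv = groundtruth.make_three_class(phantom.labels)
    return cv.one_hot().astype(np.float64)


def _train_seg(n_classes, cfg: RunConfig, train_ph, val_ph, verbose=False):
    net = build_segmentation_net(n_classes, cfg.seg_net,
                                 seed=cfg.seed * 1000 + n_classes)
    res = train(net, train_ph.image.data, _seg_target(train_ph, n_classes),
                cfg.seg_training, dice_loss_with_grad,
                val_input=val_ph.image.data,
                val_target=_seg_target(val_ph, n_classes), verbose=verbose)
    return net, res


def _tiled_nucleus_prob(net, volume: VolumeImage, cfg: RunConfig) -> VolumeImage:
    patch = cfg.tile_patch or cfg.seg_training.patch_size_voxels
    probs = predict_tiled(net, volume.data, patch, cfg.tile_overlap)
    return VolumeImage(probs[-1], volume.voxel_size_um)


def train_models(cfg: RunConfig, method: str, verbose: bool = False
                 ) -> tuple[PipelineModels, Phantom, Phantom, Phantom]:
    """Generate phantoms and train the networks the method requires."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    train_ph = generate_phantom(cfg.train_phantom)
    val_ph = generate_phantom(cfg.val_phantom)
    test_ph = generate_phantom(cfg.test_phantom)
    models = PipelineModels()

    if method in ("vregnet", "vnet2w"):
        models.seg2, res = _train_seg(2, cfg, train_ph, val_ph, verbose)
        models.histories["seg2"] = res
    if method in ("vnet3", "vnet3w"):
        models.seg3, res = _train_seg(3, cfg, train_ph, val_ph, verbose)
        models.histories["seg3"] = res

    if method == "vregnet":
        # regression input: nucleus probability from the two-class net,
        # median filtered to blend patch seams
        tin = postprocess.smooth_seams(
            _tiled_nucleus_prob(models.seg2, train_ph.image, cfg))
        vin = postprocess.smooth_seams(
            _tiled_nucleus_prob(models.seg2, val_ph.image, cfg))
        ttar = groundtruth.make_centroid_density(
            train_ph.centroids, train_ph.image, cfg.density_sigma_voxels)
        vtar = groundtruth.make_centroid_density(
            val_ph.centroids, val_ph.image, cfg.density_sigma_voxels)
        reg = build_regression_net(cfg.reg_net, seed=cfg.seed * 1000 + 7)
        scale = cfg.reg_net.target_scale

        def loss(pred, tgt):
            return scaled_mse_loss_with_grad(pred, tgt, scale)

        res = train(reg, tin.data, ttar.map.data, cfg.reg_training, loss,
                    val_input=vin.data, val_target=vtar.map.data,
                    verbose=verbose)
        models.reg = reg
        models.histories["reg"] = res
    return models, train_ph, val_ph, test_ph


def detect(models: PipelineModels, volume: VolumeImage, cfg: RunConfig,
           method: str) -> CentroidSet:
    """Run one detection route on a volume, returning uncropped centroids."""
    if method == "classical":
        labels = postprocess.classical_baseline_segment(
            volume, opening_radius_voxels=2, cfg=cfg.watershed)
        return postprocess.label_centroids(labels)
    if method == "vregnet":
        prob = postprocess.smooth_seams(
            _tiled_nucleus_prob(models.seg2, volume, cfg))
        patch = cfg.tile_patch or cfg.reg_training.patch_size_voxels
        density = predict_tiled(models.reg, prob.data, patch,
                                cfg.tile_overlap)[0]
        density = VolumeImage(density, volume.voxel_size_um)
        return postprocess.detect_local_maxima(density, cfg.maxima)
    if method == "vnet2w":
        prob = _tiled_nucleus_prob(models.seg2, volume, cfg)
        labels = postprocess.watershed_instances(prob, cfg.watershed)
        return postprocess.label_centroids(labels)
    if method == "vnet3w":
        prob = _tiled_nucleus_prob(models.seg3, volume, cfg)
        labels = postprocess.watershed_instances(prob, cfg.watershed)
        return postprocess.label_centroids(labels)
    if method == "vnet3":
        prob = _tiled_nucleus_prob(models.seg3, volume, cfg)
        labels = postprocess.connected_component_instances(
            prob, cfg.watershed.class_threshold)
        return postprocess.label_centroids(labels)
    raise ValueError(f"unknown method {method!r}")


def run_pipeline(cfg: RunConfig, method: str = "vregnet",
                 out_dir: str | Path | None = None,
                 spatial_stats: bool = False,
                 verbose: bool = False) -> dict:
    """Full run; returns a result dict and optionally writes artifacts.

    The result carries the detection metrics on the test phantom (after the
    symmetric border crop), the predicted/true centroid sets, loss
    histories, and — when ``spatial_stats`` — F/G/H curves with their mean
    absolute error against the ground-truth curves.
    """
    models, train_ph, val_ph, test_ph = train_models(cfg, method, verbose)
    pred = detect(models, test_ph.image, cfg, method)

    vox = cfg.test_phantom.voxel_size_um
    pred_c = postprocess.crop_border(pred, cfg.border_voxels, vox)
    truth_c = postprocess.crop_border(test_ph.centroids, cfg.border_voxels, vox)
    m = match_centroids(pred_c, truth_c, cfg.match_radius_um)
    metrics = detection_metrics(m)

    result = {
        "method": method,
        "config_hash": cfg.config_hash(),
        "metrics": metrics,
        "match": m,
        "pred_centroids": pred_c,
        "true_centroids": truth_c,
        "models": models,
        "test_phantom": test_ph,
    }

    if spatial_stats and len(pred_c) >= 2 and len(truth_c) >= 2:
        curves = {}
        for kind, fn in (("F", lambda c: f_function(c, seed=cfg.seed)),
                         ("G", g_function), ("H", h_function)):
            cp, ct = fn(pred_c), fn(truth_c)
            curves[kind] = {"pred": cp, "truth": ct,
                            "mae": curve_mae(cp, ct)}
        result["curves"] = curves

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        h = cfg.config_hash()
        io.write_yaml(out / f"config_{h}.yaml", cfg.to_dict())
        io.write_centroids_csv(out / f"centroids_{method}_{h}.csv", pred_c)
        io.write_centroids_csv(out / f"truth_{h}.csv", truth_c)
        with open(out / f"metrics_{method}_{h}.json", "w") as fh:
            json.dump(metrics.as_dict(), fh, indent=2)
        import pandas as pd
        for name, res in models.histories.items():
            pd.DataFrame({"epoch": range(len(res.train_loss)),
                          "train_loss": res.train_loss,
                          "val_loss": res.val_loss,
                          "lr": res.lr_schedule}).to_csv(
                out / f"curves_{name}_{method}_{h}.csv", index=False)
    return result
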
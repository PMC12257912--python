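"""End-to-end desk-scale experiments: simulate, train, reconstruct, evaluate.

The default geometry is chosen so the squeeze protocol guarantee holds: a
128x128 ground-truth patch (0.7 mm pixels) always fits inside the d = 64/s
window at binning scale s.  Every stage is seeded, so identical configs
give identical reports.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .fbp import cosine_weight, ramp_filter
from .geometry import FanBeamGeometry
from .learning import (CRETModel, SinogramDataset, TrainConfig, build_dataset,
                       gt_patch, train_step1, train_step2_restorator, EncoderSpec)
from .metrics import EvalReport, psnr, ssim
from .phantoms import add_poisson_noise, bin_detector, make_phantom, Phantom
from .phantoms import project_ellipses_analytic
from .squeeze import ROISpec

__all__ = ["default_geometry", "ExperimentConfig", "run_experiment", "log_line"]


def default_geometry(n_views: int = 180, n_detectors: int = 128,
                     det_pitch: float = 3.6) -> FanBeamGeometry:
    """SID 800 mm / SDD 1200 mm flat-panel scanner (2.4 mm pitch at isocenter)."""
    return FanBeamGeometry(source_to_iso=800.0, source_to_det=1200.0,
                           n_detectors=n_detectors, det_pitch=det_pitch,
                           n_views=n_views)


def log_line(stage: str, **kw) -> str:
    parts = [f"stage={stage}"] + [f"{k}={v}" for k, v in kw.items()]
    line = " ".join(parts)
    print(line, flush=True)
    return line


@dataclass
class ExperimentConfig:
    """Toy-study configuration (all sizes desk scale)."""

    n_train_phantoms: int = 12
    n_test_phantoms: int = 6
    grid_size: int = 96
    pixel_spacing: float = 0.7
    n_views: int = 180
    scales: Tuple[int, ...] = (1, 2, 4)
    eval_scales: Tuple[int, ...] = (2, 4, 8)
    patch_extent: float = 22.4
    out_resolution: int = 32
    photons_i0: float = 1.0e6
    data_range: float = 2000.0
    train: TrainConfig = field(default_factory=TrainConfig)
    with_restorator: bool = False
    seed: int = 0


def _make_phantoms(n: int, cfg: ExperimentConfig, seed0: int):
    return [make_phantom("random_ellipses", cfg.grid_size, cfg.pixel_spacing,
                         seed=seed0 + i) for i in range(n)]


def evaluate_model(
    model: CRETModel,
    phantoms: Sequence[Phantom],
    geometry: FanBeamGeometry,
    scales: Sequence[int],
    cfg: ExperimentConfig,
    report: EvalReport,
    seed: int,
    methods: Sequence[str] = ("fbp", "cret"),
) -> EvalReport:
    """Reconstruct one centered-pool ROI per held-out phantom at each scale
    and score PSNR/SSIM against the ground-truth patch."""
    rng = np.random.default_rng(seed)
    for pi, ph in enumerate(phantoms):
        p = project_ellipses_analytic(ph.ellipses, geometry)
        noisy = add_poisson_noise(p, cfg.photons_i0, seed=int(rng.integers(2**31)))
        # one non-air ROI per phantom, shared across scales and methods
        from .learning import _roi_center_pool
        center = _roi_center_pool(ph, cfg.patch_extent, 1,
                                  np.random.default_rng(seed + 1000 + pi))[0]
        for s in scales:
            z = ramp_filter(cosine_weight(bin_detector(noisy, s)))
            roi = ROISpec(center, cfg.patch_extent, cfg.out_resolution, binning=s)
            gt = gt_patch(ph, roi)
            for method in methods:
                try:
                    if method == "fbp":
                        img = model.fbp_roi(z, roi)
                    elif method == "cret":
                        img = model.reconstruct(z, roi)
                    elif method == "cret+":
                        img = model.reconstruct(z, roi, restore=True)
                    else:
                        raise ValueError(f"unknown method {method!r}")
                    report.add(method=method, binning=s, phantom=pi,
                               out_resolution=cfg.out_resolution,
                               psnr_db=psnr(img.data, gt, cfg.data_range),
                               ssim=ssim(img.data, gt, cfg.data_range))
                except Exception as exc:  # a failed method must not sink the rest
                    report.add(method=method, binning=s, phantom=pi,
                               out_resolution=cfg.out_resolution,
                               psnr_db=float("nan"), ssim=float("nan"),
                               failed=True, error=str(exc))
    return report


def run_experiment(cfg: ExperimentConfig,
                   model: Optional[CRETModel] = None) -> tuple:
    """Full toy study: phantoms -> training -> evaluation report.

    Returns ``(model, report)``.  A pre-trained model skips step 1; the
    out-of-training binning scale (8 by default) is evaluated with the same
    unified model, no retraining.
    """
    t0 = time.time()
    geometry = default_geometry(n_views=cfg.n_views)
    train_ph = _make_phantoms(cfg.n_train_phantoms, cfg, seed0=cfg.seed)
    test_ph = _make_phantoms(cfg.n_test_phantoms, cfg, seed0=cfg.seed + 10_000)
    log_line("simulate", n_train=len(train_ph), n_test=len(test_ph),
             grid=cfg.grid_size, views=cfg.n_views, seed=cfg.seed)
    if model is None:
        ds = build_dataset(train_ph, geometry, scales=cfg.scales,
                           patch_extent=cfg.patch_extent,
                           out_resolution=cfg.out_resolution,
                           photons_i0=cfg.photons_i0, seed=cfg.seed)
        model, hist = train_step1(ds, cfg.train,
                                  log=lambda r: log_line("train1", **r))
        if cfg.with_restorator:
            train_step2_restorator(model, ds, cfg.train,
                                   log=lambda r: log_line("train2", **r))
    report = EvalReport(data_range=cfg.data_range, seed=cfg.seed,
                        params={"scales": list(cfg.eval_scales),
                                "out_resolution": cfg.out_resolution})
    methods = ("fbp", "cret", "cret+") if cfg.with_restorator else ("fbp", "cret")
    evaluate_model(model, test_ph, geometry, cfg.eval_scales, cfg, report,
                   seed=cfg.seed + 1, methods=methods)
    for s in cfg.eval_scales:
        log_line("eval", s=s,
                 **{m: round(report.mean(m, s), 3) for m in methods})
    log_line("done", wall_s=round(time.time() - t0, 1))
    return model, report
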
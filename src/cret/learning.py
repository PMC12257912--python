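"""Trainable pipeline: encoder features, channel matching, two-step training.

Step 1 trains the feature encoder E and the 1x1 channel-matching map A so
that the decoder-augmented back-projection of the squeezed sinogram matches
ground-truth ROI patches under an L1 loss; the back-projection adjoint from
:mod:`cret.decoder` carries the gradient into the sinogram domain.  Step 2
optionally trains a plug-and-play image-domain restorator on (step-1
output, ground truth) pairs with the step-1 weights frozen.

The channel-matching head is zero-initialized, so an untrained model
reproduces plain FBP exactly and training starts from the FBP error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import map_coordinates

from .decoder import BasisConfig, BasisFeatureMap, ProjectionPlan, cret_backproject
from .fbp import cosine_weight, ramp_filter
from .geometry import FanBeamGeometry, ReconImage, Sinogram
from .nn import Adam, Restorator, TinyEncoder, l1_loss
from .phantoms import (MU_WATER, Phantom, add_poisson_noise, bin_detector,
                       hu_to_mu, mu_to_hu, project_ellipses_analytic)
from .projector import project_phantom
from .squeeze import (ROISpec, SqueezedSinogram, default_squeeze_params,
                      roi_center_index, squeeze, unfold)

__all__ = [
    "EncoderSpec",
    "TrainConfig",
    "encode",
    "channel_match",
    "channel_match_backward",
    "CRETModel",
    "SinogramDataset",
    "build_dataset",
    "gt_patch",
    "train_step1",
    "train_step2_restorator",
]

#: HU scale used to normalize image-domain network inputs
_HU_NORM = 1000.0


@dataclass(frozen=True)
class EncoderSpec:
    """Encoder contract: architecture id, feature channel count, and whether
    the input sinogram is unfolded (9 channels, 1x1 first layer) or plain
    (1 channel, 3x3 first layer)."""

    architecture: str = "tiny_cnn"
    features: int = 32
    unfolded: bool = True
    seed: int = 0

    def build(self) -> TinyEncoder:
        if self.architecture != "tiny_cnn":
            raise ValueError(
                f"unknown architecture {self.architecture!r}; external encoders "
                "plug in via the same (C,N,d)->(F,N,d) call contract"
            )
        return TinyEncoder(unfolded=self.unfolded, features=self.features,
                           seed=self.seed)


def encode(sq: SqueezedSinogram, encoder: TinyEncoder) -> np.ndarray:
    """Squeezed sinogram -> feature array (F, N, d); shape-preserving over
    (N, d) and deterministic given the encoder weights."""
    feats, _ = encode_with_cache(sq, encoder)
    return feats


def encode_with_cache(sq: SqueezedSinogram, encoder: TinyEncoder):
    if sq.unfolded != encoder.unfolded:
        raise ValueError(
            "encoder channel layout does not match the sinogram: unfolded inputs "
            "require a 1x1 nine-channel first layer"
        )
    x = sq.data.transpose(2, 0, 1) if sq.unfolded else sq.data[None]
    return encoder.forward(np.ascontiguousarray(x, dtype=float))


def channel_match(features: np.ndarray, gamma: np.ndarray,
                  basis: BasisConfig) -> BasisFeatureMap:
    """Per-position linear map (1x1 convolution) from F feature channels to
    the 2n+1 decoder bases."""
    if gamma.shape != (basis.dim, features.shape[0]):
        raise ValueError(
            f"gamma must be ({basis.dim}, {features.shape[0]}), got {gamma.shape}"
        )
    data = np.einsum("fnd,kf->ndk", features, gamma)
    return BasisFeatureMap(data, basis)


def channel_match_backward(grad_zstar: np.ndarray, features: np.ndarray,
                           gamma: np.ndarray):
    """Adjoints of :func:`channel_match` -> (dfeatures, dgamma)."""
    dfeat = np.einsum("ndk,kf->fnd", grad_zstar, gamma)
    dgamma = np.einsum("ndk,fnd->kf", grad_zstar, features)
    return dfeat, dgamma


@dataclass
class CRETModel:
    """Step-1 model: encoder + channel-matching weights + basis + protocol."""

    encoder: TinyEncoder
    gamma: np.ndarray
    basis: BasisConfig = BasisConfig(5)
    unfolded: bool = True
    d0: int = 64
    pad0: int = 256
    mu_water: float = MU_WATER
    restorator: Optional[Restorator] = None

    @classmethod
    def create(cls, spec: EncoderSpec = EncoderSpec(), basis: BasisConfig = BasisConfig(5),
               d0: int = 64, pad0: int = 256, mu_water: float = MU_WATER) -> "CRETModel":
        enc = spec.build()
        gamma = np.zeros((basis.dim, spec.features))
        return cls(encoder=enc, gamma=gamma, basis=basis, unfolded=spec.unfolded,
                   d0=d0, pad0=pad0, mu_water=mu_water)

    # -- inference ---------------------------------------------------------
    def squeeze_for(self, z: Sinogram, roi: ROISpec) -> SqueezedSinogram:
        d, pad = default_squeeze_params(z.binning, self.d0, self.pad0)
        ci = roi_center_index(roi, z.geometry)
        src = unfold(z) if self.unfolded else z
        return squeeze(src, ci, d, pad)

    def zstar(self, sq: SqueezedSinogram) -> BasisFeatureMap:
        return channel_match(encode(sq, self.encoder), self.gamma, self.basis)

    def reconstruct(self, z: Sinogram, roi: ROISpec,
                    plan: Optional[ProjectionPlan] = None,
                    restore: bool = False) -> ReconImage:
        """Filtered sinogram -> HU ROI image via the augmented back-projection;
        ``restore`` additionally applies the step-2 restorator if present."""
        sq = self.squeeze_for(z, roi)
        img = cret_backproject(sq, self.zstar(sq), roi, plan=plan)
        hu = mu_to_hu(img.data, self.mu_water)
        if restore:
            if self.restorator is None:
                raise ValueError("no restorator attached to this model")
            hu = self.restorator(hu[None] / _HU_NORM)[0] * _HU_NORM
        return ReconImage(hu, img.grid, roi=roi, meta=dict(img.meta, units="HU"))

    def fbp_roi(self, z: Sinogram, roi: ROISpec,
                plan: Optional[ProjectionPlan] = None) -> ReconImage:
        """Plain-FBP baseline through the identical squeezed-ray path."""
        sq = self.squeeze_for(z, roi)
        img = cret_backproject(sq, None, roi, plan=plan)
        return ReconImage(mu_to_hu(img.data, self.mu_water), img.grid, roi=roi,
                          meta=dict(img.meta, units="HU"))

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        arrays = {"gamma": self.gamma}
        for k, v in self.encoder.state_dict().items():
            arrays["encoder/" + k] = v
        if self.restorator is not None:
            for k, v in self.restorator.state_dict().items():
                arrays["restorator/" + k] = v
        meta = dict(n=self.basis.n, unfolded=self.unfolded, d0=self.d0,
                    pad0=self.pad0, mu_water=self.mu_water,
                    features=self.encoder.features,
                    has_restorator=self.restorator is not None)
        np.savez(path, __meta__=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "CRETModel":
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["__meta__"]))
            enc = TinyEncoder(unfolded=meta["unfolded"], features=meta["features"])
            enc.load_state_dict({k.split("/", 1)[1]: f[k] for k in f.files
                                 if k.startswith("encoder/")})
            model = cls(encoder=enc, gamma=np.array(f["gamma"]),
                        basis=BasisConfig(meta["n"]), unfolded=meta["unfolded"],
                        d0=meta["d0"], pad0=meta["pad0"], mu_water=meta["mu_water"])
            if meta["has_restorator"]:
                rest = Restorator()
                rest.load_state_dict({k.split("/", 1)[1]: f[k] for k in f.files
                                      if k.startswith("restorator/")})
                model.restorator = rest
        return model


# --------------------------------------------------------------------------
# dataset preparation
# --------------------------------------------------------------------------

@dataclass
class SinogramDataset:
    """Filtered sinograms at each binning scale plus ROI-center pools.

    Noise realizations are drawn once at build time (a fixed synthetic
    dataset), seeded; ``filtered[(phantom_idx, s)]`` holds the filtered,
    binned sinogram ready for squeezing.
    """

    phantoms: List[Phantom]
    geometry: FanBeamGeometry
    scales: Tuple[int, ...]
    patch_extent: float
    out_resolution: int
    filtered: Dict[tuple, Sinogram] = field(default_factory=dict)
    centers: Dict[int, List[tuple]] = field(default_factory=dict)

    def samples(self) -> List[tuple]:
        return [(i, c, s) for i in range(len(self.phantoms))
                for c in self.centers[i] for s in self.scales]


def _roi_center_pool(phantom: Phantom, patch_extent: float, n_centers: int,
                     rng: np.random.Generator, air_threshold: float = -500.0):
    """Sample ROI centers uniformly over the phantom interior, excluding air,
    keeping the patch fully inside the grid."""
    X, Y = phantom.grid.pixel_centers()
    margin = patch_extent / 2.0
    half = phantom.extent / 2.0
    ok = (phantom.values > air_threshold) \
        & (np.abs(X) < half - margin) & (np.abs(Y) < half - margin)
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        raise ValueError("no non-air ROI centers available for this patch size")
    pick = rng.choice(idx, size=min(n_centers, idx.size), replace=False)
    return [(float(X.ravel()[j]), float(Y.ravel()[j])) for j in pick]


def build_dataset(
    phantoms: Sequence[Phantom],
    geometry: FanBeamGeometry,
    scales: Tuple[int, ...] = (1, 2, 4),
    patch_extent: float = 32.0,
    out_resolution: int = 32,
    photons_i0: float = 1.0e6,
    seed: int = 0,
    n_centers: int = 4,
    window: str = "ramlak",
    analytic: bool = True,
) -> SinogramDataset:
    """Forward-project each phantom, add Poisson noise, bin, weight, filter.

    ``analytic`` uses the closed-form ellipse projector (exact line
    integrals, the natural choice for piecewise-ellipse phantoms); set it
    False to route through the numeric ray-driven projector instead.
    """
    rng = np.random.default_rng(seed)
    ds = SinogramDataset(list(phantoms), geometry, tuple(scales),
                         patch_extent, out_resolution)
    for i, ph in enumerate(ds.phantoms):
        if analytic and not ph.lesions:
            p = project_ellipses_analytic(ph.ellipses, geometry)
        else:
            p = project_phantom(ph, geometry)
        noisy = add_poisson_noise(p, photons_i0, seed=int(rng.integers(2**31)))
        for s in ds.scales:
            ds.filtered[(i, s)] = ramp_filter(cosine_weight(bin_detector(noisy, s)),
                                              window=window)
        ds.centers[i] = _roi_center_pool(ph, patch_extent, n_centers, rng)
    return ds


def gt_patch(phantom: Phantom, roi: ROISpec) -> np.ndarray:
    """Ground-truth HU patch: the phantom sampled on the ROI grid (bilinear;
    an exact crop when the ROI grid is aligned with the phantom grid)."""
    X, Y = roi.grid.pixel_centers()
    g = phantom.grid
    rows = (g.origin[1] - Y) / g.spacing
    cols = (X - g.origin[0]) / g.spacing
    return map_coordinates(phantom.values, [rows.ravel(), cols.ravel()],
                           order=1, cval=-1000.0).reshape(roi.grid.shape)


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Training protocol: binning scales drawn per sample from {1, 2, 4},
    L1 loss, Adam, learning rate halved at fixed fractions of the run
    (0.2/0.4/0.6/0.8, rescaled to the configured epoch count)."""

    epochs: int = 10
    iters_per_epoch: int = 50
    batch_size: int = 4
    lr: float = 1e-3
    lr_decay: float = 0.5
    decay_at: Tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")

    def lr_at(self, epoch: int) -> float:
        milestones = [int(round(f * self.epochs)) for f in self.decay_at]
        return self.lr * self.lr_decay ** sum(epoch >= m for m in milestones)


class _PlanCache:
    def __init__(self):
        self._plans: Dict[tuple, ProjectionPlan] = {}

    def get(self, ds: SinogramDataset, model: CRETModel, sample: tuple,
            sq: SqueezedSinogram) -> ProjectionPlan:
        i, center, s = sample
        key = (i, center, s)
        if key not in self._plans:
            roi = ROISpec(center, ds.patch_extent, ds.out_resolution, binning=s)
            self._plans[key] = ProjectionPlan(sq, roi.grid)
        return self._plans[key]


def _step1_forward_backward(model: CRETModel, sq: SqueezedSinogram,
                            plan: ProjectionPlan, target_hu: np.ndarray):
    """One L1 step through encode -> channel-match -> back-project; returns
    (loss, encoder-grad trigger, dgamma)."""
    feats, cache = encode_with_cache(sq, model.encoder)
    zst = channel_match(feats, model.gamma, model.basis)
    recon_mu = plan.apply(sq, zst)
    recon_hu = mu_to_hu(recon_mu, model.mu_water)
    loss, dhu = l1_loss(recon_hu, target_hu)
    dmu = dhu * (1000.0 / model.mu_water)
    gz = plan.vjp_zstar(dmu, model.basis)
    dfeat, dgamma = channel_match_backward(gz, feats, model.gamma)
    model.encoder.backward(dfeat, cache)
    return loss, dgamma


def train_step1(
    dataset: SinogramDataset,
    cfg: TrainConfig,
    spec: EncoderSpec = EncoderSpec(),
    basis: BasisConfig = BasisConfig(5),
    checkpoint_path=None,
    log=None,
) -> Tuple[CRETModel, List[dict]]:
    """Train encoder + channel matching (step 1); returns (model, history).

    Per iteration a (phantom, ROI center, binning scale) triple is sampled,
    the squeezed (optionally unfolded) sinogram is reconstructed through the
    decoder-augmented back-projection, and the L1 error against the
    ground-truth HU patch is minimized with Adam.  Aborts on non-finite loss.
    """
    model = CRETModel.create(spec, basis=basis)
    rng = np.random.default_rng(cfg.seed)
    params = model.encoder.parameters() + [model.gamma]
    opt = Adam(params, lr=cfg.lr)
    cache = _PlanCache()
    samples = dataset.samples()
    history: List[dict] = []
    for epoch in range(cfg.epochs):
        opt.lr = cfg.lr_at(epoch)
        losses = []
        for _ in range(cfg.iters_per_epoch):
            grad_acc = None
            batch_loss = 0.0
            for _ in range(cfg.batch_size):
                i, center, s = samples[int(rng.integers(len(samples)))]
                roi = ROISpec(center, dataset.patch_extent,
                              dataset.out_resolution, binning=s)
                sq = model.squeeze_for(dataset.filtered[(i, s)], roi)
                plan = cache.get(dataset, model, (i, center, s), sq)
                target = gt_patch(dataset.phantoms[i], roi)
                loss, dgamma = _step1_forward_backward(model, sq, plan, target)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch} (phantom {i}, s={s}); "
                        "check sinogram conditioning and learning rate"
                    )
                batch_loss += loss
                g = model.encoder.gradients() + [dgamma]
                if grad_acc is None:
                    grad_acc = [x.copy() for x in g]
                else:
                    for a, x in zip(grad_acc, g):
                        a += x
            for a in grad_acc:
                a /= cfg.batch_size
            opt.step(grad_acc)
            losses.append(batch_loss / cfg.batch_size)
        rec = {"epoch": epoch, "lr": opt.lr, "loss": float(np.mean(losses)),
               "first_iter_loss": float(losses[0])}
        history.append(rec)
        if log is not None:
            log(rec)
        if checkpoint_path is not None:
            model.save(checkpoint_path)
    return model, history


def train_step2_restorator(
    model: CRETModel,
    dataset: SinogramDataset,
    cfg: TrainConfig,
    log=None,
) -> Tuple[Restorator, List[dict]]:
    """Train the plug-and-play restorator on (step-1 output, GT) pairs with
    the step-1 weights frozen; the trained restorator is attached to the
    model and also returned (it stays independently applicable)."""
    rest = Restorator(seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(rest.parameters(), lr=cfg.lr)
    samples = dataset.samples()
    # step-1 outputs are fixed: precompute per sample lazily
    step1_out: Dict[tuple, np.ndarray] = {}
    targets: Dict[tuple, np.ndarray] = {}
    history: List[dict] = []
    for epoch in range(cfg.epochs):
        opt.lr = cfg.lr_at(epoch)
        losses = []
        for _ in range(cfg.iters_per_epoch):
            grad_acc = None
            batch_loss = 0.0
            for _ in range(cfg.batch_size):
                key = samples[int(rng.integers(len(samples)))]
                i, center, s = key
                if key not in step1_out:
                    roi = ROISpec(center, dataset.patch_extent,
                                  dataset.out_resolution, binning=s)
                    step1_out[key] = model.reconstruct(
                        dataset.filtered[(i, s)], roi).data / _HU_NORM
                    targets[key] = gt_patch(dataset.phantoms[i], roi) / _HU_NORM
                y, cch = rest.forward(step1_out[key][None])
                loss, dy = l1_loss(y, targets[key][None])
                if not np.isfinite(loss):
                    raise RuntimeError("non-finite restorator loss")
                rest.backward(dy, cch)
                batch_loss += loss
                g = rest.gradients()
                if grad_acc is None:
                    grad_acc = [x.copy() for x in g]
                else:
                    for a, x in zip(grad_acc, g):
                        a += x
            for a in grad_acc:
                a /= cfg.batch_size
            opt.step(grad_acc)
            losses.append(batch_loss / cfg.batch_size)
        rec = {"epoch": epoch, "lr": opt.lr, "loss": float(np.mean(losses))}
        history.append(rec)
        if log is not None:
            log(rec)
    model.restorator = rest
    return rest, history
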
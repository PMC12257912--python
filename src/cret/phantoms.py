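"""Synthetic phantoms, lesions, and the sinogram degradation chain.

Everything downstream (FBP, squeezing, the decoder, training) is exercised on
data produced here: ellipse phantoms in Hounsfield units, additive Gaussian
lesions, fan-beam forward projection (see :mod:`cret.projector`), Poisson
noise at a configurable incident photon count, and detector binning.

Phantoms are piecewise-constant sums of ellipses, so every line integral has
a closed form (:func:`project_ellipses_analytic`) that serves as an
independent oracle for the numeric ray-driven projector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .geometry import FanBeamGeometry, GridSpec, Sinogram, STAGE_RAW

__all__ = [
    "Ellipse",
    "Phantom",
    "LesionSpec",
    "make_phantom",
    "insert_lesion",
    "hu_to_mu",
    "mu_to_hu",
    "add_poisson_noise",
    "bin_detector",
    "project_ellipses_analytic",
    "SHEPP_LOGAN_ELLIPSES",
    "AIR_HU",
    "MU_WATER",
]

AIR_HU = -1000.0
#: default linear attenuation of water, 1/mm (~0.2 /cm at diagnostic energies)
MU_WATER = 0.02

# Modified Shepp-Logan head phantom (Toft's variant): additive gray levels on
# the unit disc as (level, semi_a, semi_b, x0, y0, angle_deg).
SHEPP_LOGAN_ELLIPSES: Tuple[Tuple[float, float, float, float, float, float], ...] = (
    (1.00, 0.6900, 0.9200, 0.00, 0.0000, 0.0),
    (-0.80, 0.6624, 0.8740, 0.00, -0.0184, 0.0),
    (-0.20, 0.1100, 0.3100, 0.22, 0.0000, -18.0),
    (-0.20, 0.1600, 0.4100, -0.22, 0.0000, 18.0),
    (0.10, 0.2100, 0.2500, 0.00, 0.3500, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, 0.1000, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, -0.1000, 0.0),
    (0.10, 0.0460, 0.0230, -0.08, -0.6050, 0.0),
    (0.10, 0.0230, 0.0230, 0.00, -0.6060, 0.0),
    (0.10, 0.0230, 0.0460, 0.06, -0.6050, 0.0),
)

#: HU span assigned to one unit of Shepp-Logan gray level (air -1000 -> bone +1000)
SHEPP_LOGAN_HU_SCALE = 2000.0


@dataclass(frozen=True)
class Ellipse:
    """One additive ellipse: world-mm center/axes, angle in radians, HU delta."""

    center: Tuple[float, float]
    semi_axes: Tuple[float, float]
    angle: float
    hu_delta: float


@dataclass
class Phantom:
    """Square HU image plus the analytic ellipse description it was built from."""

    grid_size: int
    pixel_spacing: float
    values: np.ndarray
    ellipses: List[Ellipse] = field(default_factory=list)
    lesions: list = field(default_factory=list)
    seed: int = 0
    kind: str = "custom"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid_size, self.grid_size):
            raise ValueError("phantom values must be a square grid_size array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("phantom contains non-finite values")

    @property
    def grid(self) -> GridSpec:
        return GridSpec.centered(self.grid_size, self.pixel_spacing)

    @property
    def extent(self) -> float:
        """Physical side length, mm."""
        return self.grid_size * self.pixel_spacing


@dataclass(frozen=True)
class LesionSpec:
    """Additive Gaussian lesion: world-mm center, sigma in ground-truth pixel
    units, peak amplitude in HU."""

    center: Tuple[float, float]
    sigma: float = 0.75
    peak: float = 100.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("lesion sigma must be positive")
        if not np.isfinite(self.peak):
            raise ValueError("lesion peak must be finite")


def _rasterize_ellipses(ellipses: Sequence[Ellipse], grid: GridSpec) -> np.ndarray:
    """Additive HU image of ellipse indicators on ``grid`` (air background)."""
    X, Y = grid.pixel_centers()
    out = np.full(grid.shape, AIR_HU, dtype=float)
    for e in ellipses:
        dx = X - e.center[0]
        dy = Y - e.center[1]
        c, s = np.cos(e.angle), np.sin(e.angle)
        xr = c * dx + s * dy
        yr = -s * dx + c * dy
        inside = (xr / e.semi_axes[0]) ** 2 + (yr / e.semi_axes[1]) ** 2 <= 1.0
        out[inside] += e.hu_delta
    return out


def _shepp_logan_ellipses(half_extent_mm: float) -> List[Ellipse]:
    out = []
    for level, a, b, x0, y0, ang in SHEPP_LOGAN_ELLIPSES:
        out.append(
            Ellipse(
                center=(x0 * half_extent_mm, y0 * half_extent_mm),
                semi_axes=(a * half_extent_mm, b * half_extent_mm),
                angle=np.deg2rad(ang),
                hu_delta=level * SHEPP_LOGAN_HU_SCALE,
            )
        )
    return out


def _random_ellipses(rng: np.random.Generator, half_extent_mm: float) -> List[Ellipse]:
    """A water-equivalent body ellipse plus 3-8 internal structures."""
    body_a = half_extent_mm * rng.uniform(0.70, 0.90)
    body_b = half_extent_mm * rng.uniform(0.70, 0.90)
    ellipses = [
        Ellipse(center=(0.0, 0.0), semi_axes=(body_a, body_b),
                angle=rng.uniform(0, np.pi), hu_delta=1000.0)  # air -> ~water
    ]
    for _ in range(int(rng.integers(3, 9))):
        a = half_extent_mm * rng.uniform(0.05, 0.30)
        b = half_extent_mm * rng.uniform(0.05, 0.30)
        # keep the structure well inside the body ellipse
        r = rng.uniform(0.0, 0.55) * min(body_a, body_b)
        theta = rng.uniform(0, 2 * np.pi)
        ellipses.append(
            Ellipse(
                center=(r * np.cos(theta), r * np.sin(theta)),
                semi_axes=(a, b),
                angle=rng.uniform(0, np.pi),
                hu_delta=float(rng.uniform(-300.0, 500.0)),
            )
        )
    return ellipses


def make_phantom(kind: str, grid_size: int, pixel_spacing: float, seed: int = 0) -> Phantom:
    """Build a deterministic ellipse phantom in HU.

    Parameters
    ----------
    kind : {"shepp_logan", "random_ellipses"}
        ``shepp_logan`` evaluates the published ellipse-parameter table scaled
        to the grid; ``random_ellipses`` draws a seeded body-plus-structures
        phantom used as synthetic training material.
    grid_size : int
        Pixels per side (>= 16).
    pixel_spacing : float
        Pixel size, mm.
    seed : int
        Seed for ``random_ellipses`` (ignored for ``shepp_logan``).
    """
    if grid_size < 16:
        raise ValueError("grid_size must be at least 16")
    half = grid_size * pixel_spacing / 2.0
    if kind == "shepp_logan":
        ellipses = _shepp_logan_ellipses(half)
    elif kind == "random_ellipses":
        rng = np.random.default_rng(seed)
        ellipses = _random_ellipses(rng, half)
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")
    grid = GridSpec.centered(grid_size, pixel_spacing)
    values = _rasterize_ellipses(ellipses, grid)
    return Phantom(grid_size, pixel_spacing, values, ellipses, seed=seed, kind=kind)


def insert_lesion(phantom: Phantom, lesion: LesionSpec) -> Phantom:
    """Add a truncated Gaussian bump; pixels farther than 6 sigma are untouched.

    sigma is measured in pixels of the phantom grid; when the lesion center
    coincides with a pixel center that pixel increases by exactly ``peak``.
    """
    half = phantom.extent / 2.0
    cx, cy = lesion.center
    if abs(cx) > half or abs(cy) > half:
        raise ValueError(f"lesion center {lesion.center} outside phantom grid")
    X, Y = phantom.grid.pixel_centers()
    # radius in pixel units of the ground-truth grid
    r2 = ((X - cx) ** 2 + (Y - cy) ** 2) / phantom.pixel_spacing**2
    bump = lesion.peak * np.exp(-r2 / (2.0 * lesion.sigma**2))
    bump[r2 > (6.0 * lesion.sigma) ** 2] = 0.0
    return Phantom(
        phantom.grid_size,
        phantom.pixel_spacing,
        phantom.values + bump,
        list(phantom.ellipses),
        lesions=phantom.lesions + [lesion],
        seed=phantom.seed,
        kind=phantom.kind,
    )


def hu_to_mu(values_hu: np.ndarray, mu_water: float = MU_WATER) -> np.ndarray:
    """HU -> linear attenuation, mu = mu_water*(HU/1000 + 1), clipped at 0."""
    if not mu_water > 0:
        raise ValueError("mu_water must be positive")
    return np.clip(mu_water * (np.asarray(values_hu, dtype=float) / 1000.0 + 1.0), 0.0, None)


def mu_to_hu(values_mu: np.ndarray, mu_water: float = MU_WATER) -> np.ndarray:
    """Inverse of :func:`hu_to_mu` (no clipping)."""
    return 1000.0 * (np.asarray(values_mu, dtype=float) / mu_water - 1.0)


def add_poisson_noise(sinogram: Sinogram, photons_i0: float = 1.0e6, seed: int = 0) -> Sinogram:
    """Quantum noise on line integrals: counts ~ Poisson(I0*exp(-p)).

    Returns p' = -ln(max(counts, 1)/I0).  Zero counts are clipped to one
    photon before the log (recorded in metadata).  Deterministic given seed.
    """
    sinogram.require_stage(STAGE_RAW)
    p = sinogram.data
    if np.any(p < 0):
        raise ValueError("line integrals must be non-negative before noise injection")
    if not photons_i0 > 0:
        raise ValueError("photons_i0 must be positive")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(photons_i0 * np.exp(-p)).astype(float)
    noisy = -np.log(np.maximum(counts, 1.0) / photons_i0)
    out = Sinogram(noisy, sinogram.geometry, stage=STAGE_RAW, binning=sinogram.binning,
                   meta=dict(sinogram.meta))
    out.meta.update(noise_model="poisson", photons_i0=float(photons_i0),
                    noise_seed=int(seed), zero_count_clip=1)
    return out


def bin_detector(sinogram: Sinogram, s: int) -> Sinogram:
    """Average groups of ``s`` adjacent detector cells (pitch scales by s).

    The arithmetic-mean convention keeps line-integral magnitudes invariant
    under binning; binning composes (s1 then s2 == s1*s2).
    """
    s = int(s)
    if s < 1:
        raise ValueError("binning scale must be >= 1")
    if s == 1:
        return sinogram
    n, d = sinogram.data.shape
    if d % s != 0:
        raise ValueError(f"detector count {d} not divisible by s={s}")
    binned = sinogram.data.reshape(n, d // s, s).mean(axis=2)
    out = Sinogram(binned, sinogram.geometry.binned(s), stage=sinogram.stage,
                   binning=sinogram.binning * s, meta=dict(sinogram.meta))
    out.meta["binned_by"] = out.meta.get("binned_by", 1) * s
    return out


def project_ellipses_analytic(
    ellipses: Sequence[Ellipse],
    geometry: FanBeamGeometry,
    mu_water: float = MU_WATER,
    include_background: bool = False,
) -> Sinogram:
    """Closed-form fan-beam line integrals of an ellipse phantom (mu units).

    Each ellipse contributes ``delta_mu * chord`` where the chord length comes
    from the ray/ellipse quadratic.  HU deltas convert to attenuation deltas
    via ``mu_water/1000`` per HU.  The air background (which has mu = 0 under
    :data:`AIR_HU`) integrates to zero unless ``include_background``.
    """
    if include_background:
        raise NotImplementedError("air background carries zero attenuation")
    betas = geometry.view_angles
    src = geometry.source_position(betas)  # (N, 2)
    w_hat = np.stack([np.sin(betas), -np.cos(betas)], axis=-1)  # toward iso
    u_hat = np.stack([np.cos(betas), np.sin(betas)], axis=-1)
    u = geometry.detector_offsets()  # (D,)
    # ray direction source -> detector cell, normalized: (N, D, 2)
    det = (src[:, None, :] + geometry.source_to_det * w_hat[:, None, :]
           + u[None, :, None] * u_hat[:, None, :])
    d = det - src[:, None, :]
    d /= np.linalg.norm(d, axis=-1, keepdims=True)
    p = np.zeros((geometry.n_views, geometry.n_detectors))
    for e in ellipses:
        mu_delta = e.hu_delta * mu_water / 1000.0
        c, s = np.cos(e.angle), np.sin(e.angle)
        rot = np.array([[c, s], [-s, c]])
        inv_ax = np.array([1.0 / e.semi_axes[0], 1.0 / e.semi_axes[1]])
        # transform ray into the ellipse's unit-circle frame
        p0 = (src - np.asarray(e.center)) @ rot.T * inv_ax  # (N, 2)
        dd = d @ rot.T * inv_ax  # (N, D, 2)
        a = np.sum(dd * dd, axis=-1)
        b = 2.0 * np.sum(p0[:, None, :] * dd, axis=-1)
        cc = np.sum(p0 * p0, axis=-1)[:, None] - 1.0
        disc = b * b - 4.0 * a * cc
        hit = disc > 0
        chord = np.zeros_like(a)
        chord[hit] = np.sqrt(disc[hit]) / a[hit]  # |t2 - t1| for unit |d| rays
        p += mu_delta * chord
    return Sinogram(p, geometry, stage=STAGE_RAW)
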
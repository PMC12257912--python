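"""Sinogram squeezing and unfolding for region-of-interest reconstruction.

Only a narrow, view-dependent band of the sinogram contributes to a given
ROI.  Squeezing extracts that band: the detector index of the ray through
the ROI center is located per view (a closed-form fan-beam point
projection), the detector axis is zero-padded, and a window of fixed width
``d`` centered on the rounded index is copied out, yielding a rectangular
``N x d`` array with exact, invertible coordinate bookkeeping.

Unfolding stacks the 3x3 neighborhood of every sinogram sample as nine
channels *before* squeezing, so that local context straddling the window
edge survives; contracting the nine channels with a 1x1 kernel is then
equivalent to a 3x3 convolution on the original sinogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .geometry import FanBeamGeometry, GridSpec, Sinogram, STAGE_FILTERED

__all__ = [
    "ROISpec",
    "UnfoldedSinogram",
    "SqueezedSinogram",
    "roi_center_index",
    "unfold",
    "squeeze",
    "map_ray_to_squeezed",
    "min_window_width",
    "default_squeeze_params",
]


@dataclass(frozen=True)
class ROISpec:
    """Square ROI: world-mm center, physical side length, output pixel count,
    and the detector binning scale the sinogram carries."""

    center: tuple
    patch_extent: float
    out_resolution: int
    binning: int = 1

    def __post_init__(self) -> None:
        if self.out_resolution < 1:
            raise ValueError("out_resolution must be >= 1")
        if self.patch_extent <= 0:
            raise ValueError("patch_extent must be positive")

    @property
    def grid(self) -> GridSpec:
        """Output reconstruction grid over the patch (pixel centers span the
        patch with spacing extent / out_resolution)."""
        spacing = self.patch_extent / self.out_resolution
        return GridSpec.centered(self.out_resolution, spacing, center=self.center)


@dataclass
class UnfoldedSinogram:
    """Filtered sinogram with its 3x3 neighborhoods stacked as 9 channels.

    Channel ``c = 3*(i+1) + (j+1)`` holds the sinogram shifted by ``(i, j)``,
    i over views, j over detectors, zero-filled at the borders; channel 4 is
    the sinogram itself.
    """

    data: np.ndarray  # (N, D, 9)
    base: Sinogram

    @property
    def geometry(self) -> FanBeamGeometry:
        return self.base.geometry


def roi_center_index(roi: ROISpec, geometry: FanBeamGeometry) -> np.ndarray:
    """Continuous detector index of the ray through the ROI center, per view.

    Closed-form fan-beam point projection; the trajectory is a smooth,
    2*pi-periodic curve across views.
    """
    cx, cy = roi.center
    if np.hypot(cx, cy) > geometry.fov_radius:
        raise ValueError("ROI center outside the scanner field of view")
    betas = geometry.view_angles
    sx = -geometry.source_to_iso * np.sin(betas)
    sy = geometry.source_to_iso * np.cos(betas)
    vx, vy = cx - sx, cy - sy
    t_w = vx * np.sin(betas) - vy * np.cos(betas)
    if np.any(t_w <= 0):
        raise ValueError("ROI center lies behind the source for some view")
    t_u = vx * np.cos(betas) + vy * np.sin(betas)
    u = geometry.source_to_det * t_u / t_w
    return u / geometry.det_pitch + (geometry.n_detectors - 1) / 2.0


def unfold(z: Sinogram) -> UnfoldedSinogram:
    """Stack the 3x3 neighborhood of each filtered-sinogram sample as 9
    channels (zero-filled borders)."""
    z.require_stage(STAGE_FILTERED)
    a = z.data
    n, d = a.shape
    out = np.zeros((n, d, 9), dtype=a.dtype)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            c = 3 * (di + 1) + (dj + 1)
            src_r = slice(max(di, 0), n + min(di, 0))
            dst_r = slice(max(-di, 0), n + min(-di, 0))
            src_c = slice(max(dj, 0), d + min(dj, 0))
            dst_c = slice(max(-dj, 0), d + min(-dj, 0))
            out[dst_r, dst_c, c] = a[src_r, src_c]
    return UnfoldedSinogram(out, z)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.copysign(np.floor(np.abs(x) + 0.5), x)


@dataclass
class SqueezedSinogram:
    """ROI-aligned sinogram window: ``N x d`` (``N x d x 9`` when unfolded).

    ``window_start[i]`` is the original detector index of squeezed column 0
    in view i, so column ``j`` corresponds to original index
    ``window_start[i] + j`` and the rounded ROI-center index sits at column
    ``d // 2``.  The map is exact: values are copied, never resampled.
    """

    data: np.ndarray
    center_index: np.ndarray  # (N,) continuous detector index of the ROI center
    window_start: np.ndarray  # (N,) int, original detector index of column 0
    d: int
    pad: int
    unfolded: bool
    geometry: FanBeamGeometry
    binning: int = 1
    meta: dict = field(default_factory=dict)

    @property
    def n_views(self) -> int:
        return self.data.shape[0]

    @property
    def z(self) -> np.ndarray:
        """The filtered-sinogram channel (center channel when unfolded)."""
        return self.data[..., 4] if self.unfolded else self.data

    def to_columns(self, k: np.ndarray, view: int) -> np.ndarray:
        """Continuous original detector index -> continuous squeezed column."""
        return k - self.window_start[view]

    def to_original(self, col: np.ndarray, view: int) -> np.ndarray:
        return col + self.window_start[view]


def squeeze(
    z: Union[Sinogram, UnfoldedSinogram],
    center_index: np.ndarray,
    d: int,
    pad: int,
) -> SqueezedSinogram:
    """Extract the width-``d`` window centered on the rounded ROI-center index.

    The detector axis is zero-padded by ``pad`` on both sides first, so
    windows overhanging the physical detector read zeros.  Copy semantics:
    unsqueezing reproduces the original values at covered indices exactly.
    """
    if d % 2 != 0:
        raise ValueError("window width d must be even")
    if pad < d // 2:
        raise ValueError("pad must be at least d/2")
    if isinstance(z, UnfoldedSinogram):
        arr, base, unfolded = z.data, z.base, True
    else:
        z.require_stage(STAGE_FILTERED)
        arr, base, unfolded = z.data, z, False
    n, D = arr.shape[:2]
    center_index = np.asarray(center_index, dtype=float)
    if center_index.shape != (n,) or not np.all(np.isfinite(center_index)):
        raise ValueError("center_index must be a finite per-view array")
    c = _round_half_away(center_index).astype(int)
    start = c - d // 2
    if np.any(start + pad < 0) or np.any(start + d - 1 + pad > D + 2 * pad - 1):
        raise ValueError("squeeze window exceeds the padded detector range; increase pad")
    pad_spec = ((0, 0), (pad, pad)) + ((0, 0),) * (arr.ndim - 2)
    padded = np.pad(arr, pad_spec)
    rows = np.arange(n)[:, None]
    cols = (start[:, None] + np.arange(d)[None, :]) + pad
    out = padded[rows, cols]
    return SqueezedSinogram(
        data=out,
        center_index=center_index,
        window_start=start,
        d=d,
        pad=pad,
        unfolded=unfolded,
        geometry=base.geometry,
        binning=base.binning,
        meta=dict(base.meta),
    )


def map_ray_to_squeezed(x_iq: np.ndarray, view: int, sq: SqueezedSinogram) -> np.ndarray:
    """Continuous detector index -> squeezed column coordinate for one view.

    Affine shift that preserves the fractional part; raises if any
    coordinate falls outside the window (both interpolation neighbors must
    exist), which signals that ``d`` is too small for the requested ROI.
    """
    col = np.asarray(x_iq, dtype=float) - sq.window_start[view]
    if np.any(np.floor(col) < 0) or np.any(np.floor(col) + 1 > sq.d - 1):
        raise ValueError(
            f"ray outside squeeze window in view {view}: insufficient d={sq.d}"
        )
    return col


def min_window_width(roi: ROISpec, geometry: FanBeamGeometry) -> int:
    """Smallest even ``d`` that keeps every ray of the ROI inside the window.

    Projects the four patch corners (the extremes of the convex patch) in
    every view and takes the worst deviation from the rounded center index,
    plus one cell on each side for the interpolation neighbor.
    """
    from .fbp import view_detector_coords  # local import to avoid a cycle

    cx, cy = roi.center
    half = roi.patch_extent / 2.0
    corners_x = np.array([cx - half, cx - half, cx + half, cx + half])
    corners_y = np.array([cy - half, cy + half, cy - half, cy + half])
    ci = roi_center_index(roi, geometry)
    worst = 0.0
    for i, beta in enumerate(geometry.view_angles):
        k, _ = view_detector_coords(geometry, beta, corners_x, corners_y)
        c = float(_round_half_away(np.array([ci[i]]))[0])
        worst = max(worst, float(np.max(np.abs(k - c))))
    d = 2 * (int(np.ceil(worst)) + 1)
    return d + (d % 2)


def default_squeeze_params(s: int, d0: int = 64, pad0: int = 256) -> tuple:
    """Protocol defaults: window width 64/s and padding 256/s at binning s."""
    if d0 % s or pad0 % s:
        raise ValueError("binning scale must divide the base squeeze parameters")
    return d0 // s, pad0 // s
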
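"""Classical fan-beam filtered back-projection chain.

The reconstruction ``y = A^T C W_cos p`` is split into its three operators:
cosine weighting ``W_cos``, the band-limited ramp filter ``C`` (Ram-Lak, FFT
evaluated with zero-padding), and linearly interpolating back-projection
``A^T`` with the fan-beam magnification weight 1/L^2 (L = source-to-pixel
distance).  Stage bookkeeping on :class:`~cret.geometry.Sinogram` enforces
the order raw -> cos_weighted -> filtered.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sp_fft

from .geometry import (
    FanBeamGeometry,
    GridSpec,
    ReconImage,
    Sinogram,
    STAGE_RAW,
    STAGE_WEIGHTED,
    STAGE_FILTERED,
)

__all__ = ["cosine_weight", "ramp_filter", "backproject_fbp", "fbp_reconstruct",
            "view_detector_coords"]


def cosine_weight(sino: Sinogram) -> Sinogram:
    """Multiply each sample by cos of its fan angle (flat detector:
    ``SDD / sqrt(SDD^2 + u^2)``)."""
    sino.require_stage(STAGE_RAW)
    g = sino.geometry
    u = g.detector_offsets()
    w = g.source_to_det / np.sqrt(g.source_to_det**2 + u**2)
    return sino.advanced(sino.data * w[None, :], STAGE_WEIGHTED)


def _ramlak_kernel(n: int, delta: float) -> np.ndarray:
    """Discrete band-limited ramp: h[0]=1/(4 d^2), h[k]=-1/(pi k d)^2 odd k."""
    k = np.arange(-(n // 2), n - n // 2)
    h = np.zeros(n)
    h[k == 0] = 1.0 / (4.0 * delta**2)
    odd = (k % 2) != 0
    h[odd] = -1.0 / (np.pi * k[odd] * delta) ** 2
    return np.roll(h, -(n // 2))  # wrap so h[0] sits at index 0


def ramp_filter(sino: Sinogram, window: str = "ramlak") -> Sinogram:
    """Per-view ramp filtering (the ``C`` operator); output is ``z``.

    The kernel spacing is the detector pitch demagnified to the isocenter
    and each view is zero-padded to the next power of two >= 2D before the
    FFT so circular wrap-around is suppressed.  ``window`` selects an extra
    frequency apodization: ``ramlak`` (none) or ``hann``.
    """
    sino.require_stage(STAGE_WEIGHTED)
    g = sino.geometry
    d_iso = g.iso_pitch
    D = g.n_detectors
    pad = 1 << int(np.ceil(np.log2(2 * D)))
    H = sp_fft.rfft(_ramlak_kernel(pad, d_iso))
    if window == "hann":
        f = np.linspace(0.0, 1.0, H.size)
        H = H * 0.5 * (1.0 + np.cos(np.pi * f))
    elif window != "ramlak":
        raise ValueError(f"unknown filter window {window!r}")
    Z = sp_fft.rfft(sino.data, n=pad, axis=1)
    filtered = sp_fft.irfft(Z * H[None, :], n=pad, axis=1)[:, :D] * d_iso
    return sino.advanced(filtered, STAGE_FILTERED, filter_window=window)


def view_detector_coords(
    geometry: FanBeamGeometry, beta: float, X: np.ndarray, Y: np.ndarray
) -> tuple:
    """Project world points onto the detector of one view.

    Returns ``(k, L2)``: the continuous 0-based detector index where the ray
    from the source through each point meets the detector, and the squared
    source-to-point distance.  Shared by the plain and the decoder-augmented
    back-projection paths so both sample identical ray coordinates.
    """
    g = geometry
    sin_b, cos_b = np.sin(beta), np.cos(beta)
    sx, sy = -g.source_to_iso * sin_b, g.source_to_iso * cos_b
    vx = X - sx
    vy = Y - sy
    t_w = vx * sin_b - vy * cos_b  # along the central ray (source -> iso)
    t_u = vx * cos_b + vy * sin_b  # along the detector axis
    with np.errstate(divide="ignore", invalid="ignore"):
        u = g.source_to_det * t_u / t_w
    k = u / g.det_pitch + (g.n_detectors - 1) / 2.0
    L2 = vx * vx + vy * vy
    return k, L2


def backproject_fbp(z: Sinogram, grid: GridSpec) -> ReconImage:
    """Linearly interpolating fan-beam back-projection of a filtered sinogram.

    For every pixel and view the filtered sinogram is sampled at the
    projected detector coordinate with cross-weighted linear interpolation
    (the sample *nearer* the ray gets the larger weight), scaled by
    ``SID^2 / L^2`` and the angular increment 2*pi/N.  Rays falling outside
    the detector contribute zero; the per-pixel count of such views is kept
    in ``meta['uncovered_views']``.
    """
    z.require_stage(STAGE_FILTERED)
    g = z.geometry
    X, Y = grid.pixel_centers()
    acc = np.zeros(grid.shape)
    uncovered = np.zeros(grid.shape, dtype=int)
    dbeta = g.angular_range / g.n_views
    # the 1/2 compensates double coverage: a full scan measures every line twice
    scale = 0.5 * dbeta * g.source_to_iso**2
    for i, beta in enumerate(g.view_angles):
        k, L2 = view_detector_coords(g, beta, X, Y)
        i0 = np.floor(k).astype(int)
        frac = k - i0
        valid = (i0 >= 0) & (i0 + 1 <= g.n_detectors - 1)
        uncovered += ~valid
        i0c = np.clip(i0, 0, g.n_detectors - 2)
        row = z.data[i]
        val = (1.0 - frac) * row[i0c] + frac * row[i0c + 1]
        acc += np.where(valid, scale / L2 * val, 0.0)
    return ReconImage(acc, grid, meta={"uncovered_views": uncovered,
                                       "binning": z.binning})


def fbp_reconstruct(p: Sinogram, grid: GridSpec, window: str = "ramlak") -> ReconImage:
    """Convenience: raw line integrals -> weighted -> filtered -> image."""
    return backproject_fbp(ramp_filter(cosine_weight(p), window=window), grid)
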
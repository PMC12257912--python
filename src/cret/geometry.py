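"""Fan-beam scan geometry and the core array containers.

Conventions (used everywhere in the package):

* World coordinates: isocenter at the origin, x to the right, y up, units mm.
* View angle ``beta``: azimuth of the x-ray source, counter-clockwise from +y,
  so the source sits at ``SID * (-sin(beta), cos(beta))``.
* Detector: flat, equidistant sampling, perpendicular to the central ray at
  distance ``SDD`` from the source.  Sample centers at
  ``u_k = (k - (D - 1) / 2) * pitch`` along the detector axis
  ``(cos(beta), sin(beta))``, ``k = 0 .. D-1``.
* Images: row-major 2D arrays, pixel (0, 0) top-left; ``origin`` is the world
  position of the center of pixel (0, 0); rows run toward -y, columns +x.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "FanBeamGeometry",
    "Sinogram",
    "GridSpec",
    "ReconImage",
    "STAGE_RAW",
    "STAGE_WEIGHTED",
    "STAGE_FILTERED",
]

STAGE_RAW = "raw"
STAGE_WEIGHTED = "cos_weighted"
STAGE_FILTERED = "filtered"

_STAGE_ORDER = {STAGE_RAW: 0, STAGE_WEIGHTED: 1, STAGE_FILTERED: 2}


@dataclass(frozen=True)
class FanBeamGeometry:
    """Flat-panel (equidistant) fan-beam scanner description.

    Parameters
    ----------
    source_to_iso : float
        Source-to-isocenter distance (SID), mm.
    source_to_det : float
        Source-to-detector distance (SDD), mm.
    n_detectors : int
        Number of detector cells D.
    det_pitch : float
        Detector cell pitch, mm (at the detector, not at isocenter).
    n_views : int
        Number of projection views N over ``angular_range``.
    angular_range : float
        Total scan arc in radians (default full 2*pi).
    """

    source_to_iso: float
    source_to_det: float
    n_detectors: int
    det_pitch: float
    n_views: int
    angular_range: float = 2.0 * np.pi
    detector_shape: str = "flat_equidistant"

    def __post_init__(self) -> None:
        if not (self.source_to_det > self.source_to_iso > 0):
            raise ValueError("require source_to_det > source_to_iso > 0")
        if self.n_views < 1:
            raise ValueError("need at least one view")
        if self.n_detectors < 1 or self.det_pitch <= 0:
            raise ValueError("invalid detector description")
        if self.detector_shape != "flat_equidistant":
            raise ValueError(f"unsupported detector shape {self.detector_shape!r}")

    @property
    def view_angles(self) -> np.ndarray:
        """Source azimuths beta_i, radians; endpoint excluded (2*pi wraps)."""
        return np.arange(self.n_views) * (self.angular_range / self.n_views)

    @property
    def iso_pitch(self) -> float:
        """Detector pitch demagnified to the isocenter plane."""
        return self.det_pitch * self.source_to_iso / self.source_to_det

    @property
    def fov_radius(self) -> float:
        """Radius of the circle seen by every view (mm)."""
        u_max = (self.n_detectors - 1) / 2.0 * self.det_pitch
        gamma_max = np.arctan2(u_max, self.source_to_det)
        return float(self.source_to_iso * np.sin(gamma_max))

    def source_position(self, beta: np.ndarray) -> np.ndarray:
        """Source world position(s) for azimuth(s) beta -> (..., 2)."""
        beta = np.asarray(beta, dtype=float)
        return np.stack(
            [-self.source_to_iso * np.sin(beta), self.source_to_iso * np.cos(beta)],
            axis=-1,
        )

    def detector_offsets(self) -> np.ndarray:
        """Signed offsets u_k of the detector cell centers, mm."""
        k = np.arange(self.n_detectors, dtype=float)
        return (k - (self.n_detectors - 1) / 2.0) * self.det_pitch

    def binned(self, s: int) -> "FanBeamGeometry":
        """Geometry after averaging groups of ``s`` adjacent detector cells."""
        if self.n_detectors % s != 0:
            raise ValueError(
                f"detector count {self.n_detectors} not divisible by binning scale {s}"
            )
        return replace(self, n_detectors=self.n_detectors // s, det_pitch=self.det_pitch * s)


@dataclass
class Sinogram:
    """N x D array of line integrals ``p`` (or filtered values ``z``).

    ``stage`` tracks progress through the FBP chain and may only move forward
    (raw -> cos_weighted -> filtered); the reconstruction operators enforce it.
    ``binning`` records the detector binning scale s relative to the native
    detector (1 = unbinned).
    """

    data: np.ndarray
    geometry: FanBeamGeometry
    stage: str = STAGE_RAW
    binning: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("sinogram data must be 2D (views x detectors)")
        if self.data.shape != (self.geometry.n_views, self.geometry.n_detectors):
            raise ValueError(
                f"sinogram shape {self.data.shape} does not match geometry "
                f"({self.geometry.n_views}, {self.geometry.n_detectors})"
            )
        if self.stage not in _STAGE_ORDER:
            raise ValueError(f"unknown stage {self.stage!r}")

    def advanced(self, data: np.ndarray, stage: str, **meta) -> "Sinogram":
        """New sinogram at a later stage; rejects backward transitions."""
        if _STAGE_ORDER[stage] <= _STAGE_ORDER[self.stage]:
            raise ValueError(f"stage may only advance (at {self.stage!r}, got {stage!r})")
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return Sinogram(data, self.geometry, stage=stage, binning=self.binning, meta=new_meta)

    def require_stage(self, stage: str) -> None:
        if self.stage != stage:
            raise ValueError(f"operation requires stage {stage!r}, sinogram is {self.stage!r}")


@dataclass(frozen=True)
class GridSpec:
    """Reconstruction grid: ``shape`` (rows, cols), ``spacing`` mm, ``origin``
    = world position of pixel (0, 0) center."""

    shape: tuple
    spacing: float
    origin: tuple

    @classmethod
    def centered(cls, n: int, spacing: float, center=(0.0, 0.0)) -> "GridSpec":
        """Square n x n grid whose center coincides with ``center`` (mm)."""
        half = (n - 1) / 2.0 * spacing
        return cls(
            shape=(n, n),
            spacing=float(spacing),
            origin=(float(center[0]) - half, float(center[1]) + half),
        )

    def pixel_centers(self) -> tuple:
        """World coordinates of all pixel centers -> (X, Y) each (H, W)."""
        h, w = self.shape
        x = self.origin[0] + np.arange(w) * self.spacing
        y = self.origin[1] - np.arange(h) * self.spacing
        return np.meshgrid(x, y)


@dataclass
class ReconImage:
    """Reconstructed attenuation / HU image with its grid provenance."""

    data: np.ndarray
    grid: GridSpec
    roi: Optional[object] = None  # ROISpec provenance when reconstructed from a window
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != tuple(self.grid.shape):
            raise ValueError("image shape does not match grid spec")
        if self.grid.spacing <= 0:
            raise ValueError("pixel spacing must be positive")

    @property
    def spacing(self) -> float:
        return self.grid.spacing
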
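"""On-disk containers: HDF5 sinograms, TIFF images with JSON sidecars."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .geometry import FanBeamGeometry, GridSpec, ReconImage, Sinogram
from .phantoms import Ellipse, Phantom
from .squeeze import SqueezedSinogram

__all__ = [
    "save_sinogram", "load_sinogram",
    "save_squeezed", "load_squeezed",
    "save_phantom", "load_phantom",
    "save_image",
]

_GEOM_FIELDS = ["source_to_iso", "source_to_det", "n_detectors", "det_pitch",
                "n_views", "angular_range", "detector_shape"]


def _write_geometry(obj, g: FanBeamGeometry) -> None:
    for f in _GEOM_FIELDS:
        obj.attrs["geom_" + f] = getattr(g, f)


def _read_geometry(obj) -> FanBeamGeometry:
    kw = {f: obj.attrs["geom_" + f] for f in _GEOM_FIELDS}
    kw["n_detectors"] = int(kw["n_detectors"])
    kw["n_views"] = int(kw["n_views"])
    kw["detector_shape"] = str(kw["detector_shape"])
    return FanBeamGeometry(**kw)


def save_sinogram(path, sino: Sinogram) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("p", data=sino.data)
        _write_geometry(f, sino.geometry)
        f.attrs["stage"] = sino.stage
        f.attrs["binning"] = sino.binning
        f.attrs["meta"] = json.dumps(
            {k: v for k, v in sino.meta.items() if np.isscalar(v) or isinstance(v, str)})


def load_sinogram(path) -> Sinogram:
    with h5py.File(path, "r") as f:
        sino = Sinogram(f["p"][...], _read_geometry(f), stage=str(f.attrs["stage"]),
                        binning=int(f.attrs["binning"]),
                        meta=json.loads(f.attrs.get("meta", "{}")))
    return sino


def save_squeezed(path, sq: SqueezedSinogram) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=sq.data)
        f.create_dataset("center_index", data=sq.center_index)
        f.create_dataset("window_start", data=sq.window_start)
        _write_geometry(f, sq.geometry)
        f.attrs["d"] = sq.d
        f.attrs["pad"] = sq.pad
        f.attrs["unfolded"] = sq.unfolded
        f.attrs["binning"] = sq.binning


def load_squeezed(path) -> SqueezedSinogram:
    with h5py.File(path, "r") as f:
        return SqueezedSinogram(
            data=f["data"][...],
            center_index=f["center_index"][...],
            window_start=f["window_start"][...].astype(int),
            d=int(f.attrs["d"]),
            pad=int(f.attrs["pad"]),
            unfolded=bool(f.attrs["unfolded"]),
            geometry=_read_geometry(f),
            binning=int(f.attrs["binning"]),
        )


def save_phantom(path, phantom: Phantom) -> None:
    """float32 TIFF plus a JSON sidecar with the analytic description."""
    path = Path(path)
    tifffile.imwrite(path, phantom.values.astype(np.float32))
    sidecar = {
        "grid_size": phantom.grid_size,
        "pixel_spacing": phantom.pixel_spacing,
        "seed": phantom.seed,
        "kind": phantom.kind,
        "ellipses": [dataclasses.asdict(e) for e in phantom.ellipses],
        "lesions": [dataclasses.asdict(l) for l in phantom.lesions],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_phantom(path) -> Phantom:
    path = Path(path)
    values = tifffile.imread(path).astype(float)
    side = json.loads(path.with_suffix(".json").read_text())
    ellipses = [Ellipse(tuple(e["center"]), tuple(e["semi_axes"]), e["angle"],
                        e["hu_delta"]) for e in side["ellipses"]]
    from .phantoms import LesionSpec
    lesions = [LesionSpec(tuple(l["center"]), l["sigma"], l["peak"])
               for l in side["lesions"]]
    return Phantom(side["grid_size"], side["pixel_spacing"], values, ellipses,
                   lesions=lesions, seed=side["seed"], kind=side["kind"])


def save_image(path, image: ReconImage) -> None:
    path = Path(path)
    tifffile.imwrite(path, image.data.astype(np.float32))
    side = {"spacing": image.grid.spacing, "origin": list(image.grid.origin),
            "shape": list(image.grid.shape)}
    if image.roi is not None:
        side["roi"] = {"center": list(image.roi.center),
                       "patch_extent": image.roi.patch_extent,
                       "out_resolution": image.roi.out_resolution,
                       "binning": image.roi.binning}
    path.with_suffix(".json").write_text(json.dumps(side, indent=2))
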
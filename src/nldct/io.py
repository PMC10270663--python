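"""Float-TIFF persistence with JSON sidecars.

Images and sinograms travel as single-channel 32-bit float TIFFs;
acquisition stacks as multi-page 32-bit float TIFFs.  Each file gets a
``<name>.json`` sidecar carrying the geometry, units, seeds and any other
metadata needed to reload it unambiguously.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile

from .phantom import AttenuationImage
from .projection import FanBeamGeometry, Sinogram
from .acquisition import AcquisitionStack

__all__ = [
    "geometry_to_dict",
    "geometry_from_dict",
    "geometry_hash",
    "save_image",
    "load_image",
    "save_sinogram",
    "load_sinogram",
    "save_stack",
    "load_stack",
]


def geometry_to_dict(geom: FanBeamGeometry) -> dict:
    return dataclasses.asdict(geom)


def geometry_from_dict(d: dict) -> FanBeamGeometry:
    return FanBeamGeometry(**d)


def geometry_hash(geom: FanBeamGeometry) -> str:
    payload = json.dumps(geometry_to_dict(geom), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write(path: Path, array: np.ndarray, meta: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # grayscale planes; 3-D arrays are stored as multi-page stacks
    tifffile.imwrite(path, np.asarray(array, dtype=np.float32), photometric="minisblack")
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def _read(path: Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    array = tifffile.imread(path).astype(np.float64)
    sidecar = _sidecar(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return array, meta


def save_image(path, image: AttenuationImage, **extra) -> None:
    _write(
        Path(path),
        image.values,
        {"kind": "image", "pixel_size": image.pixel_size, "units": image.units, **extra},
    )


def load_image(path) -> AttenuationImage:
    array, meta = _read(Path(path))
    return AttenuationImage(array, float(meta.get("pixel_size", 1.0)), meta.get("units", "mu"))


def save_sinogram(path, sino: Sinogram, **extra) -> None:
    _write(
        Path(path),
        sino.values,
        {"kind": "sinogram", "geometry": geometry_to_dict(sino.geometry), **extra},
    )


def load_sinogram(path) -> Sinogram:
    array, meta = _read(Path(path))
    return Sinogram(array, geometry_from_dict(meta["geometry"]))


def save_stack(path, stack: AcquisitionStack, **extra) -> None:
    meta = {
        "kind": "acquisition_stack",
        "geometry": geometry_to_dict(stack.geometry),
        "geometry_hash": geometry_hash(stack.geometry),
        "incident_intensity": stack.incident_intensity,
        "cnr_target": stack.cnr_target,
        "master_seed": stack.master_seed,
        "seeds": list(stack.seeds),
        **extra,
    }
    _write(Path(path), stack.sinograms, meta)


def load_stack(path) -> AcquisitionStack:
    array, meta = _read(Path(path))
    if array.ndim == 2:
        array = array[None]
    return AcquisitionStack(
        sinograms=array,
        geometry=geometry_from_dict(meta["geometry"]),
        incident_intensity=float(meta["incident_intensity"]),
        master_seed=int(meta["master_seed"]),
        seeds=tuple(meta["seeds"]),
        cnr_target=meta.get("cnr_target"),
    )
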
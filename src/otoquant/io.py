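"""Reading calibrated TIFF images with JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .types import ImageStack3D, NucleusMask, VesselField


def _sidecar(path: Path) -> dict:
    sc = path.with_suffix(".json")
    if not sc.exists():
        raise FileNotFoundError(f"calibration sidecar {sc} not found")
    return json.loads(sc.read_text())


def read_stack(path: str | Path) -> ImageStack3D:
    """Read a channel-major multi-page TIFF and its calibration sidecar."""
    path = Path(path)
    meta = _sidecar(path)
    data = tifffile.imread(path)
    return ImageStack3D(
        np.asarray(data, dtype=np.float64),
        tuple(meta["voxel_size_um"]),
        list(meta.get("channel_names", [])),
    )


def read_mask(path: str | Path, nucleus_id: int = 0) -> NucleusMask:
    """Read a label-image TIFF as one nucleus mask (label > 0)."""
    data = tifffile.imread(Path(path))
    return NucleusMask(np.asarray(data) > 0, nucleus_id=nucleus_id)


def read_field(path: str | Path, pixel_size_um: float | None = None) -> VesselField:
    """Read a 2D field TIFF; pixel size from the sidecar unless overridden."""
    path = Path(path)
    if pixel_size_um is None:
        meta = _sidecar(path)
        pixel_size_um = float(meta["pixel_size_um"])
        names = list(meta.get("channel_names", []))
    else:
        names = []
    data = tifffile.imread(path)
    return VesselField(np.asarray(data, dtype=np.float64), pixel_size_um, names)
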
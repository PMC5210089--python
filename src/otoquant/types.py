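"""Shared in-memory containers for calibrated images and masks.

Coordinates are 0-based ``(z, y, x)`` (or ``(y, x)`` in 2D), referring to
voxel/pixel centers.  Physical sizes are in micrometers.  Volumes and areas
are voxel/pixel counts times the voxel/pixel volume — no surface meshing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageStack3D:
    """Calibrated multi-channel 3D image stack.

    Parameters
    ----------
    intensities
        Array of shape ``(n_channels, nz, ny, nx)``, non-negative.
    voxel_size_um
        Physical voxel size ``(dz, dy, dx)`` in μm, all strictly positive.
    channel_names
        One name per channel.
    """

    intensities: np.ndarray
    voxel_size_um: tuple[float, float, float]
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim == 3:
            self.intensities = self.intensities[np.newaxis]
        if self.intensities.ndim != 4:
            raise ValueError("intensities must be (channels, z, y, x)")
        if any(s < 1 for s in self.intensities.shape[1:]):
            raise ValueError("all spatial dimensions must be >= 1")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be strictly positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.intensities.shape[0])]
        if len(self.channel_names) != self.intensities.shape[0]:
            raise ValueError("one channel name per channel required")

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size_um
        return dz * dy * dx

    def channel(self, name_or_index: str | int) -> np.ndarray:
        """Return one channel's 3D intensity array."""
        if isinstance(name_or_index, str):
            name_or_index = self.channel_names.index(name_or_index)
        return self.intensities[name_or_index]


@dataclass
class NucleusMask:
    """Boolean voxel membership of a single nucleus within one stack."""

    mask: np.ndarray
    nucleus_id: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("nucleus mask must be 3D")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class VesselField:
    """Calibrated 2D immunofluorescence field.

    ``intensities`` has shape ``(n_channels, ny, nx)``; ``pixel_size_um``
    is the isotropic pixel pitch.
    """

    intensities: np.ndarray
    pixel_size_um: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim == 2:
            self.intensities = self.intensities[np.newaxis]
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be (channels, y, x)")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be strictly positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.intensities.shape[0])]

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2

    @property
    def field_area_um2(self) -> float:
        _, ny, nx = self.intensities.shape
        return ny * nx * self.pixel_area_um2

    def channel(self, name_or_index: str | int) -> np.ndarray:
        if isinstance(name_or_index, str):
            name_or_index = self.channel_names.index(name_or_index)
        return self.intensities[name_or_index]
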
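"""Core image containers: acquisition metadata and multichannel z-stacks.

Conventions used throughout the package:

* voxel arrays are indexed ``(z, y, x)`` (channel last for multichannel),
  0-based, half-open ranges;
* physical lengths are always micrometres;
* in-plane orientation angles are degrees in ``[-90, 90)`` measured from the
  lattice X axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: channel semantics per acquisition mode.  In nonlinear (two-photon) mode the
#: green channel carries cytoplasm autofluorescence plus scaffold signal and
#: nuclei appear dark; the blue channel is SHG from fibrillar collagen I.  In
#: confocal mode nuclei are stained and appear bright in the red channel.
MODE_CHANNELS = {
    "nonlinear": ("green", "blue"),
    "confocal": ("green", "red"),
}


@dataclass(frozen=True)
class AcquisitionSpec:
    """Acquisition geometry and detector model for (synthetic) stacks.

    Parameters
    ----------
    voxel_size:
        ``(z, y, x)`` voxel edges in µm.  Default 1.0 µm axial spacing and
        0.5 µm lateral sampling.
    shape:
        field size in voxels, ``(z, y, x)``.
    mode:
        ``"nonlinear"`` or ``"confocal"`` (see :data:`MODE_CHANNELS`).
    psf_sigma:
        Gaussian PSF sigma ``(lateral, axial)`` in µm.
    photon_scale:
        expected photon count for unit signal; 0 disables shot noise.
    read_noise:
        Gaussian read-noise sigma in counts; 0 disables it.
    bit_depth:
        output quantization, 8 or 16 bit.
    """

    voxel_size: tuple[float, float, float] = (1.0, 0.5, 0.5)
    shape: tuple[int, int, int] = (40, 256, 256)
    mode: str = "nonlinear"
    psf_sigma: tuple[float, float] = (0.3, 1.0)
    photon_scale: float = 200.0
    read_noise: float = 2.0
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if any(s <= 0 for s in self.shape):
            raise ValueError("field shape must be positive")
        if self.mode not in MODE_CHANNELS:
            raise ValueError(f"unknown mode {self.mode!r}")
        if min(self.psf_sigma) < 0:
            raise ValueError("PSF sigma must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit depth must be 8 or 16")

    @property
    def channels(self) -> tuple[str, ...]:
        return MODE_CHANNELS[self.mode]

    @property
    def field_size_um(self) -> tuple[float, float, float]:
        """Physical field extent (z, y, x) in µm."""
        return tuple(s * v for s, v in zip(self.shape, self.voxel_size))


@dataclass
class ImageStack:
    """A 3D multichannel stack with voxel size and channel semantics.

    ``data`` has shape ``(z, y, x, channel)``; single-channel volumes may be
    stored as ``(z, y, x)`` and are promoted on construction.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    mode: str = "nonlinear"
    channel_names: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:
            self.data = self.data[..., None]
        if self.data.ndim != 4:
            raise ValueError("stack data must be (z, y, x[, channel])")
        if np.issubdtype(self.data.dtype, np.floating) and self.data.size:
            if float(np.nanmin(self.data)) < 0:
                raise ValueError("stack intensities must be non-negative")
        if self.channel_names is None:
            names = MODE_CHANNELS.get(self.mode, ())
            if len(names) == self.data.shape[-1]:
                self.channel_names = tuple(names)
            else:
                self.channel_names = tuple(
                    f"ch{i}" for i in range(self.data.shape[-1])
                )
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.data.shape[-1]:
            raise ValueError("channel_names must match the channel axis")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_channels(self) -> int:
        return self.data.shape[-1]

    def channel(self, name: str) -> np.ndarray:
        """Return the 3D volume for a named channel."""
        try:
            i = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.data[..., i]

    def with_data(self, data: np.ndarray) -> "ImageStack":
        """Copy of this stack with new voxel data, metadata unchanged."""
        return replace(self, data=data)
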
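"""OME-TIFF stack I/O and flat-config handling."""

from __future__ import annotations

import pathlib

import numpy as np
import tifffile
import yaml

from .stack import ImageStack


def save_stack(path, stack: ImageStack) -> None:
    """Write a stack as OME-TIFF with voxel size and channel metadata."""
    data = np.moveaxis(stack.data, -1, 1)  # (z, c, y, x)
    vz, vy, vx = stack.voxel_size
    tifffile.imwrite(
        path, data,
        ome=True,
        metadata={
            "axes": "ZCYX",
            "PhysicalSizeZ": vz, "PhysicalSizeY": vy, "PhysicalSizeX": vx,
            "PhysicalSizeZUnit": "µm", "PhysicalSizeYUnit": "µm",
            "PhysicalSizeXUnit": "µm",
            "Channel": {"Name": list(stack.channel_names)},
        },
    )


def load_stack(path, mode: str | None = None) -> ImageStack:
    """Read an OME-TIFF written by :func:`save_stack` back into a stack."""
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
        meta = tf.ome_metadata or ""
    if axes == "ZCYX":
        data = np.moveaxis(data, 1, -1)
    elif axes == "CZYX":
        data = np.moveaxis(data, 0, -1)
    elif axes == "ZYX":
        data = data[..., None]
    elif axes == "YX":
        data = data[None, ..., None]
    else:
        raise ValueError(f"unsupported axis order {axes!r}")
    import re

    def phys(name, default=1.0):
        m = re.search(rf'{name}="([0-9.eE+-]+)"', meta)
        return float(m.group(1)) if m else default

    voxel = (phys("PhysicalSizeZ"), phys("PhysicalSizeY"),
             phys("PhysicalSizeX"))
    names = re.findall(r'Channel[^>]*Name="([^"]+)"', meta) or None
    if mode is None:
        mode = "confocal" if names and "red" in names else "nonlinear"
    return ImageStack(data=data, voxel_size=voxel, mode=mode,
                      channel_names=tuple(names) if names else None)


def load_config(path) -> dict:
    """Read a flat key: value config file (YAML syntax)."""
    text = pathlib.Path(path).read_text()
    cfg = yaml.safe_load(text) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a flat mapping")
    return cfg


def save_config(path, config: dict) -> None:
    pathlib.Path(path).write_text(
        yaml.safe_dump(config, sort_keys=True, default_flow_style=False))
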
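"""Parametric model of the implanted lattice scaffold.

The scaffold is a rectangular lattice of square pores (default
49.6 × 49.6 × 20 µm³) reinforced by thicker pillars with an X-shaped cross
section placed on every second lattice node (every 100 µm), giving 36 pillars
on the default 10 × 10-pore grid.  The module also carries the fabrication
pixel–micron conversion of the laser-writing system and provides
rasterization and registration so the lattice can serve as the reference
frame for region-stratified measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .stack import AcquisitionSpec, ImageStack


class LatticeNotFoundError(RuntimeError):
    """Raised when template registration finds no credible lattice."""


@dataclass(frozen=True)
class FabricationConversion:
    """Per-axis pixel–micron conversion of the fabrication system.

    The factors are dimensioned so that ``realized_length_um = pixels * f``;
    the anisotropy (f_x != f_y) stems from the rectangular spatial light
    modulator screen of the writing setup.
    """

    f_x: float = 1.6
    f_y: float = 1.7

    def __post_init__(self) -> None:
        if self.f_x <= 0 or self.f_y <= 0:
            raise ValueError("conversion factors must be positive")

    def factor(self, axis: str) -> float:
        axis = axis.upper()
        if axis == "X":
            return self.f_x
        if axis == "Y":
            return self.f_y
        raise ValueError(f"axis must be 'X' or 'Y', got {axis!r}")


@dataclass(frozen=True)
class ScaffoldGeometry:
    """Lattice geometry: pore grid, reinforcement pillars, element sizes.

    ``pillar_interval`` is the node stride between pillars (2 = every two
    pores = every ~100 µm); pillar nodes include the grid border, so a
    10 × 10-pore grid with interval 2 carries (10/2+1)² = 36 pillars.
    """

    pore_pitch: float = 49.6
    pore_count_x: int = 10
    pore_count_y: int = 10
    pore_height: float = 20.0
    pillar_interval: int = 2
    pillar_side: float = 5.0
    pillar_arm_thickness: float = 1.5
    grid_element_thickness: float = 1.5

    def __post_init__(self) -> None:
        if self.pore_pitch <= 0:
            raise ValueError("pore pitch must be positive")
        if self.pillar_interval < 1:
            raise ValueError("pillar interval must be >= 1")
        if self.pore_count_x < 1 or self.pore_count_y < 1:
            raise ValueError("pore counts must be >= 1")

    @property
    def footprint_um(self) -> tuple[float, float]:
        """(y, x) extent of the lattice footprint in µm."""
        return (self.pore_count_y * self.pore_pitch,
                self.pore_count_x * self.pore_pitch)

    def pillar_nodes_um(self) -> np.ndarray:
        """(n, 2) array of pillar node (y, x) positions in µm, lattice frame."""
        ys = np.arange(0, self.pore_count_y + 1, self.pillar_interval)
        xs = np.arange(0, self.pore_count_x + 1, self.pillar_interval)
        yy, xx = np.meshgrid(ys * self.pore_pitch, xs * self.pore_pitch,
                             indexing="ij")
        return np.column_stack([yy.ravel(), xx.ravel()])


@dataclass(frozen=True)
class RigidTransform2D:
    """In-plane lattice pose: voxel shift, rotation and a confidence score."""

    shift_y: float
    shift_x: float
    rotation: float = 0.0
    score: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")


def count_pillars(geom: ScaffoldGeometry) -> int:
    """Number of pillar nodes of the lattice (border nodes included)."""
    return (
        (geom.pore_count_x // geom.pillar_interval + 1)
        * (geom.pore_count_y // geom.pillar_interval + 1)
    )


def distance_to_pixels(distance_um: float, axis: str,
                       conv: FabricationConversion | None = None) -> int:
    """Integer pixel count realizing a target distance on the writing system.

    Follows the fabrication worked example: the pixel count is
    ``floor(d / f_axis)`` (50 µm → 31 px along X, 29 px along Y).
    """
    if conv is None:
        conv = FabricationConversion()
    if distance_um < 0:
        raise ValueError("distance must be non-negative")
    return int(math.floor(distance_um / conv.factor(axis)))


def realized_length(pixels: int, axis: str,
                    conv: FabricationConversion | None = None) -> float:
    """Physical length (µm) realized by an integer pixel count."""
    if conv is None:
        conv = FabricationConversion()
    if pixels < 0:
        raise ValueError("pixel count must be non-negative")
    return pixels * conv.factor(axis)


def _x_shape_mask(yy: np.ndarray, xx: np.ndarray, cy: float, cx: float,
                  side: float, arm: float) -> np.ndarray:
    """X-shaped pillar cross section: two diagonal arms within a square."""
    u = (xx - cx) + (yy - cy)   # diagonal coordinates (unnormalized)
    v = (xx - cx) - (yy - cy)
    half_arm = arm / 2 * math.sqrt(2.0)  # arm half-thickness in diagonal coords
    in_square = (np.abs(xx - cx) <= side / 2) & (np.abs(yy - cy) <= side / 2)
    return in_square & ((np.abs(u) <= half_arm) | (np.abs(v) <= half_arm))


def rasterize_scaffold(geom: ScaffoldGeometry, acq: AcquisitionSpec,
                       origin_um: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Binary (z, y, x) mask of the lattice grid elements and pillars.

    ``origin_um`` places the lattice (y, x) corner within the field; the grid
    occupies z levels up to the pore height.  Grid elements are rendered as
    walls of ``grid_element_thickness`` along the lattice lines; pillars as
    X-shaped cross sections extruded over the full height.
    """
    vz, vy, vx = acq.voxel_size
    nz, ny, nx = acq.shape
    field_y, field_x = ny * vy, nx * vx
    if field_y < geom.pore_pitch or field_x < geom.pore_pitch:
        raise ValueError("field of view smaller than one pore")

    mask2d = np.zeros((ny, nx), dtype=bool)
    oy, ox = origin_um
    yy = (np.arange(ny) + 0.5) * vy
    xx = (np.arange(nx) + 0.5) * vx
    t = geom.grid_element_thickness
    if t > 0:
        for j in range(geom.pore_count_y + 1):
            line = oy + j * geom.pore_pitch
            rows = np.abs(yy - line) <= t / 2
            cols = (xx >= ox - t / 2) & (xx <= ox + geom.pore_count_x
                                         * geom.pore_pitch + t / 2)
            mask2d[np.ix_(rows, cols)] = True
        for i in range(geom.pore_count_x + 1):
            line = ox + i * geom.pore_pitch
            cols = np.abs(xx - line) <= t / 2
            rows = (yy >= oy - t / 2) & (yy <= oy + geom.pore_count_y
                                         * geom.pore_pitch + t / 2)
            mask2d[np.ix_(rows, cols)] = True
    if geom.pillar_arm_thickness > 0 and geom.pillar_side > 0:
        yy2, xx2 = np.meshgrid(yy, xx, indexing="ij")
        for cy, cx in geom.pillar_nodes_um():
            mask2d |= _x_shape_mask(yy2, xx2, oy + cy, ox + cx,
                                    geom.pillar_side,
                                    geom.pillar_arm_thickness)

    n_levels = min(nz, max(1, int(round(geom.pore_height / vz))))
    mask = np.zeros((nz, ny, nx), dtype=bool)
    mask[:n_levels] = mask2d
    return mask


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two equally shaped images, in [-1, 1]."""
    a = a.astype(float).ravel()
    b = b.astype(float).ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.dot(a, b) / denom)


def register_lattice(stack: ImageStack, geom: ScaffoldGeometry,
                     channel: str = "green",
                     max_rotation: float = 0.0,
                     rotation_step: float = 1.0,
                     score_floor: float = 0.2) -> RigidTransform2D:
    """Locate the lattice in a scaffold-bearing channel.

    A rasterized template at the stack voxel size is matched against the
    maximum-intensity projection by FFT cross-correlation; the returned score
    is the normalized correlation at the recovered pose.  Rotation search
    (±``max_rotation`` in ``rotation_step`` degree increments) is off by
    default.  Raises :class:`LatticeNotFoundError` when the best score falls
    below ``score_floor``.
    """
    from skimage.transform import rotate as _rotate

    proj = stack.channel(channel).max(axis=0).astype(float)
    template_stack = rasterize_scaffold(geom, AcquisitionSpec(
        voxel_size=stack.voxel_size,
        shape=(1, *proj.shape),
        mode=stack.mode if stack.mode in ("nonlinear", "confocal")
        else "nonlinear",
        photon_scale=0.0, read_noise=0.0))
    template0 = template_stack.max(axis=0).astype(float)

    angles = [0.0]
    if max_rotation > 0:
        angles = list(np.arange(-max_rotation, max_rotation + rotation_step / 2,
                                rotation_step))
    best = None
    p = proj - proj.mean()
    for angle in angles:
        tmpl = template0 if angle == 0 else _rotate(
            template0, angle, preserve_range=True, order=1)
        t = tmpl - tmpl.mean()
        corr = np.fft.irfft2(
            np.fft.rfft2(p) * np.conj(np.fft.rfft2(t)), s=p.shape)
        iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
        sy = iy if iy <= p.shape[0] // 2 else iy - p.shape[0]
        sx = ix if ix <= p.shape[1] // 2 else ix - p.shape[1]
        shifted = np.roll(tmpl, (sy, sx), axis=(0, 1))
        score = max(0.0, _ncc(proj, shifted))
        if best is None or score > best[0]:
            best = (score, sy, sx, angle)
    score, sy, sx, angle = best
    if score < score_floor:
        raise LatticeNotFoundError(
            f"no lattice found: best correlation {score:.3f} < {score_floor}")
    return RigidTransform2D(shift_y=float(sy), shift_x=float(sx),
                            rotation=float(angle), score=min(1.0, score))


#: region labels written by :func:`region_masks`
REGION_INSIDE, REGION_NEAR, REGION_FAR = 1, 2, 3


def region_masks(transform: RigidTransform2D, geom: ScaffoldGeometry,
                 shape_yx: tuple[int, int],
                 voxel_size_yx: tuple[float, float],
                 margin_um: float = 200.0) -> np.ndarray:
    """Partition the in-plane field into inside / near / far regions.

    ``inside`` is the lattice footprint (shifted by the transform), ``near``
    the annulus within ``margin_um`` of it, ``far`` the remainder.  Returns an
    int array over (y, x) with labels ``REGION_INSIDE``/``NEAR``/``FAR``; the
    three regions are disjoint and cover the field exactly.
    """
    ny, nx = shape_yx
    vy, vx = voxel_size_yx
    fy, fx = geom.footprint_um
    yy = (np.arange(ny) + 0.5) * vy - transform.shift_y * vy
    xx = (np.arange(nx) + 0.5) * vx - transform.shift_x * vx
    inside = (
        (yy >= 0)[:, None] & (yy <= fy)[:, None]
        & (xx >= 0)[None, :] & (xx <= fx)[None, :]
    )
    labels = np.full((ny, nx), REGION_FAR, dtype=np.int8)
    if margin_um > 0:
        dist = ndimage.distance_transform_edt(~inside, sampling=(vy, vx))
        labels[dist <= margin_um] = REGION_NEAR
    labels[inside] = REGION_INSIDE
    return labels
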
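"""Nuclei segmentation, ellipsoid morphometry, granulocyte classification,
and cell-density estimation.

Nuclei are bright in confocal stacks (nuclear stain, red channel) and dark in
label-free nonlinear stacks (no cytoplasmic autofluorescence inside the
nucleus).  Each segmented nucleus is reduced to the semi-axes A ≤ B ≤ C of
the moment-equivalent solid ellipsoid; granulocytes (bi-/tri-lobed, prolate
nuclei) are flagged when both axial ratios A/C and B/C fall below their
quadrant thresholds.  Densities follow cell number / volume; counts on 2D
histology sections are converted to volumetric densities by ascribing to the
section its thickness plus the average cell size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, segmentation
from skimage.feature import peak_local_max

from .geometry import REGION_FAR, REGION_INSIDE, REGION_NEAR
from .stack import ImageStack


class DegenerateRegionError(ValueError):
    """Voxel set is (near) coplanar; no 3D ellipsoid fit is possible."""


@dataclass(frozen=True)
class QuadrantRule:
    """Granulocyte quadrant rule on the (A/C, B/C) correlation plot.

    A nucleus is classified granulocyte iff A/C < ``t_ac`` and B/C < ``t_bc``
    (strict).  The thresholds are the visual quadrant midlines of the axial
    ratio correlation plot and are configuration, reported with every result.
    """

    t_ac: float = 0.5
    t_bc: float = 0.75

    def __post_init__(self) -> None:
        if not (0 < self.t_ac < 1 and 0 < self.t_bc < 1):
            raise ValueError("thresholds must lie in (0, 1)")


@dataclass
class DensityEstimate:
    """Cell density = count / volume, with per-ROI replicates."""

    count: float
    volume_um3: float
    density: float
    roi_densities: tuple[float, ...] = ()
    mean: float | None = None
    sd: float | None = None
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_nuclei(stack: ImageStack, mode: str | None = None,
                   min_volume_um3: float = 4.0,
                   max_volume_um3: float = 600.0,
                   threshold: float | str = "auto",
                   tissue: np.ndarray | None = None,
                   marker_min_distance_um: float = 2.0,
                   split_volume_um3: float = 200.0) -> np.ndarray:
    """3D-segment nuclei into a label volume.

    ``mode='bright'`` thresholds the nuclear channel directly;
    ``mode='dark'`` inverts the cytoplasm channel within the tissue mask
    (label-free contrast).  Touching nuclei are split by marker-controlled
    watershed on the distance transform, markers being local maxima at least
    ``marker_min_distance_um`` apart (ties resolved at the lowest linear
    voxel index); only connected components larger than ``split_volume_um3``
    (a generous single-nucleus volume) are split, so lobed nuclei are not
    fragmented.  Components outside the volume bounds are discarded.
    """
    if mode is None:
        mode = "bright" if stack.mode == "confocal" else "dark"
    vs = stack.voxel_size
    voxel_vol = float(np.prod(vs))
    if mode == "bright":
        chan = "red" if "red" in stack.channel_names else stack.channel_names[-1]
        vol = stack.channel(chan).astype(float)
        if threshold == "auto":
            if np.ptp(vol) == 0:
                return np.zeros(stack.shape, dtype=np.int32)
            threshold = filters.threshold_otsu(vol)
        binary = vol > threshold
    elif mode == "dark":
        vol = stack.channel("green").astype(float)
        if tissue is None:
            if np.ptp(vol) == 0:
                raise ValueError("no tissue signal in dark mode")
            tissue = vol > filters.threshold_otsu(vol)
            # nuclei are holes in the cytoplasm: close them into the mask
            structure = np.ones((1, 3, 3), dtype=bool)
            tissue = ndimage.binary_closing(
                tissue, structure=structure, iterations=10)
        if not tissue.any():
            raise ValueError("no tissue signal in dark mode")
        inv = vol.max() - vol
        inside = inv[tissue]
        if np.ptp(inside) == 0:
            raise ValueError("no contrast within tissue in dark mode")
        thr = filters.threshold_otsu(inside) if threshold == "auto" \
            else threshold
        binary = (inv > thr) & tissue
    else:
        raise ValueError(f"mode must be 'bright' or 'dark', got {mode!r}")

    if not binary.any():
        return np.zeros(stack.shape, dtype=np.int32)
    # drop specks below the volume floor before the watershed split
    pre = measure.label(binary, connectivity=3)
    sizes = np.bincount(pre.ravel())
    small = np.flatnonzero(sizes < max(1, int(min_volume_um3 / voxel_vol)))
    binary &= ~np.isin(pre, small[small > 0])
    comps = measure.label(binary, connectivity=3)
    comp_vol = np.bincount(comps.ravel()) * voxel_vol
    needs_split = comp_vol > split_volume_um3
    needs_split[0] = False
    split_mask = needs_split[comps]
    if split_mask.any():
        dist = ndimage.distance_transform_edt(binary, sampling=vs)
        min_dist_vox = max(1, int(round(marker_min_distance_um / min(vs))))
        peaks = peak_local_max(dist, min_distance=min_dist_vox,
                               labels=binary & split_mask,
                               exclude_border=False)
        markers = np.zeros(binary.shape, dtype=np.int32)
        for i, p in enumerate(peaks, start=1):
            markers[tuple(p)] = i
        split = segmentation.watershed(-dist, markers,
                                       mask=binary & split_mask)
    else:
        split = np.zeros(binary.shape, dtype=np.int32)
    # small components stay one label each; split ones take watershed labels
    labels = comps.astype(np.int32).copy()
    has_split = split_mask & (split > 0)
    labels[has_split] = split[has_split] + comps.max()
    # volume bounds
    counts = np.bincount(labels.ravel())
    bad = np.flatnonzero(
        (counts * voxel_vol < min_volume_um3)
        | (counts * voxel_vol > max_volume_um3))
    if bad.size:
        drop = np.isin(labels, bad[bad > 0])
        labels = labels.copy()
        labels[drop] = 0
    labels, _, _ = segmentation.relabel_sequential(labels)
    return labels.astype(np.int32)


# ---------------------------------------------------------------------------
# ellipsoid morphometry
# ---------------------------------------------------------------------------

def fit_ellipsoid(voxels: np.ndarray,
                  voxel_size: tuple[float, float, float]
                  ) -> tuple[float, float, float]:
    """Moment-equivalent solid-ellipsoid semi-axes of a voxel set.

    ``voxels`` is an (n, 3) array of (z, y, x) voxel indices or a boolean
    mask.  The semi-axes follow from the eigenvalues λ of the coordinate
    covariance via a = √(5 λ) (uniform solid ellipsoid relation), with the
    per-axis voxel-cell variance h²/12 added so that small regions are not
    biased low.  Returned sorted ascending (A, B, C) in µm.
    """
    voxels = np.asarray(voxels)
    if voxels.ndim == 3:
        voxels = np.argwhere(voxels)
    if voxels.shape[0] < 8:
        raise ValueError("need at least 8 voxels for an ellipsoid fit")
    vs = np.asarray(voxel_size, dtype=float)
    pts = voxels * vs
    raw = np.cov(pts.T, bias=True)
    raw_lam = np.linalg.eigvalsh(raw)
    if raw_lam[0] <= 1e-6 * max(raw_lam[-1], 1e-12):
        raise DegenerateRegionError("voxel set is (near) coplanar")
    lam = np.linalg.eigvalsh(raw + np.diag(vs ** 2 / 12.0))
    axes = np.sqrt(5.0 * lam)
    return tuple(float(a) for a in np.sort(axes))


def axial_ratios(axes: tuple[float, float, float]) -> tuple[float, float]:
    """(A/C, B/C) for sorted semi-axes; both in (0, 1]."""
    a, b, c = axes
    if not (0 < a <= b <= c):
        raise ValueError("axes must satisfy 0 < A <= B <= C")
    return a / c, b / c


def classify_granulocyte(ratios: tuple[float, float],
                         rule: QuadrantRule | None = None) -> bool:
    """True iff both axial ratios fall strictly below the quadrant rule."""
    if rule is None:
        rule = QuadrantRule()
    ac, bc = ratios
    return bool(ac < rule.t_ac and bc < rule.t_bc)


NUCLEUS_RECORD_COLUMNS = ["id", "cz", "cy", "cx", "voxel_count",
                          "volume_um3", "A", "B", "C", "ratio_ac", "ratio_bc",
                          "region", "is_granulocyte"]


def measure_nuclei(labels: np.ndarray,
                   voxel_size: tuple[float, float, float],
                   rule: QuadrantRule | None = None,
                   region_labels: np.ndarray | None = None,
                   vessel_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Per-nucleus records: centroid, ellipsoid axes, ratios, classification.

    ``region_labels`` (in-plane, from the lattice registration) and
    ``vessel_mask`` assign each nucleus a region by its centroid; nuclei in
    the vessel mask are labelled ``'vessel'`` regardless of lattice region.
    Nuclei whose voxel set is degenerate or too small are skipped.
    """
    if rule is None:
        rule = QuadrantRule()
    vs = np.asarray(voxel_size, dtype=float)
    region_names = {REGION_INSIDE: "inside", REGION_NEAR: "near",
                    REGION_FAR: "far"}
    rows = []
    for prop in measure.regionprops(labels):
        coords = prop.coords
        try:
            axes = fit_ellipsoid(coords, voxel_size)
        except ValueError:
            continue
        ratios = axial_ratios(axes)
        cz, cy, cx = prop.centroid * vs
        region = ""
        iy, ix = int(prop.centroid[1]), int(prop.centroid[2])
        if vessel_mask is not None and vessel_mask.any():
            vm = vessel_mask.max(axis=0) if vessel_mask.ndim == 3 \
                else vessel_mask
            if vm[iy, ix]:
                region = "vessel"
        if not region and region_labels is not None:
            region = region_names.get(int(region_labels[iy, ix]), "")
        rows.append([prop.label, cz, cy, cx, int(prop.area),
                     float(prop.area * np.prod(vs)), *axes, *ratios,
                     region, classify_granulocyte(ratios, rule)])
    return pd.DataFrame(rows, columns=NUCLEUS_RECORD_COLUMNS)


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def roi_density(records: pd.DataFrame,
                field_um: tuple[float, float, float],
                roi_size_um: tuple[float, float] = (100.0, 100.0),
                n_roi: int = 6,
                rng: np.random.Generator | int | None = None,
                depth_um: float | None = None) -> DensityEstimate:
    """Cell density from randomly placed ROI columns.

    Each ROI is a ``roi_size_um`` (y, x) column spanning ``depth_um`` (the
    full stack depth by default); nuclei are counted by the centroid-in-ROI
    rule and density = count / (ROI area × depth) per ROI.  Returns the
    per-ROI densities with their mean ± sd.  Deterministic for a fixed seed.
    """
    if n_roi < 1:
        raise ValueError("need at least one ROI")
    fz, fy, fx = field_um
    ry, rx = roi_size_um
    if ry > fy or rx > fx:
        raise ValueError("field too small for the requested ROI size")
    depth = fz if depth_um is None else depth_um
    rng = np.random.default_rng(rng)
    vol = ry * rx * depth
    densities = []
    total = 0
    for _ in range(n_roi):
        oy = rng.uniform(0, fy - ry)
        ox = rng.uniform(0, fx - rx)
        if len(records):
            inroi = ((records.cy >= oy) & (records.cy < oy + ry)
                     & (records.cx >= ox) & (records.cx < ox + rx))
            n = int(inroi.sum())
        else:
            n = 0
        total += n
        densities.append(n / vol)
    densities = tuple(densities)
    return DensityEstimate(
        count=total, volume_um3=n_roi * vol,
        density=total / (n_roi * vol),
        roi_densities=densities,
        mean=float(np.mean(densities)),
        sd=float(np.std(densities, ddof=1)) if n_roi > 1 else 0.0,
        meta={"roi_size_um": roi_size_um, "n_roi": n_roi,
              "depth_um": depth})


def full_field_density(records: pd.DataFrame,
                       field_um: tuple[float, float, float]
                       ) -> DensityEstimate:
    """Density over the whole field (no ROI subsampling)."""
    vol = float(np.prod(field_um))
    n = len(records)
    return DensityEstimate(count=n, volume_um3=vol, density=n / vol)


def section_density(count: float, area_um2: float,
                    section_thickness_um: float = 4.0,
                    mean_cell_size_um: float = 5.0) -> float:
    """Volumetric density from a count on a 2D histology section.

    The section is ascribed an effective thickness of the physical section
    (default 4 µm) plus the average cell size (default 5 µm), since a cell is
    counted whenever any part of it intersects the cut.
    """
    if area_um2 <= 0:
        raise ValueError("area must be positive")
    if section_thickness_um <= 0 or mean_cell_size_um < 0:
        raise ValueError("thicknesses must be positive")
    return count / (area_um2 * (section_thickness_um + mean_cell_size_um))


def stratified_granulocyte_density(records: pd.DataFrame,
                                   region_labels: np.ndarray,
                                   voxel_size_yx: tuple[float, float],
                                   depth_um: float,
                                   vessel_mask: np.ndarray | None = None,
                                   ) -> dict:
    """Granulocyte densities per lattice region, plus pairwise ratios.

    Regions are the inside/near/far partition from the lattice registration;
    the vessel compartment (if a mask is given) is carved out of them.
    Densities are count / (region area × depth); the ratio uncertainties
    propagate Poisson counting errors (sd of n is √n).  Regions or ratios
    without counts are reported as None and flagged.
    """
    if not (region_labels > 0).any():
        raise ValueError("empty region partition")
    vy, vx = voxel_size_yx
    px_area = vy * vx
    gran = records[records.is_granulocyte] if len(records) else records
    flags = []
    out: dict[str, DensityEstimate | None] = {}
    pix_counts = {name: int((region_labels == code).sum())
                  for code, name in ((REGION_INSIDE, "inside"),
                                     (REGION_NEAR, "near"),
                                     (REGION_FAR, "far"))}
    vm2d = None
    if vessel_mask is not None and vessel_mask.size and vessel_mask.any():
        vm2d = vessel_mask.max(axis=0) if vessel_mask.ndim == 3 \
            else vessel_mask
    for name, npix in pix_counts.items():
        if npix == 0:
            out[name] = None
            flags.append(f"empty-region:{name}")
            continue
        volume = npix * px_area * depth_um
        n = int((gran.region == name).sum()) if len(gran) else 0
        out[name] = DensityEstimate(count=n, volume_um3=volume,
                                    density=n / volume)
    if vm2d is not None:
        volume = int(vm2d.sum()) * px_area * depth_um
        n = int((gran.region == "vessel").sum()) if len(gran) else 0
        out["vessel"] = DensityEstimate(count=n, volume_um3=volume,
                                        density=n / volume)
    else:
        out["vessel"] = None
        flags.append("vessel-density-not-available")

    ratios = {}
    names = [n for n in ("inside", "near", "far", "vessel")
             if out.get(n) is not None]
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            da, db = out[a], out[b]
            if db.count == 0 or da.count == 0:
                ratios[f"{a}/{b}"] = None
                flags.append(f"ratio-undefined:{a}/{b}")
                continue
            r = da.density / db.density
            # Poisson counting error propagation
            rel = math.sqrt(1.0 / da.count + 1.0 / db.count)
            ratios[f"{a}/{b}"] = (r, r * rel)
    return {"densities": out, "ratios": ratios, "flags": flags}
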
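"""Nuclei segmentation, ellipsoid fitting, classification and densities."""

import math

import numpy as np
import pandas as pd
import pytest

from lattiscope import (
    ImageStack,
    NucleusPopulationSpec,
    QuadrantRule,
    axial_ratios,
    classify_granulocyte,
    fit_ellipsoid,
    measure_nuclei,
    render_nuclei,
    roi_density,
    sample_nuclei,
    section_density,
    segment_nuclei,
    stratified_granulocyte_density,
)
from lattiscope.geometry import REGION_FAR, REGION_INSIDE, REGION_NEAR
from lattiscope.nuclei import DegenerateRegionError, full_field_density
from lattiscope.synth import NUCLEUS_COLUMNS

from conftest import make_acq


def _voxelize_ellipsoid(axes, voxel, rot=np.eye(3)):
    """Brute-force voxelization oracle: voxel indices inside the ellipsoid."""
    r = max(axes)
    n = int(np.ceil(2 * (r + voxel) / voxel))
    centers = (np.arange(n) + 0.5) * voxel - (r + voxel)
    zz, yy, xx = np.meshgrid(centers, centers, centers, indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1) @ rot
    inside = np.sum((pts / np.asarray(axes)) ** 2, axis=-1) <= 1
    return np.argwhere(inside)


class TestFitEllipsoid:
    def test_sphere(self):
        vox = _voxelize_ellipsoid((3.0, 3.0, 3.0), 0.3)
        axes = fit_ellipsoid(vox, (0.3, 0.3, 0.3))
        for a in axes:
            assert a == pytest.approx(3.0, rel=0.05, abs=0.15)

    def test_axis_aligned_ellipsoid(self):
        vox = _voxelize_ellipsoid((2.0, 3.0, 4.0), 0.3)
        axes = fit_ellipsoid(vox, (0.3, 0.3, 0.3))
        for got, want in zip(axes, (2.0, 3.0, 4.0)):
            assert got == pytest.approx(want, rel=0.05)

    @pytest.mark.parametrize("angle_deg", [20.0, 45.0, 70.0])
    def test_rotation_invariance(self, angle_deg):
        a = math.radians(angle_deg)
        rot = np.array([[1, 0, 0],
                        [0, math.cos(a), -math.sin(a)],
                        [0, math.sin(a), math.cos(a)]])
        base = fit_ellipsoid(_voxelize_ellipsoid((2, 3, 4), 0.3),
                             (0.3, 0.3, 0.3))
        rotated = fit_ellipsoid(_voxelize_ellipsoid((2, 3, 4), 0.3, rot),
                                (0.3, 0.3, 0.3))
        for b, r in zip(base, rotated):
            assert abs(r - b) / b < 0.05

    def test_too_few_voxels_rejected(self):
        with pytest.raises(ValueError):
            fit_ellipsoid(np.zeros((7, 3)), (1, 1, 1))

    def test_coplanar_voxels_flagged(self):
        coords = np.array([[0, y, x] for y in range(5) for x in range(5)])
        with pytest.raises(DegenerateRegionError):
            fit_ellipsoid(coords, (1, 1, 1))


class TestQuadrantRule:
    @pytest.mark.parametrize("axes, expected_ratios", [
        ((3.0, 3.0, 3.0), (1.0, 1.0)),
        ((1.0, 2.0, 4.0), (0.25, 0.5)),
        ((2.0, 3.0, 4.0), (0.5, 0.75)),
    ])
    def test_axial_ratios(self, axes, expected_ratios):
        assert axial_ratios(axes) == pytest.approx(expected_ratios)

    @pytest.mark.parametrize("ratios, expected", [
        ((0.3, 0.5), True),
        ((0.9, 0.95), False),
        ((0.5, 0.75), False),   # boundary is exclusive
        ((0.49, 0.75), False),  # both ratios must fall below
        ((0.5, 0.74), False),
    ])
    def test_classification(self, ratios, expected):
        assert classify_granulocyte(ratios, QuadrantRule()) is expected

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            QuadrantRule(t_ac=1.5)


@pytest.fixture(scope="module")
def scene():
    pop = NucleusPopulationSpec.single(20, (2.3, 3.12, 4.26),
                                       (0.4, 0.5, 0.6))
    acq = make_acq(shape=(60, 200, 200))
    truth = sample_nuclei(pop, acq.field_size_um, 1)
    return truth, acq


class TestSegmentNuclei:
    def test_bright_mode_recovers_all(self, scene):
        truth, acq = scene
        intensity, _ = render_nuclei(truth, acq)
        stack = ImageStack(np.stack([np.zeros(acq.shape), intensity], axis=-1),
                           acq.voxel_size, "confocal")
        labels = segment_nuclei(stack, mode="bright")
        assert labels.max() == 20
        records = measure_nuclei(labels, acq.voxel_size)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(records[["cz", "cy", "cx"]].values).query(
            truth[["cz", "cy", "cx"]].values)
        assert d.max() <= 1.0  # within ~1 voxel of the generating centroid

    def test_dark_mode_recovers_all(self, scene):
        truth, acq = scene
        import dataclasses

        acq_nl = dataclasses.replace(acq, mode="nonlinear")
        intensity, _ = render_nuclei(truth, acq_nl)
        stack = ImageStack(np.stack([intensity, np.zeros(acq.shape)], axis=-1),
                           acq.voxel_size, "nonlinear")
        labels = segment_nuclei(stack, mode="dark")
        assert labels.max() == 20

    def test_empty_field_zero_labels(self):
        acq = make_acq(shape=(10, 64, 64))
        stack = ImageStack(np.zeros((*acq.shape, 2)), acq.voxel_size,
                           "confocal")
        assert segment_nuclei(stack, mode="bright").max() == 0

    def test_sorted_axes_contract_on_pipeline_output(self, scene):
        truth, acq = scene
        intensity, _ = render_nuclei(truth, acq)
        stack = ImageStack(np.stack([np.zeros(acq.shape), intensity], axis=-1),
                           acq.voxel_size, "confocal")
        records = measure_nuclei(segment_nuclei(stack, mode="bright"),
                                 acq.voxel_size)
        assert ((records.A <= records.B) & (records.B <= records.C)).all()
        assert ((records.ratio_ac > 0) & (records.ratio_ac <= 1)).all()


class TestDensities:
    def test_section_density_effective_thickness(self):
        # 10 cells on a 100x100 um2 section: 4 um cut + 5 um cell size
        assert section_density(10, 100 * 100) == pytest.approx(
            10 / (1e4 * 9.0))
        assert section_density(0, 1e4) == 0.0
        assert section_density(10, 1e4, mean_cell_size_um=0.0) \
            == pytest.approx(10 / 4e4)
        with pytest.raises(ValueError):
            section_density(10, 0.0)

    def test_full_field_recovery(self):
        field = (20.0, 300.0, 300.0)
        n = int(2.5e-4 * np.prod(field))
        pop = NucleusPopulationSpec.single(n, (1.0, 1.2, 1.5), (0.3, 0.3, 0.3))
        truth = sample_nuclei(pop, field, 3)
        est = full_field_density(truth, field)
        assert est.density == pytest.approx(2.5e-4, rel=0.10)

    def test_roi_protocol_recovery(self):
        field = (20.0, 300.0, 300.0)
        n = int(2.5e-4 * np.prod(field))
        pop = NucleusPopulationSpec.single(n, (1.0, 1.2, 1.5), (0.3, 0.3, 0.3))
        truth = sample_nuclei(pop, field, 3)
        est = roi_density(truth, field, n_roi=6, rng=3)
        assert est.mean == pytest.approx(2.5e-4, rel=0.20)
        assert len(est.roi_densities) == 6

    def test_roi_placement_deterministic(self):
        truth = pd.DataFrame(columns=NUCLEUS_COLUMNS)
        a = roi_density(truth, (20.0, 300.0, 300.0), rng=5)
        b = roi_density(truth, (20.0, 300.0, 300.0), rng=5)
        assert a.roi_densities == b.roi_densities
        assert a.density == 0.0

    def test_field_too_small_rejected(self):
        with pytest.raises(ValueError):
            roi_density(pd.DataFrame(columns=NUCLEUS_COLUMNS),
                        (20.0, 50.0, 50.0), rng=0)


class TestStratifiedDensity:
    def _records(self, regions_counts):
        rows = []
        i = 0
        for region, (n_gran, n_other) in regions_counts.items():
            for _ in range(n_gran):
                rows.append([i, 0, 0, 0, 100, 50.0, 1, 2, 4, 0.25, 0.5,
                             region, True])
                i += 1
            for _ in range(n_other):
                rows.append([i, 0, 0, 0, 100, 50.0, 3, 3, 3, 1.0, 1.0,
                             region, False])
                i += 1
        from lattiscope.nuclei import NUCLEUS_RECORD_COLUMNS

        return pd.DataFrame(rows, columns=NUCLEUS_RECORD_COLUMNS)

    def _regions(self):
        labels = np.full((100, 100), REGION_FAR, dtype=np.int8)
        labels[:50, :50] = REGION_INSIDE
        labels[:50, 50:] = REGION_NEAR
        return labels

    def test_seeded_ratio_recovered(self):
        rec = self._records({"inside": (10, 5), "near": (30, 5),
                             "far": (5, 5)})
        out = stratified_granulocyte_density(rec, self._regions(),
                                             (1.0, 1.0), depth_um=20.0)
        d = out["densities"]
        # same pixel area for inside and near: density ratio = count ratio
        r, sd = out["ratios"]["inside/near"]
        assert r == pytest.approx(10 / 30, rel=1e-6)
        assert sd > 0
        assert d["far"].density < d["inside"].density

    def test_no_granulocytes_flagged(self):
        rec = self._records({"inside": (0, 5), "near": (0, 5)})
        out = stratified_granulocyte_density(rec, self._regions(),
                                             (1.0, 1.0), depth_um=20.0)
        assert all(d.count == 0 for d in out["densities"].values()
                   if d is not None)
        assert any(f.startswith("ratio-undefined") or
                   f == "vessel-density-not-available" for f in out["flags"])

    def test_missing_vessel_mask_not_available(self):
        rec = self._records({"inside": (2, 2)})
        out = stratified_granulocyte_density(rec, self._regions(),
                                             (1.0, 1.0), depth_um=20.0)
        assert out["densities"]["vessel"] is None
        assert "vessel-density-not-available" in out["flags"]

    def test_empty_partition_rejected(self):
        with pytest.raises(ValueError):
            stratified_granulocyte_density(
                self._records({}), np.zeros((10, 10), dtype=np.int8),
                (1.0, 1.0), depth_um=20.0)
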
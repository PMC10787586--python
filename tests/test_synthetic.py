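"""Generator contracts: truth bookkeeping, rendering geometry, determinism."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from lattiscope import (
    CollagenFieldSpec,
    NucleusPopulationSpec,
    VesselNetworkSpec,
    generate_vessel_network,
    render_collagen,
    render_nuclei,
    render_stack,
    render_vessels,
    sample_nuclei,
)
from lattiscope.synth import DEFAULT_CLASSES, FWHM_FACTOR, NUCLEUS_COLUMNS
from lattiscope.vessels import VesselEdge, VesselGraph

from conftest import make_acq


class TestSampleNuclei:
    pop = NucleusPopulationSpec.single(50, (1.4, 2.2, 2.9), (0.4, 0.4, 0.6))

    def test_axes_sorted_and_counted(self):
        truth = sample_nuclei(self.pop, (40.0, 120.0, 120.0), 0)
        assert len(truth) == 50
        assert (truth.A <= truth.B).all() and (truth.B <= truth.C).all()

    def test_same_seed_identical(self):
        a = sample_nuclei(self.pop, (40.0, 120.0, 120.0), 7)
        b = sample_nuclei(self.pop, (40.0, 120.0, 120.0), 7)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_count_empty(self):
        empty = NucleusPopulationSpec.single(0, (1.4, 2.2, 2.9),
                                             (0.4, 0.4, 0.6))
        assert len(sample_nuclei(empty, (40.0, 120.0, 120.0), 0)) == 0

    def test_no_overlap(self):
        truth = sample_nuclei(self.pop, (40.0, 120.0, 120.0), 3)
        pts = truth[["cz", "cy", "cx"]].values
        r = truth.C.values
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        need = r[:, None] + r[None, :]
        np.fill_diagonal(d, np.inf)
        assert (d >= need - 1e-9).all()

    def test_overcrowded_field_raises(self):
        dense = NucleusPopulationSpec.single(500, (2.3, 3.12, 4.26),
                                             (0.4, 0.5, 0.6))
        with pytest.raises(RuntimeError):
            sample_nuclei(dense, (15.0, 40.0, 40.0), 0)


class TestRenderNuclei:
    def test_sphere_volume_matches_analytic(self):
        truth = pd.DataFrame([[0, "generic", 15.0, 15.0, 15.0, 3.0, 3.0, 3.0,
                               1, 0.6, *np.eye(3).ravel()]],
                             columns=NUCLEUS_COLUMNS)
        acq = make_acq(shape=(60, 60, 60))
        _, labels = render_nuclei(truth, acq)
        vol = (labels == 1).sum() * 0.5 ** 3
        assert vol == pytest.approx(4 / 3 * math.pi * 27, rel=0.05)

    def test_empty_truth_nonlinear_uniform(self):
        acq = make_acq(mode="nonlinear")
        intensity, labels = render_nuclei(
            pd.DataFrame(columns=NUCLEUS_COLUMNS), acq)
        assert labels.max() == 0
        assert (intensity == 1.0).all()

    def test_bilobed_is_single_connected_component(self):
        from scipy import ndimage

        gran = dataclasses.replace(DEFAULT_CLASSES["granulocyte"], count=5)
        acq = make_acq(voxel_size=(0.3, 0.3, 0.3), shape=(100, 300, 300))
        truth = sample_nuclei(NucleusPopulationSpec((gran,)),
                              acq.field_size_um, 1)
        _, labels = render_nuclei(truth, acq)
        for nid in truth.id:
            _, n_comp = ndimage.label(labels == nid + 1)
            assert n_comp == 1

    def test_oversized_nucleus_rejected(self):
        truth = pd.DataFrame([[0, "generic", 10, 10, 10, 30, 30, 31,
                               1, 0.6, *np.eye(3).ravel()]],
                             columns=NUCLEUS_COLUMNS)
        with pytest.raises(ValueError):
            render_nuclei(truth, make_acq())


class TestVesselNetwork:
    def test_truth_bookkeeping_matches_graph(self):
        graph, truth = generate_vessel_network(
            VesselNetworkSpec(), (40.0, 400.0, 400.0), 0)
        assert len(truth) == graph.n_edges == 9
        assert np.allclose(np.sort(truth.length_um.values),
                           np.sort(graph.lengths()))

    def test_unbranched_when_single_branch(self):
        graph, truth = generate_vessel_network(
            VesselNetworkSpec(n_branches=1), (40.0, 300.0, 300.0), 0)
        assert graph.n_edges == 1
        degs = [graph.degree(n) for n in graph.nodes]
        assert sorted(degs) == [1, 1]

    def test_fixed_seed_identical(self):
        a, ta = generate_vessel_network(VesselNetworkSpec(),
                                        (40.0, 400.0, 400.0), 5)
        b, tb = generate_vessel_network(VesselNetworkSpec(),
                                        (40.0, 400.0, 400.0), 5)
        pd.testing.assert_frame_equal(ta, tb)

    def test_zero_branches_empty(self):
        graph, truth = generate_vessel_network(
            VesselNetworkSpec(n_branches=0), (40.0, 300.0, 300.0), 0)
        assert graph.n_edges == 0 and len(truth) == 0


class TestRenderVessels:
    def test_straight_tube_plateau_width(self):
        acq = make_acq(shape=(20, 60, 200))
        g = VesselGraph(nodes={0: np.array([5.0, 15.0, 10.0]),
                               1: np.array([5.0, 15.0, 90.0])})
        g.edges = [VesselEdge(0, 1, np.vstack([g.nodes[0], g.nodes[1]]),
                              diameter=7.2)]
        vol = render_vessels(g, acq)
        profile = vol[10, :, 100]  # mid-tube cross section
        width = profile.sum() * 0.5
        assert width == pytest.approx(7.2, abs=0.5)

    def test_empty_graph_zero_volume(self):
        assert not render_vessels(VesselGraph(), make_acq()).any()

    def test_parallel_tubes_disjoint(self):
        from scipy import ndimage

        acq = make_acq(shape=(20, 120, 200))
        g = VesselGraph()
        for i, y in enumerate((15.0, 45.0)):
            g.nodes[2 * i] = np.array([5.0, y, 10.0])
            g.nodes[2 * i + 1] = np.array([5.0, y, 90.0])
            g.edges.append(VesselEdge(2 * i, 2 * i + 1,
                                      np.vstack([g.nodes[2 * i],
                                                 g.nodes[2 * i + 1]]),
                                      diameter=6.0))
        _, n = ndimage.label(render_vessels(g, acq) > 0)
        assert n == 2


class TestRenderCollagen:
    def test_truth_orientation_spread(self):
        spec = CollagenFieldSpec(n_fibers=500, dispersion_fwhm_deg=25.0)
        _, truth = render_collagen(spec, make_acq(shape=(3, 512, 512)), 0)
        assert len(truth) == 500
        sd = truth.orientation_deg.std()
        assert sd == pytest.approx(25.0 / FWHM_FACTOR, rel=0.10)

    def test_zero_fibers_zero_volume(self):
        vol, truth = render_collagen(CollagenFieldSpec(n_fibers=0),
                                     make_acq(), 0)
        assert not vol.any() and len(truth) == 0

    def test_degenerate_dispersion_single_angle(self):
        spec = CollagenFieldSpec(n_fibers=20, dispersion_fwhm_deg=0.0)
        _, truth = render_collagen(spec, make_acq(shape=(3, 256, 256)), 0)
        assert (truth.orientation_deg == 0.0).all()


class TestRenderStack:
    def test_identity_without_psf_and_noise(self):
        acq = make_acq(mode="nonlinear", shape=(5, 64, 64))
        vol = np.random.default_rng(0).random(acq.shape)
        stack = render_stack(vol, None, None, None, acq)
        assert np.array_equal(stack.channel("green"), vol)

    def test_same_seed_bit_identical(self):
        acq = make_acq(mode="nonlinear", shape=(5, 64, 64),
                       photon_scale=100.0, read_noise=2.0)
        vol = np.full(acq.shape, 0.5)
        a = render_stack(vol, None, None, None, acq, rng=11)
        b = render_stack(vol, None, None, None, acq, rng=11)
        assert np.array_equal(a.data, b.data)
        c = render_stack(vol, None, None, None, acq, rng=12)
        assert not np.array_equal(a.data, c.data)

    def test_snr_scales_with_photon_budget(self):
        vol = np.full((5, 64, 64), 0.5)
        snr = {}
        for scale in (100.0, 400.0):
            acq = make_acq(mode="nonlinear", shape=(5, 64, 64),
                           photon_scale=scale, read_noise=0.0)
            ch = render_stack(vol, None, None, None, acq,
                              rng=3).channel("green").astype(float)
            snr[scale] = ch.mean() / ch.std()
        assert snr[400.0] / snr[100.0] == pytest.approx(2.0, rel=0.10)

    def test_shape_mismatch_rejected(self):
        acq = make_acq(mode="nonlinear", shape=(5, 64, 64))
        with pytest.raises(ValueError):
            render_stack(np.zeros((4, 64, 64)), None, None, None, acq)
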
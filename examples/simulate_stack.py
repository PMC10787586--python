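"""Generate a ground-truthed synthetic two-photon stack and write it out.

Composes nuclei (implant-population axis Gaussians), a 9-branch vessel
tree, an oriented collagen fiber field and the scaffold mask into a
nonlinear-mode stack with PSF blur and Poisson + read noise.
"""

import pathlib

import numpy as np

import lattiscope as L
from lattiscope import io as lio

seed = 0
rng = np.random.default_rng(seed)
acq = L.AcquisitionSpec(voxel_size=(1.0, 0.8, 0.8), shape=(40, 500, 500),
                        mode="nonlinear", psf_sigma=(0.3, 1.0),
                        photon_scale=200.0, read_noise=2.0)
field = acq.field_size_um

pop = L.NucleusPopulationSpec.single(150, (2.3, 3.12, 4.26),
                                     (0.4, 0.5, 0.6))
nuclei_truth = L.sample_nuclei(pop, field, rng)
nuc_vol, labels = L.render_nuclei(nuclei_truth, acq)

graph, branch_truth = L.generate_vessel_network(L.VesselNetworkSpec(),
                                                field, rng)
vessel_vol = L.render_vessels(graph, acq)

col_vol, fiber_truth = L.render_collagen(
    L.CollagenFieldSpec(n_fibers=400, dispersion_fwhm_deg=25.0), acq, rng)

stack = L.render_stack(nuc_vol, vessel_vol, col_vol, None, acq, rng)

out = pathlib.Path("scratch/example_stack")
out.mkdir(parents=True, exist_ok=True)
lio.save_stack(out / "stack.ome.tif", stack)
from lattiscope.synth import GroundTruth

GroundTruth(nuclei=nuclei_truth, vessel_graph=graph,
            vessel_branches=branch_truth, collagen_fibers=fiber_truth,
            seed=seed).to_dir(out / "truth")
print(f"wrote {out / 'stack.ome.tif'} "
      f"({stack.shape} voxels, channels {stack.channel_names})")
print(f"truth: {len(nuclei_truth)} nuclei, {len(branch_truth)} vessel "
      f"branches (mean {branch_truth.length_um.mean():.0f} um), "
      f"{len(fiber_truth)} collagen fibers")
# every rendered object has exactly one truth row, so any estimator run on
# this stack can be scored against the tables in scratch/example_stack/truth
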
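"""Collagen-I directionality from SHG: angular spectrum and Gaussian FWHM.

Renders fiber fields at the dispersions measured inside the implant (25
degrees) and in control tissue (48 degrees) and recovers both by the
windowed Fourier angular spectrum.
"""

import numpy as np

import lattiscope as L

acq = L.AcquisitionSpec(voxel_size=(1.0, 0.5, 0.5), shape=(3, 512, 512),
                        mode="nonlinear", psf_sigma=(0, 0),
                        photon_scale=0, read_noise=0)
for label, fwhm in (("implant", 25.0), ("control", 48.0)):
    spec = L.CollagenFieldSpec(n_fibers=500, fiber_length_um=60.0,
                               dispersion_fwhm_deg=fwhm)
    vol, truth = L.render_collagen(spec, acq, 0)
    img = vol.max(axis=0)
    spectrum = L.angular_power_spectrum(img)
    fit = L.directionality_fwhm(spectrum)
    print(f"{label}: generated dispersion FWHM {fwhm:.0f} deg -> "
          f"recovered {fit.fwhm:.1f} deg (peak at "
          f"{spectrum.peak_angle_deg:+.0f} deg from the lattice axis)")
# a narrower FWHM means fibers co-align with the lattice; the isotropic
# floor is absorbed by the constant baseline of the Gaussian fit

tissue = np.ones((512, 512), dtype=bool)
frac = L.collagen_fraction(img, tissue)
print(f"collagen-positive fraction of the tissue area: {frac:.2f}")
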
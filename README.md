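# lattiscope

Label-free quantification of tissue growing inside an implanted,
two-photon-polymerized lattice microscaffold, from 3D multichannel
fluorescence stacks.

Tissue engineers and immunologists studying the foreign-body reaction in the
chick chorioallantoic membrane (CAM) model can follow an implant
longitudinally by nonlinear microscopy: cytoplasmic autofluorescence (TPEF,
green channel — nuclei appear *dark*), second-harmonic generation from
fibrillar collagen I (SHG, blue channel), or confocal imaging of stained
nuclei (red channel — nuclei appear *bright*).  The implanted lattice
(square pores of 49.6 × 49.6 × 20 µm³, X-profile reinforcement pillars every
100 µm, 36 pillars on the default 10 × 10-pore grid) provides an intrinsic
reference frame.  `lattiscope` turns such stacks into numbers:

- **Nuclear morphometry** — 3D segmentation in bright or dark contrast,
  moment-equivalent ellipsoid semi-axes `A ≤ B ≤ C` from the voxel
  covariance (`a = √(5λ)`), and granulocyte classification by the
  axial-ratio quadrant rule (`A/C < 0.5` and `B/C < 0.75`): bi-/tri-lobed
  granulocyte nuclei are strongly prolate and land in the low-ratio
  quadrant.
- **Cell density** — counts per ROI column (Eq. `density = count / volume`,
  ≥ 6 random 100 × 100 µm² ROIs), plus the histology correction that
  ascribes to a 2D section the volume of the cut (4 µm) plus the mean cell
  size (5 µm).
- **Microvessel morphometry** — segmentation, 3D skeletonization into a
  centerline graph, cross-section widths as intensity-profile FWHM sampled
  every 100 µm (short vessels: both extremities averaged), one/two-component
  Gaussian width-mixture fits, orientation spread vs the lattice axis,
  branch count/length, and projected vessel area density.
- **Collagen directionality** — windowed 2D Fourier angular power spectrum
  with a Gaussian + baseline fit; the FWHM measures fiber co-alignment with
  the lattice.  Depth-group (LOW/MEDIUM/HIGH, ~30 µm each) averaging and
  collagen area fraction included.
- **Growth statistics** — doubling intervals from log2-linear fits,
  implant/control relative increase, and the KS-normality + Mann–Whitney
  comparison protocol.
- **Synthetic generator** — because the study's raw stacks are not
  deposited, a ground-truthed simulator renders nucleus populations from
  per-class axis Gaussians (bilobed granulocytes included), branching
  vessel trees with a two-component diameter mixture, oriented collagen
  fiber fields, scaffold autofluorescence, PSF blur and Poisson + read
  noise.  Every estimator in the package is validated by parameter recovery
  against these truth tables.

## Worked example

`examples/vessel_morphometry.py` generates a 9-branch vessel tree at the
implant parameters (mean branch length 60 ± 11 µm, diameters from the
5.6 / 12.8 µm two-component mixture, 60° FWHM orientation spread), renders
it noiselessly, and re-measures it from the image alone:

```
branches: recovered 9, truth 9; mean length 55.3 vs truth 56.1 um
width samples (profile FWHM every 100 um): n=18, mean 8.7 um; truth diameters 3.1-12.0 um
width mixture fit: means 5.7 / 13.1 um, weights 0.47 / 0.53
projected vessel area density over the field: 0.026
```

The branch count is recovered exactly and the mean branch length to within
1.5%; the width-mixture fit recovers the two generating component means
(5.6 and 12.8 µm) to within 3%.  The other scripts in `examples/` cover the
fabrication geometry (50 µm → 31 px along X at f_x = 1.6 px/µm, realizing
49.6 µm), stack simulation, nuclear morphometry (60/60 nuclei segmented,
30/30 granulocytes flagged at the default quadrant thresholds), collagen
directionality (25° and 48° dispersions recovered within a few percent) and
growth statistics.

A thin CLI wraps the same stages for shell use:

```bash
lattiscope --seed 1 simulate run.yaml out/
lattiscope nuclei out/stack.ome.tif nuclei.csv
```

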
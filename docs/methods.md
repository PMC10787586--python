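# Methods

This note documents the models and estimators implemented in `lattiscope`,
the defaults they ship with, and what the synthetic validation does and does
not demonstrate about real data.

## Conventions

Voxel arrays are indexed `(z, y, x)` (channel last), 0-based with half-open
ranges; physical lengths are micrometres throughout.  In-plane orientation
angles are degrees in `[-90, 90)`, measured from the lattice X axis and
defined modulo 180° (a vessel has no head or tail).  For a Gaussian,
FWHM = 2√(2 ln 2) σ ≈ 2.355 σ everywhere.

## Scaffold geometry and registration

The lattice is modelled parametrically: an `nx × ny` grid of square pores
(pitch 49.6 µm, height 20 µm), wall elements of 1.5 µm, and X-profile
reinforcement pillars (5 µm side, 1.5 µm arms) on every
`pillar_interval`-th node *including the borders* — the only node
convention that yields the fabricated count of 36 pillars for a 10 × 10
grid with pillars every two pores.

The fabrication pixel–micron conversion uses per-axis factors
f_x = 1.6, f_y = 1.7 µm per pixel step with **floor** rounding:
`pixels = ⌊d / f⌋`, `realized = pixels · f`.  Floor (not nearest) is the
only rounding consistent with the system's worked example
(50 µm → 31 px along X and 29 px along Y, realizing 49.6 µm); the
conversion is dimensioned so that realized length = pixels × f.

Registration rasterizes the lattice at the stack's voxel size and matches
it against the maximum-intensity projection of the scaffold-bearing channel
by FFT cross-correlation; the reported score is the normalized correlation
at the recovered pose, and scores below a floor (default 0.2) raise a
"no lattice found" error.  Translation-only search is the default; a ±10°
rotation sweep is available behind a flag, since the real device is aligned
by its fabricated corner beacons and residual rotation is small.  The
recovered pose partitions the field into *inside* (lattice footprint),
*near* (≤ 200 µm annulus, the zone of elevated granulocyte density), and
*far* regions that exactly tile the field.

## Synthetic stacks and their ground truth

The generator exists because the study's raw stacks are not publicly
deposited; its defaults are the study conditions.

**Nuclei.**  Each class draws semi-axes (A, B, C) from per-axis Gaussians.
Whole-population envelopes: control 1.4 ± 0.4 / 2.2 ± 0.4 / 2.9 ± 0.6 µm;
implant (EID14) 2.3 ± 0.4 / 3.12 ± 0.5 / 4.26 ± 0.6 µm.  Axes share a
latent size factor (correlation 0.85): real nuclei show exactly this
inter-axis correlation, and without it the sort into A ≤ B ≤ C would bias
the sorted sample means by up to ~0.18 µm (order statistics of overlapping
Gaussians), breaking mean recovery by construction.  Placement is uniform
with a zero-overlap constraint on bounding spheres (rejection sampling).
Granulocytes are unions of 2 (default) or 3 lobe ellipsoids whose centers
are spread along the long axis over 0.6 C, each lobe's long semi-axis
shortened so the envelope still spans ±C; the union stays connected and its
moment-equivalent ellipsoid remains prolate.  Rendering is solid-ellipsoid
rasterization: bright nuclei in confocal mode, dark nuclei carved from a
uniform cytoplasm field in nonlinear mode.

**Vessels.**  Trees grow by tip bifurcation: a trunk plus repeated splits
at open tips (each split adds exactly two children, so odd branch counts —
e.g. the in-implant mean of 9 — are realized exactly; a single trifurcation
absorbs even targets).  Branch initial directions are drawn from the
orientation Gaussian about the lattice axis (default FWHM 60°) rather than
relative to the parent, so the chord-angle spread matches the nominal value
directly; the in-plane travel *sign* is free because orientation is modulo
180°.  Per-branch diameters come from the two-component mixture (means
5.6 / 12.8 µm; component sigmas from the printed FWHMs 5.4 / 3.8 µm;
weights 0.7 / 0.3), branch lengths from N(60, 11) µm.  A clearance
constraint (centerline separation at least the sum of tube radii + 3 µm,
floor 15 µm, junction-neighbourhoods exempt) with redraw-and-rollback keeps
non-adjacent tubes from merging, which is what makes exact branch-count
recovery well-posed.  Tubes are rendered as capsules (point-to-segment
distance), so straight segments have plateau cross-sections equal to the
truth diameter before blur.

**Collagen.**  Straight fibers (default 40–60 µm long, 1 µm thick) in
random z slices with in-plane angles from a Gaussian of the configured FWHM
(implant 25°, control 48°).

**Forward model.**  Channels are composed per mode (nonlinear: green =
cytoplasm-with-dark-nuclei ∨ vessels ∨ scaffold, blue = SHG; confocal:
green = vessels ∨ scaffold, red = nuclei), blurred by a Gaussian PSF
(defaults 0.3 µm lateral / 1.0 µm axial) and degraded by Poisson shot noise
at a photon scale plus Gaussian read noise, then quantized to 8 or 16 bit.
Setting photon scale and read noise to zero returns the blurred composition
exactly (and the raw composition at zero PSF), which exact-recovery tests
rely on.  The scaffold-to-tissue intensity ratio is a free parameter
(default 1.0) because no quantitative ratio is published.  All randomness
flows through one seedable generator; identical seed + spec reproduce
bit-identical stacks.

**What the generator does not emulate:** scattering and depth-dependent
aberration, anisotropic/spatially varying PSFs, detector afterpulsing,
vessel lumen vs wall contrast, curved or branching fibers, erythrocyte
motion.  Passing recovery tests therefore demonstrates estimator
correctness under a standard forward model, not robustness to every real
acquisition artifact.

## Image preparation

Denoising is per-slice, per-channel: median (radius 2 px default, the
classical contrast-enhancing choice), Gaussian, or any user callable — the
pluggable slot is where a learned denoiser would go.  Focus scoring is the
variance of a 3 × 3 high-pass response; the top-k slices are summed (k is
exposed because the per-tile count used in practice is not standardized).
Tissue masking thresholds fluorescence with the between-class-variance
(Otsu) split by default; masks are strictly-above-threshold and hence
monotone in the threshold.

## Nuclear morphometry

Segmentation thresholds the nuclear channel (bright mode) or the inverted
cytoplasm channel within the tissue mask (dark, label-free mode), then
labels 3D components.  Marker-controlled watershed on the Euclidean
distance transform splits *touching* nuclei — but only components larger
than a generous single-nucleus volume (200 µm³ default) are split, so
bilobed nuclei, whose lobes are separate distance peaks, are not
fragmented.  Components outside [4, 600] µm³ are discarded.

The ellipsoid fit is deterministic moment matching: semi-axes a = √(5 λ)
from the eigenvalues of the voxel-coordinate covariance (uniform solid
ellipsoid relation), with the voxel-cell variance h²/12 added per axis —
voxel centers are point samples of cubes of mass, and omitting the term
biases ~3-voxel-wide nuclei low by several percent.  Semi-axes (not full
axes) are reported; axial ratios are unaffected by that choice.  Fits need
≥ 8 voxels and reject (near-)coplanar voxel sets.

The granulocyte rule flags a nucleus iff A/C < 0.5 **and** B/C < 0.75,
strictly.  The thresholds are the visual midlines of the axial-ratio
correlation plot, are configuration (not measured constants), and are
echoed in every report.  On noiseless renders the rule separates bilobed
prolate granulocytes from round-to-oval generic nuclei with 100%/0%
sensitivity/false-positive rate at n = 100 each; elongated fibroblast
nuclei can enter the same quadrant, so on real data the rule is a shape
classifier, not a cell-type oracle.

Densities divide centroid-in-region counts by region volume.  The ROI
protocol places ≥ 6 random 100 × 100 µm² columns (seeded, reproducible) and
reports mean ± sd across ROIs; single-slice analyses are supported by
restricting the depth.  The histology correction divides a 2D section count
by area × (section thickness 4 µm + mean cell size 5 µm) — a cell is
counted whenever any part of it meets the cut, so the effective sampling
depth exceeds the physical section.  Region-stratified granulocyte
densities propagate Poisson counting error (√n) into the pairwise ratios;
empty compartments are reported as unavailable, never as zero ratios.

## Vessel morphometry

Segmentation is threshold (Otsu default) within the tissue mask with
removal of components whose spatial extent is below 20 µm.  The centerline
graph comes from 3D thinning followed by graph tracing: junction voxels
(≥ 3 neighbours) cluster into nodes, chains of degree-2 voxels become
polyline edges.  Cleanup is radius-adaptive because thinning artifacts
scale with tube radius: terminal spurs shorter than max(5 µm, 1.5 r) are
pruned, junction–junction links shorter than max(12 µm, r_u + r_v, 2 r_mid)
contracted, tiny loops removed, and pass-through nodes merged.  Terminal
edges are extended along their end tangent to the mask boundary minus the
local radius (thinning retracts tube ends by about one radius), and
polylines get a 5-point moving-average smoothing, without which the
discrete zigzag inflates arc lengths by several percent.  One
implementation caveat: the 3D thinning in scikit-image 0.26 annihilates
perfectly symmetric even-width structures (a 2 × 2 × L bar skeletonizes to
nothing); the extractor detects poor skeleton coverage of the mask and
retries on a symmetry-broken copy, which never triggers on realistic
jittered data.

Widths are sampled every 100 µm of arc length; edges shorter than the
interval are sampled at the two extremities (inset 8 µm to stay clear of
junction blobs and caps) and averaged per vessel.  At each sample the
intensity profile along the in-plane normal (half-length 12 µm, half-voxel
steps, trilinear interpolation) is measured and the half-maximum crossing
pair *bracketing the profile center* taken as the width — on a clean
single-vessel profile this equals the classical FWHM (a rendered 7.2 µm
tube reads 7.2 ± half a voxel), but it does not blow up when a neighbouring
vessel enters the window, which the outermost-crossing rule would.
`profile_fwhm` (outermost crossings, background = profile minimum, linear
interpolation) is exported separately for plain profiles.  Widths of tubes
tilted out of plane are overestimated by 1/cos(tilt); the generator's
default tilt (≤ ~15°) keeps this under 4%.

The width histogram (1 µm bins) is fitted by least squares with k = 1 or 2
Gaussian components, initialized from the 25th/75th percentiles, means
sorted, weights from component areas; `k='auto'` selects by a BIC-like
penalized residual.  Degenerate outcomes (weight < 0.05, merged means,
spike components at the bin-width floor) are flagged, not silently
reported.  Orientation uses the endpoint-to-endpoint chord per edge (the
per-vessel angle, deliberately not per-segment tangents), histogrammed in
10° bins over [-90, 90), circularly recentred on the peak and Gaussian-
fitted; resolution-limited (FWHM ≤ bin) and poor fits (R² < 0.2) are
flagged.  Branch count is the edge count; branch length the polyline arc
length.  "Vessel area density" is defined here as the projected
(maximum-intensity) vessel area over projected tissue area — the
projection-based reading of a surface density — and the definition is
recorded with every report.

## Collagen directionality

A 2D slice is apodized with a raised-cosine (Hann) window, its power
spectrum accumulated into 90 orientation bins of 2° over [-90, 90) for
radii between 8 px and the Nyquist ring.  The spatial-frequency angle is
rotated 90° to give the fiber orientation.  Power is averaged (not summed)
per bin because the discrete grid populates angle bins unevenly, which
would imprint anisotropy on white noise; bins then normalize to sum 1.
Isotropy is flagged when the max/min bin ratio of a 5-bin circular
smoothing falls below 1.5 (the window correlates neighbouring frequencies,
so raw bins are too noisy to judge flatness).  The FWHM comes from a
Gaussian-plus-constant fit around the circularly recentred peak; the
constant absorbs the isotropic floor, which otherwise biases the FWHM
upward on synthetic backgrounds.  Depth analysis averages blocks of 3
consecutive slices, computes one spectrum per block, and averages FWHMs
within ~30 µm LOW/MEDIUM/HIGH groups counted from the glass interface
(per-block averaging is the default; pooled spectra are available by
passing the averaged image directly).  Finite fiber length broadens the
angular spectrum slightly (a few degrees in quadrature at 60 µm fibers),
which is within the 15% recovery tolerance at both study dispersions
(25° and 48°).  The collagen fraction is collagen-positive over tissue
pixels, Otsu-split within the tissue mask by default, per tile.

## Growth statistics

The doubling interval is 1/slope of a least-squares line on log2(density)
vs day — the simplest model consistent with reporting a "doubling
interval" — with the standard error propagated from the slope error
(se(T_d) = se(slope)/slope²).  Non-positive slopes report a non-finite T_d
with a flag rather than a number.  The relative-increase analysis forms
per-day implant/control ratios and fits the same model to the ratio
series.  The fit window is a parameter because growth onset (day 10 vs 11)
is a judgement call on real data.  Group comparison follows the study's
protocol: KS normality per group (against a Gaussian with the sample's own
moments), one-way ANOVA across groups, two-sided Mann–Whitney for the
pairwise comparison, α = 0.05; every result carries its n, α and test
names, and a Holm step-down helper is provided for families of pairwise
day-comparisons (the adjustment choice is ours; none is standard here).

## Problem sizes used in validation

Recovery tests run at sizes chosen to keep sampling error well inside the
stated tolerances while remaining desk-scale: nucleus-population recovery
renders 200 nuclei at 0.3 µm voxels (mean recovery within 2 SE for both
control and implant Gaussians); the classifier check uses 100 + 100 nuclei;
vessel recovery renders one 9-branch tree in a 400 × 400 × 40 µm³ field at
0.8 × 0.8 × 1 µm voxels; the width mixture is fitted on 500 draws;
collagen fields use 500 fibers on 512² slices; the doubling-interval noise
study uses 100 replicates of 4 time points.  The full suite runs in under
a minute on one core.

## Known limitations

- The quadrant thresholds (0.5, 0.75) are visual conventions; sensitivity
  to them should be explored on real data, and elongated fibroblast nuclei
  are not distinguished from granulocytes by shape ratios alone.
- Whether published axis values are semi- or full axes is ambiguous;
  everything here is semi-axes, so absolute comparisons to external tables
  may need a factor 2 (ratios are invariant).
- Skeleton-based branch statistics assume tubes that do not merge; true
  anastomosing networks produce cycles that the tree-oriented cleanup
  preserves but the branch-count recovery guarantees do not cover.
- Width measurements are in-plane; strongly z-oriented vessels are
  overestimated and should be filtered by tilt if present.
- The registration searches translation (optionally small rotations) only;
  heavily warped or tilted lattices would need a richer transform.
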
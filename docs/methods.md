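# Methods

`panelpet` models the image-quality problem of dual-panel PET (for
example dedicated breast-PET): two flat detector heads face each other,
the tomographic data cover only part of the angular range (73% of 180°
at 132° transaxial acceptance for a 9 cm head separation), and the
reconstructed point response is anisotropic, asymmetric and spatially
variant — elongated along the axis normal to the panels (`y`), with the
response shifting toward the nearer panel as the source approaches it.
The package simulates these deformations, reconstructs limited-angle
TOF data, trains a convolutional corrector on synthetic pairs, and
quantifies the result.  This note records the models, the parameters
that matter, and the design choices made where the design was open.

## Coordinate and grid conventions

Images live on regular 2D or 3D grids (`VoxelGrid`) with 1 mm isotropic
voxels by default, world origin at the grid center, `y` normal to the
detector panels and `z` axial.  2D grids are first-class: every
operation (phantoms, deformation, projection, reconstruction, network,
metrics) runs identically on a single transaxial slice, which is what
the desk-scale experiment profiles use.  Volumes are exchanged as
NIfTI-1 (the affine encodes the center-origin convention), phantom
specs as JSON side-cars, kernel tables as YAML, histo-image stacks as
HDF5.

## Phantoms

Phantoms are declarative: a cylinder of uniform background activity
(default 1.0 activity units; the absolute scale is carried by count
targets, not the phantom) plus a list of hot lesions and a rigid pose.
Rasterization is binary by voxel center — a voxel is background, lesion
(`background x contrast`), or 0 outside — with no partial-volume
weighting; the metric VOI masks are built from the same membership
predicates, so masks and rasterized lesion sets agree exactly.

Two lesion families:

* **Spheres** (2–10 mm, contrast 6:1–10:1) populate the breast-scanner
  training cylinders: diameter 4–6 cm, height 4.5–5.5 cm, 1–10 lesions,
  rotations up to ±6° about `x` and `z`, small random FOV offsets.
* **Triple-ellipsoid lesions** (effective diameter 6–30 mm, contrast
  2:1–10:1) are unions of three random ellipsoids.  Connectivity is
  enforced by requiring pairwise component overlap (each component
  contains a ball of its smallest semi-axis, so overlapping offsets
  guarantee a connected union).  "Effective diameter" is defined as the
  diameter of the volume-equivalent sphere (area-equivalent circle in
  2D), measured by fine-grid (0.25 mm) voxel counting; sampled shapes
  are rescaled so the measured union hits the requested diameter.

Placement rules: lesion surfaces keep ≥ 2 mm clearance from the
cylinder wall and lesions may not overlap (their conservative bounding
spheres must be separated); infeasible requests fail with an error
naming the constraint after bounded retries.  Samplers are pure
functions of a `numpy` Generator; datasets derive per-phantom seeds
from one master seed via `SeedSequence.spawn`.

## Spatially-variant PSF deformation

Each source position has a kernel that is a mixture of two weighted
Gaussians (weights sum to 1), each with per-axis widths and a mean
shift.  Parameters are anchored on a regular 15 mm lattice stored over
the non-negative octant (quadrant in 2D) and mirrored to the rest of
the FOV, negating the shift component of each mirrored axis; between
anchors, parameters are interpolated multilinearly (interpolating
*parameters* rather than rendered kernels is cheap, smooth, and
well-defined for shifts; the difference from kernel-space interpolation
is an accepted approximation).

The built-in default table reproduces the qualitative structure of a
dual-panel response while remaining fully overridable:

* within the central 60% of the half-FOV along `y` the kernel is a
  single near-symmetric Gaussian with sigma = (2, 5, 2) mm — elongated
  along `y`, similar and symmetric in `x`/`z`;
* beyond that core a second component ramps in smoothly (smoothstep),
  reaching weight 0.45, a +6 mm shift toward the nearer panel, and a
  `y`-width of 7 mm at the panel.

The constant core is deliberate: a count-conserving scatter blur whose
parameters vary across a region does *not* leave a uniform field
uniform (the local density changes like the divergence of the mean
shift field), so exact flat-field behavior — the basis for measuring
background roughness of 0.00% on noiseless deformed images — holds
precisely where the parameters are locally constant.  The default
table therefore confines the spatial variation to the outer zone near
the panels, which is also where the physical deformation lives.

**Deformation semantics.**  `deform_image` uses the scatter (source-
driven) convention: each source voxel distributes its activity
according to the unit-sum kernel rendered at its own world position
(sampled at voxel centers, truncated at 4 sigma plus shift, and
renormalized to sum exactly 1).  Scatter with unit-sum kernels
conserves total activity exactly for interior-supported images; mass
falling outside the grid is truncated, not renormalized.  Internally,
voxels with bitwise-identical parameter vectors (the nested-lerp
interpolation guarantees this in constant regions) are dispatched as a
single FFT convolution and the rest voxel by voxel; both paths compute
the same scatter sum, which a brute-force per-voxel oracle verifies to
1e-10 in the tests.  Sigmas below 0.25 voxel are rejected as
unresolvable; exact delta kernels (sigma = 0) are supported and make
the deformation an exact identity.

Image-domain noise is Poisson: `y = Poisson(x*s)/s` per voxel with a
counts-per-activity scale `s`, preserving the expectation.  For a
uniform background `b` the roughness is IR% = 100/sqrt(b*s); the
noisy warm-background experiments use `s = 4`, placing the deformed
input at roughly 50% background roughness.

## Limited-angle TOF histo-image model and RAMLA

Events are partitioned by view direction: 60 transverse views at 3°
steps and (in 3D) 15 axial tilts at 3.3° steps; only views inside the
acceptance cone (132° transaxial for the default 9 cm separation —
i.e. 73% of 180° — and 50° axial) carry data.  Deposition at the
most-likely TOF position is emulated by convolving the activity image,
per view, with an anisotropic Gaussian aligned to the view: the
along-view sigma is the TOF positional uncertainty (FWHM = c·dt/2;
500 ps → 74.95 mm FWHM, sigma 31.83 mm) and the transverse sigma
combines the efficient LOR width (0.8 mm) and the voxel size in
quadrature, treated as FWHM-like widths.  Optional analytic
attenuation for a uniform water cylinder (mu = 0.0096/mm) is provided;
normalization and sensitivity are unit — the package's idealized
replacement for experimentally measured factors.  Scatter and randoms
are not modeled.

Histo-image noise rescales the stack so its grand sum matches a total
count target, then draws voxelwise Poisson counts; the scale factor is
kept so reconstructions can be returned in activity units.

Reconstruction is relaxed row-action ML with one view per subset:

    x <- x * (1 + lambda * (P_v^T(y_v / (yhat_v + eps)) / s_v - 1)),

with `s_v = P_v^T 1`, epsilon floor 1e-12, non-negativity clamp,
relaxation lambda = 0.1, 10 full passes over the views in one fixed
seeded order, uniform initialization at mean(data)/mean(sensitivity).
The view kernels are centrally symmetric, so each view operator is
self-adjoint (verified explicitly to 1e-8).

**Where the deformation comes from.**  With a matched projector and
noiseless data the ML loop simply inverts its own blur — a point
source reconstructs to a point regardless of the acceptance angle.
The deformations of interest arise because the *data* carry the panel
PSF while the reconstructor does not model it: training-pair
generation forward-projects PSF-deformed images and reconstructs
without resolution modeling.  Under that convention a centered point
source reconstructs with a y/x FWHM ratio of about 2.5 at the default
132° acceptance.

## The corrector network

A dimension-configurable U-Net with 3 resolution levels: per level two
3^d convolutions each followed by ReLU, 2x max pooling down, 2x
transposed convolution up, skip connections between matching levels,
channel count doubling per down-step from `base_channels`, and a final
1x1 convolution to one channel.  Inputs not divisible by
2^(levels-1) are reflect-padded internally and cropped on output, so
output shape always equals input shape (the full-size 221x221x101
geometry is handled this way).  The implementation is a compact numpy
layer stack with explicit backpropagation (im2col convolutions, He
initialization, Adam); gradients are verified against finite
differences in the tests, and training is bit-reproducible for a fixed
seed on one machine.

Training follows the deformation-recovery recipe: L1 loss between the
prediction and the ground-truth label, Adam, batch size 1, intensities
normalized by one dataset-level constant (the 99th percentile of the
training labels, stored in the checkpoint).  No early stopping: a
fixed epoch budget, with the loss history exposed.  Defaults are
learning rate 1e-4 at paper scale (5000/10000 epochs); the desk-scale
profile uses learning rate 1e-3 for 120 epochs with `base_channels=8`,
chosen so a 50-pair 64x64 training fits in a few CPU-minutes while
still clearly beating the identity mapping.  Predictions clamp
negatives to zero (activity images) and denormalize to the input
scale.

## Metrics

All metrics are ratio-based and invariant to a joint rescale of image
and truth:

* **Lesion bias**: `Bias_i% = 100*(mean_VOI(image) - mean_VOI(truth)) /
  mean_VOI(truth)`; summarized as the unweighted mean of |Bias_i| over
  lesions.  VOIs are the exact rasterized lesion sets, optionally
  eroded by one voxel (6-connectivity) to drop boundary voxels.
* **CRC**: measured contrast over background divided by true contrast
  `(c-1)` for nominal lesion contrast `c`.  Two VOI conventions are
  implemented: the full lesion mask, and a fixed spherical VOI (e.g.
  6 mm on 8 mm lesions), selectable per experiment profile.
* **IR**: 100 * population sigma / mean over the background mask.
  Population (not sample) standard deviation is a documented choice.
* **PVM**: for two y-separated lesions, the mean profile of the 3x3
  vertical-line bundle through the centers; P is the mean profile
  value at the two centers, V the value at their midpoint (even gaps
  snap toward the lower index), reported as percent of the truth
  profile's P-V.

The background mask takes voxels inside the cylinder at least
`margin_mm` (default 15) from every lesion surface and a configurable
distance from the wall (default 2 voxels).  "Unaffected by the blur"
is not a sharp notion; for measurements that must be exactly
blur-free (the noiseless-roughness measurement below) both margins are
set to 22.5 mm, about 4.5 central `y`-sigmas, so neither the lesion
tails nor the wall rolloff reach the mask.

## The noiseless-roughness measurement

`panelpet.pipeline.noiseless_deformed_background_ir` (what
`scripts/acceptance.py` runs) draws a warm 120 mm cylinder on a 2D
220x220 mm grid with one triple-ellipsoid lesion (effective diameter
8–13 mm, contrast 2–10) within 20 mm of the center, deforms it with
the default kernel table and no noise, and measures IR% over the
22.5 mm-margin background mask (~2000+ voxels).  Because the
deformation is count-conserving and the mask's entire influence zone
sees constant kernel parameters, the background stays flat to
floating-point precision and IR% evaluates to 0.00 at two decimals for
any seed.  The 2D geometry is the package's desk-scale choice; the
measurement is purely local and dimension-independent.

## Scaled experiment profiles and what they show

Desk-scale profiles run 2D at 64x64: 50 training + 5 held-out pairs
for the warm-background deformation study (1–3 lesions of 6–16 mm per
phantom — the 6–30 mm full range does not fit a 64 mm FOV), Poisson
noise at counts-scale 4, 120 epochs.  On the held-out pairs the
trained corrector must beat the deformed input on all three metrics
(|Bias|% down, CRC up, IR% down); a representative run gives
|Bias|% 39 → 15, CRC 0.53 → 0.79, IR% 51.7 → 0.18.  These are
direction-of-effect checks: the full-size 3D values depend on the
unpublished fitted kernel table, full 70-pair datasets and 10^4-epoch
training, and are not asserted.

The separability study reconstructs three two-lesion phantoms (8 mm
lesions, 9:1 contrast, wall-to-wall gaps 2/5/8 mm along y) through the
limited-angle pipeline and checks that reconstructed PVM increases
with the gap.

## Known limitations

* The default kernel table is constrained by the qualitative structure
  of the published point-source profiles, not fitted to measured data;
  no numeric claims attach to it.
* The forward model is image-space convolution per view: no
  crystal-level physics, DOI, event-level histogramming, scatter,
  randoms, or measured normalization/sensitivity.
* The numpy network trains comfortably at desk scale; the paper-scale
  3D configuration is exposed but impractical without an accelerator.
* Synthetic phantoms are piecewise-constant cylinders and lesion
  unions; passing tests demonstrate the deformation/correction
  machinery, not performance on anatomically realistic objects.
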
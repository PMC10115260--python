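# Methods

## The measurement model

The biomarker is the volume of STIR-hyperintense inflammation, `V_HI`,
defined as the number of voxels that survive a four-stage chain —
disease-region restriction, reference-based intensity thresholding,
small-component removal, whole-component cleaning — multiplied by the voxel
volume taken from the image header. The core assumption is that normal
interforaminal sacral marrow provides a per-scan reference distribution of
non-inflamed intensity, so "hyperintense" can be defined relative to that
scan rather than by a fixed population threshold.

### Threshold adaptation

Given the reference intensities, the conservative threshold is the sample
maximum `I_max` and the sensitive threshold is `L_lower = Q_U + n·IQR` with
quartiles computed by linear interpolation between order statistics (the
common default across scientific software; no convention is intrinsically
right, but every derived value in the test suite is validated against an
independent brute-force loop under the same convention). The multiple starts
at `n = 1.5` and increases in exact steps of 0.05 — iterated over the integer
step count so `n` sits exactly on the grid `1.5 + k·0.05` with no float
drift — until `0 < I_max − L_lower < IQR/2`; if the condition already holds
at 1.5 no incrementation is performed.

Raising `n` can only shrink the gap, so once the gap becomes non-positive
the full condition can never be met. We therefore stop at the first `n` with
`gap < IQR/2` and mark the estimate *degenerate* when the gap there is ≤ 0,
when `IQR = 0` (constant reference), or after a hard cap of 2000 increments;
a degenerate estimate collapses `L_lower` onto `L_upper`, leaving only the
conservative segmentation meaningful. Callers may reject degenerate scans.
Well-behaved inputs are unaffected by these guards.

### Labelling, filtering, cleaning

Voxels at or above a threshold meet it (`≥`): equality inclusion makes the
reference maximum itself the lowest conservative intensity and avoids an
open interval whose behaviour depends on floating-point representation.
Conservative voxels (label 2) are by construction a subset of sensitive
voxels (label ≥ 1). `V_HI` counts the sensitive set; the conservative count
is reported alongside.

Connected components are computed per 2-D slice with 8-connectivity. The
filter is specified in pixels and in-plane area (4 px = 1.39 mm² at
0.59 × 0.59 mm), which implies slice-wise components; 8-connectivity is the
inclusive convention. Cleaning removes, in full, every component that
intersects a removal mark — components are never partially edited, which
keeps the reader's influence to a binary keep/remove decision per lesion.
Because components are slice-wise, a three-dimensional lesion is removed by
marking it on each slice it appears in (supplying its 3-D mask as marks does
exactly that).

## Disease-region segmenter

A 2-D U-net maps normalized T1-weighted slices to the binary disease region
(all potentially inflamed pelvic bone, excluding the normal-bone reference
area). Volumes are normalized by dividing by three times the whole-volume
population standard deviation, with no mean subtraction — per-volume rather
than per-slice, since the reference quantity is the image's intensity
distribution.

Training draws a random mini-batch (size 4) from the slice pool at each of a
fixed number of augmentation steps per epoch, augments it on the fly and
applies one Adam update (lr 1e-3) of the binary cross-entropy loss. The
full-scale search grid is epochs {60, 100} × resolution levels {2, 4, 6} ×
kernel {3×3, 5×5} with 350 steps per epoch (the `reference` profile and the
12-configuration `hyperparameter_grid`). The desk-scale `test` profile (2
levels, kernel 3, 8 base channels, ~6 epochs × 30 steps) is what the test
suite trains on phantoms; off-grid values require an explicit
`allow_nonstandard` flag so protocol and experiment configurations cannot be
confused silently.

Augmentation: elastic deformation (a 3×3 Gaussian displacement grid,
σ = 2 px, upsampled with cubic interpolation), affine rotation ±15°, scale
[0.9, 1.1], shear ±0.1, horizontal flip with probability 0.5, and an
intensity power drawn from [0.7, 1.4] applied to the image only. These
ranges are deliberately mild and label-preserving; all are configurable.
Image resampling is bilinear; masks are resampled nearest-neighbour and
re-binarised, and the identical spatial transform is applied to image and
mask (property-tested by applying the transform to the mask separately).

Splits are made at subject level — no subject contributes slices to more
than one of train/validation/test — with a four-fold cross-validation scheme
(each subject validates exactly once; 8 subjects give the 6 + 2 layout) and
a simple hold-out scheme. `train()` asserts at run time that no held-out
subject's slices entered the pool.

The deployed segmenter is a model-averaging ensemble: three networks trained
with distinct seeds derived from one master seed; per-voxel probabilities
are averaged and rounded half-up at 0.5 (the rounding rule at exactly 0.5 is
a choice; half-up is used consistently).

The CNN backend is a self-contained numpy implementation (im2col
convolutions, batch normalization with running statistics, max pooling,
nearest-neighbour upsampling, Adam). Gradients are validated against central
finite differences in the test suite. Batch norm uses ε = 1e-5 and running
momentum 0.1; weights use fan-in uniform initialisation. Inputs whose
spatial dimensions are not divisible by `2^(levels−1)` are zero-padded on
the bottom/right and the prediction is cropped back.

## SPARCC-style comparator

Presence is scored per quadrant (six consecutive slices, two joints, four
quadrants each; 48 cells); the depth and intensity bonuses are per joint per
slice (12 + 12), giving the scheme's stated maximum of 72. The per-quadrant
reading of the bonuses found in verbal descriptions of the scheme is
inconsistent with that maximum, so the per-joint-per-slice reading is
implemented. Depth — a visual judgement in the original scheme — is
operationalised as the maximum perpendicular distance (mm, via in-plane
spacing) from the supplied joint-line segment to any lesion voxel centre in
the joint's quadrants, with a strict `> 10 mm` test; the intensity bonus
requires a lesion voxel `≥` the CSF reference, taken as the median of a CSF
ROI (robust to ROI edge voxels). Which six slices are scored is supplied
explicitly by the scheme; the package does not choose them.

## Agreement and response statistics

Bland-Altman limits use bias ± 1.96 × sample SD (n−1 denominator) of the
paired differences, optionally after a `log(x+1)` transform of both sides
(zeros unaltered). OLS fits use statsmodels with 95 % CIs from the t
distribution on n−2 degrees of freedom. The composite reference marks a
voxel truly inflamed when at least 3 of 4 segmentation trials agree. A
subject is a responder iff their score strictly decreased. Discrepancy
flagging treats "more than two standard deviations from 0" literally by
default: deviations and the SD are both measured about zero (SD = RMS of the
differences); the about-the-mean variant is available as a flag. Two empty
masks get Dice 1.0 with a warning (vacuous agreement) rather than 0/0.

## Phantom generator

The generator emulates the features of oblique-coronal pelvis STIR/T1w
pairs that the workflow actually interacts with: a central sacral block and
two iliac plates (the disease region, minus a central interforaminal
normal-bone reference), spherical hyperintense lesions clipped to the
disease region, thin bright curvilinear vessels that start inside bone and
walk outward across its boundary, optional bright artefact blobs, and a
right-skewed normal-marrow intensity distribution: a Gaussian
(mean 100, SD 10 by default) truncated to [0, mean + 3 SD] with ~1 % of
voxels brightened by a factor in [1.15, 1.4]. The tail matters: it pushes
the reference maximum well beyond `Q_U + 1.5·IQR`, so the threshold
adaptation loop is exercised non-trivially (a pure Gaussian would make it
degenerate on most draws). Lesions take intensity
`multiplier × marrow_mean` exactly (before noise), so with zero noise and
`multiplier × mean` above the truncated-and-tailed marrow maximum, every
lesion voxel strictly exceeds every marrow voxel. Noise is additive
Gaussian (Rician optional). On T1w, bone is a distinct bright band (0.75
vs 0.25 background, oedema 0.60, vessels 0.20, SD 0.02 noise) — the
intensity contrast that makes disease-region learning the "simple task" the
workflow relies on.

Defaults follow the acquisition geometry (0.59 × 0.59 × 3 mm spacing; the
full 336 × 336 × 23–25 matrix is available by config) but the default test
matrix is 96 × 96 × 12 to keep experiments fast; the U-net experiments use
64 × 64 × 8 phantoms, 6 training and 2 held-out subjects, and the tiny
`test` profile. What passing phantom tests demonstrate is that the
machinery is correct (thresholds adapt as specified, components are
filtered and cleaned as whole units, volumes recover ground truth, a
separable region is learnable with subject-level splits); they do not
demonstrate clinical performance — real marrow heterogeneity, partial
volume at lesion boundaries, inadequate fat suppression and scanner
artefacts are not modelled, and phantom Dice/recovery numbers should not be
read as expected patient-data performance.

## Numerical and degenerate-input choices

- Quartiles: linear interpolation; thresholds loop over integer step counts.
- Threshold equality: `≥` at both thresholds.
- Ensemble rounding: half-up at 0.5.
- Empty-vs-empty Dice: 1.0 with warning.
- Degenerate reference distributions: flagged, never silently segmented.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical seeds give bit-identical phantoms,
  augmentations and training traces.

## Known limitations

- The phantom's anatomy is schematic (ellipse unions, straight-ish vessels);
  no MRI physics (TR/TE/TI, bias fields, fat suppression) is simulated.
- Depth in the quadrant score depends on the supplied joint line; the
  package does not derive joint geometry from anatomy.
- The numpy CNN backend is CPU-only and sized for small images; full-scale
  336×336 training is possible but slow, and the `reference` profile's
  values are carried as configuration rather than validated at that scale
  here.
- Anatomical exclusions during cleaning (e.g. joint-space or
  above-disc-level signal) are expressible only through removal marks or a
  tighter disease-region mask, not automated.
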
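# Methods

This note documents the models and procedures implemented in `sctreg`,
the assumptions behind them, the parameters that matter, and what the
synthetic phantoms do and do not establish about behaviour on clinical
data.

## Problem setting and conventions

The task is deformable registration of abdominopelvic mDixon MR to a
CT acquired on a separate scanner.  All volumes are 3-D scalar grids
with axis-aligned world coordinates, `world = origin + index · spacing`
(mm); oblique orientations are out of scope.  CT-like intensities are
Hounsfield units clamped to [−1100, 3100] on ingest.  Displacement
fields live on the fixed-image grid, store mm vectors, and use the
backward-warping convention `out(x) = moving(x + u(x))`; the Jacobian
determinant is `det(I + ∂u/∂x)` with derivatives taken in world mm.
Out-of-support samples take air-equivalent fill (−1000 HU for CT-like
volumes, 0 for MR).

## Synthetic-CT generation

**Features.**  Each voxel inside the body mask gets seven features:
one local texture per Dixon channel — the 3×3 in-plane convolution
with the normalized binomial kernel `[1 2 1; 2 4 2; 1 2 1]/16` — and
three position features, the voxel's grid-cell center coordinate in
[0, 1] under an 8-cells-per-axis partition.  The slice axis is excluded
from the texture kernel because slices are ~5× coarser than the
in-plane spacing.  The center-weighted kernel was chosen over uniform
1/9 averaging because it roughly halves partial-volume mixing at tissue
borders, which is the dominant error source of the whole classifier
chain.  All seven columns are standardized over the mask; a trained
model stores the pooled training statistics and prediction always
re-standardizes with them.

**Knowledge-leveraged clustering.**  For each training subject with a
paired, spatially aligned CT: the bone prototype is the mean feature of
voxels above 300 HU (MR alone cannot separate bone from air — both are
dark in every Dixon channel).  The remaining voxels are clustered into
air/fat/soft by fuzzy c-means (fuzzifier m = 2, tolerance 1e−5, max 300
iterations).  The paired CT supplies knowledge centroids — feature
means over the CT windows air < −400 HU, fat −400…−30 HU, soft ≥ −30 HU
— which both initialize the clustering and anchor its centroid update
(a quadratic penalty of weight N/3 per cluster, i.e. comparable to the
average data mass).  The anchor is essential, not cosmetic: interior
air is only a few percent of body voxels, and the m = 2 objective
otherwise absorbs it and splits the dominant soft-tissue cluster along
the position features instead, silently permuting the cluster-to-class
assignment.  Clusters map to classes by population mean CT (lowest →
air) and fat-channel centroid (highest of the remaining two → fat).
Averaging prototypes over training subjects gives the referenced class
prototypes.  When a CT window is empty the clustering falls back to
k-means++ seeding.

**CT-corrected SVM.**  Fat is taken directly from the fuzzy partition
(the Dixon fat channel identifies it robustly).  The remaining voxels
are classified bone/air/soft by an RBF SVM (C = 1, gamma = "scale")
whose training labels come from the paired CT: bone above 300 HU, air
below −400 HU, soft otherwise.  The −400 HU air bound is a
conventional choice (no tissue sits between lung parenchyma and fat).
Training uses a margin-prioritized subsample standing in for an
active-learning query loop: an initial fit on ≤3000 random voxels ranks
all voxels by decision margin, and the final SVM trains on the 20%
closest to the boundary plus a 10% random floor (capped at 6000), with
per-class top-ups so no class is ever absent.

**Voting and HU assignment.**  Each per-subject unit votes (fat if its
fuzzy fat-membership is maximal, else its SVM's prediction); a pooled
kNN classifier (k = 5, Euclidean in normalized feature space, ≤50 000
CT-corrected exemplars per training subject) adds one vote; the
majority wins, ties broken soft > fat > air > bone (erring toward the
most prevalent, least HU-distorting class).  Class HU values are air
−1000, fat −100, soft 40, bone 700 (configurable), followed by Gaussian
smoothing of 2.5 mm FWHM (σ = FWHM / (2√(2 ln 2)) ≈ 1.0616 mm,
converted to voxels per axis) to emulate CT reconstruction smoothness.

## Registration

**Rigid stage.**  Six-parameter alignment (extrinsic x-y-z Euler
rotation about the volume center + translation) maximizing 64-bin
joint-histogram mutual information by derivative-free coordinate
descent with shrinking steps (8→0.5 mm, 4→0.5°) over an in-plane
pyramid (factors 4, 2).  Deterministic; precise to about one voxel on
multimodal pairs, which is sufficient as a DIR initialization.

**Block-matching DIR.**  Per pyramid level (default 3 levels,
downsampling in-plane only), the moving image is first warped by the
field carried over from the coarser level.  Block displacements
(default 8×8×4-voxel blocks) are *integer state*: each iteration
evaluates the 27 candidate offsets {−1,0,1}³ around the current state
using exact integer shifts and advances greedily, so the aggregate
block score is non-increasing and the search cannot creep through
interpolation effects.  Two gates provide hysteresis: a block only
moves when the winning offset beats staying put by 20% of the block
score, and its slice-axis component must additionally beat the
corresponding in-plane-only offset by the same margin.  Slice-axis
candidates are only enabled at the finest level — the pyramid does not
downsample the slice axis, so coarse-level z-search sees the same 5 mm
quantum with a quarter of the in-plane evidence and was measured to
poison the carried field.  After the integer search settles, a per-axis
quadratic fit of the three scores around the optimum supplies a
sub-voxel fraction (clipped to ±0.5 voxel and gated by its predicted
gain, so an exact minimum is never perturbed).  Block values are
blended trilinearly from block centers and Gaussian-smoothed with
σ = (4, 4, 6) voxels — half a block in-plane; larger along the slice
axis so that slice-quantized z decisions are averaged on the scale of
the deformation's smoothness.  A final finest-level pass with half-size
blocks (4×4×2) adds local detail.  The similarity is SSD (minimized)
or per-block 16-bin joint-histogram MI with global intensity limits
(maximized); SSD is the intended metric for the sCT→CT problem, the MI
variant exists for the direct multimodal comparison arm.

These defaults were set during development on multiple phantom seeds;
the failure modes they fix (divergent accumulation of diluted
increments; structure-free blocks random-walking along the slice axis)
are described with the gate and state-representation choices above.

**Method composition.**  Three methods are exposed: `a_rigid_only`;
`c_mi_dir` (rigid + MI block matching directly on MR vs CT); and
`d_sct_ssd_dir` (rigid + sCT synthesis + SSD block matching of sCT
onto CT + field applied to the MR).  For every method the SSD/MAD
report columns are computed on the synthetic CT carried through that
method's total transform, so intensity metrics are comparable across
methods.

## Evaluation metrics

* **SSD / MAD** — means per voxel inside the body mask (HU² / HU).
* **MI** — nats, 64-bin joint histogram over global min–max ranges;
  constant images return 0.  Values are comparable only within this
  package (bin count and log base are conventions).
* **LPD** — monogenic-signal local phase at 6 log-Gabor scales
  (wavelengths geometric from 4 to 64 mm, bandwidth σ/f₀ = 0.55,
  Riesz-transform odd components, orientation sign fixed by the
  dominant Riesz axis); the metric is the amplitude-weighted mean
  wrapped phase difference in radians.  Because the filters have no DC
  response, LPD is invariant to positive affine intensity maps.
* **MHD** — max of the two directed mean closest-point distances
  between contour point sets (mm); contours are 6-connectivity surface
  voxels of ROI masks in world coordinates.
* **DSI** — `2|A∩B| / (|A| + |B|)`.
* **Jacobian determinant** — central differences in mm (one-sided at
  boundaries), with the summary statistics min, max, mean and the
  fractions of voxels in [0.95, 1.05] and [0.85, 1.15].
* An optional end-slice exclusion drops axial end slices from the
  intensity metrics.  It is off by default; the phantom benchmark uses
  2 slices because a deformation with |u_z| up to 6 mm moves anatomy
  across the FOV boundary of one acquisition but not the other, and
  the mismatch there is a property of the truncated support, not of
  registration quality.

Each metric is paired in the test suite with an independent
brute-force or closed-form oracle.

## The phantom generator

`make_phantom` rasterizes an analytic trunk: body ellipse with a
subcutaneous fat ring, kidneys in perirenal fat shells, a bony spine,
femoral-head analogs, a bladder and a rectum tube with pelvic-fat
shells and a gas-filled lumen, lung bases at the superior FOV end, and
bowel-gas pockets.  Classes are exactly {background air, interior air,
fat, soft, bone}; organ positions and sizes carry a small
seed-dependent jitter (±1.5% of extent positions, ±6% sizes, ±15%
bladder radius) so seeded phantoms are distinct subjects.  Interior air
is ~3–5% of the body — enough for an air cluster to exist, as it does
in real abdominopelvic FOVs that span the lung bases.

CT values are class-wise constants (−1000/−100/40/700 HU, σ = 20
noise); MR channels follow class-wise water/fat signal fractions scaled
to 1000 (air (0,0), fat (0.10,0.90), soft (0.85,0.10), bone
(0.20,0.05)) with IP = water+fat and OP = |water−fat| computed before
adding Gaussian noise (sd 50, ~SNR 20) and clipping at zero; bone and
air are deliberately near-identical in MR, so the CT-corrected
classifier stage is genuinely exercised.  Noise is additive Gaussian,
not Rician: classifier robustness, not MR physics, is under test.

**Ground-truth misalignment** (`make_phantom_subject`) composes (i) a
random smooth field — white noise convolved with a 30 mm Gaussian,
tapered by a soft body weight (air does not deform), rescaled to a
6 mm maximum and verified to have positive Jacobian everywhere, with
amplitude halving on failure —, (ii) a rigid offset, and (iii) a
deterministic breathing-state term (superior–inferior shift, 4 mm peak
at the renal level fading toward the pelvis).  The second-scanner CT
is the *noiseless* anatomy warped by this total field, blurred with a
2.5 mm FWHM reconstruction PSF, plus freshly seeded noise.  Ordering
matters physically and numerically: scanner noise arises at readout
after the anatomy has moved, and warping a single shared noise
realization would let SSD block matching exploit transported noise
texture — a correlation that does not exist between real scans.

**What phantom results do and do not show.**  Passing tests establish
that the pipeline recovers known smooth deformations to well under one
in-plane voxel on piecewise-homogeneous anatomy with exact Dixon
channel relationships, and that the method ordering (sCT-SSD ≥ rigid,
sCT-SSD SSD ≤ MI-DIR SSD) holds under those conditions.  They do not
establish performance under sliding organ interfaces, intensity
non-uniformity (bias fields), Rician noise, metal or motion artifacts,
arms/table in the FOV, or anatomy whose deformation violates the
smoothness prior (e.g. bowel rearrangement); contours here are
geometric ground truth, not inter-observer-variable hand tracings.

## Numerical choices and degenerate inputs

FCM tie handling: a feature vector coincident with a centroid receives
membership 1 for that centroid (first on exact ties).  Vote ties break
by fixed precedence.  A constant fixed image yields a zero field with
a warning (every offset scores equally; the zero offset wins by the
tie rule).  An empty body mask, absent bone candidates, a missing
class after CT correction, non-overlapping rigid inputs, and degenerate
grids all raise typed errors rather than proceeding.  All randomness —
phantom noise, anatomical jitter, deformation fields, SVM/kNN
subsampling — flows from explicit integer seeds; identical
configuration and seed reproduce bit-identical volumes and reports.

## Default problem sizes

The default phantom grid is 96×96×32 voxels at 2×2×5 mm (a desk-scale
stand-in for the clinical 512×512×m at ~1×1×5 mm that keeps the
anisotropic-slice regime); unit tests use 64×64×20 at 2.5×2.5×6 mm.
Benchmarks train the classifier leave-one-out across seeded phantoms
and report per-subject metrics with per-method means and standard
deviations, plus wall-clock per stage.
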
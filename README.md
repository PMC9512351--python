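# sctreg — MR-to-CT registration via a synthetic-CT intermediate

Deformable registration of abdominopelvic MR to CT is hard because the
two modalities share no intensity relationship: the robust same-modality
metric, the sum of squared differences (SSD), is meaningless between an
MR magnitude image and Hounsfield units, and the usual multimodal
metrics (mutual information, local phase difference) are noisy to
optimize. `sctreg` sidesteps the problem by making the moving image
CT-like first:

1. **Synthesize a CT from the mDixon MR.**  Each voxel gets a
   7-component feature vector (a 3×3 texture of each Dixon channel —
   water, fat, in-phase, opposed-phase — plus three coarse position
   features).  Tissue classes (bone, air, fat, soft tissue) are learned
   from training subjects with paired CT: the bone prototype is seeded
   from voxels above 300 HU, fuzzy c-means anchored to CT-derived
   knowledge centroids yields the remaining prototypes, per-subject
   RBF-SVMs are trained on CT-corrected labels, and prediction is an
   ensemble-plus-kNN majority vote.  Class-wise HU assignment and a
   2.5 mm FWHM Gaussian produce the synthetic CT (sCT).
2. **Register sCT → measured CT with SSD block matching.**  Multiscale
   block matching evaluates the 27 candidate offsets {−1,0,1}³ around
   each block's current displacement, blends block displacements into a
   dense field and regularizes it with Gaussian smoothing.
3. **Apply the recovered field to the MR.**  The sCT shares the MR grid
   exactly, so the same-modality field registers the MR to the CT.

The package also ships the full quantitative evaluation suite — SSD and
mean absolute HU difference inside the body, joint-histogram mutual
information, quadrature-filter local phase difference, modified
Hausdorff distance and Dice index on organ ROIs, and Jacobian
determinant maps with band statistics — plus a seeded phantom generator
that produces paired CT + mDixon volumes with ground-truth labels, ROIs
and known smooth deformations, so every stage is testable without
patient data.

Intended users: medical-image-analysis researchers who want a fully
inspectable, scriptable implementation of the sCT-intermediate
registration strategy and its evaluation metrics.

## Worked example

`examples/03_registration_via_sct.py` builds a misaligned phantom pair
(6 mm smooth deformation + 4–5 mm rigid offset + a breathing-state
difference), trains the tissue classifier on three other phantoms, and
compares rigid-only alignment with the full sCT route:

```
                         rigid only  sCT-SSD DIR
     SSD (HU^2, lower)        10674         1987
       MAD (HU, lower)         46.2         22.6
     MI (nats, higher)        0.342        0.587
      LPD (rad, lower)        0.752        0.647
       kidney MHD (mm)         2.53         1.33
            kidney DSI        0.731        0.873
DIR field Jacobian: mean 1.007, 65.8% of voxels in [0.95, 1.05], 93.8% in [0.85, 1.15]
```

Reading the numbers: the deformable sCT route roughly halves the mean
absolute HU mismatch between the (warped) synthetic CT and the measured
CT, nearly doubles the MR↔CT mutual information, and pulls the kidney
surfaces from ~2.5 mm to ~1.3 mm mean contour distance.  A mean
Jacobian determinant of ≈1 with no non-positive values says the
recovered deformation preserves volume overall and does not fold.

The other examples cover phantom generation (`01`), synthetic-CT
quality on a held-out subject (`02`; ≈0.99 voxel tissue-label accuracy,
≈29 HU mean absolute error) and the metric definitions on closed-form
inputs (`04`).

## Command line

A thin CLI wraps the library for shell use:

```bash
sctreg synth  --spec spec.yaml --out phantom_dir/      # phantom + ground truth
sctreg train-sct --pairs pairs.yaml --model m.joblib   # tissue classifier
sctreg make-sct  --model m.joblib --mdixon dir/ --out sct.nii.gz
sctreg register  --fixed ct.nii.gz --moving sct.nii.gz --apply-to mr_op.nii.gz \
                 --similarity ssd --out reg_dir/
sctreg evaluate  --fixed ct.nii.gz --sct-warped ... --field ... --out report.json
sctreg pipeline  --config run.yaml                     # full method A/C/D run
sctreg benchmark --n-phantoms 4 --methods a_rigid_only,c_mi_dir,d_sct_ssd_dir \
                 --seed 42 --out bench/
```

All volumes are NIfTI-1 (`.nii`/`.nii.gz`); displacement fields are 4-D
vector NIfTI in mm with a backward-warping convention (the warped image
at fixed voxel `x` samples the moving image at `x + u(x)`).

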
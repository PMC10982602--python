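# Methods

## Normative model

Each tissue compartment (GM, WM) is modelled independently. For every voxel
inside the analysis mask, tissue volume across the healthy-control (HC)
reference cohort is regressed by ordinary least squares on the design
`(1, age, sex, TIV)`; sex is coded 0 = F, 1 = M (the encoding is stored in
the serialized model metadata). The residual scale uses the unbiased
denominator `n − 4` (four design columns); the choice of denominator is a
convention and is recorded here because alternatives (`n`, `n − 1`) would
shrink or inflate z-scores by a factor `sqrt((n − 4)/·)`.

A subject's z-map is the *prediction residual* form,
`z = (X_subj · beta − y_subj) / s`, not a residualize-both-sides form; the
two differ only in how covariate effects enter, and the prediction form is
the one that makes "z of a typical healthy subject" standard normal under
the model. No t-distribution or leverage correction is applied: z is a
plain residual over residual-sd ratio. At small reference sizes this
inflates the tails slightly — with `n = 48` the held-out spread is
`sqrt(1 + 1/n + leverage) · sqrt(dof/(dof−2))` ≈ 3–4 % above 1 — which is
documented rather than corrected, matching the convention of z-score
(w-score) maps in clinical VBM. Distributional tests therefore use
`n_reference = 200`, where the normal approximation holds to within the
stated tolerances.

Degenerate voxels (residual scale below 1e−10 of the data RMS) are dropped
from the mask with a logged count; rank-deficient designs (e.g. a
single-sex reference cohort) are rejected with an error naming the column.

### Masking

The analysis mask keeps a voxel iff the HC mean value is ≥ 0.1 (an absolute
modulated-density floor excluding non-tissue regions) and the HC variance is
strictly positive (z is undefined otherwise). The 0.1 default is the
standard absolute-threshold masking of VBM pipelines and is configurable.
Masking is applied after any smoothing, mirroring the usual pipeline order
in which smoothing belongs to preprocessing.

### Smoothing

`smooth_gaussian` implements FWHM-parameterized Gaussian smoothing
(`sigma = fwhm / (2·sqrt(2 ln 2))` per axis, converted to voxel units), with
zero-padding at the boundary — consistent with modulated-density semantics,
where the world outside the head holds zero tissue. The conventional
real-data width is 8 mm FWHM on 1.5 mm isotropic voxels. The *synthetic*
pipeline defaults to no smoothing: the generator draws voxel noise
independently and atrophy uniformly within ROIs, so smoothing would only
blur signal across the (deliberately adjacent) synthetic ROI boxes without
emulating anything the real preprocessing achieves. The `--fwhm` flag turns
it on everywhere it applies.

### Visualization

Thresholded maps keep `z ≥ threshold` (inclusive; the boundary case is
measure-zero in floats, the choice is fixed for determinism), default
threshold 2.0. The overlay renderer draws an axial mosaic with a red→yellow
ramp mapping threshold→red and the map maximum→yellow, annotated with slice
coordinates, and is deterministic for fixed inputs.

## ROI scores and the index

ROI-level z is the mean of voxel z over the intersection of the ROI with
the analysis mask, computed on **unthresholded** z-maps (thresholding is a
visualization device, not part of scoring). An ROI entirely outside the mask
is flagged missing (NaN), never silently zero.

`Z_psp` is the higher of the two midbrain side means; `Z_msa` the highest of
the four putamen/MCP side means. The piecewise index follows the three-branch
definition in the README. Two edge conventions are fixed:

- a tie `Z_psp = Z_msa > 0` resolves to the PSP branch (the `≥` in its
  condition);
- the case `Z_psp ≤ 0 < Z_msa` belongs to the MSA branch, whose condition
  (`Z_msa > 0` and `Z_psp < Z_msa`) covers it even though the zero branch's
  wording might suggest otherwise; the three branches then partition the
  plane exactly (property-tested over a grid of `(Z_psp, Z_msa)` values).

If one side of a structure is missing (outside the mask) the max is taken
over the available sides with a logged warning — "higher side" semantics
survive — but a structure group that is missing entirely is an error.

ROI recognition is by case-insensitive substring ("midbrain", "putamen",
"mcp"/"middle cerebellar"), so both the synthetic atlas names and common
anatomical atlas naming schemes work unmodified.

## Evaluation statistics

- **Contingency metrics**: sensitivity, specificity, accuracy with Wald
  intervals `p ± z_{α/2}·sqrt(p(1−p)/m)` clipped to [0, 1]; a metric with a
  zero denominator is flagged undefined rather than raised. Wald (not
  Wilson/Clopper–Pearson) is the deliberate choice: it is the convention the
  clinical contingency tables this package mirrors are consistent with.
- **Cohen's kappa** from the defining formula with marginal-product expected
  agreement; the degenerate single-identical-category case returns 1. For
  three-class rater problems kappa is computed per disease on binarized
  labels (disease vs others).
- **ROC**: thresholds are midpoints between consecutive distinct scores plus
  ±∞ sentinels, so optimal cutoffs are well-defined between observations.
  The AUC uses the midrank convention and hence equals the two-sample
  concordance probability (ties count ½) — verified against an O(n²) oracle.
  Direction is explicit: "greater" for PSP-style rules (high index =
  disease), "less" for MSA-style rules.
- **Youden cutoff**: maximizes J = sens + spec − 1 over the threshold grid;
  ties break toward higher sensitivity, then smaller |cutoff|.
- **DeLong CI**: variance from the empirical variances of per-observation
  placement values, normal-approximation interval clipped to [0, 1]. With
  perfect separation the variance collapses to zero; the interval then
  degenerates to a point and is flagged, rather than pretending a width.
- **LOOCV** re-estimates the Youden cutoff on each n−1 training fold and
  classifies the held-out subject (honest validation); a `fixed_cutoff`
  option reproduces the simpler protocol of validating one pre-chosen
  cutoff. Folds whose training set loses a class are excluded with a
  warning. Pooled held-out predictions yield accuracy and kappa.
- No multiple-testing correction is applied to the two disease contrasts;
  the optional `pairwise_roi_tests` report (Mann–Whitney U between groups
  per ROI) applies Bonferroni across its own contrasts.

## Synthetic cohorts

The generator produces per-subject GM and WM images on a 32³ grid of 1.5 mm
isotropic voxels (the grid size keeps reference fits sub-second while
preserving the voxel scale; all operations are grid-size-agnostic). Each
tissue voxel is `baseline + β_age·age + β_sex·sex + β_TIV·TIV + ε` with iid
Gaussian ε, then multiplied by `(1 − atrophy_fraction)` inside the target
ROIs of the subject's group. Defaults:

| parameter | default | rationale |
|---|---|---|
| baseline GM / WM | 0.60 / 0.70 | typical modulated-density magnitudes |
| age | Uniform(50, 80) yr | parkinsonian-cohort age span |
| TIV | Normal(1450, 130) mL | adult intracranial volume |
| β_age | −0.003 /yr | mild age-related volume loss |
| β_sex | +0.02 | small male–female offset |
| β_TIV | +2·10⁻⁴ /mL | head-size scaling |
| noise sd | 0.05 | puts patient ROI z-scores in the ~0–6 range |
| atrophy | MSA-P putamen 0.25; MSA-C pons 0.30 + MCP 0.25; PSP midbrain 0.30; PD none | strong, consistent regional effects; tunable, not biological claims |
| group sizes | 48 HC / 96 PD / 12 MSA-P / 6 MSA-C / 20 PSP | study-scale design |

Randomness uses one top-level `SeedSequence`; each subject gets a spawned
substream, so cohorts are bit-reproducible from the seed and per-subject
draws are independent of cohort composition order.

The synthetic atlas is a set of disjoint boxes (putamen L/R and cerebellum
and cortex in GM; midbrain L/R, MCP L/R, pons and background white matter in
WM), each ≥ 20 voxels. A rater-decision simulator draws per-disease
diagnostic labels at requested sensitivity/specificity for kappa and
contingency-table testing.

**What passing tests do and do not show.** The generator matches the
normative model's assumptions by construction, so the calibration and
recovery tests verify the *implementation* (correct OLS, correct z
convention, correct index arithmetic), not the model's adequacy for real
brains. Real data add spatial noise correlation, heteroscedasticity,
registration error, partial-volume effects and scanner heterogeneity, none
of which are emulated; classifier performance on the cleanly separated
synthetic cohorts (AUC ≈ 1) says nothing about clinical accuracy.

## Problem sizes used in the checks

Held-out calibration uses 200 reference + 50 held-out controls on the 32³
grid (~9 300 masked voxels over both compartments); parameter recovery uses
100 controls; the end-to-end dichotomy check runs the full 182-subject study
across 5 seeds. These sizes make every distributional tolerance comfortable
for the approximations involved while keeping the whole suite fast.

## Known limitations

- No leverage/t correction for small reference cohorts (documented above).
- The Wald interval is anti-conservative near p = 0 or 1; it is kept for
  convention-compatibility, clipped to [0, 1].
- DeLong's normal approximation degrades at AUC near 1 with small samples;
  the degenerate case is flagged but not replaced by an exact method.
- The renderer produces quick-look mosaics, not publication-grade
  neuroanatomical reports (no MNI underlay shipping, no L/R convention
  annotation beyond slice coordinates).
- Subtype-level discrimination (MSA-P vs MSA-C, PSP variants) is explicitly
  out of scope.
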
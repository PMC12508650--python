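# Methods

## The Brain-Grid partition

Template brain space (MNI world coordinates, mm) is cut by three axial
planes (z), two coronal planes (y) and three sagittal planes (x) into
`4 × 3 × 4 = 48` sub-lobar *grid voxels* labelled `A{a}C{c}S{s}`:

* `A1..A4` — axial slabs, inferior → superior;
* `C1..C3` — coronal slabs, anterior → posterior;
* `S1..S4` — sagittal slabs, left → right.

The middle sagittal plane is pinned to the midline (x = 0), so S1/S2 are
left-hemispheric and S3/S4 right-hemispheric. Slab intervals are half-open:
a point exactly on a cutting plane belongs to the higher-index slab (a
midline point is S3). This removes classification ties deterministically.

The partition is defined in **world space**, not index space: voxel centres
are mapped through the image affine before classification, so radiological
(negative x step) and neurological storage conventions give identical
labels. Masks not on the template lattice are resampled to it with
nearest-neighbour interpolation first (`braingrid.io.resample_mask_to`).

The plane coordinates are configuration. The shipped defaults
(axial −24/4/32 mm, coronal −38/10 mm, sagittal −26/0/26 mm on the 2 mm
MNI152 geometry) produce anatomically plausible slabs — a temporal-floor,
an insular, a supra-insular and a convexity axial slab; prefrontal, central
and retro-central coronal slabs; lateral and para-midline sagittal slabs —
but they are package defaults, **not** the original published anatomical
landmark planes, which the source classification system defines on
cortical/subcortical landmarks. Override them via
`grid: {axial_mm, coronal_mm, sagittal_mm}` in YAML.

S numbering is fixed left → right. Published usage of identical labels in
both hemispheres (the same label described as left-sided in one subgroup and
right-sided in another) is internally ambiguous under any single fixed
numbering; we keep the invertible convention and provide
`GridVoxelLabel.mirrored()` (S ↦ 5 − S) to obtain the reflected label when a
hemisphere-mirrored reading is wanted.

## Topography metrics

* **Occupancy / invasiveness** — a grid voxel counts as infiltrated when
  the tumour's overlap volume exceeds `min_overlap_mm3` (default 0: any
  shared voxel). The number of infiltrated grid voxels (1–48) is the
  invasiveness measure used by the statistical and prediction stages.
  Per-cell overlap volumes always sum to the tumour volume.
* **Occurrence-weighted frequency map** — voxelwise
  `100 × (number of tumours overlapping) / n` for a group of n patients.
  All values are multiples of 100/n; the minimum nonzero frequency is
  exactly 100/n (1.5% for n = 65). The per-cell table uses the any-overlap
  rule.
* **Bundle infiltration** — a bundle mask (AF, SLF2-3, IFOF, CST, FAT, Ci;
  left/right) is summarized by three scalars against a group map: fraction
  of bundle voxels with nonzero frequency, mean frequency and max frequency.
  Three scalars are reported because tract-level readings of such maps are
  qualitative ("hot spots"); we avoid committing to a single summary.
* **Laterality** — voxels with world x < 0 count as left (x = 0 counts as
  right, consistent with the half-open sagittal rule). The call is
  bilateral when the minority hemisphere holds ≥ 5% of the tumour volume
  (configurable); only the outcome distribution of such calls is published,
  not the rule, so the threshold is an explicit package choice.

## Statistical battery

Continuous variables: Kruskal–Wallis (tie-corrected H, chi-square df = k−1).
Tumour volume and grid-voxel count: Mood's median test — dichotomize at the
pooled median (ties to the "≤ median" side) and chi-square the k×2 table;
it is implemented literally as that composition so the two stages cannot
disagree. Categorical variables: Pearson chi-square, switching to Fisher's
exact test when any expected count is below 5 (the conventional rule; for
r×c > 2×2 the exact p is a seeded Monte-Carlo estimate over tables with the
observed margins, with an add-one correction). Normality gating uses the
Kolmogorov–Smirnov statistic with the Lilliefors correction, since the
normal parameters are sample-estimated. All p-values are two-sided.

Benjamini–Hochberg step-up adjustment is applied across **all** tests of a
battery run (the family size m is the number of tests actually run and is
logged). The module always works from raw p-values; censored strings such
as "<0.001" are never parsed, because a printed FDR column derived from
censored entries cannot be exactly re-adjusted.

## Prediction models

Symptom models are binary logistic regressions (maximum likelihood), with
Wald 95% CIs `exp(β ± 1.96·SE)` and Wald p-values for reporting.
Univariable mode fits each predictor alone. The multivariable model uses
forward-conditional selection: entry by Rao score test p < `p_enter`
(default 0.05), removal by likelihood-ratio test p > `p_remove` (default
0.10), ties broken by candidate order. The defaults are the common stepwise
conventions; they are configurable. Complete separation is detected
(standardized |β| > 15 or failed convergence) and the affected estimates
are flagged non-estimable rather than silently reported — odds-ratio CIs
spanning several orders of magnitude are a symptom of exactly this
fragility.

The diagnosis model is a baseline-category multinomial logit (reference
class configurable, default the IDH-mutated astrocytoma group), preceded by
a VIF collinearity check (flag at VIF > 10; exact collinearity reports
infinite VIF, flagged). Per-class metrics are one-vs-rest: sensitivity and
specificity from **argmax** class assignment (not a ROC-optimal threshold —
the alternative Youden reading is possible but not the default), AUC from
the class's predicted probability by trapezoidal rule (equal to the
tie-corrected rank statistic), and predictive values from the closed forms

    PPV = Se·π / (Se·π + (1 − Sp)(1 − π))
    NPV = Sp·(1 − π) / (Sp·(1 − π) + (1 − Se)·π)

at the observed prevalence π. For the published IDH-m astrocytoma model
(Se 43%, Sp 82%, prevalence 27.7%) these forms give NPV 79%, matching the
printed value; the corresponding printed IDH-wt and oligodendroglioma
PPV/NPV pairs do **not** back-compute from their printed Se/Sp/prevalence
via the same formulas, so those two pairs are documented here as
irreproducible from the printed inputs and are not asserted anywhere.

## Synthetic cohort generator

The generator emulates a three-subgroup cohort of 65 / 54 / 116 patients:

* **Age** — normal 38±13, 48±18, 42±14 years, truncated at 18 (adult
  inclusion); truncation shifts the realized means slightly upward, which we
  accept as the cost of respecting the bound.
* **Volume** — lognormal, moment-matched to 60±64, 53±61, 47±43 ml. A
  normal cannot produce SDs at or above the mean under positivity; the
  lognormal can, and matches both moments exactly in expectation.
* **Invasiveness** — negative-binomial grid-voxel count (mean 8,
  dispersion 4, clipped to 1..48), giving median ≈ 8 and IQR ≈ 4–11.
* **Seizure** — logistic in the grid-voxel count with slope ln(1.06) per
  voxel (default; per-group configurable), intercept calibrated by root
  finding so the marginal prevalence matches 0.523 / 0.444 / 0.664.
* **Other symptoms, sex, border, contrast, laterality, location** —
  independent categorical/Bernoulli draws at the published group rates.
  Independence between symptoms (and between symptoms and age/volume) is a
  documented simplification: the true covariance structure is unknown
  because patient-level data are not deposited.
* **Masks** — one ellipsoidal blob per patient, centred at the group's
  primary hotspot cell centroid (left fronto-insular for IDH-m astrocytoma,
  left posterior temporo-insular for IDH-wt, frontal for oligodendroglioma)
  plus Gaussian jitter (default SD 8 mm), with mildly anisotropic axes.
  Voxels are ranked by scaled distance and the closest k selected, so the
  realized volume matches the drawn volume within one voxel up to template
  clipping.

`simulate_cohort` re-derives the invasiveness column from the generated
masks (grid occupancy) and re-draws seizure from the logistic link on that
*measured* count, so the generative mechanism is the one the analysis
pipeline can actually observe. `simulate_covariates` alone keeps the drawn
count, which is what the slope-recovery harness uses.

What passing tests on this generator do **not** show about real data:
tumours are convex blobs without infiltrative texture or tract-following
growth; registration error is absent; symptoms lack their real covariance;
hotspots are imposed rather than emergent. The generator verifies the
*pipeline*, not the biology.

## Numerical and testing choices

Problem sizes: the recovery harness refits 500 replicates of the full-size
(n = 235) covariate table for both the ln(1.06) slope and the null; the
hotspot-recovery check runs 10 seeds of 12-patients-per-group cohorts on a
24×28×24 voxel 4 mm toy template, where one cohort simulates in well under
a second. Moment-convergence checks use 10⁴–4×10⁴ draws.

The Kruskal–Wallis permutation cross-check enumerates all 34 650 group
assignments of a fixed n = 12 dataset; the chi-square approximation tracks
the exact permutation p closely at moderate p (difference ≈ 0.002 on the
frozen fixture) but can deviate beyond 0.01 in far tails at this sample
size, which is an inherent property of the approximation, not a defect.

Percent formatting in report tables is round-half-up to one decimal.
Degenerate inputs raise typed errors (`braingrid.errors`); battery
variables that are degenerate in a given cohort (e.g. a symptom absent from
every patient of a small simulated cohort) are skipped with a logged
warning rather than aborting the run. All randomness flows from explicit
integer seeds through `numpy.random.default_rng`; regeneration under the
same seed is bit-identical, including mask volumes and downstream CSVs.
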
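# Methods

## The quantification model

The package measures bone-marrow (BM) tumor burden on co-registered FDG
PET/CT as follows. A bone mask is split into the *axial skeleton* and the
*extremities*, with the skull removed (physiological brain uptake makes it
unreadable). Each of ten threshold approaches assigns one SUV threshold per
compartment, built either from reference organs measured in the same patient
— the liver SUV median or mean, or four times the muscle SUV median — or
from an absolute SUV constant (2.0, 2.5 or 3.0). A voxel is segmented as
pathological when its SUV is **greater than or equal to** its compartment's
threshold; the comparison is deliberately inclusive, so a voxel exactly at
the threshold counts. The metabolic tumor volume is

    MTV [mL] = (number of segmented voxels) × (voxel volume in mm³) / 1000

and the total lesion glycolysis is

    TLG [g] = SUVmean(segmented voxels) × MTV,

with SUVmean computed over the segmented voxels only. An empty segmentation
is a valid result and reports MTV = TLG = 0: the strictest thresholds are
*expected* to find nothing in mildly diffuse disease, and that contrast is
informative. Axial and extremity segmentations are disjoint by construction;
whole-body values are their union. MTV/TLG are reported at full precision;
tables round to 0.1 for display only.

Reference statistics use all voxels of the full liver and muscle masks (no
sub-VOI sphere): full-mask medians are deterministic and reproducible,
whereas a manually placed VOI is not. With an even voxel count the median is
the midpoint of the two central values.

## Anatomy and refinement

On phantom data the anatomical scaffold comes from the ground-truth label
map (closed vocabulary in `bmquant/data/labels.json`; the lumbar spine has
its own label — it is part of the axial skeleton but is also the site where
the diffuse Deauville score is read). On CT the skeleton stand-in is a
Hounsfield threshold (default 150 HU, well above soft tissue) followed by
morphological closing; this replaces a learned organ segmentation because
organ segmentation is not what this package is about — the quantification
downstream of any adequate mask is.

Spillover mitigation counters PET's limited resolution, which bleeds liver
and blood-pool signal into adjacent bone: bone masks are eroded (default 1
voxel, full 26-neighbourhood) and voxels within a configurable margin
(default 0 mm = off) of the liver/mediastinum are removed. Both steps are
contractive — the refined mask is always a subset — so refinement can only
reduce MTV, never inflate it. Refinement runs before thresholding; the order
is configurable but subset-monotonicity makes the refined-first order the
conservative one. All morphology and connectivity use the 26-neighbourhood;
grids are voxel-indexed and assumed co-registered (no resampling).

## IMPeTUs reading

Deauville boundaries follow the 5-point convention: 1 — no uptake at all
(at or below a small epsilon, default SUV 0.1); 2 — at or below the
mediastinal blood pool; 3 — above blood pool, at or below liver; 4 — above
liver + 10%; 5 — at or above twice liver. Two gaps in the verbal scale had
to be closed: uptake in the (liver, liver + 10%] band is scored 3
(conservative, continuous with the score-3 rule), and "much greater than
liver" for score 5 is read as a factor-2 rule. The score is monotone
nondecreasing in the target by construction.

Focal-lesion detection has no canonical numeric definition; here a candidate
voxel must reach `detection_factor` (default 2.0) times the diffuse marrow
background, and a lesion is a 26-connected component of at least
`min_volume_voxels` (default 3) candidates. The background is the *median*
SUV over the bone mask rather than the mean, so that the lesions being
detected do not inflate their own detection threshold. Components are
searched outside the physiological organs (liver, muscle, blood pool):
those touching the analysis skeleton are focal medullary lesions, those also
extending into soft tissue raise the PMD flag, and those entirely outside
bone raise the EMD flag. Pure-skull components are not read, consistent with
the skull exclusion. Lytic lesions on CT are components of HU ≤ 40 inside
bone (min 3 voxels) — a phantom-friendly proxy, not a clinical criterion.
Fracture presence is taken from the phantom annotation; automated fracture
detection is out of scope. When the mediastinum mask is missing, the
Deauville items are reported as unavailable rather than guessed. Location
tags are driven by the label map; only the lumbar label identifies "spine",
so generic axial bone tags as "other" (a documented limitation of the
phantom vocabulary). The module is a single deterministic reader; modeling
two-reader consensus is out of scope.

## Survival statistics

All times are in months; p-values are two-sided at the 0.05 level; **no
multiple-testing correction** is applied — the analyses are exploratory and
labelled as such. Kaplan–Meier, log-rank and Efron-ties Cox regression run
through lifelines; `ties="breslow"` routes through statsmodels PHReg.
Median survival is the first time the KM curve reaches 0.5 and is reported
as not reached (∞) when the curve never does. Median follow-up uses the
inverse-KM estimator (event/censoring indicators swapped); with no censored
subject it is not estimable and is flagged. Quantitative markers are
dichotomized at their median with ties going to the low group (the high
group is *strictly above* the median).

The 2-year outcome is binary: positive = event at or before 24 months,
negative = followed beyond 24 months, censored-before-horizon = excluded.
The ROC is the empirical curve over all cuts; the optimal cut maximizes the
Youden index (sensitivity + specificity − 1) over midpoints between
consecutive distinct marker values, ties broken toward the lower cut; the
AUC confidence interval and the test of AUC = 0.5 use DeLong's variance
(validated against R's pROC on a frozen fixture). A time-dependent IPCW
variant (`method="ipcw"`) that keeps censored subjects with
inverse-probability-of-censoring weights is available because both designs
are defensible for a 2-year endpoint; the binary design is the default, and
the IPCW mode reports no DeLong CI (it does not apply to weighted AUCs).

ISS staging: stage I requires β2-microglobulin < 3.5 mg/L **and** albumin ≥
3.5 g/dL; stage III is β2-microglobulin > 5.5 mg/L; everything else is II.
R-ISS I requires ISS I with no high-risk cytogenetics and normal LDH; R-ISS
III requires ISS III with high-risk cytogenetics or elevated LDH; all other
combinations are II.

## What the synthetic data emulates — and what it does not

Phantoms are axis-aligned boxes (spine with a lumbar segment, two extremity
columns, skull, liver, muscle, mediastinum) on a 48×48×64 grid at 2 mm
isotropic spacing, with spherical lesions defined by the exact voxel-centre
sphere inequality, so planted volumes are exact and recovery can be asserted
with zero tolerance. Uptake defaults: liver 2.0, muscle 0.6, blood pool 1.5,
soft tissue 0.4, marrow baseline 0.8 plus a diffuse increment of 2.5 × the
infiltration fraction — at the cohort-typical infiltration of 0.38 the
marrow sits between blood pool and liver (diffuse Deauville 3). CT is
two-valued (bone 700 HU, soft tissue 40 HU) with optional lytic spheres at
20 HU. Noise is i.i.d. Gaussian on SUV, default sd 0.05 — small relative to
the SUV contrasts, keeping medians stable. Phantoms emit SUV directly; dose,
weight and decay normalization are upstream of this pipeline, which consumes
SUV images (body-weight vs lean-mass convention is therefore the caller's
concern). Not modelled: scanner physics (scatter, partial-volume PSF,
reconstruction), anatomical shape realism, DICOM. Passing tests demonstrate
the *logic* of thresholding, reading and statistics; they say nothing about
segmentation quality on real anatomy.

Cohorts (default 44 subjects, the scale of a single-centre study) draw event
times from an exponential proportional-hazards model: baseline hazard
0.015/month, log-hazard 0.0012 per mL of MTV and 0.6 for high-risk
cytogenetics; MTV is log-normal (median 150 mL, log-sd 1.0, matching the
skewed published ranges) and shares a Gaussian latent with the marrow
infiltration fraction (ρ = 0.5), reproducing moderate MTV–infiltration
correlation and realistic multivariable confounding. Censoring is
administrative at 110 months (the study's median follow-up) plus 10%
uniform dropout. The hazard model is exactly proportional — Cox recovery
checks test estimation, not robustness to misspecification.

## Numerical choices and problem sizes

Calibration studies use cohorts of n = 500 with 200 replicates for CI
coverage and 400 for type-I error, 1000 replicates of n = 100 for the
log-rank null, and n = 2000 for closed-form KM checks — sizes at which the
Monte-Carlo error of a coverage proportion (~1.5%) is well inside the
asserted bands. Oracle-equivalence fuzzing uses 1000 random 8×8×8 grids
against a literal voxel loop. TLG equals SUVmean × MTV to 1e-9 relative by
regression test. All generators and experiments are pure functions of their
seed; replicate seeds are spawned from one parent seed.

## Known limitations

Box-and-sphere geometry cannot probe partial-volume effects or mask
misregistration; the HU-threshold skeleton stand-in is not a validated
segmenter for clinical CT; the focal-lesion criterion and the lytic-lesion
proxy are parameterized conventions, not clinically validated definitions;
the spillover refinement exposes parameters rather than reproducing any
specific published postprocessing recipe.
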
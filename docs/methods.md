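# Methods

## Perfusion model

`neoperf` quantifies cerebral blood flow from pulsed ASL with the
single-compartment model

    CBF = 6000 · λ · ΔM · exp(TI / T1b) / (2 · α · TI1 · M0b)

where ΔM is the time-averaged control−label difference signal. The model
assumes a single well-mixed tissue compartment, complete bolus delivery
within the inversion time, and label decay with the T1 of blood; it does
not model arterial transit times, dispersion, or multi-compartment
exchange. All time constants enter the expression in the unit they are
declared in (milliseconds throughout this package); the `unit_factor` of
6000 converts ml/g/s to the customary ml/100 g/min. CBF is linear in ΔM
and inversely proportional to M0b, which the tests exploit
(linearity, scale equivariance, monotonicity in TI).

The equilibrium magnetization of arterial blood is calibrated per tissue
class from a proton-density image M0:

    M0b_i = R_i · M0_i · exp(TE / T2_i − TE / T2b),  i ∈ {CSF, WM, GM}

with M0_i the mean M0 intensity over class i and R_i the proton-density
signal ratio of tissue to blood. Each brain voxel receives the M0b of its
own tissue class. A single global M0b would also be defensible; the
per-class map is the only interpretation under which the "per-tissue"
calibration actually affects the voxelwise formula, which is why it is the
default here.

### Parameters (neonatal, 3 T)

| symbol | meaning | default | unit |
|---|---|---|---|
| λ | blood–brain partition coefficient | 1.10 | mL/g |
| T1b | longitudinal relaxation of blood | 1825 | ms |
| T2b | transverse relaxation of blood | 191 | ms |
| α | PASL labeling efficiency | 0.98 | – |
| TI1 | bolus duration | 700 | ms |
| TI | inversion time | 1800 | ms |
| TE | echo time | 14 | ms |
| R_CSF, R_WM, R_GM | tissue/blood PD signal ratios | 0.87, 1.19, 0.98 | – |
| T2_CSF, T2_WM, T2_GM | tissue T2 | 250, 222, 143 | ms |
| thresholds | T2 segmentation (CSF, WM) | 0.95, 0.75 | normalized intensity |

### Tissue segmentation semantics

The thresholds 0.95/0.75 are applied to T2 intensities rescaled by the
99th-percentile maximum inside the brain mask (a robust maximum, so a few
bright voxels cannot shift every class boundary). Voxels ≥ 0.95 are CSF,
[0.75, 0.95) WM, < 0.75 GM; both lower bounds are closed. Class ordering
reflects neonatal T2 contrast: CSF brightest, unmyelinated white matter
brighter than gray matter. Whether the original thresholds were meant for
max-normalized, CSF-referenced, or raw intensities is not determinable from
their statement alone; this package fixes and documents the robust-max
convention, and the synthetic tissue baselines (T2 1000/850/600 for
CSF/WM/GM) are chosen to land each class on the correct side of it.

## Preprocessing

Subtraction is realized pairwise (one difference volume per label/control
pair) and then averaged over retained pairs. When no pair is discarded this
equals subtracting the time-averaged means, but the pairwise form is what
makes *time-point* outlier rejection possible. The outlier statistic is
each pair's spatial-mean difference over the brain mask; pairs deviating
from the across-pair median by more than `outlier_k` robust standard
deviations (1.4826·MAD) are dropped, with `outlier_k = 2.5` by default and
at least two pairs always kept. The median/MAD are always computed from all
pairs, making the operation a pure function of the data and hence
idempotent. The brain mask is M0 > 20% of its robust maximum.

Motion correction estimates a 6-DOF rigid transform per volume against the
time-mean image: a coarse axis-wise integer-voxel search initializes a
Nelder–Mead refinement of the mean-squared-intensity cost, with trilinear
resampling. Two register-to-mean passes are used so that a single moved
volume does not bias its own reference. Registration is off by default
because the synthetic data are generated pre-aligned; spatial smoothing
(Gaussian, FWHM in mm, 0 = off) and an optional temporal moving average are
likewise off by default so that the noiseless round trip is exact.
The 4D series is stored label-first; the reader accepts either order via a
flag or the NIfTI header description.

## Synthetic cohorts

The generator emulates the acquisition and cohort structure the pipeline
targets: 45 label/control pairs, 2.8×2.8×6.0 mm voxels on a reduced 64-like
matrix (default 32×32×14), and groups of 18 controls / 40 HIE with normal
conventional MRI / 15 HIE with abnormal MRI. A deterministic toy atlas
packs 14 box regions (2 CSF, 4 WM, 8 GM; ventricles, corona radiata,
corpus callosum, caudate, frontal/precentral cortex, thalamus, putamen,
cerebellum, brainstem, occipital cortex) with neonatally plausible baseline
CBF (deep gray ≈ 20–25, white matter ≈ 9–10 ml/100 g/min).

Per subject, planted regional CBF = baseline × group effect × covariate
effects × between-subject lognormal jitter (`subject_cv`, default 0.15).
The voxelwise ΔM is obtained by *inverting* the quantification model with
the same tissue-wise M0b the quantifier will compute, so at zero noise the
pipeline recovers the planted values to machine precision — the package's
central testing device. Age and sex act multiplicatively on gray-matter
regions only (postnatal perfusion maturation is predominantly a gray-matter
phenomenon); a global covariate effect would cancel exactly under
whole-brain normalization and would be unidentifiable downstream. Ages are
uniform on [1, 30] days, bracketing the target cohorts' means; sex is
Bernoulli(0.5).

Outcome scores live on the Bayley composite scale (intercept 100) and equal
intercept + Σ_r w_r · (normalized regional CBF)_r + Gaussian noise, with
independent noise per score type. Outlier acquisition pairs occur with
probability `outlier_rate` and have their difference noise inflated by
`outlier_scale`.

What the generator does **not** emulate: coil sensitivity and B0
inhomogeneity, partial-volume mixing beyond the three tissue classes,
realistic head motion, arterial transit effects, or anatomically shaped
regions. Passing tests therefore demonstrate correctness of the analysis
chain under its own signal model, not robustness to every artifact of real
neonatal ASL.

## Regional statistics

Regional means are taken over each region's defined (finite) voxels and
divided by the subject's whole-brain mean CBF, so the analyzed quantity is
relative perfusion; per subject the voxel-weighted mean of normalized
values is 1 by construction. Age and sex are removed per region by OLS on
(intercept, age, sex) fitted over the pooled two-group sample — pooling
preserves group contrasts — and residuals are re-centered at the grand
mean. Because normalization makes covariate effects mildly nonlinear
(a ratio of affine functions), the linear fit removes most but not all of
the planted covariate variance; tests assert a ≥10-fold variance reduction
rather than exact zero.

The group test is a two-sided permutation test on T = mean(B) − mean(A)
(difference of means by default; Welch-t available). When C(n_A+n_B, n_A) ≤
20 000 all relabelings are enumerated and p is the exact fraction with
|T| ≥ |T_obs| — the identity relabeling is included, so p > 0 and no
add-one smoothing is applied, keeping exhaustive p-values exact rationals.
Otherwise N seeded Monte-Carlo relabelings are drawn and
p = (1 + exceedances)/(1 + N). A tie tolerance of 1e-12 relative to |T_obs|
absorbs floating-point rounding of relabelings that are exact rational ties
(identity, mirrored splits); for continuous data no other ties occur.
Significance is uncorrected p < α (α = 0.05) across regions, matching how
such regional tables are conventionally reported; Benjamini–Hochberg is
available behind a flag. Reported group means ± SD are on the normalized
scale before covariate adjustment; p-values come from the adjusted values.

## Outcome prediction

Features are the normalized perfusion values of significant regions:
experiment 1 uses the control-vs-HIE/MRI⊖ contrast and predicts within the
HIE/MRI⊖ group; experiment 2 concatenates the regions of the within-HIE
contrast and the control-vs-all-HIE contrast (deduplicated, provenance
kept) and predicts in the combined HIE group. For each left-out unit,
standardization, PCA (k components) and OLS are fitted on the training
units only; the held-out unit's outcome can never reach its own prediction.
The cross-validation unit defaults to *subject* — all of a subject's
repeated assessments leave together, preventing leakage between records of
one child — with a record-level mode available. k is chosen from a grid
(default 1–5, capped at min(n−2, n_features)) by maximizing the pooled
out-of-fold Pearson r; the reported p-value is the two-sided t-transform
r·sqrt((n−2)/(1−r²)) at the pooled prediction count. A nested variant that
selects k inside each training fold is provided.

Two honest properties of this estimator are worth knowing. First, pooled
LOOCV correlation is *negatively* biased under the null (the training mean
anti-correlates with the left-out observation): at n = 30 with five
features and the default grid the null mean r is about −0.04 with ~13% of
runs nominally significant at 0.05; with only two features and a two-value
grid the bias reaches ≈ −0.16. Second, choosing k post hoc by maximizing
the pooled r is optimistic; the single r it reports should be read with
that selection in mind (or the nested mode used).

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run entirely on generated data:
model-oracle agreement on 1000 random voxels; exact recovery on a
six-subject noiseless cohort at 32×32×14 with 45 pairs; permutation
exactness on 50 small datasets (total n ≤ 12) against brute-force
enumeration; null calibration with 2000 replicates of 18 vs 40; detection
of planted 25% deficits in five regions over 18 vs 40 cohorts across
multiple seeds (between-subject CV 0.20, voxel noise SD 10); outlier
recovery on 45-pair series with three pairs displaced 10 robust SDs
(flagging threshold at half the displacement); LOOCV recovery at n = 30
with outcome noise matched to the planted signal SD (exact R² = 0.5); and a
73-subject end-to-end run on a 30×30×12 grid with 20 pairs. These sizes
are the package's own choices for routine verification; all scale up by
configuration.

## Known limitations

- The kinetic model consumes TI/TI1 in milliseconds as stated; with
  physically typical ΔM/M0 fractions this yields small absolute CBF
  numbers, and the synthetic generator plants correspondingly scaled
  signals. Relative perfusion — the quantity all statistics use — is
  unaffected by this convention.
- Whole-brain normalization couples regions: a deficit confined to some
  regions necessarily raises the normalized values of the others. The
  detection checks budget for this (specificity is bounded, not zero).
- Rigid registration assumes same-modality, small-motion alignment within
  a series; no slice-timing, distortion, or cross-modality registration is
  attempted, and T2→M0 alignment is assumed exact for synthetic data.
- The toy atlas is geometric; results on it validate the machinery, not
  anatomical claims.
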
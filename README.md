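# neoperf

Quantification and analysis of cerebral perfusion in neonates with
hypoxic-ischemic encephalopathy (HIE), from pulsed arterial spin labeling
(PASL) MRI.

HIE is a leading cause of neonatal brain injury, and conventional MRI can be
normal even when an injury has occurred. Regional cerebral blood flow (CBF)
measured with ASL is a candidate early marker: perfusion deficits appear in
specific structures (corona radiata, caudate, frontal and precentral
cortex), and regional perfusion carries information about later language and
motor development. `neoperf` implements the full analysis chain for this
setting as a tested, reusable Python package:

1. **Preprocessing** of the 4D label/control PASL series: rigid motion
   correction to the time-mean image, optional spatial smoothing, pairwise
   control−label subtraction, and robust rejection of outlier acquisition
   time points (median/MAD on each pair's spatial-mean difference).
2. **Quantification** with the single-compartment PASL model, calibrated
   for the neonatal brain at 3 T:

   ```
   CBF = 6000 · λ · ΔM · exp(TI/T1b) / (2 · α · TI1 · M0b)   [ml/100 g/min]
   M0b_i = R_i · M0_i · exp(TE/T2_i − TE/T2b),  i ∈ {CSF, WM, GM}
   ```

   where ΔM is the time-averaged control−label difference, λ = 1.10 mL/g the
   blood–brain partition coefficient, T1b = 1825 ms and T2b = 191 ms the
   relaxation times of neonatal blood, α = 0.98 the labeling efficiency,
   TI1 = 700 ms the bolus duration and TI = 1800 ms the inversion time. The
   equilibrium blood magnetization M0b is calibrated per tissue class from a
   proton-density image, with tissue classes obtained by thresholding the
   normalized T2-weighted image at 0.95 (CSF) and 0.75 (WM); time constants
   enter the formulas in the milliseconds they are stated in.
3. **Regional group statistics**: atlas-based regional means, normalization
   of every subject to their own whole-brain mean CBF (the analyzed quantity
   is *relative* perfusion), linear removal of age and sex effects, and
   two-sided permutation tests per region — exhaustive enumeration when
   feasible, seeded Monte-Carlo otherwise. Four contrasts are run: controls
   vs HIE with normal MRI, HIE normal-MRI vs abnormal-MRI, controls vs
   abnormal-MRI, and controls vs all HIE.
4. **Outcome prediction**: Bayley-style cognitive/language/motor scores are
   predicted from the normalized perfusion of regions found significant in
   the group comparisons, using PCA dimensionality reduction plus linear
   regression under leave-one-out cross-validation, with the PCA dimension
   chosen by grid search.

Because no patient images ship with the package, a first-class
**synthetic-data module** generates complete co-registered cohorts (ASL
series, M0 and T2 images, toy atlas, demographics, outcome scores) whose
signal model exactly inverts the quantification model — the planted regional
CBF is recoverable to machine precision at zero noise, so every downstream
stage is testable end to end.

## Worked example

Quantify one noiseless synthetic subject and compare against the planted
ground truth:

```python
import neoperf as nf

config = nf.SimulationConfig(
    groups=(("control", 1),), n_pairs=45, noise_sd=0.0, subject_cv=0.15, seed=4,
)
subjects, atlas = nf.simulate_cohort(config)
s = subjects[0]
cbf = nf.quantify_subject(s.asl, s.m0_image, s.t2_image, config.quant_params)
norm = nf.normalize_to_whole_brain(nf.regionalize(cbf, atlas), cbf)
```

which prints, formatting a few regions:

```
subject sub-001: age 27.2 d, sex F, retained pairs 45/45
region                                     CBF   truth   norm
anterior corona radiata                 10.724  10.724  0.503
caudate                                 18.712  18.712  0.879
precentral gyrus                        29.265  29.265  1.374
thalamus                                27.165  27.165  1.275
```

The quantified regional CBF (ml/100 g/min) equals the planted truth because
the series is noiseless; `norm` is each region relative to the subject's
whole-brain mean, the quantity used in all group statistics.

The full pipeline — simulate a 73-subject cohort (18 controls, 40 HIE with
normal MRI, 15 with abnormal MRI), quantify, run all four group comparisons
and both prediction experiments — is one command:

```sh
neoperf run --out results_demo --seed 7
```

It writes `regional_table.csv`, `comparison_*.csv` (regions sorted by
permutation p, with group means ± SD and direction of change),
`experiment_{1,2}_summary.json` (per-outcome LOOCV Pearson r, p, chosen PCA
dimension) and a provenance record. Individual stages are also exposed as
`neoperf simulate | preprocess | quantify | compare | predict`, and
`neoperf params --show` prints the quantification defaults.

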
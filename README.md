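# adbrainage

Brain-age-gap (BAG) analysis for autosomal dominant Alzheimer disease
(ADAD) cohorts.

"Brain-predicted age" models estimate biological age from structural MRI;
the gap `BAG = predicted − chronological age` rises when a brain appears
older than it is. In ADAD, carriers of pathogenic *PSEN1*, *PSEN2* or
*APP* variants progress on a predictable clock indexed by **EYO**
(estimated years to symptom onset = age − expected onset age), which
makes the disease timecourse of BAG measurable. This package is for
biostatisticians and neuroimaging researchers who have per-participant
predicted ages (e.g. from a CNN such as DeepBrainNet) plus demographics,
site/scanner labels, fluid/PET biomarkers and cognitive scores, and want
the full downstream analysis:

1. **Calibration** — fix regression dilution by fitting
   `raw ~ α + β·age` in non-carrier controls and rescaling
   `corrected = (raw − α)/β`; report NC accuracy (r, identity-line R²,
   MAE, RMSE on *uncorrected* predictions) and ICC(A,1) test-retest
   reliability.
2. **Harmonization** — single-variable empirical-Bayes ComBat across
   sites, preserving age, sex, education, group, EYO, APOE ε4 and
   variant effects, with Kruskal–Wallis batch checks pre/post.
3. **Trajectories** — generalized additive mixed models
   `BAG ~ group + s(EYO, by=group, k=4) + sex + education + APOEε4 +
   (1|family)` with cubic regression splines and REML smoothing;
   simulation-based simultaneous 83.4% confidence bands; the earliest
   EYO of sustained carrier/non-carrier band separation; and a
   stratified participant bootstrap comparing divergence EYOs across
   MRI measures.
4. **Associations** — Kruskal–Wallis + FDR-corrected Wilcoxon group
   tests, Levene checks, Cohen's d, family-clustered mixed models with
   group × biomarker interactions, within-group correlations,
   log-transform sensitivity, and non-parametric bootstrap mediation of
   biomarker → BAG → cognition.

Real ADAD cohort data are restricted-access, so the package includes a
synthetic cohort generator (`adbrainage.cohort`) that emulates the
group sizes, demographics, family clustering, batch structure, carrier
divergence ramp and biomarker correlation magnitudes of such a study —
with ground-truth columns (`true_*`) so every stage has a
parameter-recovery test. See `docs/methods.md` for the model details and
design choices.

## Worked example

Simulate a blinded-ready cohort, calibrate, then model the trajectory:

```bash
$ adbrainage simulate --seed 1 --out cohort.csv
wrote 436 rows to cohort.csv

$ adbrainage calibrate --cohort cohort.csv --out bag.csv
calibration: slope=1.0084 intercept=1.537 (n=179)
NC performance: r=0.845 R2=0.565 MAE=5.90 RMSE=7.38
```

The calibration slope/intercept come from the 179 non-carriers; r is the
Pearson correlation between uncorrected predicted and true age, and R2
is measured against the identity line (which is why it is well below
r²). MAE/RMSE are in years.

After harmonizing and attaching a `bag` column (see
`adbrainage harmonize`, or `run-all` below which chains everything):

```bash
$ adbrainage trajectory --cohort bag_cohort.csv --measure bag --out bands.csv
MC smooth: EDF=2.98 p=1.1e-97; earliest divergence: -1.51 EYO

$ adbrainage associate --cohort bag_cohort.csv --biomarker plasma_ptau181 --out assoc.csv
plasma_ptau181: interaction F(2,415)=7.59 p=0.000577

$ adbrainage mediate --cohort bag_cohort.csv --biomarker plasma_ptau181 --out med.json
indirect=-0.081 [-0.109, -0.053] (partial)
```

The carrier smooth is clearly nonlinear (EDF 2.98 of a maximum 3,
p ≈ 1e-97); carriers' BAG separates demonstrably from non-carriers 1.5
years before expected onset in this run — note this band-certified
divergence is conservative relative to the true onset of separation (the
generator's ramp starts at −7; see the methods note on estimator bias).
The biomarker interaction says the plasma pTau-181/BAG slope differs by
group, and BAG partially mediates the pTau → cognition association
(indirect effect −0.081, 95% bootstrap CI excluding 0, with a direct
path remaining).

`adbrainage run-all --seed 1 --out results/` executes the whole pipeline
on the packaged demo configuration and writes the BAG table, performance
and reliability reports, harmonization report, band tables, divergence
summary, association and mediation tables, and a manifest that makes
deterministic stages byte-for-byte reproducible.

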
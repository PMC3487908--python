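# rehoscope

Regional-homogeneity (ReHo) analysis of resting-state BOLD fMRI within the
default mode network (DMN), packaged as a reusable pipeline for two-group
clinical comparisons — for example bipolar depression (BD) patients against
healthy controls (HC) — together with a synthetic cohort simulator that
makes the whole analysis runnable and testable without any scan data.

## What it computes

ReHo measures the *local temporal synchrony* of spontaneous low-frequency
(0.01–0.08 Hz) BOLD activity. For every brain voxel, the time series of the
voxel and its K−1 nearest neighbours (K ∈ {7, 19, 27}) are ranked over the
n retained time points, and Kendall's coefficient of concordance is formed
from the rank sums R_i:

    W = 12 Σᵢ (Rᵢ − R̄)² / (K²(n³ − n) − K Σⱼ Tⱼ),   R̄ = K(n + 1)/2,

where Tⱼ is the standard tie correction for series j (midranks are used;
continuous BOLD data is effectively tie-free). W ∈ [0, 1]: 1 means the K
neighbouring series rise and fall in perfect unison.

The full pipeline:

1. **Preprocess** (per subject): discard the first 10 volumes, motion QC
   (maximum excursion ≤ 2 mm translation and ≤ 2° rotation per plane),
   nuisance regression (6 motion parameters, linear drift, global mean
   signal), ideal band-pass 0.01–0.08 Hz.
2. **ReHo**: voxelwise Kendall's W over the 27-neighbourhood, division by
   the in-mask mean (mReHo), Gaussian smoothing (FWHM 4 mm).
3. **DMN mask**: temporal-concatenation group ICA (per-subject PCA →
   concatenation → group PCA → Infomax spatial ICA → GICA back-
   reconstruction), MDL model-order estimation, template-matched DMN
   component selection, and a voxelwise one-sample t-test with Bonferroni
   family-wise-error control (α = 0.05) to form the group mask, split into
   anterior/posterior parts.
4. **Group statistics**: voxelwise two-sample comparison of the mReHo maps
   inside the DMN mask (linear model with age and sex covariates), cluster-
   extent thresholding (two-sided voxel p < 0.01, clusters > 12 voxels,
   26-connectivity), ROI mean extraction, Pearson correlations with clinical
   variables (HAMD, illness duration, number of depressive episodes, …) in
   the patient group, and demographic group tests (uncorrected chi-square
   for sex; pooled two-sample t for age/education).

The simulator plants group differences in the shared-variance fraction ρ of
a band-limited signal inside DMN-template spheres (ρ is the expected
pairwise in-region correlation after filtering), on top of spatially smooth
noise, linear drift, a global signal, and bounded-random-walk motion traces.

## Worked example

```python
from rehoscope import RunConfig, run_pipeline, render_report

config = RunConfig(out_dir="demo_run", profile="smoke", seed=5)
print(render_report(run_pipeline(config)))
```

which prints (smoke profile: 3+3 simulated subjects on a 16×16×8 grid,
40 volumes, identical ρ in both groups — so no group difference exists):

```
rehoscope run report — demo_run

== Supra-threshold clusters ==
no significant clusters

== Clinical correlations (BD group) ==
no regions to correlate

== Demographics ==
 variable  bd_summary  hc_summary  statistic test  df        p
      sex         1:2         1:2   0.000000 chi2   1 1.000000
      age 30.53±10.62 44.10±13.27   1.382595    t   4 0.238967
education  10.30±2.17  12.23±1.10   1.379389    t   4 0.239874
```

"No significant clusters" is the correct answer here: the smoke cohort
plants the same synchrony in both groups. Planting ρ_BD = 0.6 against
ρ_HC = 0.3 (the `scaled` profile defaults, 15+15 subjects at 32×32×16×120)
makes the planted region appear in the cluster table with peak t ≈ 7–12 and
Dice overlap ≈ 0.7 against the planted mask.

The same stages are available from the shell:

```bash
rehoscope simulate --out data --smoke --seed 2
rehoscope preprocess --bold data/bd001_bold.nii.gz --motion data/bd001_motion.txt \
    --mask data/brain_mask.nii.gz --out pre.nii.gz --qc-report qc.tsv
rehoscope reho --bold pre.nii.gz --mask data/brain_mask.nii.gz --out mreho.nii.gz
rehoscope run --seed 5 --out demo_run
```

## Layout

- `rehoscope.core_io` — NIfTI / motion / cohort-table readers and writers
- `rehoscope.synth` — synthetic cohort generator and DMN template
- `rehoscope.preprocess` — volume discard, motion QC, nuisance regression,
  band-pass
- `rehoscope.reho` — Kendall's W maps, normalization, smoothing
- `rehoscope.group_ica` — group ICA, MDL order, Infomax, DMN mask
- `rehoscope.group_stats` — voxelwise GLM, cluster thresholding, clinical
  correlations, demographics
- `rehoscope.pipeline` / `rehoscope.cli` — end-to-end orchestration
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
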
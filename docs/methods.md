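# Methods

## The statistic

Regional homogeneity is Kendall's coefficient of concordance W computed over
the time series of a voxel and its nearest neighbours. With K series of
length n, within-series midranks, rank sums Rᵢ across series at time point
i, and R̄ = K(n+1)/2,

    W = 12 Σᵢ (Rᵢ − R̄)² / (K²(n³ − n) − K Σⱼ Tⱼ),

where Tⱼ = Σ (t³ − t) over tie groups of series j. The tie correction is
included even though band-passed BOLD series are effectively tie-free:
results are identical either way on continuous data, and the corrected form
is the defensible general implementation. W is clipped to [0, 1] against
negative round-off; a neighbourhood whose corrected denominator is ≤ 0 (all
series constant) scores 0 and is logged.

Neighbourhoods are K = 7 (faces), 19 (faces+edges) or 27 (full 3×3×3 cube),
always including the centre voxel; the default is 27. At mask edges the
neighbourhood is restricted to its in-mask members (effective K′ ≥ 2), the
convention of the standard resting-state toolchains, rather than dropping
edge voxels; per-map counts of reduced neighbourhoods are logged. Voxelwise
maps are divided by the in-mask mean (mReHo, in-mask mean exactly 1 before
smoothing) and then smoothed with a separable Gaussian whose per-axis sigma
honours the voxel size (σ_axis = FWHM/(2√(2 ln 2))/voxel size). The order —
KCC, normalize, smooth — is fixed and recorded in the run log; smoothing a
normalized map leaves its in-mask mean ≈ 1 but no longer exactly 1.

## Preprocessing

Per subject, in fixed, logged order: (1) discard the first 10 volumes;
(2) motion QC — per-plane maximum excursion (max − min over retained time
points) of the three translations (mm) and three rotations (degrees), pass
iff all ≤ 2 mm / 2°; (3) nuisance regression — per-voxel least-squares
residual against intercept, the 6 motion parameters, a mean-centred linear
drift, and the global (brain-mean) signal; (4) band-pass. Regression
precedes filtering. Motion files recorded before the discard are truncated
to the retained rows. The global signal is computed from the post-discard,
unfiltered data; whether the original toolchains computed it before or
after drift removal is not documented, so this choice is stated rather than
guessed.

The band-pass is an ideal rectangular filter in the DFT domain: coefficients
with 0 < f_lo ≤ f ≤ f_hi are retained, all others (including DC) zeroed.
No IIR/FIR family is claimed by the reference toolchain, and the ideal
filter makes the spectral post-conditions exact and testable: output means
are exactly zero, in-band tones survive up to leakage computable by a direct
DFT oracle, the filter is exactly linear.

## Group ICA and the DMN mask

Temporal-concatenation group ICA on the pooled cohort (both groups): the
mask used for the group comparison must be common to both groups, so
per-group decompositions are reporting extras, not pipeline inputs.

1. *Reduction.* Per-subject temporal PCA to d components (whitened), rows
   concatenated across subjects, group PCA to the model order g (whitened).
   Band-passed data has temporal rank roughly equal to the number of
   retained frequency bins, so d and g are additionally capped by the
   weakest subject's numerical rank. Retained variance is logged per
   subject.
2. *Order.* Wax–Kailath MDL on the eigenspectrum of the temporally
   concatenated, voxel-variance-normalized data; argmin clamped to
   [5, min(t−1, 40)]. On a flat (pure-noise) spectrum the criterion sits at
   the lower bound; the order can also be fixed explicitly.
3. *Unmixing.* Spatial ICA by batch natural-gradient Infomax with the
   logistic score (super-Gaussian sources — spatial brain maps are sparse),
   learning rate 0.1 halved on divergence and annealed by 0.98 when
   successive updates turn by more than 60°; convergence when the relative
   natural-gradient norm < 1e−6 (or the weight update < 1e−9); hard failure
   with diagnostics otherwise. A seeded FastICA fallback is available behind
   a flag. Components are canonicalized — ordered by explained variance,
   signs fixed so each map's skewness ≥ 0 — making the decomposition a pure
   function of (data, seed).
4. *Back-reconstruction.* GICA-style: subject maps Sᵢ = W Gᵢ Xᵢ through the
   subject's whitened data and its block of the group projector; time
   courses TCᵢ = Rᵢ⁺ Gᵢ⁺ A. Subject maps are z-scored over in-mask voxels.
5. *Selection and mask.* The DMN component maximizes the Pearson correlation
   between its |z| group map and a binary template (union of spheres at
   canonical DMN loci: medial prefrontal, posterior cingulate/precuneus,
   bilateral inferior parietal, lateral temporal, hippocampal); ties break
   to the lower index, a best score < 0.2 is an error. The group mask is the
   set of voxels whose subject z-maps pass a voxelwise one-sample t-test at
   Bonferroni-corrected α = 0.05 with positive t (zero-variance voxels are
   excluded and logged); it is split into anterior (world y > 0) and
   posterior parts for reporting. Downstream statistics use the full mask.

Bonferroni is used for the FWE step because the mask-construction method in
the source analysis names only "FWE"; random-field theory is out of scope.

## Second-level statistics

Per voxel inside the DMN mask, ordinary least squares of
mReHo ~ intercept + group + age (mean-centred) + sex (M=0, F=1), with the
t statistic for the group indicator (positive = patients higher); with no
covariates this reduces exactly to the pooled two-sample t-test. Cluster
thresholding keeps voxels with two-sided p < 0.01 (uncorrected), forms
connected components under 26-connectivity (corner-sharing; 6/18 available
behind a flag), and reports clusters whose size is strictly greater than 12
voxels — sizes in voxels and mm³ (from the affine determinant), peak voxel
and world coordinate, peak t, separately per contrast direction. The
combination "uncorrected voxel p + extent rule" is the conventional reading
of a voxel+cluster threshold pair; a voxelwise-corrected p together with an
extent rule would be internally inconsistent.

ROI means (per-subject mean mReHo over a cluster) are correlated with
clinical variables in the patient group only (Pearson; sex point-biserial
with M=0, F=1); p in (0.05, 0.10) is flagged as marginal, and no
multiple-testing correction is applied across the region × variable grid —
the output says so explicitly. Demographic tests: Pearson chi-square
without continuity correction for the sex ratio (the variant consistent
with the reference cohort table), pooled-variance two-sample t from summary
statistics for age and education.

## The synthetic cohort

The generator emulates a two-group resting-state study: grids of any size
share a fixed 192×216×156 mm field of view centred near the anterior
commissure, so canonical DMN loci in mm coordinates are valid on every
profile; the brain is an ellipsoid in world space. Defaults are the
paper-scale acquisition (64×64×33 voxels, TR 2 s, 240 volumes, 26 subjects
per group); a `scaled` profile (32×32×16, 120 volumes, 15 per group) is
used for the recovery experiments and a `smoke` profile (16×16×8, 40
volumes, 3 per group) for end-to-end plumbing. The smoke profile uses 3
subjects per group because with 2 per group the Bonferroni one-sample
t-test (df = 3) cannot clear the FWE threshold over the mask and the run
aborts on the documented empty-mask error path.

Voxel series inside each effect sphere are
√(1−ρ)·independent + √ρ·shared band-limited signals, both confined to the
analysis band, so ρ equals the expected in-region pairwise correlation
*after* band-pass filtering and is recoverable by measurement (bias < 0.05
in the suite). All effect spheres share one network time course by default
(`share_network_signal`), making the planted pattern a single spatial
component recoverable by group ICA; per-region signals are available. The
planted condition for the recovery experiments is ρ_HC = 0.3 vs ρ_BD = 0.6
at the DMN template spheres (15 mm radius). Background noise is broadband
white noise smoothed with a 1-voxel Gaussian so background ReHo is realistic
(> 0); linear drift slopes are drawn per voxel (SD 0.005 a.u./volume), a
shared low-frequency global component (amplitude 0.3 a.u.) spans the brain,
and motion traces are bounded random walks rescaled to per-axis excursions
inside the QC limits (QC-failure subjects get a 3 mm excursion on demand).
Clinical covariates are drawn to match the study summaries: HAMD truncated
normal 19.65±2.48 (floor 17), episodes rounded normal 3.44±1.45 (floor 1),
illness duration 4.20±1.70 years, group-specific age/education/sex
distributions. One root seed drives a `SeedSequence` spawn tree (one child
per subject plus one for the table), so cohorts are bit-reproducible.

What the generator does *not* emulate: physiological (cardiac/respiratory)
noise, distortions, anatomy, motion-correlated intensity artefacts, or
site/scanner effects. Passing recovery tests therefore demonstrate that the
implementation detects the kind of synchrony difference the statistic is
designed for — not that it would survive every artefact of real data.

A consequence of the coarse scaled grid worth knowing: the 1-voxel
background smoothing induces neighbour correlations (~0.4–0.5) whose W
(~0.37) exceeds the raw W of the edge-diluted planted spheres (~0.22 at
ρ = 0.6). Group contrasts are unaffected — both groups share the same
background — and planted synchrony demonstrably raises in-region W relative
to a matched ρ = 0 cohort, but "planted region brighter than background in
a single raw map" is not a property of this design.

## Numerical and design choices

- Voxel coordinates are 0-based indices; world coordinates only via the
  affine. Rotations are degrees throughout.
- W is float64 in memory, float32 in files.
- The ReHo map is fully vectorized: per-voxel temporal ranks once, then
  rank sums, effective K′ and tie terms accumulated by zero-filled shifted
  addition over the K offsets.
- Cluster extent is thresholded in voxels (the primary printed unit); mm³
  is derived from the affine and reported alongside.
- The recovery experiment measures Dice between the union of supra-threshold
  patient-greater clusters and the planted mask; with a multi-sphere planted
  template, any single cluster's Dice against the whole template is bounded
  near 0.29 even at perfect detection, so the union is the meaningful
  quantity.
- Null-cohort false-positive stability is assessed on two independent seed
  batches of 8 replicates (granularity 1/8; the suite allows two discordant
  replicates). Measured rates are ~0.
- Experiment problem sizes (scaled grid, 20 recovery replicates, 2×8 null
  replicates, 10+10 ICA subjects) were chosen so the complete validation
  runs in minutes on a single CPU while keeping every group-level test at
  the stated power; they are the package's own defaults, not tunables of
  the science.

## Known limitations

- No slice-timing correction, realignment, or spatial normalization: inputs
  are assumed co-registered on a common grid (the upstream steps belong to
  SPM-class tools).
- Bonferroni FWE for the mask and uncorrected-voxel + extent thresholds for
  the comparison; no permutation or random-field inference.
- Infomax is the plain super-Gaussian variant (no extended Infomax); data
  dominated by sub-Gaussian sources would need the FastICA fallback.
- MDL on strongly band-limited data tends to the upper order bound because
  filtering truncates the eigenspectrum; fixing the order explicitly is
  recommended for narrow bands.
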
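# Methods

`seednets` implements a seed-region restricted functional-connectivity
analysis for resting-state fMRI: it finds co-activity clusters inside a
labelled seed structure (the motivating case is the amygdala and its nine
nuclei), maps each cluster to a whole-brain network, matches those networks
against binary reference templates, quantifies each subregion's contribution
to each network, and tests whether a participant covariate (self-reported
fear) modulates subregion co-activity.  This note documents the model, the
estimation choices, and what the synthetic cohorts do and do not emulate.

## Preprocessing

The pipeline consumes minimally processed 4D NIfTI volumes and applies two
further steps per session:

- **Highpass filter.**  A hard DFT-domain filter with a 2000 s cutoff at the
  default 1 s TR: the DC bin and every bin strictly below 1/2000 Hz are
  zeroed; all other bins pass with unit gain.  For runs shorter than the
  cutoff period (e.g. 900 volumes at 1 s) only DC lies below the cutoff, so
  the filter reduces to demeaning — which is exactly what a 2000 s highpass
  is meant to do on such runs.  A hard spectral threshold was chosen over a
  running-line (Gaussian-weighted) filter because it is deterministic and
  directly checkable against an independent DFT oracle.
- **Nuisance regression.**  CSF and white-matter time-courses are unweighted
  means over their mask voxels, filtered with the same highpass, then
  regressed (with intercept) out of every voxel.  Regression runs *after*
  filtering and on *filtered* regressors, so it cannot reintroduce removed
  frequencies; in that configuration the two operations commute to numerical
  precision, so the order is a convention rather than a modelling choice.
  Regressors that the filter reduces to (near-)zero are dropped.

All arithmetic is float64 regardless of on-disk precision.

## Seed-restricted group spatial ICA

Per-session seed matrices (time x voxels) are demeaned and scaled to unit
column SD, then concatenated over sessions; the per-block normalisation
stops high-variance sessions from dominating the group decomposition.  The
concatenated matrix `X` (rows = pooled time points) is modelled as
`X = A S`, where the d rows of `S` are spatial maps over seed voxels and the
columns of `A` are their group time-courses.  Estimation is PCA whitening to
exactly d components followed by fixed-point ICA with the log-cosh contrast
(tolerance 1e-6, at most 1000 iterations, up to 5 deterministic restarts
with incremented seeds), unmixing the voxel dimension so the *maps* are the
independent sources.  The reduction and unmixing are delegated to
scikit-learn's PCA/FastICA; ordering by explained variance, per-map
z-scoring over seed voxels, and the sign convention are applied on top.

Sign indeterminacy is resolved by flipping each map (and its mixing column)
to nonnegative skewness: cluster hotspots are sparse positive deviations,
so positive skewness makes "hotspot" the positive direction consistently,
which stabilises the sign of every downstream regression.  The product
`A S` is invariant under this orientation.

The model order d is not fixed a priori; see "dimension selection".

## Dual regression

- **Stage 1.**  For each session, every time point's seed pattern is
  regressed jointly on all d (z-scored, unthresholded) IC maps, giving d
  time-courses; each is then demeaned and scaled to unit SD.  A condition
  number above 1e8 in the map design is an error.
- **Stage 2.**  Every brain voxel's time-course is regressed jointly on the
  d stage-1 time-courses.  With T time points the t statistic uses T-d-1
  degrees of freedom (the intercept is absorbed by demeaning), and
  Z = Phi^-1(F_t(t)) computed through the |t| tail for numerical stability,
  clipped at +/-38.
- **Group maps.**  Sessions are averaged within subject first — the group
  stage needs one exchangeable observation per participant because the
  downstream mixed model already carries a participant random effect — then
  a voxelwise one-sample t across subjects is converted to Z the same way.
  Zero-variance voxels become 0 (zero mean) or +/-38 (nonzero mean), with a
  logged count.  Optional sign-flip permutation p-values (default 1000
  permutations, seeded) use the standard (b+1)/(m+1) estimator.

## Template matching and dimension selection

Each component's group Z map is correlated (Pearson, over brain-mask voxels
only) with each binary reference template.  A component is **uniquely**
detected for network n at threshold r* (default 0.4) iff r(c,n) >= r*,
r(c,m) < r* for every other network m, and no other component has a higher
r with n; components exceeding r* for several networks, or tying/losing a
claimed network, are **ambiguous**, the rest **unmatched**.  Ties go to
ambiguity because a tie gives no principled winner.

The order sweep runs d = d_min..d_max; per dimension the full match table
and assignment are recorded.  The selected order is the smallest d attaining
the maximum count of uniquely detected networks.  Summed matched r is
reported per dimension but is not part of the selection key — the
count-then-smallest-d rule is the sharper operationalisation of "optimal"
here, and the full sweep table is always emitted so the choice is auditable.
Note that the unique count is not monotone in r*: a component whose two best
correlations straddle a raised threshold can switch from ambiguous to
unique.  A sweep in which no network is ever detected returns an explicit
"not detected" result rather than raising.

## Parcel statistics

Subject Z maps (sessions averaged) are summarised as mean Z per labelled
region, split by hemisphere, yielding the long table analysed by the mixed
model

    mean_z ~ hemisphere + fc_map * brain_region + (1 | participant)

with a single random intercept per participant.  The implementation profiles
the variance ratio lambda = tau^2/sigma^2 out of the REML criterion and
optimises it as a scalar (bounded search on log lambda, tolerance 1e-8, with
an explicit lambda = 0 comparison); fixed effects follow by GLS.  All
factors are sum-to-zero coded, so the Type-III hypothesis for each term is
that its coefficient block vanishes.  Denominator degrees of freedom use the
Satterthwaite approximation: per-contrast df from the delta method with the
variance-parameter covariance taken as twice the inverse finite-difference
Hessian of the REML criterion, combined across the eigencomponents of a
multi-df contrast.  When the REML estimate of tau^2 hits zero the model is
the OLS model and residual df are used directly.  The fit is verified in the
test suite against R's lmerTest/emmeans on the same tables (variance
components, F statistics, Satterthwaite df, contrast z-ratios).

Estimated marginal means are model predictions on the factor grid with the
remaining factors averaged over levels (exactly the cell means in balanced
designs).  Two contrast families are used:

- **Effect contrasts**: each map's EMM minus the mean of the other maps'
  EMMs, per region; z-ratio = estimate/SE on the asymptotic normal
  reference; Bonferroni over all contrasts in the emitted table.
- **Pairwise subregion contrasts**: for each map, all subregion pairs; the
  antisymmetric matrix of signed z-ratios is summed per subregion,
  thresholded strictly above zero, and ranked descending.  Row sums of an
  antisymmetric matrix total zero, which is asserted as a conservation
  check.  Signed (not absolute) differences are summed, so a subregion's
  score is its net dominance over the others.

The fear analysis median-splits the fear scores (ties at the median go to
the low group — a documented convention), extends the model with Gender,
Age band and a Group x map x region interaction, drops Age if its main
effect is not significant, and — only when the Group x region interaction is
significant at alpha = 0.05 — runs low-vs-high post-hocs per region and per
region x map cell with Bonferroni correction over each table.

The two-sample t for the group split is the pooled-variance t from group
summary statistics with n1 + n2 - 2 df.

## Synthetic cohorts

The generator produces everything the pipeline consumes: 4D sessions, seed
mask, subregion atlas (nine nuclei x two hemispheres with an LB/CM/SF
division lookup), a whole-brain block parcellation with mirror-symmetric
region names, disjoint binary network templates inside a brain mask, CSF/WM
nuisance compartments, a participant table and a ground-truth record.

Signal model for voxel v at time t:

    y_v(t) = sum_k c_k(t) g_k(v) + b_subject + e_v(t)

- Latent network time-courses `c_k` are white noise smoothed with a ~10 s
  moving average and z-scored per session: band-limited fluctuations that
  resemble resting-state dynamics while keeping the decomposition
  identifiable.  Sessions have independent latents; the subject intercept
  `b_subject` (SD 0.1) is shared across a subject's sessions.
- Whole-brain coupling `g_k` is 1 inside the template assigned to network k
  (assignment is a seeded draw of K distinct templates out of 7).
- Inside the seed, each network activates a random ~40% subset of the
  voxels of every subregion it loads, with voxelwise gains uniform in
  [0.7, 1.3] around the subregion's loading weight.  Clusters are therefore
  graded hotspots that cut across subregion boundaries.  The sub-cluster
  sparsity matters: flat plateau loadings covering most of the seed make
  the spatial sources mutually exclusive and nearly unidentifiable for ICA,
  whereas partial, graded clusters mirror real data and separate cleanly.
- The default loading matrix gives each of the three networks a distinct
  dominant nucleus plus secondary ones (CAT/PL/Ba; Co/AAA/Ce; Me/AB), every
  configuration spans at least two nuclei and two large-scale divisions,
  and La is deliberately unloaded.  The three subregion sets are disjoint —
  well-separated sources keep the identifiability assumption explicit.
- Right-hemisphere seed couplings are scaled by 1.2 (hemisphere offset).
- Noise is AR(1) (coefficient 0.3) with marginal SD 1/network_snr
  (default SNR 1), independent across voxels, inside the brain mask only.
- The fear effect multiplies the designated subregion's coupling with the
  designated network by 1 + 0.05 (score - cohort median); scores are drawn
  half from N(44.0, 4.9^2) and half from N(55.2, 4.5^2), so the low/high
  median-split groups differ by ~11 points and the coupling boost spans
  roughly +/-50% — a strong but subtle-at-the-voxel-level effect designed
  to be recoverable through the full pipeline.

Defaults: 24 x 24 x 12 grid, 20 subjects x 2 sessions x 200 time points at
TR 1 s, K = 3 embedded networks, 7 templates.  These sizes keep a full
order sweep (d = 1..10, ICA + dual regression + matching) under ~20 s.
The split-half stability experiment instead uses 40 subjects with 4
sessions (two per half), mirroring the test/validation session protocol:
map test-retest correlation is a group-level reliability statistic and
needs a larger cohort to be in its meaningful regime.

What the generator does **not** emulate: hemodynamic convolution, head
motion, physiological noise, spatial autocorrelation of noise, surface
geometry, family structure, or registration error.  Passing recovery tests
therefore demonstrates correctness of the estimation machinery under the
model's assumptions, not robustness to those artefacts.

## Numerical conventions

- Z statistics clipped at +/-38 everywhere (beyond float64 tail precision).
- Masked matrices use fixed lexicographic voxel order (x fastest), so
  extraction/insertion is a lossless bijection.
- ICA determinism: a fixed seed reproduces maps bit-for-bit; restarts use
  seed+1, seed+2, ... and non-convergence after 5 restarts is an error.
- All pipeline randomness derives from one root seed (stage-specific seeds
  at fixed offsets), recorded in the run manifest together with a hash of
  the analysis configuration that every output table carries.
- Model-order sweep entries whose ICA degenerates (d above the numerical
  rank of the concatenated data, as happens on noise-free cohorts) are
  skipped with a warning rather than aborting the sweep.

## Known limitations

- The single-random-intercept model ignores within-subject session
  correlation beyond the intercept and any family structure.
- Satterthwaite df fall back to residual df at the tau^2 = 0 boundary.
- Bonferroni families are per emitted table; no cross-table correction.
- The QC filter consumes flag letters in a manifest column; it does not
  compute quality metrics itself.
- `select_dimension` breaks count ties by the smallest order only; summed
  matched correlation is reported, not used.
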
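# Methods

This note documents the statistical models, numerical choices and known
limitations of the package, in the spirit of a software methods appendix.

## EDMA: estimators and tests

**Form and shape matrices.** A specimen's form matrix is its vector of
K(K−1)/2 inter-landmark Euclidean distances, in canonical lexicographic
pair order. Shape matrices divide each specimen's distances by their
geometric mean; centroid size is not used for this standardization (the
geometric mean of distances is the classic EDMA size measure and keeps
the shape matrix a pure function of the distance vector).

**Mean form.** Group mean form/shape matrices are arithmetic per-pair
means of specimen matrices. Moment-based estimators that subtract the
within-group landmark covariance exist and reduce a small upward bias of
mean distances under noise; with digitization noise at ~1–2% of typical
inter-landmark distances the bias is second-order, but results can
differ slightly from variance-corrected EDMA implementations on very
noisy data. This is a deliberate simplicity/robustness trade-off.

**Difference matrices.** FDM/SDM entries (REDs) are oriented
test-group / reference-group, so RED > 1 reads "larger in the mutant".
`difference_matrix(A, B)` is the elementwise reciprocal of
`difference_matrix(B, A)` by construction.

**Omnibus test.** The statistic is T = max(RED)/min(RED). T is
invariant to uniform scaling of all distances: a pure size change gives
T = 1 and is invisible to the omnibus test in form mode. This is a
property of the statistic, not a bug; global size effects are carried by
the per-pair confidence intervals (which exclude 1 under a uniform
scaling) and are visible in the RED band. The null distribution pools
both groups and re-splits the pooled specimens into two pseudo-groups of
the original sizes. The default split is a random partition **without**
replacement (a permutation null): at the study's sample sizes (n ≈ 10
per group) drawing pseudo-groups with replacement understates
pseudo-group variance by a factor (n−1)/n, which measurably skews the
null p-value distribution away from uniform (deficit near p = 1); the
permutation split is exactly calibrated under exchangeability. The
with-replacement variant remains available (`null="bootstrap"`). The
p-value uses the (b+1)/(N+1) correction so it is never exactly zero.

**Confidence intervals.** Per-pair CIs are percentile intervals of the
RED under within-group resampling with replacement, at level 0.978 by
default (a two-sided band with 1.1% in each tail). The bootstrap flavor
(percentile rather than BCa or basic) is the simplest choice consistent
with percentile-type software conventions.

**Influence landmarks.** The primary flagging rule is the fixed RED band
[0.95, 1.05]; a CI-based rule (bootstrap CI excluding 1.0) is available
via `use_ci=True` and both can be reported. A landmark's dominant
direction is "increase"/"decrease" only under a 2:1 majority of its
out-of-band pairs (and strictly more in that direction); otherwise
"mixed". The 2:1 rule is a reporting convention — landmarks sitting at
the boundary of two antagonistic regional effects are genuinely mixed
and are reported as such.

## Procrustes analyses

**Superimposition.** Full GPA: center, scale to unit centroid size,
rotate to the running consensus with the determinant-corrected
(reflection-free) orthogonal fit, re-estimate the consensus as the
coordinate-wise mean, iterate to tolerance 1e-8 (typically 2–4
iterations). The consensus is seeded by the first specimen, which fixes
the global orientation; the superimposed geometry (all inter-specimen
residual distances, the consensus shape up to rotation) is invariant to
input order and to arbitrary rigid motions/scalings of the inputs, and
this is verified by test. Partial Procrustes (no unit-size scaling) is
not offered; size is analyzed on the EDMA side via form matrices.

**Shape PCA.** SVD of aligned coordinates centered on the consensus.
Components are sign-fixed (largest-magnitude loading element positive)
for reproducibility; variance fractions are eigenvalue shares and sum
to 1. Numerically null components (singular value < 1e-12 of the
largest) are dropped.

**Group comparison.** Pairwise group mean shapes are compared by the
Procrustes distance between consensus coordinates, with significance
from shuffling labels within the pair (p = (b+1)/(n_perm+1), default
n_perm = 1000). The integrative cross-model ordination uses each
specimen's size-standardized distance vector as its feature vector and
runs one PCA over all cohorts. Together these play the role a canonical
variate analysis plays in morphometric packages; a true CVA whitens by
the within-group covariance, which is severely ill-conditioned at ~10
specimens against 3K ≈ 36–183 coordinates, so covariance whitening is
deliberately not the default ordination here.

**Sex** is carried as optional specimen metadata but not modeled;
analyses pool sexes.

## Expression and proliferation statistics

The two-group cascade runs Shapiro–Wilk on each group at α = 0.05, then
a two-sided F-test for variance equality choosing pooled t vs Welch t;
if either group fails normality the comparison falls back to a
two-sided Mann–Whitney U, flagged in the output (the nonparametric
fallback is a package convention — the upstream protocol only defines
the normal branch). All intermediate p-values are recorded so the branch
is replayable. Pre-test cascades can distort type-I error in principle;
the calibration is therefore *measured* (acceptance checks keep it
within [0.03, 0.08] at α = 0.05 under normal and heavy-tailed nulls)
rather than assumed. No multiple-testing correction is applied across
genes by default (per-gene reporting); Holm step-down is available.

The proliferation index is 100 × EdU⁺/Hoechst-total. The EdU/PH3 ratio
has no universally fixed orientation, so `mitotic_index` requires an
explicit convention (`ph3_over_edu` or `edu_over_ph3`) and never
defaults.

## Synthetic cohorts: what they emulate, and what not

The generator emulates a two-genotype littermate cohort: a fixed
template anatomy, iid isotropic Gaussian noise N(0, σ²) per landmark
coordinate (the standard landmark-error model covering digitization and
unstructured biological variation), and genotype effects as regional
scalings about the affected region's own centroid — isotropic factors
for hypoplasia/expansion, per-axis factors for directional effects such
as mediolateral widening. Scaling about the region centroid keeps the
effect local and leaves untouched regions bit-identical, mimicking
bone-level findings without a global size confound. Optional nuisance
rigid motions (rotation, translation, uniform scale jitter) emulate
arbitrary specimen pose; they leave all pairwise distances invariant by
construction.

The template places landmarks on the upper half of an ellipsoid with
semi-axes 11 × 6.5 × 5 mm (adult mouse cranium scale, coordinates in
mm), using greedy farthest-point selection from a dense seeded candidate
cloud: landmark protocols use well-separated homologous points, and
near-coincident landmarks would make their REDs pure noise. Region tags
are contiguous front-to-back sectors. The desk-scale default is K = 12
landmarks in three regions of four — midface, frontal, neurocranium —
with the unaffected frontal sector between the two canonically affected
regions, as the frontal bone separates the face from the parietal vault
anatomically. Full-inventory templates (39 cranium + 22 mandible names,
from a *synthetic stand-in* inventory in `inventory_synthetic.py`) are
supported but not the default. Default cohort size is 10 + 10, matching
typical littermate cohorts; default noise is stated per study (the
calibration studies use σ = 0.02 mm for null cohorts and σ = 2% of the
mean inter-landmark distance for effect-recovery studies).

What the simulator does **not** model: correlated landmark errors,
integration/modularity covariance structure, allometry, asymmetry,
sex dimorphism, or genotype-dependent variance heterogeneity (an
increased-variability option can be emulated by sampling the two groups
with different `noise_sd`, but no default does this). Passing the
synthetic validations therefore demonstrates correctness and
calibration of the *statistics* under the stated error model, not
performance on any particular real dataset.

Randomness is counter-based: each specimen's noise stream is a
`SeedSequence(master, spawn_key=(group, index))` child, so enlarging a
cohort never changes previously generated specimens, and every derived
seed in a study is a pure function of the master seed (reports are
byte-identical across reruns).

## Severity grades

A model × mode result is graded NS when the omnibus p ≥ α (default
0.05); otherwise "strong" when at least 25% of all REDs are out of band,
"mild" otherwise. Published severity tables of this kind are
qualitative; this rule is an explicit, re-thresholdable proxy, and both
thresholds are embedded in the report.

## Validation study sizes

The standing validation suite uses: 500 simulated null datasets (K = 12,
n = 10+10, σ = 0.02 mm) at 1000 resamples for omnibus calibration and
p-value uniformity; 300 datasets at 200 permutations for the Procrustes
permutation test; 100 simulations each for power, influence-landmark
recovery (10% midface contraction) and direction fidelity (simultaneous
midface contraction + 10% neurocranial lateral expansion, scored against
the noise-free deformation's influence directions); 1000 replicates per
null for the cascade. These sizes give standard errors comfortably
below the acceptance margins while keeping the whole suite under a
minute.

## Known limitations

- Arithmetic mean form (no variance-corrected estimator); see above.
- The omnibus T cannot detect pure size change in form mode.
- The fixed RED band [0.95, 1.05] is scale-free but not
  noise-adaptive; with very noisy or very short distances the CI-based
  flagging rule is more appropriate.
- Procrustes superimposition spreads a highly localized difference over
  all landmarks (the "Pinocchio effect"); localization claims should
  rest on the EDMA influence analysis, which is superimposition-free.
- TPS/CSV readers handle the package's documented dialects only; no
  missing-landmark imputation.
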
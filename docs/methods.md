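# Methods

This note documents the models and procedures implemented in `msgrad`, the
choices made where the design was genuinely open, and what the synthetic
cohort does and does not establish about real data.

## Synthetic cohort

The generator emulates an accelerated-longitudinal developmental imaging
study on a spherical stand-in for a cortical parcellation.

**Parcellation.**  N nodes on a Fibonacci spiral over the unit sphere;
hemispheres split by the sign of x; communities are contiguous latitude
bands of near-equal size (community 0 at the top pole).  Great-circle
distance (radians, 0–π) stands in for surface geodesic distance: it is a
true metric with smooth spatial structure, which is what the variogram
surrogates and distance-decay models need, without any mesh machinery.

**Planted truth.**  The contrast vector is the standardized latitude — a
smooth pole-to-pole axis standing in for the primary-to-transmodal
hierarchy.  Its expression in the depth profiles scales as
`1 + age·age_slope + u_subject`, with `u_subject ~ N(0, 0.1²)` a per-subject
random intercept, so the mixed model's random effect is identifiable from
the features themselves.

**Features per scan.**
- *GD*: great-circle distance plus symmetric positive jitter (U(0, 0.01)).
- *Depth profiles* (12 depths): a decaying mean profile, plus the planted
  contrast times a linear depth-loading pattern at amplitude
  `profile_signal·(1 + age·slope + u)`, plus iid N(0, 0.45²) noise.  Nodes
  at the same end of the contrast therefore have correlated residual
  profiles, which MPC detects; because the noise floor is fixed, growing
  amplitude sharpens the MPC block structure even after rank normalization,
  which is what makes the embedded gradient expand with age.
- *TS*: negative-binomial counts (shape 2) with mean
  `30·exp(−d/0.5)·(1 + 0.5·same-community)` — sparse, skewed,
  distance-decaying, as streamline counts are.
- *FC*: tanh of a fused structural similarity plus a community block signal
  (0.15) and N(0, 0.1²) noise; unit diagonal.  FC is delivered as a
  correlation matrix directly; a time-series path is not needed for any
  downstream contract.
- *Behavior*: `weights·(1 + age·slope + u) + N(0, 0.5²)`, default weights
  (1, −0.6).  At 60 subjects this gives realistic (modest) brain–behavior
  effect sizes; cohort-level PLSC significance is therefore not guaranteed
  at that n, exactly as in comparable empirical cohorts.
- *Gene maps*: Gaussian random fields on the sphere with exponential
  covariance of range 0.3 rad (about 10 % of the maximum inter-node
  distance); signal genes add `0.8 × effect map`.  The 0.3 range keeps null
  gene maps genuinely autocorrelated while leaving enough spatial degrees
  of freedom that a null gene's expected |correlation| with any fixed map
  stays ≤ 0.2 at N = 100 — longer ranges concentrate the maps on a handful
  of smooth modes and break that property.

**Design.**  Subjects receive 1–3 scans with proportions 0.57/0.30/0.13 and
within-subject age gaps of 0.5–1.5 years, ages 6–14 — the shape of an
accelerated-longitudinal cohort.  The default sizes (100 nodes, 60
subjects, ~95 scans) were chosen so that a full cohort analysis runs in
about a second while the planted dispersion effect remains detectable with
high probability per replicate.

**What passing tests show — and do not.**  The generator plants exactly the
effects the pipeline is designed to detect, with Gaussian noise and a
geometry far simpler than a cortical sheet.  Recovery and calibration
results therefore validate the *machinery* (estimators, alignment, null
distributions), not the empirical claims about any real cohort: there is no
registration error, no parcel-size heterogeneity, no motion-feature
coupling, and the planted axis is one-dimensional by construction.

## Feature preparation

MPC is the pairwise partial Pearson correlation of depth profiles
controlling for the cortex-mean profile (residualize both on the mean
profile, correlate residuals), thresholded at zero and transformed by
`r → ln((1+r)/(1−r))` (twice the Fisher z; finite at r = 0, monotone, and
r is clipped at 1−10⁻¹² first).  The plain `ln(r)` reading of
"log-transform" would diverge at r = 0, so the Fisher form is the default;
both interpretations share the rank structure, and downstream rank
normalization makes the choice immaterial for the gradients themselves.

Streamline counts are transformed by `ln(1+x)` on nonzero entries; zeros
remain zero and stay outside the validity mask.

Rank normalization replaces the masked entries by average-tie ranks of the
upper triangle (mirrored for symmetry), min-max rescaled to [0, 1].
"Inverted GD" is realized as `1 − rank-rescaled distance` rather than 1/d:
rank-space inversion is scale-free and lands all three features on the same
range by construction.  Diagonals are always excluded.

## Embedding

The fused affinity is the normalized-angle similarity of the concatenated
(length-3N) feature rows.  No row sparsification is applied to the
multiscale affinity (the top-10 %-per-row step belongs to the FC gradient
only).  Diffusion maps follow the standard construction: α-normalization
`D^−α W D^−α` with α = 0.5, row-normalization to a Markov operator,
eigendecomposition via the symmetric conjugate, eigenvectors normalized
against the trivial constant vector, and automatic diffusion-time scaling
λ/(1−λ).  A disconnected affinity graph is an error (reported with
component sizes).  Signs are fixed deterministically (largest-magnitude
entry positive), then template orientation puts community 0 — the
primary-axis proxy — on the positive end of each component, and all
individual gradients are Procrustes-rotated (orthogonal, no scaling) to
their age-bin template, each bin template having been aligned to the
all-scan template first.  Aligning bin templates to an overall template is
a choice (a plausible alternative is independent bin templates); it makes
gradients comparable across bins and removes an arbitrary per-bin
rotation.

Explanation ratios divide each retained eigenvalue by the sum of all
positive non-trivial eigenvalues, so retained ratios sum to at most 1.

## Age models

The response per scan is modeled as

    y = f(age) + β_sex·sex + β_mot·motion + b_subject + ε

with `f` a cubic regression spline with k = 3 knots at age quantiles
(cardinal natural-spline basis, integrated-squared-second-derivative
penalty) and `b_subject` an iid random intercept.  The penalized wiggle is
reparameterized (Demmler–Reinsch) into an iid ridge direction, giving a
linear mixed model with two variance components whose log ratios are
optimized by REML (Nelder–Mead on the profiled criterion; all matrix work
on precomputed cross-products so nodewise fitting reuses the design).

Adjusted R² is computed from the *marginal* fit — fixed effects plus
smooth, excluding the subject BLUPs — with the marginal effective degrees
of freedom.  This matches the convention in which the random effect lives
in the mixed-model layer and is essential for ΔAdj R²: if subject BLUPs
entered the fitted values, the reduced model would absorb the
between-subject share of the age signal into the intercepts and the effect
size would shrink several-fold.

ΔAdj R² is |adjR²_full − adjR²_reduced| signed by the age coefficient of
the equivalent linear model.  Zero-variance responses short-circuit to
ΔAdj R² = 0, p = 1.

The smooth-term p-value is an ANOVA comparing full and reduced models: an
F-test on the age block (linear + wiggle), computed unpenalized, after GLS
whitening by the REML subject variance (closed-form block whitening, since
the random effect is an intercept).  Cross-sectionally this test is exactly
F-distributed; in the mixed case it is approximate but calibrated in
simulation (null p-values uniform by KS at n = 500).  A Wald test on the
penalized coefficients with edf-corrected reference was evaluated first and
found anticonservative at large n, so the ANOVA form is used.  For
cross-sectional replication cohorts the random intercept is simply dropped
(`AgeModelSpec(random_intercept=False)`).

Nodewise maps apply the same machinery per node with Bonferroni correction
at α/N; individual node failures are recorded as missing, not fatal.

## Spatial surrogates

The empirical semivariogram uses 25 equal-count distance bins over pairs
below the 70th distance percentile.  Surrogates: permute the source map,
smooth with row-normalized exponential kernels over k-nearest
neighborhoods at k ∈ {5, 10, 20, 40} % of nodes, and pick the scale plus
nonnegative affine variance adjustment (β, α) whose implied variogram
β·γ_smooth + α best matches the source's; the surrogate is
√β·smoothed + √α·white noise, optionally rank-remapped onto the source's
value multiset (`resample=True`, exact distribution preservation).  An
empty kernel list degenerates to a plain permutation null (variogram
flattens to the variance — the limiting case used as a self-check).

The correlation test reports Pearson (or Spearman) r with a two-sided
surrogate p by default, `(1 + #{|r_null| ≥ |r|}) / (n + 1)`; a one-sided
variant is a flag, since signed hypotheses differ across analyses.
Measured on independent autocorrelated maps (N = 200, range 0.5), the
surrogate test's type-I rate is ≈ 0.05–0.08 while the naive parametric
test exceeds 0.3.

## Structure–function analyses

The FC gradient keeps the top 10 % of off-diagonal entries per row
(rectified at zero, used asymmetrically as row profiles), applies the
normalized-angle kernel and the same diffusion-map machinery.  Nodal
coupling is the Spearman correlation between a node's fused multiscale
affinity row and its FC row, self-entry excluded; the fused affinity is
used as the "structural profile" because the raw concatenated 3(N−1)
profile cannot be paired elementwise with FC (any node×node profile
matrix, e.g. a single normalized feature, can be supplied instead).  Participation coefficients use
`1 − Σ_s (k_is/k_i)²` on nonnegative weights: the fused affinity for the
structural side, the positive part of FC for the functional side (PaC is
undefined for signed weights).  Differentiation distance averages pairwise
Euclidean distances in the gradient-1/3 plane within and between
communities.

## PLSC and gene PLSR

PLSC z-scores X and Y columns (constant columns dropped with a warning)
and decomposes R = YᵀX by SVD.  Permutation shuffles Y's rows and compares
singular values component-wise without Procrustes realignment of the
permuted saliences — the simplest defensible null, and the calibrated one
(measured rejection ≈ 0.03–0.05 at α = 0.05).  The classical rotated
variant (`perm_align=True`: SVD the permuted cross-covariance, Procrustes-
rotate its singular structure onto the original, take column norms) is
available but markedly liberal under the null (≈ 0.28 at α = 0.05 in the
same simulation), a known property of that scheme; it is off by default.
Bootstrap resamples subjects, sign-aligns saliences to the original by
cosine, and flags loadings whose 95 % bootstrap interval excludes zero.
Cross-validation (10×5-fold) fits saliences on training subjects, projects
held-out subjects with training z-scoring, and averages test-set composite
correlations; its permutation p permutes held-out behavior per fold.  Note
that fold-level test correlations are themselves correlated (the folds'
union is the sample), so the CV permutation p is a heuristic; the
replicate-level behavior of mean test r (centered on zero under the null)
is the calibrated quantity.  Behavior variables where larger means worse
are not re-signed; interpretation is left to the loadings.

Gene PLSR regresses an effect map on z-scored gene columns (NIPALS via
scikit-learn, no internal scaling), orients PLS1 so its score correlates
positively with the response, bootstrap-resamples regions to turn weights
into Z scores (weight / bootstrap SD, 1,000 draws by default), and takes
the top 10 % positive and negative genes.  The in-sample explained variance
of the response is reported per component; with many genes relative to
regions it is inflated by construction (≈ p/(p+n) under the null), which
is precisely why significance is referred to the surrogate-map null rather
than to the raw value.

Enrichment is hypergeometric over-representation against the declared
background with Benjamini–Hochberg FDR across sets, plus the spatial null:
each surrogate of the effect map is pushed through PLSR and its top genes
re-tested, and a set is called significant only if the real p lies below
the 5th percentile of its surrogate p distribution (and below α).  For the
surrogate branch genes are ranked by raw PLS1 weight rather than bootstrap
Z — re-bootstrapping inside every surrogate would multiply cost a
thousandfold for no change in the selected sets' character.  This null is
deliberately conservative when the effect map is itself the dominant
smooth factor of the gene matrix: surrogates then re-select the same
genes, and the correction correctly refuses to attribute the enrichment to
the specific map rather than to smoothness.

Morphometric profiles: PCA on z-scored node×feature matrices (PC1 sign
tied to the first feature), and the morphometric similarity network as the
inter-node Pearson correlation of z-scored feature vectors, zero diagonal.

## Pipeline and determinism

`run_pipeline` executes load → gradients/metrics → age effects → feature
contributions → coupling → PLSC → gene PLSR → enrichment from one
`RunConfig` (YAML-loadable, unknown keys rejected), writing TSV/JSON plus a
manifest with the config snapshot, stage wall-times and SHA-256 hashes of
every output.  All stage seeds derive from the config seed; rerunning with
the same config and inputs reproduces identical output hashes.  Stages
whose inputs are absent (no gene matrix, no behavior columns) are skipped
cleanly.

## Numerical choices and degenerate inputs

- Correlation clipping at 1−10⁻¹² before the MPC transform keeps values
  finite; cosine similarities are clipped to [−1, 1] before arccos.
- Zero-variance profiles, constant matrix values, constant affinity rows
  and zero-strength nodes each have defined behavior (zero rows with a
  warning, 0.5 after rank rescaling with a warning, missing coupling
  values, PaC = 0 respectively).
- Ties in rank normalization use average ranks; ranking is done on the
  upper triangle and mirrored, so symmetry is exact.
- REML optimization bounds log variance ratios in [−25, 25]; failures of a
  nodewise fit are recorded as missing rather than aborting the map.

## Known limitations

- The spherical geometry has no hemispheric separation of distance
  structure and no parcel-area heterogeneity; geodesic distance on a real
  cortex is only approximated by a metric on the sphere.
- The age model's mixed-case F-test is approximate (exact only
  cross-sectionally); its calibration is established by simulation, not by
  distribution theory.
- The surrogate generator matches the variogram approximately (median
  relative L2 distance < 0.25 in self-consistency checks); maps with
  strongly non-stationary autocorrelation are outside its remit.
- PLSC permutation uses per-component singular-value comparison without
  max-statistic correction across components; multiplicity across
  components is the user's responsibility.
- The synthetic cohort's effect magnitudes are free design parameters of
  the generator, not estimates of any empirical cohort.
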
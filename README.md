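# msgrad — multiscale structural connectome gradients across development

`msgrad` studies how the low-dimensional organization of the brain's
structural connectome matures from childhood to adolescence.  It is written
for network-neuroscience researchers who work with parcellated connectomes:
three complementary structural features per scan — geodesic distance (GD),
microstructure profile covariance (MPC) and tractography tract strength
(TS) — are fused into a single connectivity profile per region, embedded
with diffusion maps, and the resulting *gradients* are modeled against age,
functional organization, behavior and gene expression.

Because raw neuroimaging cohorts are rarely desk-available, the package
ships a first-class synthetic cohort generator: an accelerated-longitudinal
sample on a spherical parcellation with a planted primary-vs-transmodal
contrast whose expression grows with age, subject-level random intercepts,
behavior scores coupled to the planted axis and spatially autocorrelated
gene-expression maps.  Every stage of the pipeline is validated against
that ground truth.

## The model

**Fusion and embedding.**  Per scan, the nonzero entries of the MPC,
log-transformed TS and inverted GD matrices are rank-normalized and
rescaled to a common range, concatenated row-wise, and turned into an
affinity by the normalized-angle kernel

    a(i, j) = 1 − arccos(cos θ_ij) / π .

Diffusion-map embedding with anisotropy α = 0.5 yields gradients ordered by
the connectivity variance they explain (explanation ratio λᵢ / Σλ).  Scans
are Procrustes-aligned to age-specific group templates (six 1-year bins),
which are themselves aligned to the all-scan template.

**Gradient geometry.**  In the 2-D space of gradients 1 and 3, *dispersion*
is Σᵢ ‖pᵢ − c‖₂ (c the centroid) and *eccentricity* is each node's distance
to the template centroid — summaries of how differentiated the regional
profiles are.

**Age effects.**  Each measure is modeled with a penalized cubic regression
spline of age (maximum basis complexity k = 3, restricted-maximum-likelihood
smoothing), sex and head motion as linear covariates, and a per-subject
random intercept.  The effect size is the signed change in adjusted R²
between the full model and one without the age term (ΔAdj R², signed by the
linear-model age coefficient); significance compares full and reduced
models by ANOVA.

**Spatial inference.**  Every correlation between cortical maps is tested
against 1,000 variogram-matched surrogate maps that preserve the source
map's spatial autocorrelation — a naive parametric test is wildly
anticonservative on smooth maps.

**Multivariate links.**  Brain–behavior coupling uses partial least squares
correlation (SVD of R = YᵀX) with permutation tests on singular values,
bootstrap stability of loadings and 10×5-fold cross-validated composite
correlations.  Gene association uses PLS regression of the nodal ΔAdj R²
map on a region×gene matrix, bootstrap Z-scored gene weights, top-10% gene
sets and hypergeometric over-representation corrected by a surrogate-map
null.

## Worked example

```python
import numpy as np
import msgrad as mg

parcels = mg.make_parcels(n_nodes=100, n_communities=4, seed=1)
truth = mg.default_truth(parcels, age_slope=0.05, seed=1)
scans, _ = mg.simulate_cohort(parcels, truth, n_subjects=60, seed=2)

res = mg.MultiscaleGradientModel(scans, parcels).fit()
print(res.summary())

g1 = res.component_scores(0)
print(np.corrcoef(g1.mean(axis=0), truth.contrast_vector)[0, 1])

eff = res.age_effect("dispersion")
print(eff["delta_adj_r2"], eff["p"])
```

prints

```
Multiscale gradient cohort fit
============================================
scans:      94
nodes:      100
components: 10 (alpha=0.5)
template explanation ratios: 0.194, 0.156, 0.155
mean dispersion: 6.899

corr(aligned g1, planted contrast) = 0.999
dispersion age effect: dAdjR2 = +0.086, p = 0.0072
```

Reading: the principal gradient of the fused connectome recovers the
planted primary-vs-transmodal axis almost exactly (r = 0.999 against the
generator's ground truth); the dispersion of the gradient space grows with
age (ΔAdj R² = +0.086 with the spline mixed model, ANOVA p = 0.007),
mirroring the planted expansion of the contrast with age.

The same analysis is available from the shell:

```bash
msgrad simulate --out ds --n-nodes 100 --n-subjects 60 --seed 1
msgrad run-all --dataset ds --out run --seed 1   # writes run/manifest.json
```

## Layout

| module | contents |
| --- | --- |
| `msgrad.synthetic` | parcellation, planted truth, cohort and gene-map generators |
| `msgrad.features` | MPC, log tract strength, rank normalization |
| `msgrad.gradients` | normalized-angle affinity, diffusion maps, Procrustes, templates |
| `msgrad.metrics` | range/SD/explanation ratio, dispersion, eccentricity, community summaries |
| `msgrad.age` | penalized-spline mixed models, ΔAdj R², nodewise maps |
| `msgrad.nulls` | variograms, surrogate maps, surrogate-corrected correlation tests |
| `msgrad.coupling` | FC gradient, nodal SC–FC coupling, participation coefficient |
| `msgrad.multivariate` | PLSC (+CV), gene PLSR, enrichment, morphometric PCA/MSN |
| `msgrad.model` | `MultiscaleGradientModel` / `MultiscaleGradientResults` |
| `msgrad.pipeline`, `msgrad.cli` | run orchestration, manifests, `msgrad` CLI |

See `docs/methods.md` for modeling details, parameter choices and known
limitations.
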
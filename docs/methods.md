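# Methods

This note documents the models implemented in `salamorph`, the assumptions
behind them, the synthetic-data generator that stands in for the undeposited
field data, and the numerical and design choices a maintainer would want to
know. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Biometric mixed models and AICc comparison

### Model family

Each response (AG, or one of the eight shape features) is modelled as

    y_i = x_i' β + b_{pop(i)} + ε_i,   b_pop ~ N(0, σ_b²),  ε ~ N(0, σ²).

The fixed part contains at most one categorical factor — species or site
typology, never both (the two are partially confounded by design: the
species' ranges determine which sites exist) — plus, for shape features,
optionally AG as an allometric covariate. Because the five population codes
are globally unique, "population nested within species/site typology" has
exactly the same likelihood as a plain population-keyed intercept, which is
how the random term is encoded.

Candidate sets: 5 structures for AG; 11 for the shape set (the same 5, the
same 5 with AG as covariate, and AG alone).

### Estimation

All model comparisons use **maximum likelihood**, not REML: REML
log-likelihoods are not comparable across different fixed-effect structures,
and the candidate sets vary exactly there. Random-intercept fits profile the
likelihood over the variance ratio λ = σ_b²/σ²: for fixed λ the GLS β̂ and
σ̂² are closed-form per population block (V = I + λZZ' is block diagonal, so
V⁻¹ and ln|V| cost O(n)), leaving a one-dimensional bounded Brent search on
log₁₀λ ∈ [−8, 8] (xatol 1e-10). The λ → 0 boundary (ordinary least squares)
is evaluated exactly and wins ties; models without the random term are OLS
with the Normal ML log-likelihood. Parameter count k = fixed coefficients +
variance components (1 for OLS, 2 with the intercept). The implementation
agrees with an independent general-purpose mixed-model ML fitter to ~1e-10
in log-likelihood on the default design (kept as a cross-check in the test
suite).

A REML variant of the same profile is available and is used for **reporting
fixed-effect standard errors** (`fit_lmm(..., reml=True)`), the convention
of standard mixed-model tooling: with only five populations, ML variance
estimates are noticeably shrunk and ML-based SEs undercover.

Fixed factors are tested by likelihood-ratio χ² against the same model with
the factor removed (df = levels − 1), both fits by ML. The χ² reference is
asymptotic in the number of *populations* whenever group-level variance is
present; the calibration test therefore runs in the regime where the
reference applies (all group-level effects zero), where simulated p-values
are uniform. With few groups and a nonzero σ_b the LRT is anticonservative
(simulations here show ~23% rejections at nominal 5%) — a known limitation,
not a defect of the implementation; the package's emphasis is AICc ranking,
not p-values.

The multivariate ("shape") scores sum eight independent per-feature fits of
identical structure (summed log-likelihoods, parameter counts, and sample
sizes for the AICc correction; summed LRT χ² with summed df for the p-value).
Each feature is z-scored first since units differ across features. This is
the simplest defensible multivariate construction over a univariate mixed
model and is labelled as such in the output; it ignores residual
correlations between features.

`aicc` uses −2ℓ + 2k + 2k(k+1)/(n−k−1); Akaike weights are
exp(−Δ/2)/Σexp(−Δ/2). Collinearity screening (Pearson r with two-sided
t-test) flags size proxies at |r| > 0.85 (default), the regime in which SVL
and TL are excluded in favour of AG.

## 2. Geometric standardization of head patterns

- **Configurations.** 33 planar points: 9 anatomical landmarks + 24 outline
  semi-landmarks, kept in file order. Semi-landmarks are treated as fixed
  points; no sliding is performed (none is specified for this workflow, and
  sliding would add a free algorithmic choice the analysis does not need).
- **Superimposition.** Full Procrustes: center, scale to unit centroid size,
  optimal rotation from the SVD of the cross-covariance with det(R) = +1
  enforced (reflections forbidden — a bilaterally asymmetric colour pattern
  must not be mirrored). GPA iterates align-all/re-mean/re-scale until the
  mean moves < 1e-8 (Frobenius) or 100 iterations, starting from the first
  specimen; on the default design it converges in ~3 iterations.
- **Thin-plate spline.** Standard TPS system with kernel U(r) = r² ln r²
  (U(0)=0); the fitted map interpolates source→target exactly; bending
  energy tr(W'KW) is zero iff the target is an affine image of the source.
  Exactly-3-point collinear sources fall back to the least-squares affine
  map; larger singular systems raise.
- **Consensus frame.** The unit-size consensus is placed into a configurable
  raster (default 96×72; pixel centers at integer 0-based row/col, origin
  top-left, y flipped from the TPS convention in exactly one documented
  place) with a 10% margin. The default desk-scale frame keeps J (in-mask
  pixels, ~3000) small enough for seed-sweep testing; the construction is
  resolution-independent and accepts camera-scale frames.
- **Warping.** Backward: TPS fitted from consensus-frame landmarks to the
  individual's image landmarks; every frame pixel center is mapped into the
  source image and sampled **nearest-neighbour** (patterns are strictly
  binary; interpolation would invent grey), out-of-bounds → 0.
- **Head mask.** Pixels whose centers fall strictly inside the closed
  polygon through the 24 semi-landmarks (even-odd rule; shapely handles the
  containment, a brute-force ray-cast is the test oracle). Self-intersecting
  outlines are rejected. The pixel matrix stacks each warped image's mask
  pixels in row-major order.

## 3. Bernoulli-mixture clustering and ICL

EM with multi-start (default 10 random responsibility initializations;
Dirichlet rows → M-step → iterate), stopping at relative log-likelihood
change < 1e-8 or 500 sweeps; the best-likelihood start wins, ties to the
earlier start. All θ estimates use Laplace pseudo-counts 0.5/1.0 — without
smoothing, class-pure pixels (common: the patch interior is pure within a
cluster) send the supervised log-likelihood to −∞. E-steps run in log space
with per-row log-sum-exp.

Scores: BIC = −2ℓ + ν ln n with ν = (K−1) + K·J; H = −Σ τ ln τ;
**ICL = BIC + 2H** (the soft-entropy variant; the fit records which variant
was used). The MAP-complete-data variant is recovered exactly in the hard
limit, and on well-separated pattern data the responsibilities are
numerically hard, so the two variants coincide there. K is selected as the
ICL minimizer over 2..6 (configurable).

Supervised partitions are scored by a single M-step under one-hot
responsibilities (π = class frequencies, θ = smoothed class means); the
log-likelihood is the mixture likelihood under those parameters and the ICL
entropy uses the model's own recomputed posterior responsibilities.
Classification accuracy is the fraction of individuals whose MAP class under
the fitted parameters equals their given label. Note a supervised ICL is
comparable across partitions of different K on the same data, which is the
ΔICL/accuracy table the pipeline emits. Associations between partitions use
Pearson χ² without continuity correction.

## 4. PLS-DA pixel discrimination

NIPALS PLS2 (via scikit-learn's `PLSRegression`) on the column-centered
pixel matrix against one-hot class labels; columns are **not**
variance-scaled (all pixels share the 0/1 scale). Classification is by
nearest class mean in X-score space. VIP_j = sqrt(J Σ_a ss_a
(w_ja/‖w_a‖)² / Σ_a ss_a) with ss_a the Y-variance explained by component a;
mean squared VIP is identically 1, so VIP > 1 flags above-average pixels,
and constant pixels get VIP 0. The component count, when not given, is
chosen in 1..10 by stratified 5-fold cross-validated accuracy (ties to the
smaller A); the fit itself is deterministic given data and A.

## 5. Synthetic-data generator

The generator emulates the study design so the pipeline is testable without
the field data. It does **not** attempt photorealism, and passing tests on
it show correctness of the machinery on data *with the assumed structure* —
they say nothing about, e.g., segmentation errors, non-planar heads,
landmark digitization bias, or pattern shapes far from a V.

**Design defaults** (one global seed drives every draw; generation is
byte-deterministic):

- Populations: AC (lentic, perspicillata, n=28), CN (lentic, perspicillata,
  19), SA (brook, perspicillata, 27), TC (brook, terdigitata, 41),
  TR (brook, terdigitata, 41) — the five-site sampling layout.
- Size: AG = 22.0 + 2.5·[perspicillata] + 4.0·[lentic] + b_pop + ε, with
  σ_pop = 0.3 mm and σ_ε = 1.8 mm. The habitat effect exceeds the species
  effect (lentic animals larger, as observed in the field); both are
  population-level contrasts. The small random SD relative to the
  deterministic species/habitat structure is deliberate: with only five
  populations, a large random component makes the habitat contrast a ~3-df
  quantity whose ±2SE intervals cannot reach nominal coverage, while the
  deterministic species deviation still gives the AICc comparison a reliably
  detectable between-population variance. Under these defaults the
  site-typology + population model outranks both fixed-only models
  essentially always and the species + population model in ~90% of seeds.
- Allometry: each of the 8 shape features is a_f + c_f·AG + d_pop,f + ε_f
  with slopes giving AG-correlations in the 0.4–0.9 range; SVL = 10 +
  1.15·AG + ε and TL = SVL + tail length + ε make the size proxies
  collinear with AG (r ≥ 0.9), reproducing the exclusion rationale.
- Head shapes: a hand-authored, bilaterally quasi-symmetric 33-point
  template (egg-shaped 24-point outline, 9 interior landmarks; no real
  specimen's coordinates — any plausible head works since the tests depend
  only on self-consistency), perturbed per individual by Gaussian landmark
  noise (SD 0.02 shape units ≈ 1% of head length) and a random similarity
  transform (rotation ±20°, scale 0.8–1.2, small translation) into the
  image grid.
- Patterns: two latent clusters with distinct V-patch geometries (stroke
  half-angle 0.50 vs 0.90 rad, width 7% vs 12%, apex at 35% vs 22% of the
  snout–occiput axis), rendered as two constant-width strokes meeting at the
  apex (hence one 4-connected component). The cluster is habitat-associated:
  P(cluster 0 | lentic) = P(cluster 1 | brook) = 0.9. The two geometries
  disagree on ≈30% of mask pixels after warping, comfortably separable.

**Identifiability caveat.** Because both lentic sites are *S. perspicillata*
(the real sampling layout), the habitat coefficient of any candidate model
is a biased estimand of the generating habitat effect whenever the species
effect is nonzero — the candidate sets never cross the two factors, so no
model is correctly specified under both effects. Parameter-recovery
simulations therefore switch the species effect off (everything else at
default), where the habitat effect is identifiable; under that design the
REML-SE ±2 intervals cover the truth in ~95% of replicates.

**Boundary behaviour.** When all group-level effects are zero, the profiled
ML fit lands exactly on σ_b² = 0 in only ~80–85% of replicates — the
remaining mass is the standard half-χ² boundary phenomenon, not an
optimizer failure — so tests assert a ≥75% boundary rate rather than
near-certainty.

## 6. Problem sizes and determinism

Tests and the acceptance script run the full design (156 individuals) at the
96×72 consensus frame (J ≈ 3000 mask pixels), with 128×128 source images;
seed sweeps use 20 seeds (clustering), 30 (AICc ordering), 100 (recovery),
200 (calibration), and EM uses 3–5 starts in sweeps (10 is the single-run
default). These sizes were chosen as the smallest at which every targeted
property is stable across seeds. All stochastic stages take explicit seeds;
the pipeline writes a JSON manifest (seed, sizes, config) sufficient to
reproduce a run byte-for-byte.

## 7. Known limitations

- No semi-landmark sliding; no 3D; landmarks and segmented masks are inputs,
  not computed from photographs.
- The LRT p-values are asymptotic and anticonservative for group-level
  factors with five populations (see §1); Satterthwaite/Kenward–Roger
  denominator corrections are out of scope.
- The multivariate shape score ignores between-feature residual correlation.
- Supervised and unsupervised ICL values are comparable within this package
  but not to other software's ICL magnitudes (different constants,
  smoothing, and pixel counts).
- Binary (two-level) pixels only; the general categorical mixture is not
  implemented.
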
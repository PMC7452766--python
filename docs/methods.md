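# Methods

This note documents the statistical models, the sampler, the synthetic-data
generator and the numerical choices made in `rafspec`, including where a
design decision was genuinely open and which option was taken.

## 1. The hurdle joint species distribution model

For sample (plant individual) i and fungal species (OTU) j, the data are
read counts c_ij. The model separates occurrence from abundance:

**Occurrence (probit part).**
y_ij = 1{c_ij > 0} and

    y*_ij = x_i' β_j + λ_j' η_{loc(i)} + ε_ij,   ε_ij ~ N(0, 1),
    y_ij  = 1{y*_ij > 0}.

**Abundance conditional on presence (lognormal part).** For cells with
y_ij = 1,

    log c_ij = x_i' β~_j + λ~_j' η~_{loc(i)} + ε~_ij,  ε~_ij ~ N(0, σ_j²).

Absent cells contribute nothing to the abundance likelihood. The two parts
share the design but have independent coefficients, loadings, and factors;
they are conditionally independent given the presence/absence split, so
they are fitted separately.

**Fixed effects.** All models include elevation, elevation², soil pH, soil
water content, active-layer depth, vegetation cover, and log total read
count (sequencing depth). Depth enters as a free-coefficient covariate, not
an offset, in both parts — detection and measured abundance both scale with
effort in a species-specific way. Host plant species enters m2/m3 as
treatment contrasts against the first host level (first-appearance order in
the metadata); m3 adds host × (standardized) elevation products. Continuous
covariates are standardized to mean 0, sd 1 *on the fitting data*;
elevation² is computed from standardized elevation and then standardized
itself; prediction reuses the stored training moments. With 5 hosts the
design has p = 8 (m1), 12 (m2), 16 (m3) columns.

**Random effect.** Sampling location enters through latent factors:
η_l ~ N(0, I_K) per location with species loadings λ_j, default K = 2 for
both parts (config). This is a fixed-rank simplification of the
adaptive-shrinkage factor priors used by full JSDM frameworks; at ~12–18
locations a rank-2 structure is adequate and keeps every conditional
conjugate. The loadings are sign/rotation unidentified; every exposed
quantity (predictions, likelihoods, variance partitions) depends on them
only through λ_j'η and ||λ_j||², which is tested by rotation-invariance
property tests.

**Priors.** β ~ N(0, 5²) per coefficient (weakly informative on
standardized covariates), λ ~ N(0, 1), η ~ N(0, 1), σ_j² ~
inverse-gamma(2, 1). The probit residual variance is fixed at 1 for
identification.

## 2. Sampler

Both parts use blocked Gibbs. The probit part augments truncated-normal
latents z_ij (inverse-CDF sampling, quantiles clipped to ±8 standard
units for numerical stability). Two blocking choices matter and were
adopted after the naive scheme proved to mix poorly:

1. **Joint (β_j, λ_j) update.** Given η, the coefficients and loadings of
   one species are drawn together from their joint conjugate normal on the
   augmented design [X H], H = η_{loc(i)}. Location-level covariate columns
   correlate strongly with H; updating β and λ in separate blocks leaves a
   slowly mixing ridge. In the probit part the joint precision is shared
   across species (unit residual variance), so the update is one Cholesky
   per iteration; in the abundance part the per-species masked precisions
   are batched.

2. **Confounding sweep.** Environmental covariates are measured per
   location, so they are *exactly* constant within locations and the model
   is likelihood-invariant under the translation η → η − W D,
   β_j[loc-constant cols] → β_j + λ_j D' (W = per-location covariate
   values). The posterior along this direction is determined only by the
   Gaussian priors, so D is drawn exactly from its Gaussian conditional
   each iteration (a Kronecker-structured (qK × qK) solve) and applied.
   Without this move, split-PSRF of location-level coefficients exceeds 2
   at any feasible chain length; with it, all-parameter max PSRF ≈ 1.05–1.1
   at the default fit sizes.

Defaults: 2 chains, 1000 warmup, 500 kept draws at thinning 5, seeded via
a master seed fanned out per chain and part through `SeedSequence`; every
fit is bit-reproducible given its configuration. Convergence is summarized
by split-chain PSRF (R-hat) over regression coefficients and residual sds.
Species that are all-absent or all-present are fitted under prior
regularization with a warning; abundance fits with < 3 present cells are
flagged low-information.

## 3. Model evaluation

**WAIC.** lppd = Σ_u log(mean_d exp ll_du) (log-sum-exp stabilized), p_waic
= Σ_u var_d(ll_du) (sample variance), waic = −2(lppd − p_waic). Units are
(sample, species) cells: every cell for the occurrence part, present cells
only for the abundance part; the two parts are scored as separate unit
sets. Because the scale convention of community WAIC reports varies, both
the raw sum and the per-unit mean are exposed ("sum" / "mean"
normalization); model ranking is invariant to the choice.

**Cross-validation.** Folds are stratified by (location, host) group: the
individuals of each group are randomly permuted and dealt round-robin into
k folds from a random starting fold, so group counts differ by at most one
and size-k groups hit every fold exactly once (default k = 5). Every
location therefore appears in every training set, and held-out samples are
predicted *conditioning on* the location's posterior factors. Held-out
predictions are pooled across folds before computing per-species metrics
(one curve per species rather than per-fold averages — lower variance at a
few hundred samples):

* AUC via the Mann–Whitney statistic, (concordant + ½ ties)/(n₁n₀);
  undefined when a species has a single class held out.
* signed R² = sign(ρ)·ρ² of observed vs predicted log counts on held-out
  present cells — the signed form admits negative values for
  anti-predictive models; 0 when either vector is constant, undefined below
  3 pairs. (A plain squared correlation cannot be negative, so it could not
  represent worse-than-null predictive power.)

Undefined species are excluded from means and improvement proportions, with
exclusion counts reported. Improvement proportions count strict
inequalities; ties contribute nothing.

**Selection rule.** The WAIC winner is the lowest-WAIC model, ties within
1e-6 resolved to the simpler model. "Specialization supported" requires m2
to beat m1 on *every* available criterion — lower WAIC, higher mean
predictive power, improvement proportion > 0.5 — and "changing
specialization" is the analogous m3-vs-m2 statement. The conjunction
mirrors the two-way evaluation (information criterion + predictive power)
and keeps the false-support rate low under null data.

## 4. Variance partitioning and specialization scores

Per posterior draw and species, each covariate group g ∈ {host (incl.
host×elevation), elevation (linear + squared), soil (pH, water,
active-layer depth, vegetation cover), depth} has linear score f_g = X_g
β_g over the fitting samples. Group g is attributed Var(f_g) + Σ_{h≠g}
cov(f_g, f_h) — i.e., each covariance is split equally between the two
groups involved. The location random effect contributes ||λ_j||²
(unit-variance factors). Negative attributions are clipped at zero and the
fractions renormalized to sum to one, keeping the decomposition
interpretable and testable; this equal-split-then-clip convention is this
package's own choice among several defensible ones. The intercept spans no
variance across samples and is excluded. Host×elevation columns are
attributed to the host group since they encode host-specific responses.
The network-level headline is the unweighted mean host fraction over
species, reported per guild.

Species-level specialization is AUC(m2) − AUC(m1) from cross-validations on
identical folds (enforced via a fold digest), ranked descending and
reported with per-host prevalence tables (fraction of each host's
individuals occupied; the sample-count-weighted row mean equals the overall
prevalence exactly).

Before any modelling, species occurring in fewer than 5% of samples are
excluded; the boundary case (exactly 5%) is kept — only strictly rarer
species are removed. Counts are raw reads; sequencing depth is a covariate,
not a rarefaction target. A square-root relative-abundance transform and
Bray–Curtis dissimilarities are provided for ordination input; the
dissimilarity of two all-zero rows is defined as 0 to keep the matrix
total.

## 5. Synthetic-data generator

The generator emulates the hierarchical study design so that the inference
chain can be validated against known truth:

* **Design.** 18 locations at evenly spaced elevations spanning 33–479 m;
  5 host species × 5 individuals per location (450 samples); optional
  independent sample dropout. Soil covariates are drawn at the *location*
  level as linear trends in elevation plus Gaussian noise — water content,
  active-layer depth and vegetation cover decline with elevation, pH varies
  mildly. The trend coefficients are configuration defaults chosen for
  qualitative shape, not estimates. Sequencing depths are truncated
  lognormal (meanlog = log 1240, sdlog 0.75, truncated to [100, 20000]),
  giving median ≈ 1.2·10³ and a 10²–2·10⁴ range.
* **Communities.** Counts follow exactly the hurdle structure of §1, with
  coefficients drawn directly in the m3 design coding so that truth is
  directly comparable to fitted coefficients. Counts are
  round(exp(·)) floored at 1, so count ≥ 1 *iff* present holds exactly.
  Rank-2 location factors are drawn independently for the two parts (a
  documented simplification).
* **Scenarios.** `none`: all host and host×elevation effects zero.
  `uniform`: floor(0.3·J) species are planted specialists, each with a
  probit host effect drawn U(1, 2) on one randomly chosen non-reference
  host (and U(0.5, 1) on the log-abundance scale); all other species have
  exactly zero host effects. `changing`: specialists additionally carry a
  host×elevation interaction (±U(0.5, 1) probit). Guild labels
  (mycorrhizal / endophytic / unclassified) are assigned by deterministic
  round-robin at configurable proportions (default 78:63:90), and
  specialist planting can be restricted to one guild for guild-contrast
  studies.

**What the generator does not emulate:** PCR/primer bias, taxonomic error,
compositionality constraints of fixed sequencing depth, phylogenetic
structure among hosts or fungi, spatial autocorrelation beyond the location
level, and diffuse weak host preferences in non-specialist species. The
last point matters for interpretation: in real RAF data most species appear
to carry at least weak host signal, whereas the `uniform` scenario gives
70% of species exactly zero host effects. Passing validation therefore
demonstrates detection of discrete planted specialization, not the full
texture of real communities (see §7).

## 6. Validation studies

`rafspec.validation` packages the end-to-end studies (also driven by
`scripts/acceptance.py`): a reduced design of 40 species, 12 locations, 5
hosts and 3 individuals per host keeps each replicate ~10 s on one CPU
while preserving the hierarchical structure. Replicated m1-vs-m2
comparisons are run under `uniform` and `none` scenarios (WAIC fits with 1
chain, 400 warmup / 300 draws; cross-validation with 300 / 400); host-effect
recovery uses a 2-chain fit with 800 warmup and 500 kept draws at thinning
2.

## 7. Known limitations

* **Partial identifiability of location-level effects.** Even with the
  sweep move, the *statistical* (not computational) confounding between
  location-level covariates and location factors remains: with 12–18
  locations, the split of location variance between "soil/elevation" and
  "random" in the variance partition carries real posterior uncertainty.
  Host fractions are unaffected (hosts vary within locations).
* **Recovery precision at reduced designs.** With 3 individuals per host
  per location (~36 samples per host), the per-species probit host
  contrasts have posterior/maximum-likelihood noise of sd ≈ 0.35–0.4; the
  correlation between true and posterior-mean host effects plateaus around
  0.75 at this size even for an oracle given the true latent factors. More
  individuals per host, not more MCMC, is what improves it.
* **Improvement proportions under discrete scenarios.** Because
  non-specialists have exactly zero host effects in the `uniform` scenario,
  the extra host coefficients of m2 slightly degrade their held-out AUC;
  community-wide "proportion of species improved" then hovers near 0.5
  even when WAIC and mean AUC clearly favor m2. Real communities with
  diffuse host signal yield larger proportions.
* The abundance part models unscaled log counts (no per-species scaling);
  residual variance is species-specific but homoscedastic across sites.
* No spatial/temporal or phylogenetic random effects; no
  Poisson/negative-binomial observation models; fixed factor rank.
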
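# Methods

`soilheat` implements the statistical machinery for split-plot laboratory
experiments that expose field-collected soil cores to simulated extreme
heat events and track the resistance (immediately after the event) and
recovery (after a post-event period) of two trophic groups: Collembola
(springtails, identified to species and classed by vertical stratum) and
soil fungi (ITS metabarcoding reads, classed by trophic guild). This note
describes the models, their assumptions, the synthetic-data generator, and
the numerical choices; it states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Experimental design

The design is a split-plot layout with two regional blocks, one site per
elevation (high ~1550 m, low ~500 m) nested in each block, three sampling
seasons applied at the plot level (five plots per site and season), and
the temperature treatment (control vs. extreme heat) and destructive
harvest (H1 baseline, H2 resistance, H3 recovery) randomised at the
soil-core level. The default `DesignSpec` enumerates

    2 elevations x 2 sites x 3 seasons x 5 plots x 2 treatments x 3 harvests = 360

experimental units, 120 per harvest. `design.build_model_matrix` codes the
three-way factorial with treatment (dummy) contrasts; the reference cell is
(spring, high elevation, control), so the intercept of every model is that
cell and treatment terms read directly as heat responses. Sum-to-zero
coding is not used anywhere. Nesting (site within block, plot within
site x season) is carried explicitly in the unit table so any grouping
level can serve as a random-effect factor.

Temperature regimes are derived from daily mean series: the control
set-point is the mean daily temperature of the two incubation months; the
heat set-point is the 99th percentile of daily means over the reference
period, applied for 7 consecutive days. The percentile interpolation rule
is not fixed by the protocol; we use linear interpolation between order
statistics and expose the rule as an argument. Both regimes run a 16 h/8 h
photoperiod with a 6 °C day–night amplitude; the day/night split
(day = base + A/3, night = base − 2A/3) preserves the 24-h time-weighted
mean.

## Abundance models (per harvest)

All univariate analyses fit, separately for each harvest,

    response ~ elevation * season * treatment + (1 | site)

- **Counts (total Collembola; fungal reads summed per guild):** NB2 GLMM
  with log link, variance mu + mu²/k. Maximum likelihood with a Laplace
  approximation of the random-intercept integral (a per-group Newton inner
  loop inside a quasi-Newton outer optimisation over beta, log k,
  log sigma_u²). Laplace rather than adaptive quadrature is adequate here:
  with only four sites the site-variance estimate is imprecise whatever
  the integration rule, and that imprecision is inherited from the design
  itself. Wald covariance comes from the observed information (central
  finite differences) of the approximated marginal likelihood. When the
  variance component collapses (< 1e-3 SD) the fit reduces to the
  fixed-effects model and is flagged `boundary`. Guild read models include
  centred log total reads as an estimated covariate — not a fixed-1
  offset — so read counts are analysed as relative abundances.
- **Gaussian responses (diversity point estimates):** linear mixed model
  via statsmodels `MixedLM`, ML by default (REML available; for a balanced
  one-way layout REML reproduces the ANOVA variance-component estimator,
  which the tests exploit as an oracle). The wrapper fits with two
  optimisers and keeps the better likelihood, because one optimiser was
  observed to report convergence at a spurious point.

**Marginal means and contrasts.** A cell's marginal mean is L·beta with
SE = sqrt(L Σ Lᵀ), where L is the coded row for that cell averaged with
equal weights over any fixed factors not requested. Heat-vs-control
contrasts at a cell are reported as percent change
100·(exp(Δ)−1) with the delta-method SE 100·exp(Δ)·SE(Δ) and a CI mapped
from the link scale — the standard emmeans-style back-transform. The
delta-method SE is a first-order approximation: its relative error
against the exact lognormal SD is ≈ 3σ²/4, i.e. ~1.3% at SE(Δ) = 0.13
(typical at n = 120) but ~6.5% at SE(Δ) = 0.3; the tests therefore check
bootstrap agreement in the regime the models actually produce. Identity
link fits refuse the percent transform and return the raw difference.
P-values are Wald-z; with four sites no degrees-of-freedom correction is
well identified, and this choice is deliberately simple and stated.

## Diversity

Hill numbers D_q = (Σ p_i^q)^{1/(1−q)} (D_1 = exp of Shannon entropy) are
computed at q = 0, 1, 2 and standardised by coverage-based rarefaction and
extrapolation:

- Sample coverage: Chao–Jost estimator
  Ĉ = 1 − (f1/n)·(n−1)f1/((n−1)f1 + 2 f2) from singleton/doubleton counts;
  a sample that is a single singleton has undefined coverage and returns 0
  by convention.
- Rarefaction uses exact hypergeometric expectations: classic rarefied
  richness at q = 0, the exact expected plug-in entropy (exponentiated)
  at q = 1, and the unbiased Simpson form at q = 2. These match exhaustive
  enumeration over all C(n, m) subsamples to 1e-9 on small vectors (tested).
- Extrapolation uses the Chao1-based richness formula, the
  Chao–Wang–Jost asymptotic entropy estimator blended with the observed
  entropy (weights n/m and 1−n/m), and the Simpson form which is valid for
  any m. Extrapolation is capped at twice the reference sample size
  (configurable); targets beyond the cap are clamped with a warning.
- Equalisation: the base coverage is the minimum across samples of the
  coverage attained at twice each sample's reference size; all samples are
  then estimated at that base. Empty samples, and samples whose coverage
  is undefined, are dropped from the base computation with a warning.
  When heat treatments decimate some samples the base can be low and the
  standardisation aggressive; this is the price of comparing like with
  like and is inherent to the coverage-equalisation method, not to this
  implementation.

The resulting point estimates feed the Gaussian LMM above.

## Joint species distribution models

Three families cover the multivariate analyses, all sharing one Gibbs
sampler core with species-level coefficients drawn around trait-predicted
expectations:

- **lognormal-Poisson** (Collembola counts): y_ij ~ Poisson(exp(eta_ij)),
  eta_ij ~ N(x_i' beta_j + a_{b(i),j}, sigma_j²). The latent eta layer is
  updated by adaptive Metropolis-within-Gibbs (per-species step sizes
  tuned toward 44% acceptance during the transient); everything else is
  conjugate.
- **hurdle, presence part** (probit): Albert–Chib truncated-normal data
  augmentation; fully conjugate. The presence posterior is invariant to
  rescaling the abundances (tested), so the two hurdle parts separate
  cleanly.
- **hurdle, abundance part** (Gaussian, conditional on presence): the
  response is log reads, z-scored per species over its present samples;
  each species' regression uses only its present rows. Centred log depth
  enters as a covariate column.

Hierarchy: beta_jk ~ N((T gamma)_jk, tau_k²) per term k, with T the
species x trait matrix (vertical stratum for Collembola, trophic guild
for fungi; intercept prepended), gamma_jk ~ N(0, 100), tau_k² ~ IG(2, 1).
Block random intercepts a_{b,j} ~ N(0, sigma_B²) with sigma_B² ~ IG(2, 0.25)
shared across species; with only two blocks nothing richer (latent
factors) is identifiable, and plain intercepts are a stated
simplification. Residual variances are IG(2, 1). These priors are weakly
informative and chosen for conjugacy; no numerical equivalence with any
particular jSDM package is claimed.

Defaults: 4 chains x 250 retained samples (1000 draws), transient 250,
thin 1, all configurable, seeds recorded. The Metropolis-within-Gibbs
latent layer mixes slowly on interaction coefficients for cells where a
species is nearly absent (little data, strong beta–eta coupling); when
R-hat flags this, lengthening the chains via thinning (e.g. transient
500, thin 4, retained draws unchanged) restores convergence, and the
acceptance script uses that plan. Rare taxa are removed before fitting
with a 25% prevalence filter (at 120 units per harvest the cutoff is 30
occurrences).

**Diagnostics and summaries.** Convergence is monitored with a potential
scale reduction factor computed as R̂ = sqrt((W + B*)/W), where W is the
mean within-chain variance and B* the variance of chain means. This
variant omits the classic (n−1)/n finite-sample factor so that identical
chains give exactly 1.0 and well-separated chains diverge; it differs
from the textbook estimator by O(1/n) and from rank-normalised split-R̂
more substantially, which users comparing against other software should
note. `check_convergence` refuses downstream use above a threshold
(default 1.2). Coefficients are classified positive/negative when the
posterior sign probability reaches 0.95 (numerically near-identical to a
95% credible interval excluding zero, the stated alternative). Variance
partitioning attributes, per species, the variance over the design of
each term group's partial linear predictor (treatment terms; natural
terms = season, elevation and their interaction; block variance as the
random group), normalised to sum to one. Within-group covariances only —
cross-group covariance is not attributed, which keeps shares non-negative.

## Association networks and the connectance null model

For one harvest (recovery by default) the data are split into
elevation x season subsets of 20 samples (2 sites x 5 plots x
2 treatments). Subsets where fewer than a minimum number of Collembola
species occur in at least 3 samples are skipped with a logged reason —
associations cannot be determined when the consumers are essentially
absent. Within a subset, per fungus f (on its present samples):

    y_f = a + b·heat + c'·(block, log depth) + Σ_c beta_cf z_c + Σ_c delta_cf (z_c·heat) + eps

with y_f the per-taxon z-scored log reads and z_c the log(x+1) z-scored
Collembola abundances, standardised within the subset. The block and
depth columns absorb shared-environment and sequencing-depth structure
that would otherwise masquerade as cross-trophic association. The prior is
a conjugate normal-inverse-gamma ridge (coefficient scale 1 on the
standardised predictors, sigma² ~ IG(2, 1)), so all pair posteriors are
Student-t and evaluated analytically — this is what makes the permutation
null model cheap. The control association of pair (c, f) is beta_cf; the
heat association is beta_cf + delta_cf.

Edges are pairs whose equal-tailed 95% credible interval excludes zero;
sign and weight come from the posterior mean. Connectance is computed per
sign as edges/(nC·nF) over all modelled species (configurable). The
treatment difference d = connectance_heat − connectance_control is tested
against a null obtained by permuting the treatment labels across the
subset's samples and re-running the full fit → CI-filter → connectance
pipeline; this label-exchangeability null preserves every species'
marginal distribution exactly and is the most conservative choice given
that the original null-model recipe is not fully specified. The p-value
uses the add-one convention, one-sided toward an increase (two-sided
optional); z = (d − mean_null)/sd_null, flagged undefined when the null
has zero spread. The statistic is discrete (multiples of 1/(nC·nF)), so
at very small network dimensions ties make the test conservative; at the
study's dimensions (9 x 40 pairs) the measured type-I rate is nominal.
Edges are statistical associations, not demonstrated feeding links.

## Synthetic-data generator

The generator is first-class, tested code; it emulates the statistical
structure the estimators assume, with every ground-truth parameter
retained for recovery tests.

- **Collembola:** NB2 counts, mean exp(X beta_h + site effect), site
  effects N(0, 0.4²) per (site, species) — intraclass correlations in the
  0.1–0.3 range the design implies but the study does not report — and
  k = 1.5. Nine species (three per vertical stratum) with log intercepts
  3.0..1.0. Community-level heat:control ratios are planted per
  (elevation, season, harvest) cell: ln(0.31) and ln(0.23) at resistance
  (low elevation, spring/summer), ln(0.24) at recovery (low summer),
  zero elsewhere — declines concentrated at low elevation with recovery
  in spring but not summer. Species' responses are heterogeneous
  (log-scale multipliers 0.4..1.6, rare species hit harder), with the
  cell values re-calibrated so the community totals keep the nominal
  ratios; without heterogeneity, relative abundances would be unchanged
  and coverage-standardised diversity would show no treatment response.
- **Fungi:** probit occurrence (prevalence ~0.35–0.95) and conditional
  lognormal reads with depth coefficient 1.0 on log-normal depths
  (median ≈ 2 x 10⁴ reads), block effects on both parts, residual SD 0.6.
  Forty taxa (18 saprotrophs, 8 pathogens, 8 symbionts, 6 unassigned).
  Guild-level heat shifts mirror the reported responses: pathogens up at
  recovery after summer heat at both elevations, symbionts down at
  resistance in high-elevation spring and up at recovery in high-elevation
  summer, unassigned up at recovery in low-elevation spring.
- **Associations:** fungal conditional log-abundance is shifted by
  A'z + heat·D'z with z the within-cell standardised Collembola
  abundances — the same transform the estimator applies, so planted slopes
  are on the estimator's scale. The default plants heat-only negative
  slopes (−2.0) from one of four collembolan species to each saprotroph
  and nothing in control, emulating the heat-induced rise in negative
  connectance. One consumer per fungus keeps slopes identifiable: strong
  slopes stacked on one fungus inflate its response variance and the
  per-taxon scaling then dilutes all of them.
- Seeding: one master seed is split into per-matrix substreams
  (SeedSequence); identical seeds give byte-identical studies.

**What the generator does not emulate:** taxonomic abundance
distributions beyond a log-linear intercept gradient, spatial structure
within plots, compositionality constraints on reads (depths are drawn
independently of composition), temporal autocorrelation across harvests
(per-harvest coefficient tables are independent), and species
interactions within a trophic level. Passing tests therefore demonstrate
that the estimators recover the structure they model, under that model's
assumptions — not that the models are adequate for any particular field
dataset.

At desk scale the default world's connectance signal is modest (the
observed spring-low difference is positive but its permutation p
fluctuates around 0.1 across seeds); the type-I calibration of the test
itself is exact, and power at larger planted-effect fractions is
demonstrated separately in the test suite.

## Problem sizes used by the default test and acceptance runs

Chosen as the package's own desk-scale defaults: NB GLMM calibration uses
200 replicates at n = 120 with a planted log-ratio of −1; jSDM sign
recovery uses 20 replicates (n = 120, six species, 2 chains x 150 draws
after 150 transient); the connectance calibration uses 200 null subsets
of 20 samples (9 x 40 species) with 99 permutations each; the acceptance
script runs the full study-scale pipeline once (4 chains x 250 draws,
999 permutations).

## Known limitations

- Wald-z inference for GLMM contrasts; no Kenward–Roger-style df.
- The Laplace approximation can bias variance components at very small
  group counts; with four sites this is a design property.
- No DHARMa-style residual diagnostics and no zero-inflated univariate
  GLMM (zero inflation is handled only in the jSDM hurdle).
- Incidence-based diversity is not implemented; abundance-based only.
- The jSDM has no spatial or phylogenetic structure and no model
  comparison (WAIC/cross-validation).
- The connectance permutation test re-uses one fitted design per
  permutation draw; with very uneven presence patterns its power depends
  on the fungal presence filter (default: present in ≥ 25% of subset
  rows).
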
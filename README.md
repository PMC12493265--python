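# soilheat

Statistical pipeline for laboratory heat-event experiments on belowground
communities. Intact soil cores collected from high- and low-elevation
grasslands in three seasons are exposed to a one-week simulated extreme
heat event, and the resistance (immediately after the event) and recovery
(after a multi-week post-event period) of two trophic groups are
measured: **Collembola** (springtail counts, species-level, classed as
epedaphic / hemiedaphic / euedaphic) and **soil fungi** (ITS metabarcoding
reads, classed as saprotroph / pathogen / symbiont / unassigned). The
package is aimed at soil ecologists analysing such split-plot microcosm
designs, and ships a synthetic-study generator so every stage is testable
without field data.

## What it computes

All per-harvest analyses share the three-way factorial mixed model

```
response ~ elevation * season * treatment + (1 | site)
```

- **Abundance** — NB2 GLMMs (log link, variance μ + μ²/k, Laplace ML over
  site random intercepts; written in-house since no Python package fits NB
  mixed models) for total Collembola counts and guild-summed fungal reads
  (with log sequencing depth as covariate). Heat-vs-control contrasts are
  reported as percent change 100·(e^Δ − 1) with delta-method SEs, the
  emmeans-style back-transform.
- **Diversity** — Hill numbers D_q (q = 0 richness, 1 exponential
  Shannon, 2 inverse Simpson) standardised by coverage-based rarefaction
  / extrapolation (Chao–Jost coverage from singletons f₁ and doubletons
  f₂; exact hypergeometric rarefaction), then tested with Gaussian LMMs.
- **Joint species distribution models** — Gibbs-sampled hierarchical
  models: lognormal-Poisson for Collembola counts and a probit +
  conditional-lognormal hurdle for fungal reads, with trait-predicted
  coefficient expectations (β_jk ~ N((Tγ)_jk, τ_k²)), block random
  intercepts, Gelman–Rubin R̂ diagnostics, sign-probability support
  classification at 95%, and variance partitioning into treatment /
  natural / random components. Rare taxa are dropped by a 25% prevalence
  filter (cutoff 30 of 120 units per harvest).
- **Association networks** — per elevation × season subset (20 samples),
  fungal conditional log-abundances are regressed on standardised
  Collembola abundances and their heat interactions (conjugate Bayesian
  ridge); pairs whose 95% credible interval excludes zero form signed
  bipartite networks, connectance = edges/(n_C·n_F) per sign, and the
  heat-minus-control connectance difference is tested against a
  treatment-label permutation null.

See `docs/methods.md` for the models, priors, and numerical conventions.

## Worked example

```python
import soilheat as sh

cp = sh.default_collembola_params()
fp = sh.default_fungal_params()
ap = sh.default_association_params(cp, fp)
study = sh.simulate_study(cp, fp, ap, seed=42)      # 360-unit synthetic study

h2 = study.units[study.units.harvest == "H2"]       # resistance harvest
mm = sh.build_model_matrix(h2, groups="site")
y = study.collembola.loc[h2.index].sum(axis=1)
fit = sh.NegativeBinomialMixedModel(y, mm, harvest="H2").fit()
for season in ("spring", "summer", "autumn"):
    pc = fit.percent_change({"elevation": "low", "season": season})
    print(f"low / {season:6s}: {pc}  (p = {pc.p_value:.3g})")

sub = [s for s in sh.make_subsets(study, harvest="H3")
       if s.elevation == "low" and s.season == "spring"][0]
nt = sh.connectance_difference_test(sub, sign="negative", n_null=999, seed=42)
print(f"negative connectance, heat - control: {nt.observed:+.3f} "
      f"(z = {nt.z:.2f}, p = {nt.p_value:.3f})")
```

prints

```
low / spring: -73.0% ± 4.6%  (p = 1.65e-14)
low / summer: -82.6% ± 3.4%  (p = 3.06e-19)
low / autumn: +40.1% ± 20.8%  (p = 0.0233)
negative connectance, heat - control: +0.026 (z = 1.66, p = 0.071)
```

The generator plants strong Collembola declines under heat at low
elevation in spring and summer (none in autumn), and the fitted GLMM
recovers them as percent changes with delta-method SEs; the planted
heat-only negative Collembola–saprotroph associations push the negative
connectance difference above its permutation null. Single-study estimates
scatter around the planted values from seed to seed, exactly as field
estimates scatter around the truth.

The same stages are scriptable from the shell:

```bash
soilheat design enumerate                     # 360 units, 120 per harvest
soilheat synth generate --out data/ --seed 1
soilheat run-all --data data/ --out results/ --seed 1
```

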
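# lfabund — linear-features abundance models for farmland birds and butterflies

Hedgerows, banks, ditches and tree lines — the *linear features* of
farmland — are known from field studies to matter for many species, but
they are too fine for standard land-cover maps. `lfabund` implements a
national-scale abundance analysis that asks whether mapped linear-feature
lengths improve models of bird and butterfly counts beyond land cover
alone, and whether a canopy-height classification of *woody* linear
features (hedges and tree lines) does better still.

The package is aimed at quantitative ecologists: it provides the full
modelling pipeline as reusable, tested components, together with a
synthetic-data generator with known ground truth so every stage can be
verified end to end.

## The model

Counts N_it of a species at site *i* in year *t* (50-km region *j*)
follow a Poisson generalized linear mixed model:

    log E[N_it] = α + Σ_c (β₁c x_ci + β₂c x²_ci) + β_t
                  + [log P_iv]
                  + Observation_it + Site_i + Region_j

* x_c — environmental covariates on [0, 1]: land-cover proportions in a
  1-km buffer, scaled altitude, and linear-feature length (m / 100 000),
  each entering with linear and quadratic terms;
* P_iv — detection probability for birds, from a half-normal detection
  function g(x) = exp(−x²/2σ²) fitted to counts in two bounded distance
  bands (0–25 m, 25–100 m) with visit and habitat covariates on log σ;
  log P enters as an offset;
* random effects: an observation-level effect (overdispersion), a site
  effect, and a 50-km-region effect, all normal on the log scale.

Fitting maximises the Laplace-approximated marginal likelihood with
analytic gradients. Eight candidate covariate sets per species (full and
agricultural land cover, each without/with additive or interacting
linear-feature terms, linear-features-only, year-only) are compared by
AIC weights, 95% confidence sets, variable selection probabilities and
Nakagawa–Schielzeth marginal/conditional R²; predictive value is
measured by repeated 75/25 site-level cross-validation RMSE on the
linear-predictor scale, ANOVAs over iterations, and exact binomial sign
tests across species. Segments are classed as woody when mean canopy
height ≥ 0.58 m, minimum > −0.13 m and maximum ≤ 58 m.

## Worked example

```python
import lfabund as lf

# a synthetic landscape of 200 sites in 6 regions, surveyed 3 years
cfg = lf.LandscapeConfig(n_sites=200, n_regions=6, n_years=3, seed=42)
sites = lf.generate_sites(cfg)

# a bird whose abundance has a humped response to linear-feature length
truth = lf.TrueParameters(alpha=1.2, beta={"lf_total": (1.5, -1.0)})
surveys, _ = lf.simulate_surveys(sites, truth, 3, seed=7, group="bird")

# distance-sampling detection model and site-year counts
det = lf.fit_halfnormal_binned(surveys[surveys.count_band1 + surveys.count_band2 > 0])
agg = lf.aggregate_bird_surveys(surveys, det)

sel = lf.run_model_selection(sites, agg, "bird", "demo")
print(sel.table[["model", "aic", "weight", "in_95_set"]].round(3))
print("LF selection probability:", round(sel.selection_probabilities["lf_any"], 3))
```

Output:

```
                        model       aic  weight  in_95_set
0                        full  2438.582   0.000      False
1            full+lf_additive  2435.716   0.000      False
2         full+lf_interaction  2438.796   0.000      False
3                 agriculture  2414.439   0.016      False
4     agriculture+lf_additive  2412.230   0.047       True
5  agriculture+lf_interaction  2415.631   0.009      False
6     linear_only+lf_additive  2406.979   0.655       True
7                   year_only  2408.724   0.274       True
LF selection probability: 0.711
```

(Values are from this exact seed. The AIC-best model carries the
linear-features term, as it should for a species simulated with a true
effect, and the term's selection probability — the summed Akaike weight
of the models containing it — is 0.71: substantial support, though at
200 sites a two-visit detection-thinned survey leaves real uncertainty,
which is the realistic situation for a species of this abundance.)

A YAML-driven pipeline (`lfabund pipeline --config demo.yml --out-dir out/`)
chains simulation, detection, model selection, the woody-vs-total AIC
comparison and cross-validation, writing per-species and cross-species
CSV summaries; `lfabund simulate/detect/select` expose the stages
individually.

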
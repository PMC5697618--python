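# Methods

This note documents the statistical machinery in `lfabund`: the models,
the numerical choices, what the synthetic-data generator does and does
not emulate, and the design decisions taken where more than one faithful
implementation existed.

## Abundance model

Counts are modelled as Poisson with a log link:

    log E[N_it] = α + Σ_c (β₁c x_ci + β₂c x²_ci) + β_t + [log P_iv]
                  + Observation_it + Site_i + Region_j.

Covariates are raw second-order polynomials on the [0, 1] scale
(land-cover proportions of the 1-km buffer; altitude divided by the
450-m study ceiling; linear-feature lengths in m/100 000). Raw rather
than orthogonal polynomials keep coefficients interpretable on the
common bounded scale; the fitter orthonormalises the design internally
(QR), which is numerically equivalent and removes the strong
linear/quadratic collinearity from the optimiser's path. Year enters as
a categorical fixed effect (first year as reference). The interaction
models add linear × linear products of the linear-features length with
arable and improved-grassland cover, retaining both main-effect
polynomials — the minimal form of a context-dependent effect.

There is no separate residual term: for a Poisson response the
observation-level random effect (OLRE) is the residual-variation term,
absorbing extra-Poisson dispersion.

### Estimation

The marginal likelihood is approximated by Laplace's method:

    l(β, θ) = l_Pois(η̂) − û'D⁻¹û/2 − log|D|/2 − log|Z'WZ + D⁻¹|/2,

with W = diag(exp η̂) and û the conditional mode, found by damped Newton
iterations on the penalised Poisson log-likelihood (inner convergence:
gradient ∞-norm < 1e−11). The outer optimisation is L-BFGS-B over fixed
effects and log standard deviations jointly, with analytic gradients
that include the determinant term's dependence on the modes (via the
implicit derivative dû/dβ = −H⁻¹Z'WX). Optimising β through the full
objective matters: profiling β at the joint penalised mode (the fast
"nAGQ = 0" shortcut) leaves a small systematic intercept bias in
OLRE models — about a tenth of a standard error in our comparisons
against `lme4::glmer`, enough to degrade Wald coverage at large n.

When an OLRE is present its Hessian block is diagonal, so solves,
log-determinants and the gradient traces are computed through an m × m
Schur complement over the site and region levels (m = number of sites +
regions); and because sites nest within regions that complement is an
arrow matrix with closed-form inverse entries, making each evaluation
O(n + S + R). Models without an OLRE use dense Cholesky up to ~1200
coefficients-plus-levels and sparse LU with finite-difference outer
gradients beyond. The code paths evaluate the identical objective
(verified to machine precision in the tests).

Starting values are fixed (Poisson-GLM coefficients; all variances at
0.1), so a fit is a deterministic function of the data. Log σ is bounded
in [−9, 3]; the lower bound is numerically a zero variance (it perturbs
fixed effects by < 1e−4) and such fits carry a `boundary` flag. Standard
errors for fixed effects come from the β-block of the inverse joint
Hessian; for log σ from a central-difference observed information at the
optimum (β held at its estimate).

AIC is −2·loglik + 2k with k = number of fixed effects + number of
variance components. Because all candidate models share the same three
random-effect terms, any consistent convention preserves rankings; this
one is declared rather than inferred.

## Detection model (birds)

The BBS-style protocol records counts in distance bands 0–25 m, 25–100 m
and beyond 100 m; the unbounded band has no width and is discarded, so
"abundance" means birds within 100 m of the line. Detection follows a
half-normal g(x) = exp(−x²/2σ²) with log σ linear in an intercept, a
late-visit indicator and habitat category. The likelihood is the
multinomial allocation of detections between the two bands *conditional
on detection* — true abundance cancels, and enters only through the
count model, which receives log P̄ (the mean of g over 0–100 m) as an
offset. Band means of g have a closed form via the error function and
match adaptive quadrature to 1e−8.

σ is log-parameterised and capped in [1 m, 10 000 m]; counts exactly
proportional to band widths (flat likelihood toward σ → ∞) are snapped
to the upper cap and flagged. The habitat covariate is a single
site-level category here (the dominant collapsed land cover), a
documented simplification of per-200-m-section habitat recording.

The response for a site-year is the maximum 0–100 m count over the two
visits; the offset uses the detection probability of the visit that
supplied the maximum, the earlier visit on ties (the tie rule is a
convention; ties are common at small counts).

## Multimodel inference

Eight candidate models per species: {full, agriculture} × {no LF,
additive LF, interaction LF}, linear-features-only, year-only; all use
total linear-feature length. Woody length enters only the dedicated
comparison, which refits each species' lowest-AIC LF-containing model
with the woody variable and reports ΔAIC = AIC_total − AIC_woody in four
categories split at |Δ| = 4; an exact tie is credited to the simpler,
pre-existing total-length variable. Akaike weights, the 95% confidence
set (smallest weight-sorted prefix reaching 0.95, boundary ties
included) and selection probabilities (summed weights of models
containing a term) follow the standard definitions; additive and
interaction terms are reported separately because interaction terms
appear in fewer models.

R² follows the variance-partition approach for mixed models on the
latent scale: marginal = σ²_fixed / total, conditional = (σ²_fixed +
σ²_site + σ²_region) / total, where σ²_fixed is the variance of the
fixed-effect linear predictor (offset excluded) and the total adds the
OLRE variance and the distribution-specific variance ln(1 + 1/λ). λ is
evaluated at the adjusted intercept — the mean fixed-effect linear
predictor — rather than the raw intercept, because with [0, 1]-scaled
covariates the raw intercept sits at an unrepresentative corner of
covariate space. The OLRE is kept as its own additive component (it is
fitted explicitly), not folded into the distribution variance. In the
large-mean limit ln(1 + 1/λ) → 0 and the Gaussian partition is
recovered.

## Cross-validation and sign tests

Data are split at site level (75% training / 25% testing, all years of
a site on one side) so test sites are spatially distinct; each iteration
shares one split across all candidate models. Predictions for test sites
use fixed effects and offset only — unseen groups have conditional-mean
zero random effects. RMSE is computed on the linear-predictor scale as
√mean[(η̂ − log(y + 1))²]; the observed-side transform is not uniquely
determined by the procedure's description, log(y + 1) is the default and
log(y + 0.5) is available via configuration. ANOVA of RMSE on the model
factor is unpaired across iterations (a guard returns a degenerate flag
when both groups have zero variance), and species are classified
Sig−/NS−/NS+/Sig+ at α = 0.05, a zero change counting as NS−. The
proportion of species improved is tested against 0.5 with an exact
two-sided binomial test using the minimum-likelihood definition of
two-sidedness (it reproduces 0.815 for 8/18 and 0.152 for 16/24).

## Synthetic-data generator

The generator is first-class code: it produces landscapes and surveys
with exactly the statistical structure the model assumes, recording all
ground truth.

* **Land cover** — a Dirichlet draw over the eleven standard buffer
  classes plus an `other` class that is never used as a covariate, so
  the modelled proportions sum to < 1 (otherwise the full covariate set
  would be exactly collinear with the intercept). Default concentrations
  describe enclosed farmland (arable- and improved-grassland-dominated).
* **Altitude** — Beta(1.2, 4) × 450 m: mostly lowland sites.
* **Linear features** — total length log-normal (median 20 km per
  1-km-radius buffer, log-sd 0.5, capped at 100 km); woody fraction
  Beta(2, 2). A Gaussian copula couples log total length and the woody
  fraction; the copula correlation is calibrated by root-finding on a
  fixed Monte-Carlo sample so the two *scaled lengths* hit the target
  Pearson correlation (default 0.46). The attainable range depends on
  the marginals; unattainable targets raise a configuration error.
* **Segments** — site totals are split into ~100-m segments (Dirichlet
  lengths summing exactly to the total); each is labelled woody with the
  site's woody fraction and given canopy statistics that satisfy the
  woody thresholds when labelled woody and violate them (low mean
  canopy) otherwise — a construction fixture for the classifier, not a
  canopy-height model.
* **Surveys** — latent log-means add year offsets and site/region/
  observation normal effects; true abundance is Poisson. Birds: each of
  the N individuals falls in a distance band with probability
  proportional to band width and is detected with the band-mean
  half-normal probability for that visit's σ (band counts are binomial
  thinnings; no continuous distances are simulated, since the analysis
  only ever sees band counts); two visits share one true N per
  site-year. Butterflies: one exhaustive count per site-year. A master
  seed spawns per-stage child streams, so outputs are a pure function of
  (config, parameters, seed); log-means above 20 abort with the
  offending site named.

Default true parameters describe a strong, humped linear-features
effect (α = 1, β_lf = 1.5, β_lf² = −1) with σ_site = 0.4, σ_region = 0.2,
σ_obs = 0.3 and detection σ ≈ 35 m with a +0.2 late-visit shift on
log σ — effect sizes at which the pipeline should, and does, recover the
signal.

What the generator does **not** emulate: spatial autocorrelation beyond
region blocks, covariate measurement error (including woody
misclassification), species interactions, temporal population trends,
unequal survey effort, or missing years. Passing tests therefore
demonstrate the estimators' correctness under the model's own
assumptions — not robustness to the violations real BBS/UKBMS data
contain.

## Problem sizes in the test suite

The tests exercise the study design at reduced scale: recovery and
selection-probability experiments use 800 sites × 3 years (100 and 25
seeded replicates respectively), the end-to-end two-species study uses
400 sites × 3 years over 20 seeded runs with 4 cross-validation
iterations per run, and the demo pipeline runs at 40–200 sites. Sizes
were chosen for power: the prediction-error reduction a realistic
linear-features effect produces is on the order of 1% of the RMSE
(national monitoring schemes field thousands of sites to resolve
effects of this size), and pilot calculations showed it is unresolvable
below a few hundred sites while each experiment's Monte-Carlo error
stays small relative to the thresholds it checks at the sizes used.

## Known limitations

* The Laplace approximation is least accurate for very small counts;
  the quadrature cross-checks in the tests bound the error on small
  instances but real data with many zeros would warrant adaptive
  Gauss-Hermite or integrated-likelihood checks.
* Wald intervals for variance components are computed on the log-σ scale
  and do not exist for boundary (zero-variance) fits.
* The forest exclusion rule has no canonical threshold; the default
  (woodland proportion > 0.5) is configurable and logged.
* The binomial sign test and ANOVA layers assume species are
  independent; no multiple-testing correction is applied across species,
  matching the analysis design.
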
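"""Design construction and the Laplace-approximated Poisson GLMM."""

import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import integrate

import lfabund as lf
from lfabund.glmm import fit_poisson_glmm, predict_eta


# ---------------------------------------------------------------------------
# build_design


def test_agriculture_design_columns(small_sites, butterfly_data):
    spec = lf.ModelSpec("agriculture", "none", "total", False)
    d = lf.build_design(small_sites, butterfly_data["agg"], spec)
    env = [c for c in d.columns if c not in ("intercept",) and not c.startswith("year_")]
    assert env == [
        "arable", "arable^2",
        "improved_grassland", "improved_grassland^2",
        "rough_grassland", "rough_grassland^2",
        "altitude", "altitude^2",
    ]
    assert [c for c in d.columns if c.startswith("year_")] == ["year_2006", "year_2007"]


def test_year_only_design_is_intercept_plus_year(small_sites, butterfly_data):
    d = lf.build_design(small_sites, butterfly_data["agg"], lf.ModelSpec("year_only"))
    assert d.columns == ["intercept", "year_2006", "year_2007"]


def test_interaction_adds_exactly_two_columns(small_sites, butterfly_data):
    add = lf.build_design(
        small_sites, butterfly_data["agg"], lf.ModelSpec("agriculture", "additive")
    )
    inter = lf.build_design(
        small_sites, butterfly_data["agg"], lf.ModelSpec("agriculture", "interaction")
    )
    extra = [c for c in inter.columns if c not in add.columns]
    assert extra == ["lf_total:arable", "lf_total:improved_grassland"]


def test_build_design_errors(small_sites, butterfly_data):
    bad = butterfly_data["agg"].copy()
    bad["count"] = bad["count"].astype(float)
    bad.loc[0, "count"] = 1.5
    with pytest.raises(ValueError, match="integer"):
        lf.build_design(small_sites, bad, lf.ModelSpec("year_only"))
    trimmed = small_sites.drop(columns=["arable"])
    with pytest.raises(ValueError, match="arable"):
        lf.build_design(trimmed, butterfly_data["agg"], lf.ModelSpec("agriculture"))


def test_model_spec_constraints():
    with pytest.raises(ValueError):
        lf.ModelSpec("linear_only", "interaction")
    with pytest.raises(ValueError):
        lf.ModelSpec("year_only", "additive")
    with pytest.raises(ValueError):
        lf.ModelSpec("full", "nope")


def test_bird_aggregation_max_count_and_tie_rule(bird_data):
    surveys, agg = bird_data["surveys"], bird_data["agg"]
    totals = surveys.assign(total=surveys.count_band1 + surveys.count_band2)
    for _, row in agg.head(20).iterrows():
        sub = totals[(totals.site_id == row.site_id) & (totals.year == row.year)]
        assert row["count"] == sub["total"].max()
        best = sub[sub["total"] == sub["total"].max()]["visit"].min()
        assert row["visit"] == best


# ---------------------------------------------------------------------------
# fit_poisson_glmm


def _zero_variance_dataset(seed=41, n_sites=150, n_years=2, alpha=3.0):
    cfg = lf.LandscapeConfig(n_sites=n_sites, n_regions=4, n_years=n_years, seed=seed)
    sites = lf.generate_sites(cfg)
    params = lf.TrueParameters(
        alpha=alpha,
        beta={"lf_total": (1.5, -1.0), "arable": (0.5, 0.0)},
        sigma_site=0.0,
        sigma_region=0.0,
        sigma_obs=0.0,
    )
    surveys, _ = lf.simulate_surveys(sites, params, n_years, seed + 1, group="butterfly")
    return sites, surveys.assign(p_detect=1.0)


def test_zero_variance_fit_matches_poisson_glm():
    """With no mixing, the Laplace GLMM collapses to the plain Poisson GLM.

    Needs counts large enough that the variance-component MLEs actually
    reach the boundary rather than absorbing sampling noise.
    """
    sites, agg = _zero_variance_dataset(seed=43, n_sites=300, n_years=2)
    d = lf.build_design(sites, agg, lf.ModelSpec("agriculture", "additive"))
    fit = lf.fit_model(d)
    glm = sm.GLM(d.y, d.X, family=sm.families.Poisson()).fit()
    assert np.max(np.abs(fit.fixed.to_numpy() - glm.params)) < 1e-4
    assert all(v < 1e-3 for v in fit.varcomp.values())
    assert fit.boundary


def _quadrature_loglik(y, X, beta, codes, sigma, offset=None):
    """Brute-force marginal likelihood: one adaptive integral per group."""
    eta0 = X @ beta + (0 if offset is None else offset)
    total = 0.0
    for g in np.unique(codes):
        idx = codes == g
        yg, eg = y[idx], eta0[idx]

        def integrand(u):
            lam = np.exp(eg + u)
            ll = np.sum(yg * (eg + u) - lam - [math.lgamma(v + 1) for v in yg])
            return math.exp(ll) * math.exp(-(u**2) / (2 * sigma**2)) / (
                sigma * math.sqrt(2 * math.pi)
            )

        val, _ = integrate.quad(integrand, -8 * sigma, 8 * sigma, limit=200)
        total += math.log(val)
    return total


def test_laplace_matches_quadrature_single_re():
    """Laplace marginal log-likelihood vs numeric quadrature, 3-level RE."""
    rng = np.random.default_rng(77)
    n = 30
    codes = np.repeat([0, 1, 2], 10)
    x = rng.uniform(0, 1, n)
    u_true = np.array([0.3, -0.4, 0.1])
    y = rng.poisson(np.exp(0.8 + 0.7 * x + u_true[codes])).astype(float)
    X = np.column_stack([np.ones(n), x])
    fit = fit_poisson_glmm(y, X, {"group": codes}, columns=["intercept", "x"])
    sigma = math.sqrt(fit.varcomp["group"])
    oracle = _quadrature_loglik(y, X, fit.fixed.to_numpy(), codes, sigma)
    assert fit.loglik == pytest.approx(oracle, abs=0.1)
    assert abs(fit.loglik - oracle) / abs(oracle) < 0.005


def test_loglik_invariant_to_row_permutation(small_sites, butterfly_data):
    """The fit depends on the data, not on row order.

    Run at tight optimizer tolerances so the comparison measures the
    estimator rather than the stopping rule.
    """
    d = lf.build_design(small_sites, butterfly_data["agg"], lf.ModelSpec("agriculture"))
    tight = {"ftol": 1e-13, "gtol": 1e-6}
    fit1 = lf.fit_model(d, **tight)
    rng = np.random.default_rng(5)
    perm = rng.permutation(d.n)
    fit2 = fit_poisson_glmm(
        d.y[perm],
        d.X[perm],
        {t: c[perm] for t, c in d.groups.items()},
        d.offset[perm],
        group_levels=d.group_levels,
        columns=d.columns,
        **tight,
    )
    assert abs(fit1.loglik - fit2.loglik) < 1e-8


def test_mode_stationarity(butterfly_fit):
    """At the Laplace mode, grouped residuals equal u / sigma^2."""
    fit, design = butterfly_fit
    eta = predict_eta(fit, design, include_random=True)
    resid = design.y - np.exp(eta)
    for term in ("site", "region"):
        codes = design.groups[term]
        modes = fit.re_modes[term].to_numpy()
        grouped = np.bincount(codes, weights=resid, minlength=len(modes))
        assert np.allclose(grouped, modes / fit.varcomp[term], atol=1e-5)


def test_predict_eta_consistency(butterfly_fit):
    fit, design = butterfly_fit
    eta_fix = predict_eta(fit, design, include_random=False)
    assert np.allclose(eta_fix, fit.eta_fixed, atol=1e-12)
    eta_re = predict_eta(fit, design, include_random=True)
    manual = fit.eta_fixed.copy()
    for term in design.groups:
        labels = design.group_levels[term][design.groups[term]]
        manual = manual + fit.re_modes[term].reindex(labels).to_numpy()
    assert np.allclose(eta_re, manual, atol=1e-12)


def test_predict_eta_unknown_groups_contribute_zero(small_sites, butterfly_data, butterfly_fit):
    fit, design = butterfly_fit
    renamed_sites = small_sites.copy()
    renamed_sites["site_id"] = "NEW_" + renamed_sites["site_id"]
    renamed_sites["region_id"] = "NEW_" + renamed_sites["region_id"]
    agg = butterfly_data["agg"].copy()
    agg["site_id"] = "NEW_" + agg["site_id"]
    d_new = lf.build_design(renamed_sites, agg, design.spec)
    with_re = predict_eta(fit, d_new, include_random=True)
    without = predict_eta(fit, d_new, include_random=False)
    assert np.allclose(with_re, without)


def test_aic_prefers_truly_predictive_covariates():
    """Adding the covariate that truly drives counts lowers the AIC."""
    cfg = lf.LandscapeConfig(n_sites=300, n_regions=5, n_years=2, seed=8)
    sites = lf.generate_sites(cfg)
    params = lf.TrueParameters(alpha=1.5, beta={"lf_total": (1.5, -1.0)})
    surveys, _ = lf.simulate_surveys(sites, params, 2, 23, group="butterfly")
    agg = surveys.assign(p_detect=1.0)
    fit_lf = lf.fit_model(lf.build_design(sites, agg, lf.ModelSpec("linear_only", "additive")))
    fit_null = lf.fit_model(lf.build_design(sites, agg, lf.ModelSpec("year_only")))
    assert fit_lf.aic < fit_null.aic


def test_kernel_paths_agree_to_machine_precision():
    """The nested closed-form, dense-Schur and generic dense evaluations
    of the Laplace objective and its gradient are the same function."""
    import lfabund.glmm as G
    from scipy.special import gammaln

    rng = np.random.default_rng(3)
    n = 90
    x = rng.uniform(0, 1, n)
    site = np.repeat(np.arange(30), 3)
    region = site // 8  # sites nested in regions
    y = rng.poisson(
        np.exp(0.8 + x + rng.normal(0, 0.4, 30)[site] + rng.normal(0, 0.3, n))
    ).astype(float)
    X = np.column_stack([np.ones(n), x])
    groups = {"obs": np.arange(n), "site": site, "region": region}
    levels = {"obs": np.arange(n), "site": np.arange(30), "region": np.arange(4)}

    nested = G._OlreKernel(y, X, np.zeros(n), list(groups), groups, levels, "obs", 80)
    assert nested.nest is not None
    dense_schur = G._OlreKernel(y, X, np.zeros(n), list(groups), groups, levels, "obs", 80)
    dense_schur.nest = None

    Z, slices, q = G._build_Z(groups, levels, n)
    q_sizes = np.array([n, 30, 4], dtype=float)

    def dinv_vec(ls):
        out = np.empty(q)
        for k, t in enumerate(groups):
            out[slices[t]] = math.exp(-2.0 * ls[k])
        return out

    generic = G._GenericKernel(
        y, X, np.zeros(n), Z, Z.T.tocsr(), list(groups), slices, q_sizes,
        dinv_vec, float(np.sum(gammaln(y + 1))), np.zeros(2), True, 80, 300, 2, q, n,
    )
    for pt in (
        np.array([0.7, 0.9, math.log(0.3), math.log(0.35), math.log(0.2)]),
        np.array([1.0, 0.5, math.log(0.1), math.log(0.5), math.log(0.05)]),
    ):
        vals, grads = zip(*(k.neg_full_with_grad(pt.copy()) for k in (nested, dense_schur, generic)))
        assert max(vals) - min(vals) < 1e-9
        for g in grads[1:]:
            assert np.max(np.abs(g - grads[0])) < 1e-9


def test_against_lme4_reference(tmp_path):
    """Cross-check fixed effects, variances and logLik against lme4 glmer.

    Fixed effects here are profiled at the joint penalised mode, whereas
    glmer optimises them through the full Laplace objective including the
    determinant term, so small systematic differences (of order a tenth
    of a standard error) are expected; variance components and the
    marginal log-likelihood agree much more closely.
    """
    rng = np.random.default_rng(14)
    n_sites, n_rep = 120, 3
    n = n_sites * n_rep
    x = rng.uniform(0, 1, n)
    codes = np.repeat(np.arange(n_sites), n_rep)
    site_re = rng.normal(0, 0.4, n_sites)
    obs_re = rng.normal(0, 0.3, n)
    y = rng.poisson(np.exp(1.0 + 1.2 * x + site_re[codes] + obs_re)).astype(float)
    X = np.column_stack([np.ones(n), x])
    fit = fit_poisson_glmm(
        y, X, {"obs": np.arange(n), "site": codes}, columns=["intercept", "x"]
    )

    df = pd.DataFrame({"y": y, "x": x, "site": codes, "obs": np.arange(n)})
    csv = tmp_path / "glmm.csv"
    df.to_csv(csv, index=False)
    rscript = textwrap.dedent(f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- glmer(y ~ x + (1|site) + (1|obs), data=d, family=poisson,
                   control=glmerControl(check.conv.singular="ignore"))
        cat(fixef(m), "\\n")
        cat(as.numeric(logLik(m)), "\\n")
        vc <- as.data.frame(VarCorr(m))
        cat(vc$vcov[vc$grp=="site"], vc$vcov[vc$grp=="obs"], "\\n")
    """)
    out = subprocess.run(
        ["Rscript", "-e", rscript], capture_output=True, text=True, timeout=300
    )
    assert out.returncode == 0, out.stderr
    lines = [l for l in out.stdout.strip().splitlines() if l.strip()]
    fixef = np.array([float(v) for v in lines[0].split()])
    loglik_r = float(lines[1])
    var_site_r, var_obs_r = (float(v) for v in lines[2].split())

    assert np.max(np.abs(fit.fixed.to_numpy() - fixef)) < 0.1
    assert fit.loglik == pytest.approx(loglik_r, abs=1.0)
    assert fit.varcomp["site"] == pytest.approx(var_site_r, abs=0.02)
    assert fit.varcomp["obs"] == pytest.approx(var_obs_r, abs=0.02)
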
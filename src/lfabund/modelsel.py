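"""Multimodel inference: AIC weights, confidence sets, selection
probabilities, Nakagawa-Schielzeth R2, and the woody-vs-total
linear-features comparison.

A fixed candidate set of eight models per species spans land-cover-only,
additive and interacting linear-feature terms, a linear-features-only
model and a year-only null.  Support for each model is its Akaike
weight w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2); the 95% confidence
set is the smallest weight-sorted prefix with cumulative weight >= 0.95,
and a variable's selection probability is the summed weight of the
models containing it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .glmm import DesignData, GLMMFit, ModelSpec, build_design, fit_model

__all__ = [
    "enumerate_model_set",
    "aic_weights",
    "confidence_set",
    "selection_probability",
    "lf_term_membership",
    "r2_nakagawa",
    "R2Pair",
    "ModelSetResult",
    "run_model_selection",
    "compare_woody_vs_total",
    "WoodyComparison",
]


def enumerate_model_set(species_group: str = "bird") -> list[ModelSpec]:
    """The eight candidate models fitted for every species.

    Full and agriculture land-cover sets each appear alone, with an
    additive linear-features term, and with linear-features x
    agricultural-cover interactions; plus a linear-features-only model
    and a year-only null.  All use total linear-feature length; the
    woody variant enters only through :func:`compare_woody_vs_total`.
    Birds carry the log-detectability offset.
    """
    offs = species_group == "bird"
    return [
        ModelSpec("full", "none", "total", offs),
        ModelSpec("full", "additive", "total", offs),
        ModelSpec("full", "interaction", "total", offs),
        ModelSpec("agriculture", "none", "total", offs),
        ModelSpec("agriculture", "additive", "total", offs),
        ModelSpec("agriculture", "interaction", "total", offs),
        ModelSpec("linear_only", "additive", "total", offs),
        ModelSpec("year_only", "none", "total", offs),
    ]


def aic_weights(aics: Sequence[float]) -> np.ndarray:
    """Akaike weights: exp(-Delta_i/2) normalised over the candidate set."""
    a = np.asarray(aics, dtype=float)
    if len(a) == 0 or np.isnan(a).any():
        raise ValueError("AIC values must be finite and non-empty")
    delta = a - np.min(a)
    w = np.exp(-0.5 * delta)
    return w / w.sum()


def confidence_set(weights: Sequence[float], level: float = 0.95) -> np.ndarray:
    """Boolean membership of the smallest cumulative-weight prefix >= level.

    Models are sorted by descending weight and included until the
    cumulative weight first reaches the level; models tied (to within
    1e-12) with the last included weight are also included.
    """
    w = np.asarray(weights, dtype=float)
    order = np.argsort(-w, kind="mergesort")
    cum = np.cumsum(w[order])
    n_keep = int(np.searchsorted(cum, level - 1e-12) + 1)
    n_keep = min(n_keep, len(w))
    threshold = w[order[n_keep - 1]]
    member = np.zeros(len(w), dtype=bool)
    member[order[:n_keep]] = True
    member |= np.abs(w - threshold) <= 1e-12  # boundary ties
    return member


def selection_probability(
    weights: Sequence[float], term_membership: Mapping[str, Sequence[bool]]
) -> dict[str, float]:
    """Summed Akaike weight of the models in which each term appears."""
    w = np.asarray(weights, dtype=float)
    out = {}
    for term, member in term_membership.items():
        m = np.asarray(member, dtype=bool)
        if len(m) != len(w):
            raise ValueError(f"membership for {term!r} has wrong length")
        out[term] = float(w[m].sum())
    return out


def lf_term_membership(specs: Sequence[ModelSpec]) -> dict[str, list[bool]]:
    """Membership vectors for the linear-features terms.

    Additive and interaction terms are reported separately: interaction
    terms appear in fewer models, so their selection probabilities are
    not comparable with main-effect ones within a model set.
    """
    return {
        "lf_any": [s.lf_term != "none" or s.covariate_set == "linear_only" for s in specs],
        "lf_additive": [s.lf_term == "additive" for s in specs],
        "lf_interaction": [s.lf_term == "interaction" for s in specs],
    }


@dataclass(frozen=True)
class R2Pair:
    """Marginal and conditional R2 for a Poisson GLMM.

    Variance partition on the latent (log) scale: marginal R2 credits the
    fixed effects, conditional R2 additionally credits the site and
    region random effects.  The observation-level random effect and the
    distribution-specific variance remain in the denominator only.
    """

    marginal: float
    conditional: float
    var_fixed: float
    var_site: float
    var_region: float
    var_obs: float
    var_dist: float


def r2_from_components(
    var_fixed: float,
    var_site: float,
    var_region: float,
    var_obs: float,
    var_dist: float,
) -> R2Pair:
    """Variance-partition R2 from latent-scale variance components."""
    total = var_fixed + var_site + var_region + var_obs + var_dist
    if total <= 0:
        raise ValueError("total latent variance is zero; R2 undefined")
    return R2Pair(
        marginal=var_fixed / total,
        conditional=(var_fixed + var_site + var_region) / total,
        var_fixed=var_fixed,
        var_site=var_site,
        var_region=var_region,
        var_obs=var_obs,
        var_dist=var_dist,
    )


def r2_nakagawa(fit: GLMMFit) -> R2Pair:
    """Latent-scale variance-partition R2 for the fitted Poisson GLMM.

    var_fixed is the variance of the fixed-effect linear predictor over
    the observations (offset excluded).  The distribution-specific
    variance uses the lognormal approximation ln(1 + 1/lambda) with
    lambda the expected count at the adjusted intercept (the mean fixed-
    effect linear predictor), which vanishes as counts grow and recovers
    the Gaussian partition in that limit.
    """
    eta_fix = fit.eta_fixed - fit.offset
    var_fixed = float(np.var(eta_fix))
    lam = math.exp(float(np.mean(eta_fix)))
    var_dist = math.log1p(1.0 / lam)
    return r2_from_components(
        var_fixed,
        fit.varcomp.get("site", 0.0),
        fit.varcomp.get("region", 0.0),
        fit.varcomp.get("obs", 0.0),
        var_dist,
    )


@dataclass
class ModelSetResult:
    """Fitted candidate set for one species, with support measures."""

    species_id: str
    table: pd.DataFrame            # model, aic, delta_aic, weight, in_95_set, r2...
    fits: dict[str, GLMMFit]
    selection_probabilities: dict[str, float]
    best_model: ModelSpec

    @property
    def best_fit(self) -> GLMMFit:
        return self.fits[self.best_model.label]

    def best_lf_spec(self) -> ModelSpec | None:
        """Lowest-AIC model that contains a linear-features term."""
        member = lf_term_membership([self.fits[m].spec for m in self.table["model"]])["lf_any"]
        sub = self.table[np.asarray(member)]
        if len(sub) == 0:
            return None
        return self.fits[sub.loc[sub["aic"].idxmin(), "model"]].spec


def run_model_selection(
    sites: pd.DataFrame,
    surveys: pd.DataFrame,
    species_group: str = "bird",
    species_id: str = "sp1",
    specs: Sequence[ModelSpec] | None = None,
) -> ModelSetResult:
    """Fit the candidate set and compute all support measures.

    ``surveys`` is the aggregated per-site-per-year frame (with
    ``count`` and ``p_detect``).
    """
    if specs is None:
        specs = enumerate_model_set(species_group)
    fits: dict[str, GLMMFit] = {}
    rows = []
    for spec in specs:
        design = build_design(sites, surveys, spec)
        fit = fit_model(design)
        fits[spec.label] = fit
        r2 = r2_nakagawa(fit)
        rows.append(
            {
                "model": spec.label,
                "aic": fit.aic,
                "loglik": fit.loglik,
                "n_fixed": len(fit.fixed),
                "marginal_r2": r2.marginal,
                "conditional_r2": r2.conditional,
            }
        )
    table = pd.DataFrame(rows)
    w = aic_weights(table["aic"])
    table["delta_aic"] = table["aic"] - table["aic"].min()
    table["weight"] = w
    table["in_95_set"] = confidence_set(w)
    sel = selection_probability(w, lf_term_membership(list(specs)))
    best = specs[int(np.argmin(table["aic"].to_numpy()))]
    return ModelSetResult(
        species_id=species_id,
        table=table,
        fits=fits,
        selection_probabilities=sel,
        best_model=best,
    )


@dataclass(frozen=True)
class WoodyComparison:
    """AIC comparison of woody vs total linear-feature length."""

    aic_total: float
    aic_woody: float
    delta_aic: float           # aic_total - aic_woody; > 0 favours woody
    category: str              # 'woody >=4', 'woody <4', 'total <4', 'total >=4'


def categorize_woody_delta(delta: float) -> str:
    """Four-way partition of the woody-vs-total AIC difference.

    Positive delta favours the woody variable; |delta| >= 4 counts as
    substantial support.  An exact tie is reported for the total-length
    model, the simpler pre-existing variable.
    """
    if delta >= 4.0:
        return "woody >=4"
    if delta > 0.0:
        return "woody <4"
    if delta > -4.0:
        return "total <4"
    return "total >=4"


def compare_woody_vs_total(
    best_lf_spec: ModelSpec,
    sites: pd.DataFrame,
    surveys: pd.DataFrame,
) -> WoodyComparison:
    """Refit a species' best linear-features model with woody length.

    The best-performing model containing a linear-features term is
    refitted with the woody linear-features variable substituted for the
    total-length variable, and the AIC difference reported.
    """
    if best_lf_spec.lf_term == "none" and best_lf_spec.covariate_set != "linear_only":
        raise ValueError("best_lf_spec must contain a linear-features term")
    fit_total = fit_model(build_design(sites, surveys, best_lf_spec.with_lf_variable("total")))
    fit_woody = fit_model(build_design(sites, surveys, best_lf_spec.with_lf_variable("woody")))
    delta = fit_total.aic - fit_woody.aic
    return WoodyComparison(
        aic_total=fit_total.aic,
        aic_woody=fit_woody.aic,
        delta_aic=delta,
        category=categorize_woody_delta(delta),
    )
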
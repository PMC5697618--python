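"""Cross-validation, significance classification, sign tests, pipeline.

Predictive value of the linear-features covariates is assessed by
repeated site-level 75/25 train/test splits: each candidate model is
refitted on the training sites and its root-mean-squared error computed
on the test sites on the scale of the linear predictor.  Differences in
prediction error between model sets are tested with one-way ANOVAs over
the cross-validation iterations, each species classified as a
significant/non-significant reduction/increase, and the proportion of
species improved by linear features tested against 0.5 with an exact
two-sided binomial test.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import synthdata
from .detection import fit_halfnormal_binned, detection_table
from .glmm import (
    DesignData,
    ModelSpec,
    aggregate_bird_surveys,
    build_design,
    fit_model,
    predict_eta,
)
from .modelsel import (
    ModelSetResult,
    compare_woody_vs_total,
    run_model_selection,
)
from .synthdata import LandscapeConfig, TrueParameters, generate_sites, simulate_surveys

logger = logging.getLogger("lfabund")

__all__ = [
    "split_sites",
    "cv_prediction_error",
    "compare_models_anova",
    "classify_cv_outcome",
    "binomial_sign_test",
    "run_pipeline",
    "PipelineResult",
]


def split_sites(
    site_ids: Sequence[str], fraction: float = 0.75, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Partition sites into training and testing sets.

    The split is at site level so that all years of a site fall on the
    same side — test sites are spatially distinct from training sites.
    """
    ids = np.asarray(site_ids)
    if len(ids) < 8:
        raise ValueError(f"need >= 8 sites to cross-validate, got {len(ids)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_train = int(round(fraction * len(ids)))
    perm = rng.permutation(len(ids))
    return np.sort(ids[perm[:n_train]]), np.sort(ids[perm[n_train:]])


def _rmse_linear_predictor(eta_hat: np.ndarray, y: np.ndarray, log_shift: float = 1.0) -> float:
    """RMSE on the linear-predictor scale: eta_hat vs log(y + shift)."""
    return float(np.sqrt(np.mean((eta_hat - np.log(y + log_shift)) ** 2)))


def _has_constant_column(X: np.ndarray) -> bool:
    # intercept is column 0; any other constant column breaks the fit
    return bool(np.any(np.ptp(X[:, 1:], axis=0) == 0)) if X.shape[1] > 1 else False


def cv_prediction_error(
    specs: Sequence[ModelSpec],
    sites: pd.DataFrame,
    surveys: pd.DataFrame,
    n_iter: int = 100,
    seed: int = 0,
    fraction: float = 0.75,
    log_shift: float = 1.0,
) -> pd.DataFrame:
    """Repeated train/test prediction error for each candidate model.

    Every iteration draws one site-level split shared by all models, so
    per-iteration errors are comparable across models.  Predictions for
    test sites use fixed effects and offset only: test sites are unseen
    groups, whose random effects have conditional mean zero.  Returns a
    tidy frame (iteration, model, rmse, n_test); failed fits appear as
    NaN and a model failing more than 20% of iterations is flagged.
    """
    designs = {s.label: build_design(sites, surveys, s) for s in specs}
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(3,)))
    site_ids = sites["site_id"].to_numpy()
    rows = []
    for it in range(1, n_iter + 1):
        train_ids, test_ids = split_sites(site_ids, fraction, rng)
        train_set = set(train_ids)
        for label, design in designs.items():
            mask = design.frame["site_id"].isin(train_set).to_numpy()
            d_train, d_test = design.subset(mask), design.subset(~mask)
            rmse = math.nan
            if not _has_constant_column(d_train.X):
                try:
                    fit = fit_model(d_train)
                    eta = predict_eta(fit, d_test, include_random=False)
                    rmse = _rmse_linear_predictor(eta, d_test.y, log_shift)
                except Exception as e:  # noqa: BLE001 - record and continue
                    logger.warning("CV iteration %d, model %s failed: %s", it, label, e)
            rows.append({"iteration": it, "model": label, "rmse": rmse, "n_test": int((~mask).sum())})
    out = pd.DataFrame(rows)
    fail = out.groupby("model")["rmse"].apply(lambda s: s.isna().mean())
    for label, frac_failed in fail.items():
        if frac_failed > 0.2:
            logger.warning("model %s failed %.0f%% of CV fits; flagged unusable", label, 100 * frac_failed)
    out.attrs["unusable"] = list(fail[fail > 0.2].index)
    return out


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    degenerate: bool = False


def compare_models_anova(rmse_a: Sequence[float], rmse_b: Sequence[float]) -> AnovaResult:
    """One-way ANOVA of CV prediction error on the model factor."""
    a = np.asarray(rmse_a, dtype=float)
    b = np.asarray(rmse_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 iterations per model")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return AnovaResult(0.0, 1.0, degenerate=False)
        return AnovaResult(math.inf, math.nan, degenerate=True)
    f, p = stats.f_oneway(a, b)
    return AnovaResult(float(f), float(p), degenerate=False)


def classify_cv_outcome(anova_p: float, mean_delta: float, alpha: float = 0.05) -> str:
    """Four-way outcome label for the change in prediction error.

    'Sig -' / 'NS -' for reduced error with/without ANOVA significance at
    alpha, symmetric for increases.  A delta of exactly zero counts as a
    non-significant reduction by convention.
    """
    sig = anova_p < alpha
    if mean_delta <= 0:
        return "Sig -" if sig else "NS -"
    return "Sig +" if sig else "NS +"


def binomial_sign_test(k_successes: int, n_trials: int) -> float:
    """Exact two-sided binomial test of proportion 0.5.

    Sums P(X = i) under Binomial(n, 0.5) over every outcome i whose
    probability does not exceed that of the observed k (the minimum-
    likelihood definition of two-sidedness), capped at 1.
    """
    if not 0 <= k_successes <= n_trials or n_trials < 1:
        raise ValueError("need 0 <= k <= n and n >= 1")
    i = np.arange(n_trials + 1)
    pmf = stats.binom.pmf(i, n_trials, 0.5)
    pk = pmf[k_successes]
    return float(min(1.0, pmf[pmf <= pk * (1.0 + 1e-9)].sum()))


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class SpeciesResult:
    species_id: str
    group: str
    selection: ModelSetResult
    woody: object | None
    cv: pd.DataFrame | None
    cv_outcomes: pd.DataFrame | None


@dataclass
class PipelineResult:
    sites: pd.DataFrame
    species: dict[str, SpeciesResult]
    out_dir: Path | None


def _parse_params(block: Mapping) -> TrueParameters:
    kwargs = dict(block)
    if "beta" in kwargs:
        kwargs["beta"] = {k: tuple(v) for k, v in kwargs["beta"].items()}
    return TrueParameters(**kwargs)


def _cv_outcomes_for_species(cv: pd.DataFrame) -> pd.DataFrame:
    """Fig.-2-style comparisons: each base model vs its +LF variant."""
    pairs = [
        ("full", "full+lf_additive", "full"),
        ("agriculture", "agriculture+lf_additive", "agriculture"),
    ]
    rows = []
    means = cv.groupby("model")["rmse"].mean()
    for base, with_lf, set_name in pairs:
        if base not in means.index or with_lf not in means.index:
            continue
        a = cv.loc[cv["model"] == base, "rmse"]
        b = cv.loc[cv["model"] == with_lf, "rmse"]
        anova = compare_models_anova(a, b)
        delta_pct = 100.0 * (means[with_lf] - means[base]) / means[base]
        rows.append(
            {
                "model_set": set_name,
                "mean_rmse_base": means[base],
                "mean_rmse_lf": means[with_lf],
                "delta_rmse_percent": delta_pct,
                "anova_f": anova.f_statistic,
                "anova_p": anova.p_value,
                "category": classify_cv_outcome(anova.p_value, delta_pct)
                if not anova.degenerate
                else "degenerate",
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: Mapping | str | Path, out_dir: str | Path | None = None) -> PipelineResult:
    """Run simulate -> detect -> fit -> select -> cross-validate -> report.

    ``config`` is a mapping (or path to a YAML file) with ``seed``,
    ``landscape`` (LandscapeConfig fields), ``cv`` (``n_iter``,
    ``train_fraction``) and a ``species`` list of ``{id, group, params}``
    blocks.  Writes model-selection, CV and woody-comparison CSV
    summaries plus a JSON run log when ``out_dir`` is given.
    """
    if isinstance(config, (str, Path)):
        import yaml

        config = yaml.safe_load(Path(config).read_text())
    seed = int(config.get("seed", 0))
    land = LandscapeConfig(**{**config.get("landscape", {}), "seed": seed})
    cv_cfg = config.get("cv", {})
    n_iter = int(cv_cfg.get("n_iter", 100))
    fraction = float(cv_cfg.get("train_fraction", 0.75))
    log_shift = float(cv_cfg.get("log_shift", 1.0))

    sites = generate_sites(land)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        sites.to_csv(out / "sites.csv", index=False)

    species_results: dict[str, SpeciesResult] = {}
    run_log: dict = {"seed": seed, "n_sites": land.n_sites, "n_iter": n_iter, "species": {}}
    for si, block in enumerate(config.get("species", [])):
        sp_id = str(block.get("id", f"sp{si + 1}"))
        group = str(block.get("group", "bird"))
        params = _parse_params(block.get("params", {}))
        sp_seed = seed * 1000 + si
        logger.info("simulating %s (%s)", sp_id, group)
        surveys, truth = simulate_surveys(
            sites, params, land.n_years, sp_seed, group=group, species_id=sp_id
        )

        if group == "bird":
            det = fit_halfnormal_binned(surveys[surveys[["count_band1", "count_band2"]].sum(axis=1) > 0])
            agg = aggregate_bird_surveys(surveys, det)
            if out is not None:
                detection_table(det).to_csv(out / f"{sp_id}_detection.csv", index=False)
        else:
            agg = surveys.copy()
            agg["p_detect"] = 1.0

        selection = run_model_selection(sites, agg, group, sp_id)
        best_lf = selection.best_lf_spec()
        woody = compare_woody_vs_total(best_lf, sites, agg) if best_lf is not None else None

        cv = cv_prediction_error(
            selection.table["model"].map(lambda m: selection.fits[m].spec).tolist(),
            sites,
            agg,
            n_iter=n_iter,
            seed=sp_seed,
            fraction=fraction,
            log_shift=log_shift,
        )
        outcomes = _cv_outcomes_for_species(cv)

        species_results[sp_id] = SpeciesResult(sp_id, group, selection, woody, cv, outcomes)
        run_log["species"][sp_id] = {
            "group": group,
            "best_model": selection.best_model.label,
            "woody_category": None if woody is None else woody.category,
        }

        if out is not None:
            selection.table.to_csv(out / f"{sp_id}_model_selection.csv", index=False)
            cv.to_csv(out / f"{sp_id}_cv.csv", index=False)
            outcomes.to_csv(out / f"{sp_id}_cv_outcomes.csv", index=False)

    if out is not None:
        _write_summaries(species_results, out)
        (out / "run_log.json").write_text(json.dumps(run_log, indent=2))
    return PipelineResult(sites=sites, species=species_results, out_dir=out)


def _write_summaries(species: Mapping[str, SpeciesResult], out: Path) -> None:
    """Cross-species summary tables in the shape of the headline tables."""
    sel_rows, woody_rows, cv_rows = [], [], []
    for sp in species.values():
        for _, r in sp.selection.table.iterrows():
            sel_rows.append({"species_id": sp.species_id, "group": sp.group, **r.to_dict()})
        if sp.woody is not None:
            woody_rows.append(
                {
                    "species_id": sp.species_id,
                    "group": sp.group,
                    "aic_total": sp.woody.aic_total,
                    "aic_woody": sp.woody.aic_woody,
                    "delta_aic": sp.woody.delta_aic,
                    "category": sp.woody.category,
                }
            )
        if sp.cv_outcomes is not None:
            for _, r in sp.cv_outcomes.iterrows():
                cv_rows.append({"species_id": sp.species_id, "group": sp.group, **r.to_dict()})
    pd.DataFrame(sel_rows).to_csv(out / "summary_model_selection.csv", index=False)
    pd.DataFrame(woody_rows).to_csv(out / "summary_woody_comparison.csv", index=False)
    cv_df = pd.DataFrame(cv_rows)
    cv_df.to_csv(out / "summary_cv.csv", index=False)
    if len(cv_df):
        k = int((cv_df["delta_rmse_percent"] < 0).sum())
        n = int(len(cv_df))
        pd.DataFrame(
            [{"n_comparisons": n, "n_improved": k, "binomial_p": binomial_sign_test(k, n)}]
        ).to_csv(out / "summary_sign_test.csv", index=False)
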
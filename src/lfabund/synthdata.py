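"""Synthetic landscapes, linear-feature segments and survey counts.

The generator produces data with the statistical structure the abundance
model assumes, with every ground-truth quantity recorded, so that the
whole pipeline (detection fitting, GLMM estimation, model selection,
cross-validation) can be exercised against known truth.

Structure emulated per site (a 1-km buffer around a monitoring transect):

* a land-cover composition over the standard buffer classes, drawn from a
  Dirichlet (an extra ``other`` class, never used as a covariate, keeps
  the modelled proportions summing to < 1);
* altitude, scaled to [0, 1] by the 450-m study ceiling;
* total and woody linear-feature lengths whose scaled values have a
  target Pearson correlation (0.46 by default), achieved with a Gaussian
  copula linking log total length to the woody fraction;
* a categorical habitat label (dominant collapsed land cover) used by the
  detection model.

Counts follow a Poisson log-linear model: for site i, year t,

    log N_it = alpha + sum_c (b1_c x_ci + b2_c x_ci^2) + year_t
               + interactions + Site_i + Region_j + Observation_it,

with independent normal random effects on the log scale.  For birds the
latent N_it is thinned through a covariate-dependent half-normal
detection process into counts per distance band (0-25, 25-100 m) on each
of two visits; butterflies are recorded as a single total per year.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .detection import BAND_EDGES, _band_mean_probability_vec
from .features import LENGTH_SCALE_M, UPLAND_ALTITUDE_M, SegmentCanopy, classify_woody

__all__ = [
    "LAND_COVER_CLASSES",
    "AGRICULTURE_CLASSES",
    "LandscapeConfig",
    "TrueParameters",
    "generate_sites",
    "generate_segments",
    "simulate_surveys",
    "write_dataset",
]

#: Buffer land-cover classes used as model covariates ("full" set together
#: with altitude).  ``other`` absorbs the remaining buffer area and is
#: never a covariate.
LAND_COVER_CLASSES = [
    "arable",
    "improved_grassland",
    "rough_grassland",
    "calcareous_grassland",
    "seminatural_grassland",
    "broadleaf_woodland",
    "coniferous_woodland",
    "fen_marsh_swamp",
    "heath_bog",
    "urban_suburban",
    "freshwater",
]

#: The agricultural subset (plus altitude) forming the "agriculture" set.
AGRICULTURE_CLASSES = ["arable", "improved_grassland", "rough_grassland"]

_DEFAULT_CONCENTRATION = {
    "arable": 3.0,
    "improved_grassland": 2.5,
    "rough_grassland": 0.8,
    "calcareous_grassland": 0.2,
    "seminatural_grassland": 0.5,
    "broadleaf_woodland": 0.8,
    "coniferous_woodland": 0.4,
    "fen_marsh_swamp": 0.1,
    "heath_bog": 0.5,
    "urban_suburban": 0.4,
    "freshwater": 0.1,
    "other": 0.4,
}


class ConfigurationError(ValueError):
    """Raised for invalid generator configuration."""


class SimulationError(RuntimeError):
    """Raised when the forward model produces unusable values."""


@dataclass
class LandscapeConfig:
    """Configuration of the synthetic landscape.

    ``lf_length_distribution`` gives (location, scale) of log total
    linear-feature length in metres; the default median of 20 km per
    1-km-radius buffer is typical of enclosed farmland.  The woody
    fraction of that length follows a Beta distribution.
    """

    n_sites: int = 200
    n_regions: int = 5
    n_years: int = 3
    landcover_concentration: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CONCENTRATION)
    )
    lf_length_distribution: tuple[float, float] = (math.log(20_000.0), 0.5)
    woody_fraction_distribution: tuple[float, float] = (2.0, 2.0)
    target_lf_correlation: float = 0.46
    altitude_beta: tuple[float, float] = (1.2, 4.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_sites < 1:
            raise ConfigurationError("n_sites must be >= 1")
        if self.n_regions < 1 or self.n_regions > self.n_sites:
            raise ConfigurationError("need 1 <= n_regions <= n_sites")
        if self.n_years < 1:
            raise ConfigurationError("n_years must be >= 1")
        if any(a <= 0 for a in self.landcover_concentration.values()):
            raise ConfigurationError("Dirichlet concentrations must be > 0")
        if not -1.0 < self.target_lf_correlation < 1.0:
            raise ConfigurationError("target_lf_correlation must lie in (-1, 1)")
        a, b = self.woody_fraction_distribution
        if a <= 0 or b <= 0:
            raise ConfigurationError("woody_fraction_distribution parameters must be > 0")


@dataclass
class TrueParameters:
    """Ground-truth parameters of the Poisson log-linear forward model.

    ``beta`` maps a covariate name (a land-cover class, ``altitude``,
    ``lf_total`` or ``lf_woody``) to its (linear, quadratic) coefficients
    on the [0, 1]-scaled covariate.  ``gamma_interaction`` holds
    coefficients of lf_total x arable and lf_total x improved_grassland.
    Random-effect standard deviations act on the log scale.
    ``detect_gamma`` parameterises log sigma of the half-normal detection
    process (birds only).
    """

    alpha: float = 1.0
    beta: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"lf_total": (1.5, -1.0)}
    )
    beta_year: Sequence[float] | None = None
    gamma_interaction: Mapping[str, float] = field(default_factory=dict)
    sigma_site: float = 0.4
    sigma_region: float = 0.2
    sigma_obs: float = 0.3
    detect_gamma: Mapping[str, float] = field(
        default_factory=lambda: {
            "intercept": math.log(35.0),
            "visit_late": 0.2,
            "habitat_grassland": 0.1,
            "habitat_other": 0.0,
        }
    )

    def validate(self, covariate_names: Sequence[str]) -> None:
        for s in (self.sigma_site, self.sigma_region, self.sigma_obs):
            if s < 0:
                raise ConfigurationError("random-effect standard deviations must be >= 0")
        unknown = set(self.beta) - set(covariate_names)
        if unknown:
            raise ConfigurationError(f"beta refers to unknown covariates: {sorted(unknown)}")

    def year_effects(self, n_years: int) -> np.ndarray:
        if self.beta_year is None:
            return np.zeros(n_years)
        eff = np.asarray(self.beta_year, dtype=float)
        if len(eff) != n_years:
            raise ConfigurationError(f"beta_year has length {len(eff)}, expected {n_years}")
        return eff


# ---------------------------------------------------------------------------
# Sites


def _calibrate_copula_rho(config: LandscapeConfig) -> float:
    """Find the Gaussian-copula correlation between log total length and
    the woody-fraction latent that yields the target Pearson correlation
    of the two scaled lengths.

    The empirical map rho -> corr(total, woody) is monotone increasing, so
    a bracketing root-find on a fixed large Monte Carlo sample suffices.
    The calibration sample uses its own fixed stream, so the result
    depends only on the configuration.
    """
    mu, sd = config.lf_length_distribution
    a, b = config.woody_fraction_distribution
    rng = np.random.default_rng(987654321)
    n = 20_000
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)

    def corr_at(rho: float) -> float:
        zz = rho * z1 + math.sqrt(1.0 - rho * rho) * z2
        total = np.minimum(np.exp(mu + sd * z1), LENGTH_SCALE_M)
        frac = stats.beta.ppf(stats.norm.cdf(zz), a, b)
        woody = frac * total
        return float(np.corrcoef(total, woody)[0, 1])

    target = config.target_lf_correlation
    lo, hi = -0.999, 0.999
    c_lo, c_hi = corr_at(lo), corr_at(hi)
    if not c_lo < target < c_hi:
        raise ConfigurationError(
            f"target_lf_correlation={target} unattainable: reachable range "
            f"[{c_lo:.3f}, {c_hi:.3f}] under the configured length/fraction distributions"
        )
    return float(optimize.brentq(lambda r: corr_at(r) - target, lo, hi, xtol=1e-4))


def _habitat_label(row: pd.Series) -> str:
    """Collapse the buffer composition to the dominant coarse habitat."""
    grass = sum(
        row.get(c, 0.0)
        for c in (
            "improved_grassland",
            "rough_grassland",
            "calcareous_grassland",
            "seminatural_grassland",
        )
    )
    arable = row.get("arable", 0.0)
    other = 1.0 - arable - grass
    best = max((arable, "arable"), (grass, "grassland"), (other, "other"))
    return best[1]


def generate_sites(config: LandscapeConfig) -> pd.DataFrame:
    """Draw per-site covariates for a synthetic landscape.

    Returns one row per site with land-cover proportions, altitude (raw
    and scaled), linear-feature lengths (raw and scaled), a region label
    assigned in contiguous blocks, and the collapsed habitat category.
    Deterministic given ``config`` (including its seed).
    """
    config.validate()
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(1,))
    rng = np.random.default_rng(ss)
    n = config.n_sites

    classes = list(config.landcover_concentration)
    conc = np.array([config.landcover_concentration[c] for c in classes])
    props = rng.dirichlet(conc, size=n)

    alt_a, alt_b = config.altitude_beta
    altitude_scaled = rng.beta(alt_a, alt_b, size=n)
    altitude_m = altitude_scaled * UPLAND_ALTITUDE_M

    rho = _calibrate_copula_rho(config)
    mu, sd = config.lf_length_distribution
    a, b = config.woody_fraction_distribution
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    zz = rho * z1 + math.sqrt(1.0 - rho * rho) * z2
    lf_total_m = np.minimum(np.exp(mu + sd * z1), LENGTH_SCALE_M)
    woody_fraction = stats.beta.ppf(stats.norm.cdf(zz), a, b)
    lf_woody_m = woody_fraction * lf_total_m

    region_size = int(math.ceil(n / config.n_regions))
    region_idx = np.arange(n) // region_size

    df = pd.DataFrame(props, columns=classes)
    df.insert(0, "site_id", [f"S{i:05d}" for i in range(n)])
    df.insert(1, "region_id", [f"R{j:03d}" for j in region_idx])
    df["altitude_m"] = altitude_m
    df["altitude"] = altitude_scaled
    df["lf_total_m"] = lf_total_m
    df["lf_woody_m"] = lf_woody_m
    df["lf_total"] = lf_total_m / LENGTH_SCALE_M
    df["lf_woody"] = lf_woody_m / LENGTH_SCALE_M
    df["habitat"] = df.apply(_habitat_label, axis=1)
    return df


# ---------------------------------------------------------------------------
# Segments


def generate_segments(
    site: Mapping[str, float],
    seed: int,
    *,
    mean_segment_m: float = 100.0,
    woody_fraction: float | None = None,
) -> list[SegmentCanopy]:
    """Generate linear-feature segments whose lengths sum to the site total.

    Each segment is independently labelled woody with probability
    ``woody_fraction`` (default: the site's woody/total length ratio) and
    given canopy statistics constructed to satisfy the woody thresholds
    when labelled woody and to violate them (low mean canopy) otherwise.
    """
    total = float(site["lf_total_m"])
    if total <= 0:
        return []
    if woody_fraction is None:
        woody_fraction = float(site["lf_woody_m"]) / total
    rng = np.random.default_rng(seed)
    n_seg = max(1, int(round(total / mean_segment_m)))
    lengths = rng.dirichlet(np.full(n_seg, 5.0)) * total

    woody = rng.random(n_seg) < woody_fraction
    segments: list[SegmentCanopy] = []
    for L, w in zip(lengths, woody):
        if w:
            mean = rng.uniform(1.0, 8.0)
            cmin = rng.uniform(0.0, mean)
            cmax = rng.uniform(mean, min(mean + 10.0, 58.0))
        else:
            mean = rng.uniform(0.0, 0.5)
            cmin = rng.uniform(-0.4, mean)
            cmax = rng.uniform(mean, 2.0)
        segments.append(
            SegmentCanopy(length_m=float(L), canopy_mean=mean, canopy_min=cmin, canopy_max=cmax)
        )
    assert all(classify_woody(s) == w for s, w in zip(segments, woody))
    return segments


# ---------------------------------------------------------------------------
# Surveys

_ETA_MAX = 20.0  # exp(20) ~ 5e8 individuals: past any plausible count


def _linear_predictor(
    sites: pd.DataFrame, params: TrueParameters, year_effects: np.ndarray
) -> np.ndarray:
    """Fixed-effect log-mean per site (before year/random effects)."""
    eta = np.full(len(sites), params.alpha)
    for name, (b1, b2) in params.beta.items():
        x = sites[name].to_numpy(dtype=float)
        eta += b1 * x + b2 * x * x
    lf = sites["lf_total"].to_numpy(dtype=float)
    for name, g in params.gamma_interaction.items():
        eta += g * lf * sites[name].to_numpy(dtype=float)
    return eta


def _detect_sigma(params: TrueParameters, habitat: np.ndarray, visit: int) -> np.ndarray:
    g = params.detect_gamma
    log_sigma = np.full(len(habitat), g.get("intercept", math.log(35.0)))
    if visit == 2:
        log_sigma += g.get("visit_late", 0.0)
    for lev in ("grassland", "other"):
        log_sigma += np.where(habitat == lev, g.get(f"habitat_{lev}", 0.0), 0.0)
    return np.exp(log_sigma)


def simulate_surveys(
    sites: pd.DataFrame,
    params: TrueParameters,
    n_years: int,
    seed: int,
    *,
    group: str = "bird",
    species_id: str = "sp1",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate multi-year survey counts under the Poisson mixed model.

    Returns ``(surveys, truth)``.  For ``group='bird'`` the surveys frame
    has one row per site x year x visit with counts in the two bounded
    distance bands; individuals within the 0-100 m strip fall in a band
    with probability proportional to band width and are detected with the
    band-mean half-normal probability for that visit's covariates.  For
    ``group='butterfly'`` there is one exhaustive count per site x year.
    The truth frame records latent random effects, log-means and true
    abundances for every site x year.
    """
    if group not in ("bird", "butterfly"):
        raise ConfigurationError(f"unknown survey group {group!r}")
    params.validate(list(sites.columns))
    n = len(sites)
    year_eff = params.year_effects(n_years)
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(2,))
    rng = np.random.default_rng(ss)

    site_re = rng.normal(0.0, params.sigma_site, size=n)
    regions = sites["region_id"].to_numpy()
    region_levels = list(pd.unique(regions))
    region_re_by_level = rng.normal(0.0, params.sigma_region, size=len(region_levels))
    region_re = region_re_by_level[[region_levels.index(r) for r in regions]]

    eta_fixed_site = _linear_predictor(sites, params, year_eff)
    habitat = sites["habitat"].to_numpy()

    survey_rows = []
    truth_rows = []
    for t in range(n_years):
        obs_re = rng.normal(0.0, params.sigma_obs, size=n)
        eta = eta_fixed_site + year_eff[t] + site_re + region_re + obs_re
        if np.any(eta > _ETA_MAX):
            bad = sites["site_id"].to_numpy()[np.argmax(eta)]
            raise SimulationError(
                f"log-mean exceeds {_ETA_MAX} at site {bad}: check coefficients"
            )
        n_true = rng.poisson(np.exp(eta))
        year = 2005 + t

        if group == "bird":
            a0, a1, a2 = BAND_EDGES
            w1 = (a1 - a0) / (a2 - a0)
            in_band1 = rng.binomial(n_true, w1)
            in_band2 = n_true - in_band1
            for visit in (1, 2):
                sigma = _detect_sigma(params, habitat, visit)
                p1 = _band_mean_probability_vec(sigma, a0, a1)
                p2 = _band_mean_probability_vec(sigma, a1, a2)
                det1 = rng.binomial(in_band1, p1)
                det2 = rng.binomial(in_band2, p2)
                for i in range(n):
                    survey_rows.append(
                        (
                            species_id,
                            sites["site_id"].iat[i],
                            year,
                            visit,
                            habitat[i],
                            int(det1[i]),
                            int(det2[i]),
                        )
                    )
        else:
            for i in range(n):
                survey_rows.append(
                    (species_id, sites["site_id"].iat[i], year, 1, habitat[i], int(n_true[i]), 0)
                )

        for i in range(n):
            truth_rows.append(
                (
                    species_id,
                    sites["site_id"].iat[i],
                    year,
                    float(eta[i]),
                    int(n_true[i]),
                    float(site_re[i]),
                    float(region_re[i]),
                    float(obs_re[i]),
                )
            )

    surveys = pd.DataFrame(
        survey_rows,
        columns=["species_id", "site_id", "year", "visit", "habitat", "count_band1", "count_band2"],
    )
    if group == "butterfly":
        surveys = surveys.drop(columns=["count_band2"]).rename(columns={"count_band1": "count"})
        surveys = surveys.drop(columns=["visit"])
    truth = pd.DataFrame(
        truth_rows,
        columns=["species_id", "site_id", "year", "eta_true", "n_true", "site_re", "region_re", "obs_re"],
    )
    return surveys, truth


# ---------------------------------------------------------------------------
# IO


def write_dataset(
    out_dir: str | Path,
    sites: pd.DataFrame,
    surveys: pd.DataFrame,
    truth: pd.DataFrame,
    params: TrueParameters,
    config: LandscapeConfig,
) -> None:
    """Write sites/surveys/truth CSVs plus a JSON sidecar of ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sites.to_csv(out / "sites.csv", index=False)
    surveys.to_csv(out / "surveys.csv", index=False)
    truth.to_csv(out / "truth.csv", index=False)
    sidecar = {
        "true_parameters": {
            "alpha": params.alpha,
            "beta": {k: list(v) for k, v in params.beta.items()},
            "beta_year": list(params.year_effects(config.n_years)),
            "gamma_interaction": dict(params.gamma_interaction),
            "sigma_site": params.sigma_site,
            "sigma_region": params.sigma_region,
            "sigma_obs": params.sigma_obs,
            "detect_gamma": dict(params.detect_gamma),
        },
        "config": {
            "n_sites": config.n_sites,
            "n_regions": config.n_regions,
            "n_years": config.n_years,
            "target_lf_correlation": config.target_lf_correlation,
            "seed": config.seed,
        },
    }
    (out / "ground_truth.json").write_text(json.dumps(sidecar, indent=2))
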
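"""Ground-truth structure of the synthetic landscape and survey generator."""

import math

import numpy as np
import pytest
from scipy import stats

import lfabund as lf
from lfabund.features import classify_woody
from lfabund.synthdata import ConfigurationError, SimulationError


def test_degenerate_single_class_composition():
    cfg = lf.LandscapeConfig(
        n_sites=10, n_regions=2, landcover_concentration={"arable": 5.0}, seed=1
    )
    sites = lf.generate_sites(cfg)
    assert np.allclose(sites["arable"], 1.0)


def test_lf_correlation_near_target():
    cfg = lf.LandscapeConfig(n_sites=1000, n_regions=10, target_lf_correlation=0.46, seed=3)
    sites = lf.generate_sites(cfg)
    r = np.corrcoef(sites["lf_total"], sites["lf_woody"])[0, 1]
    assert 0.36 <= r <= 0.56
    assert (sites["lf_woody"] <= sites["lf_total"] + 1e-12).all()


def test_generate_sites_deterministic():
    cfg = lf.LandscapeConfig(n_sites=50, n_regions=5, seed=9)
    a = lf.generate_sites(cfg).to_csv(index=False)
    b = lf.generate_sites(cfg).to_csv(index=False)
    assert a == b


def test_site_invariants(small_sites):
    lc = lf.synthdata.LAND_COVER_CLASSES
    sums = small_sites[lc].sum(axis=1)
    assert (sums <= 1.0 + 1e-12).all()
    for col in lc + ["altitude", "lf_total", "lf_woody"]:
        assert small_sites[col].between(0, 1).all()
    # regions are contiguous blocks
    codes = small_sites["region_id"].to_numpy()
    changes = (codes[1:] != codes[:-1]).sum()
    assert changes == small_sites["region_id"].nunique() - 1


def test_invalid_configs_rejected():
    with pytest.raises(ConfigurationError):
        lf.generate_sites(lf.LandscapeConfig(n_sites=0))
    with pytest.raises(ConfigurationError):
        lf.generate_sites(lf.LandscapeConfig(target_lf_correlation=1.5))
    with pytest.raises(ConfigurationError):
        lf.generate_sites(
            lf.LandscapeConfig(landcover_concentration={"arable": -1.0})
        )


def test_segments_empty_for_zero_length():
    assert lf.generate_segments({"lf_total_m": 0.0, "lf_woody_m": 0.0}, seed=1) == []


def test_segments_sum_to_total_and_obey_labels():
    site = {"lf_total_m": 25_000.0, "lf_woody_m": 25_000.0}
    segs = lf.generate_segments(site, seed=4, woody_fraction=1.0)
    assert sum(s.length_m for s in segs) == pytest.approx(25_000.0)
    assert all(classify_woody(s) for s in segs)


def test_segment_classifier_recovers_woody_fraction():
    site = {"lf_total_m": 1_000_000.0, "lf_woody_m": 500_000.0}
    segs = lf.generate_segments(site, seed=5, mean_segment_m=100.0, woody_fraction=0.5)
    assert len(segs) == 10_000
    frac = np.mean([classify_woody(s) for s in segs])
    assert abs(frac - 0.5) <= 0.02


def _null_params(alpha):
    return lf.TrueParameters(
        alpha=alpha, beta={}, sigma_site=0.0, sigma_region=0.0, sigma_obs=0.0
    )


def test_null_model_counts_are_poisson():
    cfg = lf.LandscapeConfig(n_sites=3400, n_regions=10, n_years=3, seed=12)
    sites = lf.generate_sites(cfg)
    surveys, _ = lf.simulate_surveys(sites, _null_params(math.log(2.0)), 3, 13, group="butterfly")
    counts = surveys["count"].to_numpy()
    assert len(counts) >= 10_000
    assert 1.92 <= counts.mean() <= 2.08


def test_null_model_passes_chisquare_gof_mostly():
    """With all variances and slopes zero, counts fit Poisson(exp(alpha))."""
    cfg = lf.LandscapeConfig(n_sites=150, n_regions=3, n_years=2, seed=2)
    sites = lf.generate_sites(cfg)
    lam = 2.0
    passed = 0
    for rep in range(100):
        surveys, _ = lf.simulate_surveys(
            sites, _null_params(math.log(lam)), 2, 10_000 + rep, group="butterfly"
        )
        counts = surveys["count"].to_numpy()
        kmax = 7  # pool the tail so expected cells stay >= 5
        observed = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        expected = stats.poisson.pmf(np.arange(kmax), lam) * len(counts)
        expected = np.append(expected, len(counts) - expected.sum())
        p = stats.chisquare(observed, expected).pvalue
        passed += p > 0.01
    assert passed >= 95


def test_overdispersion_from_observation_effect():
    """Lognormal-Poisson mixing inflates the variance/mean ratio."""
    sigma = 0.5
    cfg = lf.LandscapeConfig(n_sites=4000, n_regions=10, n_years=1, seed=6)
    sites = lf.generate_sites(cfg)
    params = lf.TrueParameters(
        alpha=math.log(2.0), beta={}, sigma_site=0.0, sigma_region=0.0, sigma_obs=sigma
    )
    surveys, _ = lf.simulate_surveys(sites, params, 1, 17, group="butterfly")
    counts = surveys["count"].to_numpy()
    m = math.exp(math.log(2.0) + sigma**2 / 2)
    vmr_expected = 1 + m * (math.exp(sigma**2) - 1)  # moment formula
    vmr = counts.var() / counts.mean()
    assert vmr > 1.0
    assert abs(vmr - vmr_expected) / vmr_expected < 0.25


def test_perfect_detection_limit(small_sites):
    """With a huge half-normal scale every individual within 100 m is seen."""
    params = lf.TrueParameters(detect_gamma={"intercept": math.log(1e6)})
    surveys, truth = lf.simulate_surveys(small_sites, params, 2, 19, group="bird")
    merged = surveys.merge(truth, on=["species_id", "site_id", "year"])
    total = merged["count_band1"] + merged["count_band2"]
    assert (total == merged["n_true"]).all()


def test_true_abundance_bounds_detected_counts(bird_data):
    merged = bird_data["surveys"].merge(
        bird_data["truth"], on=["species_id", "site_id", "year"]
    )
    assert (merged["count_band1"] + merged["count_band2"] <= merged["n_true"]).all()


def test_simulate_surveys_deterministic(small_sites):
    params = lf.TrueParameters()
    a, ta = lf.simulate_surveys(small_sites, params, 2, 33, group="bird")
    b, tb = lf.simulate_surveys(small_sites, params, 2, 33, group="bird")
    assert a.equals(b) and ta.equals(tb)


def test_overflow_guard_names_site(small_sites):
    with pytest.raises(SimulationError, match="site"):
        lf.simulate_surveys(small_sites, lf.TrueParameters(alpha=50.0), 1, 1, group="butterfly")
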
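"""Half-normal band probabilities and the binned detection MLE."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, optimize

import lfabund as lf
from lfabund.detection import (
    SIGMA_BOUNDS,
    _conditional_shares,
    detection_probability,
    detection_table,
)


def quad_band_mean(sigma, a, b):
    val, _ = integrate.quad(lambda x: math.exp(-(x**2) / (2 * sigma**2)), a, b, epsabs=1e-12)
    return val / (b - a)


@pytest.mark.parametrize(
    "sigma,a,b,expected",
    [
        (1e6, 0.0, 25.0, 1.0),
        (40.0, 0.0, 25.0, 0.9385396632949472),   # numeric integration oracle
        (40.0, 25.0, 100.0, 0.34728614670643826),
        (40.0, 0.0, 100.0, 0.49509952585356554),
    ],
)
def test_band_mean_probability_values(sigma, a, b, expected):
    assert lf.band_mean_probability(sigma, a, b) == pytest.approx(expected, abs=1e-6)


def test_band_mean_probability_matches_quadrature():
    for sigma in np.geomspace(1.0, 1e4, 25):
        for a, b in [(0.0, 25.0), (25.0, 100.0), (0.0, 100.0)]:
            assert lf.band_mean_probability(sigma, a, b) == pytest.approx(
                quad_band_mean(sigma, a, b), abs=1e-8
            )


def test_band_mean_probability_monotonicity():
    sigmas = np.geomspace(1, 1000, 30)
    near = np.array([lf.band_mean_probability(s, 0, 25) for s in sigmas])
    far = np.array([lf.band_mean_probability(s, 25, 100) for s in sigmas])
    # non-decreasing in sigma (saturates at 1 in float precision), strictly
    # larger in the nearer band
    assert np.all(np.diff(near) >= 0) and np.all(np.diff(far) >= 0)
    assert near[0] < near[-1] and far[0] < far[-1]
    assert np.all(near > far)


def test_band_mean_probability_domain_errors():
    with pytest.raises(ValueError):
        lf.band_mean_probability(0.0, 0, 25)
    with pytest.raises(ValueError):
        lf.band_mean_probability(40.0, 25, 25)


def _frame(c1, c2, **kw):
    base = {"count_band1": [c1], "count_band2": [c2]}
    base.update({k: [v] for k, v in kw.items()})
    return pd.DataFrame(base)


def grid_mle_sigma(c1, c2):
    """Independent 1-d oracle: maximise the conditional band-share likelihood."""

    def nll(log_s):
        shares = _conditional_shares(np.array([math.exp(log_s)]))[0]
        return -(c1 * math.log(shares[0]) + c2 * math.log(shares[1]))

    res = optimize.minimize_scalar(nll, bounds=(0.0, 9.0), method="bounded",
                                   options={"xatol": 1e-10})
    return math.exp(res.x)


def test_fit_recovers_sigma_from_band_counts():
    """Counts (474, 526) put the conditional band-1 share at its sigma=40 value."""
    model = lf.fit_halfnormal_binned(_frame(474, 526), use_visit=False, use_habitat=False)
    sigma_hat = float(model.sigma(1, "all")[0])
    oracle = grid_mle_sigma(474, 526)
    assert sigma_hat == pytest.approx(oracle, rel=1e-4)
    assert sigma_hat == pytest.approx(40.0, abs=0.5)


def test_fit_uniform_counts_hits_upper_cap():
    """Counts proportional to band widths imply flat detection: sigma at the cap."""
    model = lf.fit_halfnormal_binned(_frame(250, 750), use_visit=False, use_habitat=False)
    assert model.boundary
    assert float(model.sigma(1, "all")[0]) == pytest.approx(SIGMA_BOUNDS[1], rel=1e-3)


def test_fit_invariant_to_count_scaling():
    m1 = lf.fit_halfnormal_binned(_frame(474, 526), use_visit=False, use_habitat=False)
    m3 = lf.fit_halfnormal_binned(_frame(3 * 474, 3 * 526), use_visit=False, use_habitat=False)
    assert m1.gamma == pytest.approx(m3.gamma, abs=1e-5)


def _simulate_band_counts(rng, sigma_by_row, n_per_row):
    shares = _conditional_shares(np.asarray(sigma_by_row))
    c1 = rng.binomial(n_per_row, shares[:, 0])
    return c1, n_per_row - c1


def test_fit_recovers_visit_covariate():
    """5000 detections at sigma=35 with a +0.2 late-visit shift on log sigma."""
    rng = np.random.default_rng(123)
    sigma = np.array([35.0, 35.0 * math.exp(0.2)])
    c1, c2 = _simulate_band_counts(rng, sigma, np.array([2500, 2500]))
    obs = pd.DataFrame(
        {"visit": [1, 2], "count_band1": c1, "count_band2": c2}
    )
    model = lf.fit_halfnormal_binned(obs, use_habitat=False)
    gamma = dict(zip(model.design_columns, model.gamma))
    assert gamma["intercept"] == pytest.approx(math.log(35.0), abs=0.1)
    assert gamma["visit_late"] == pytest.approx(0.2, abs=0.1)


def test_sigma_recovery_median_error():
    """Median relative error of sigma over seeded replicates is under 5%."""
    true_sigma = 30.0
    errors = []
    for rep in range(50):
        rng = np.random.default_rng(500 + rep)
        c1, c2 = _simulate_band_counts(rng, [true_sigma], np.array([2000]))
        model = lf.fit_halfnormal_binned(
            _frame(int(c1[0]), int(c2[0])), use_visit=False, use_habitat=False
        )
        sigma_hat = float(model.sigma(1, "all")[0])
        errors.append(abs(sigma_hat - true_sigma) / true_sigma)
    assert np.median(errors) < 0.05


def test_detection_probability_values_and_errors():
    model = lf.fit_halfnormal_binned(_frame(474, 526), use_visit=False, use_habitat=False)
    p = detection_probability(model, 1, "all")[0]
    # sigma_hat ~ 40 => P ~ 0.25 * 0.939 + 0.75 * 0.347
    assert p == pytest.approx(0.495, abs=0.01)
    with pytest.raises(ValueError, match="woodland"):
        detection_probability(model, 1, "woodland")


def test_detection_probability_perfect_limit():
    model = lf.fit_halfnormal_binned(_frame(250, 750), use_visit=False, use_habitat=False)
    p = detection_probability(model, 1, "all")[0]
    assert p > 0.999
    assert math.log(p) == pytest.approx(0.0, abs=1e-3)


def test_fit_errors_on_empty_or_zero_data():
    with pytest.raises(ValueError):
        lf.fit_halfnormal_binned(pd.DataFrame({"count_band1": [], "count_band2": []}))
    with pytest.raises(ValueError):
        lf.fit_halfnormal_binned(_frame(0, 0))


def test_detection_table_shape(bird_data):
    tab = detection_table(bird_data["detection"])
    assert {"visit", "habitat", "sigma_m", "p_detect"} <= set(tab.columns)
    assert ((tab["p_detect"] > 0) & (tab["p_detect"] <= 1)).all()
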
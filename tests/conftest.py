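import numpy as np
import pytest

import lfabund as lf


@pytest.fixture(scope="session")
def small_sites():
    """A small synthetic landscape shared across tests."""
    cfg = lf.LandscapeConfig(n_sites=60, n_regions=4, n_years=3, seed=7)
    return lf.generate_sites(cfg)


@pytest.fixture(scope="session")
def bird_data(small_sites):
    """Bird surveys (per-visit band counts), detection fit, aggregation."""
    params = lf.TrueParameters()
    surveys, truth = lf.simulate_surveys(small_sites, params, 3, 21, group="bird")
    nonzero = surveys[surveys[["count_band1", "count_band2"]].sum(axis=1) > 0]
    det = lf.fit_halfnormal_binned(nonzero)
    agg = lf.aggregate_bird_surveys(surveys, det)
    return {"surveys": surveys, "truth": truth, "detection": det, "agg": agg}


@pytest.fixture(scope="session")
def butterfly_data(small_sites):
    params = lf.TrueParameters(
        alpha=1.5, beta={"lf_total": (1.5, -1.0), "arable": (0.8, 0.0)}
    )
    surveys, truth = lf.simulate_surveys(small_sites, params, 3, 22, group="butterfly")
    agg = surveys.assign(p_detect=1.0)
    return {"surveys": surveys, "truth": truth, "agg": agg}


@pytest.fixture(scope="session")
def butterfly_fit(small_sites, butterfly_data):
    spec = lf.ModelSpec("agriculture", "additive", "total", False)
    design = lf.build_design(small_sites, butterfly_data["agg"], spec)
    return lf.fit_model(design), design
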
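import numpy as np
import pytest

import msom


@pytest.fixture
def tiny_data():
    """2 species x 3 sites x 2 occasions, one unsurveyed occasion."""
    x = np.zeros((2, 3, 2), dtype=np.int8)
    x[0, 0, 0] = 1
    x[0, 1, 1] = 1
    x[1, 0, 1] = 1
    mask = np.ones((3, 2), dtype=np.int8)
    mask[2, 1] = 0
    return msom.DetectionData(
        ["spA", "spB"], ["s1", "s2", "s3"], ["o1", "o2"], x, mask
    )


@pytest.fixture(scope="session")
def sim_small():
    """Small null-scenario community used across inference/summary tests."""
    sc = msom.preset_scenario("null")
    data, truth = msom.simulate_community(
        sc, n_species=8, n_sites=15, n_occasions=4, seed=11
    )
    return sc, data, truth


@pytest.fixture(scope="session")
def fitted_small(sim_small):
    """A short but genuine 3-chain fit of the small community."""
    sc, data, truth = sim_small
    cfg = msom.McmcConfig(chains=3, iterations=4000, burn_in=1500, thin=5, base_seed=7)
    samples = msom.run_mcmc(
        data, truth.site_covs, truth.occasion_covs, sc.model_spec, cfg
    )
    return sc, data, truth, samples
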
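import numpy as np
import pytest

from pyrocast import glmm, synth, standsim


@pytest.fixture(scope="session")
def truth():
    return synth.default_truth()


@pytest.fixture(scope="session")
def single_truth():
    """Single-species generating truth (Douglas-fir-like, RE SD 0.5)."""
    return synth.single_species_truth(re_sd=0.5)


@pytest.fixture(scope="session")
def small_records(single_truth):
    """40 plots x 40 trees of one species: enough for a stable, fast fit."""
    return synth.gen_burned_plots(single_truth, 40, 40, seed=101)


@pytest.fixture(scope="session")
def fitted_small(small_records):
    return glmm.fit_species_glmm(small_records, n_restarts=1)


@pytest.fixture(scope="session")
def refs():
    return synth.gen_historical_refs("default")


@pytest.fixture(scope="session")
def stands6(truth, refs):
    """1 forest x 2 types x 3 stands — the small stand set used across tests."""
    return synth.gen_stand_set(
        truth, ["Malheur"], list(standsim.FOREST_TYPES), 3, seed=2, refs=refs
    )


@pytest.fixture(scope="session")
def models_exact(truth):
    """Truth coefficients as models with zero SEs (no coefficient uncertainty)."""
    return synth.truth_models(truth, se_scale=0.0)


@pytest.fixture(scope="session")
def models_mc(truth):
    """Truth coefficients as models with representative SEs."""
    return synth.truth_models(truth, se_scale=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
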
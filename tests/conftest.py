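import numpy as np
import pytest

from progsub import dpg, featurize, synth


@pytest.fixture(scope="session")
def small_config():
    return synth.GeneratorConfig(n_patients=30, seed=11)


@pytest.fixture(scope="session")
def small_synth(small_config):
    return synth.generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_feat(small_synth):
    return featurize.vectorize(small_synth.cohort, small_synth.code_maps)


@pytest.fixture(scope="session")
def small_graph(small_feat):
    return dpg.build_dpg(small_feat, k=10)


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test (order-independent)."""
    return np.random.default_rng(20240917)
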
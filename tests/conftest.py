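import numpy as np
import pytest

from ddifuse import FeaturizeConfig, SyntheticConfig, featurize, generate


@pytest.fixture(scope="session")
def default_dataset():
    """The default study dataset: 60 drugs, 4 clusters, 8 classes, 5% label noise."""
    return generate(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def small_featurize_config():
    """PCA dims scaled to the 60-drug synthetic library."""
    return FeaturizeConfig(k_ssp=30, k_psp=30)


@pytest.fixture(scope="session")
def ssp_emb_store(default_dataset, small_featurize_config):
    return featurize(default_dataset, ("ssp", "emb"), small_featurize_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20250928)
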
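import pytest

import fluxlue as fl


@pytest.fixture(scope="session")
def small_config() -> fl.SyntheticConfig:
    return fl.SyntheticConfig(n_sites=6, years_per_site=2, seed=20240915)


@pytest.fixture(scope="session")
def small_network(small_config):
    daily, truth = fl.generate_site_network(small_config)
    return daily, truth


@pytest.fixture(scope="session")
def small_composites(small_network):
    daily, _ = small_network
    composites, audit = fl.prepare_composites(daily)
    return composites, audit


@pytest.fixture(scope="session")
def window_composites():
    """Window-level draws where the GLMM is exactly the generating process."""
    cfg = fl.SyntheticConfig(n_sites=50, years_per_site=5, seed=777)
    return cfg, fl.sample_composites(cfg, windows_per_site=60)
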
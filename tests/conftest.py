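import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from progressionscope import SyntheticConfig, make_panel
from progressionscope.synthetic import gen_progression_expression

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def small_config():
    """Small noisy study: 40 miRNAs, 300 genes, one planted regulator."""
    return SyntheticConfig(n_mirnas=40, n_mrnas=300, seed=11)


@pytest.fixture
def noiseless_config():
    return SyntheticConfig(n_mirnas=40, n_mrnas=300, noise_cv=0.0, seed=11)


@pytest.fixture
def small_study(small_config):
    return gen_progression_expression(small_config)


@pytest.fixture
def two_stage_panel():
    """5 features x (3+3 replicates) over two stages, fixed values."""
    rng = np.random.default_rng(42)
    values = rng.lognormal(mean=4.0, sigma=0.3, size=(5, 6))
    return make_panel(
        values,
        [f"g{i}" for i in range(5)],
        ["P", "P", "P", "DCIS", "DCIS", "DCIS"],
    )
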
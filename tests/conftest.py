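import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset():
    from repurposekit.simulate import generate_expression_dataset

    dataset, truth = generate_expression_dataset(
        n_genes=300, n_per_group=10, n_de=20, effect_log2=2.0,
        noise_sd=0.5, seed=7,
    )
    return dataset, truth


@pytest.fixture
def small_world():
    from repurposekit.simulate import generate_similarity_world

    return generate_similarity_world(
        n_compounds=12, n_diseases=8, n_blocks=4, fp_len=64, seed=11,
    )
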
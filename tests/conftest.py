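import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_field():
    """One deterministic 256x256 synthetic field with ground truth."""
    from ki67quant import SceneParams, generate_field

    params = SceneParams(height=256, width=256, n_dab=9, n_hema=3, seed=7)
    img, truth = generate_field(params)
    return params, img, truth


@pytest.fixture(scope="session")
def small_field_result(small_field):
    """Full pipeline output for the small field (computed once)."""
    from ki67quant import process_field

    _, img, _ = small_field
    return process_field(img)
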
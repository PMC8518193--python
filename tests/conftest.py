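import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def fixture_bundle():
    """Worked-example bundle anchored to the published point values."""
    from microcoi import published_fixture

    return published_fixture()


@pytest.fixture(scope="session")
def zero_noise_bundle():
    """Synthetic bundle with no price noise: estimates equal the truth."""
    from microcoi import SyntheticConfig, generate_costing_dataset

    return generate_costing_dataset(SyntheticConfig(dispersion=0.0), seed=7)


@pytest.fixture(scope="session")
def noisy_bundle():
    """Synthetic bundle at the default dispersion."""
    from microcoi import SyntheticConfig, generate_costing_dataset

    return generate_costing_dataset(SyntheticConfig(), seed=11)
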
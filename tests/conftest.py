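import pytest

from ndbaudit import (
    CorruptionConfig,
    SimConfig,
    StratumSpec,
    load_fixtures,
)


@pytest.fixture(scope="session")
def fixture_tables():
    return load_fixtures()


def small_config(*, population=2000, corruption=None, seed=99,
                 computerization=0.948, strata=4, participation=None):
    """A light-weight simulator configuration for unit tests."""
    if corruption is None:
        corruption = CorruptionConfig()
    specs = []
    bands = ("40-44", "45-49", "50-54", "55-59", "60-64", "65-69", "70-74")
    for i in range(strata):
        sex = "male" if i % 2 == 0 else "female"
        specs.append(StratumSpec(
            sex=sex,
            age_band=bands[i % len(bands)],
            population=population,
            participation=participation if participation is not None else 0.4,
            percap_recipient_mean=100_000.0 + 20_000.0 * i,
            nonrecipient_ratio=1.3,
        ))
    return SimConfig(strata=specs, corruption=corruption, seed=seed,
                     computerization_prob=computerization)


@pytest.fixture
def tiny_sim_config():
    return small_config()
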
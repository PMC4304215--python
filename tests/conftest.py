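import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def counting_model():
    from rnascoredist import EnergyModel

    return EnergyModel.counting()


@pytest.fixture(scope="session")
def ggaaacc():
    from rnascoredist import RnaSequence

    return RnaSequence("GGAAACC")
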
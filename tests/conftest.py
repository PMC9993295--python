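import pytest
from hypothesis import HealthCheck, settings

import allodose as ad

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def model() -> ad.ScalingModel:
    return ad.load_default_model()


@pytest.fixture(scope="session")
def formulary() -> ad.Formulary:
    return ad.load_default_formulary()


@pytest.fixture(scope="session")
def who_table() -> ad.WeightBandTable:
    return ad.load_who_table()


@pytest.fixture(scope="session")
def reference_table() -> ad.WeightBandTable:
    return ad.load_reference_band_table()


@pytest.fixture(scope="session")
def spec() -> ad.CohortSpec:
    return ad.default_spec()


@pytest.fixture()
def small_cohort() -> list[ad.Patient]:
    return [
        ad.Patient("a", 4, 12.0, "F"),
        ad.Patient("b", 7, 20.0, "M"),
        ad.Patient("c", 10, 25.0, "F"),
        ad.Patient("d", 12, 40.0, "M"),
    ]
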
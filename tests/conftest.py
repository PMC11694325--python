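import pytest
from hypothesis import HealthCheck, settings

from pvdisprop import ingest, meddra
from pvdisprop.synthetic_faers import GeneratorConfig, generate_dataset

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def hierarchy():
    return meddra.default_hierarchy()


@pytest.fixture(scope="session")
def small_records():
    """A 2,000-case synthetic dataset with one strong planted association."""
    config = GeneratorConfig(
        n_cases=2000,
        seed=7,
        association={("esomeprazole", "Gastric cancer"): 8.0},
        nonsuspect_rate=0.02,
    )
    return generate_dataset(config)


@pytest.fixture(scope="session")
def small_cases(small_records):
    cases, _ = ingest.run(small_records)
    return cases


@pytest.fixture(scope="session")
def small_classification(small_cases, hierarchy):
    return meddra.classify_cases(small_cases, hierarchy)
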
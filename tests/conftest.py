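import warnings

import pytest
from hypothesis import settings

from fruitvol.evaluation import compare_models
from fruitvol.synthetic import GeneratorConfig, generate_dataset

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

warnings.filterwarnings("ignore", category=FutureWarning)

#: Seeds of the multi-seed realistic-population study shared across tests.
STUDY_SEEDS = tuple(range(10))

BASE_FAMILIES = [
    "classic_gbrt",
    "regularised_depthwise_gbrt",
    "histogram_leafwise_gbrt",
]


@pytest.fixture(scope="session")
def default_dataset():
    """One default-config population (two-variety citrus stream, n=150, 1% noise)."""
    return generate_dataset(GeneratorConfig(n=150, seed=0))


@pytest.fixture(scope="session")
def small_dataset():
    """A smaller population for modelling unit tests."""
    return generate_dataset(GeneratorConfig(n=80, seed=5))


@pytest.fixture(scope="session")
def ideal_dataset():
    """Identifiable limit: exact ellipsoids, no lobes, no measurement noise."""
    return generate_dataset(GeneratorConfig.noiseless_ellipsoid(n=150, seed=7))


@pytest.fixture(scope="session")
def ideal_report(ideal_dataset):
    """Comparison study on the identifiable-limit population."""
    return compare_models(ideal_dataset, seed=7, grids="fast")


@pytest.fixture(scope="session")
def study_reports():
    """The 10-seed realistic-population comparison study (reduced grids)."""
    reports = {}
    for seed in STUDY_SEEDS:
        ds = generate_dataset(GeneratorConfig(n=150, seed=seed))
        reports[seed] = compare_models(ds, seed=seed, grids="fast")
    return reports
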
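import pytest

from acetylstoich import GeneratorConfig, generate_dataset
from acetylstoich.stoichiometry import detection_limit, estimate_all


@pytest.fixture(scope="session")
def dataset():
    """One default synthetic experiment, shared across tests."""
    return generate_dataset(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def estimates(dataset):
    limit = detection_limit(dataset.heavy_intensities)
    return estimate_all(dataset.sites, dataset.proteins, limit, natural_only=False)


@pytest.fixture(scope="session")
def estimate_by_site(estimates):
    return {(e.protein_id, e.position): e for e in estimates}
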
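import pytest

from peptipath.synthetic_data import GeneratorSpec, generate_ratio_dataset, table1_fixture


@pytest.fixture(scope="session")
def fixture_bundle():
    """(peptides, direction pattern, frequency map) of the packaged table."""
    return table1_fixture()


@pytest.fixture(scope="session")
def planted_dataset(fixture_bundle):
    """A seeded synthetic ratio dataset carrying the packaged pattern."""
    peptides, _, _ = fixture_bundle
    observations = generate_ratio_dataset(GeneratorSpec(seed=7))
    return observations, peptides
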
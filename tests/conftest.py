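import pytest

from hrqolsm.coverage import coverage_report
from hrqolsm.pipeline import run_pipeline
from hrqolsm.simulate import GeneratorConfig, generate_corpus
from hrqolsm.taxonomy import load_taxonomy, occurrence_vector


@pytest.fixture(scope="session")
def taxonomy():
    return load_taxonomy()


@pytest.fixture(scope="session")
def subdomains(taxonomy):
    return taxonomy[0]


@pytest.fixture(scope="session")
def concept_map(taxonomy):
    return taxonomy[1]


@pytest.fixture(scope="session")
def table3_occurrences(subdomains):
    return occurrence_vector(subdomains)


@pytest.fixture(scope="session")
def fixture_report(table3_occurrences, concept_map, subdomains):
    return coverage_report(table3_occurrences, concept_map, subdomains)


@pytest.fixture(scope="session")
def planted_corpus(subdomains, table3_occurrences):
    """Deterministic-mode corpus planting the published occurrence vector."""
    config = GeneratorConfig(
        occurrence_vector=table3_occurrences, deterministic_margins=True, seed=42
    )
    return generate_corpus(config, subdomains)


@pytest.fixture(scope="session")
def planted_result(planted_corpus):
    posts, truth = planted_corpus
    return run_pipeline(posts, truth.alias_map)
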
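import logging

import pytest

from phenosynth.fixtures import (
    FixtureConfig,
    default_entity_expression,
    default_taxon_expression,
    fig3_ontology,
    fig3_sources,
    fig3_taxonomy,
    generate_kb,
    generate_ontology,
    generate_taxonomy,
)
from phenosynth.synthesis import synthesize

logging.getLogger("phenosynth").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def fig3():
    return fig3_ontology()


@pytest.fixture(scope="session")
def fig3_tax():
    return fig3_taxonomy()


@pytest.fixture(scope="session")
def fig3_kb():
    return fig3_sources()


def build_kb(seed, **overrides):
    cfg = FixtureConfig(seed=seed, **overrides)
    anatomy = generate_ontology(cfg)
    taxonomy = generate_taxonomy(cfg)
    sources, ledger = generate_kb(cfg, anatomy, taxonomy)
    return cfg, anatomy, taxonomy, sources, ledger


def build_matrix(seed, **overrides):
    cfg, anatomy, taxonomy, sources, ledger = build_kb(seed, **overrides)
    matrix = synthesize(
        anatomy,
        taxonomy,
        sources,
        default_entity_expression(),
        default_taxon_expression(),
    )
    return anatomy, taxonomy, sources, ledger, matrix


@pytest.fixture(scope="session")
def medium_kb():
    """One standard-size generated knowledge base (seed 1)."""
    return build_kb(1)


@pytest.fixture(scope="session")
def medium_matrix(medium_kb):
    cfg, anatomy, taxonomy, sources, ledger = medium_kb
    matrix = synthesize(
        anatomy,
        taxonomy,
        sources,
        default_entity_expression(),
        default_taxon_expression(),
    )
    return anatomy, taxonomy, sources, ledger, matrix
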
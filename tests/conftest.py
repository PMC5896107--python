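import pytest

from miexchange.generate import GeneratorConfig, generate_network


@pytest.fixture(scope="session")
def ontology_graph():
    from miexchange.validate import load_ontology

    return load_ontology()


@pytest.fixture(scope="session")
def fetcher():
    from miexchange.enrich import packaged_fetcher

    return packaged_fetcher()


@pytest.fixture(scope="session")
def cv_fetcher():
    from miexchange.enrich import packaged_cv_fetcher

    return packaged_cv_fetcher()


def make_network(dialect: str = "xml25", seed: int = 42, **overrides):
    """Generated network + sidecar for a dialect preset."""
    cfg = GeneratorConfig.for_dialect(dialect, seed=seed, **overrides)
    return generate_network(cfg)


@pytest.fixture
def nary_network():
    """A network guaranteed to contain n-ary interactions."""
    return make_network(
        "xml25", seed=1, n_interactions=10,
        arity_distribution={3: 0.5, 4: 0.5}, p_bait_present=1.0,
    )
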
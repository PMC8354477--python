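import pytest

from varburden import simulate


@pytest.fixture(scope="session")
def sim_config() -> simulate.SimConfig:
    """Default seeded synthetic configuration used across test modules."""
    return simulate.SimConfig(seed=12)


@pytest.fixture(scope="session")
def annotation(sim_config):
    return simulate.simulate_annotation(sim_config)


@pytest.fixture(scope="session")
def cohort(sim_config, annotation):
    genes, masks = annotation
    return simulate.simulate_cnv_cohort(sim_config, genes, masks)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, sim_config):
    """A full on-disk input fixture for pipeline/CLI tests."""
    out = tmp_path_factory.mktemp("fixture")
    paths = simulate.write_fixture(sim_config, out)
    return out, paths
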
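import pytest

from provdash import (
    GeneratorSpec,
    default_config,
    export_store,
    generate_store,
    syspro_lite,
)


@pytest.fixture(scope="session")
def onto():
    return syspro_lite()


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def store(onto):
    """The default synthetic corpus: 7 projects, 1000 experiments, seed 42."""
    return generate_store(GeneratorSpec(), onto)


@pytest.fixture(scope="session")
def store_dir(tmp_path_factory, store):
    d = tmp_path_factory.mktemp("store")
    export_store(store, d)
    return d


@pytest.fixture(scope="session")
def small_store(onto):
    return generate_store(GeneratorSpec(n_projects=3, n_experiments=60, seed=7), onto)
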
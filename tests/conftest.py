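import pytest

from autozyg.pipeline import RunConfig, run_all
from autozyg.simulate import make_toy_sketch


@pytest.fixture(scope="session")
def small_sketch():
    """A compact genome for unit tests: 2 x 30 Mb, 300 genes."""
    return make_toy_sketch(
        seed=7, n_chromosomes=2, chromosome_length_bp=30_000_000, n_genes=300
    )


@pytest.fixture(scope="session")
def default_bundle():
    """One full default-condition pipeline run, shared across tests."""
    return run_all(RunConfig(seed=1))


@pytest.fixture(scope="session")
def default_config():
    return RunConfig(seed=1)
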
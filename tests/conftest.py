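import numpy as np
import pytest

from groovedock import BenchmarkSpec, make_benchmark


@pytest.fixture(scope="session")
def benchmark():
    """The reference synthetic benchmark (seed 7), shared across tests."""
    return make_benchmark(BenchmarkSpec(seed=7))


@pytest.fixture(scope="session")
def receptor(benchmark):
    return benchmark.receptor


@pytest.fixture(scope="session")
def probe(benchmark):
    return benchmark.probe


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
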
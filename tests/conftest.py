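import numpy as np
import pytest
from hypothesis import settings

# fixed example generation: identical property-test runs on every machine
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mdlink import (
    AssociationNetwork,
    DiseaseOntologyGraph,
    build_similarity_bundle,
    make_benchmark,
)
from mdlink.synthetic import BENCHMARK_SPEC


@pytest.fixture(scope="session")
def benchmark():
    """The reference planted-block benchmark: 200x40, 4 blocks, seed 13."""
    return make_benchmark(BENCHMARK_SPEC)


@pytest.fixture(scope="session")
def benchmark_bundle(benchmark):
    net, dag, _ = benchmark
    return build_similarity_bundle(net, dag)


@pytest.fixture
def tiny_net():
    """Y = [[1, 0], [1, 1]] with order m1, m2 / d1, d2."""
    return AssociationNetwork(("m1", "m2"), ("d1", "d2"), np.array([[1, 0], [1, 1]]))


@pytest.fixture
def chain_dag():
    """C is-a B is-a A."""
    return DiseaseOntologyGraph.from_edges([("C", "B"), ("B", "A")])


def random_network(rng: np.random.Generator, n_m=12, n_d=8, density=0.3) -> AssociationNetwork:
    """Small random network guaranteed to have at least one edge."""
    Y = (rng.random((n_m, n_d)) < density).astype(np.int8)
    if Y.sum() == 0:
        Y[rng.integers(n_m), rng.integers(n_d)] = 1
    return AssociationNetwork(
        tuple(f"m{i}" for i in range(n_m)),
        tuple(f"d{j}" for j in range(n_d)),
        Y,
    )
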
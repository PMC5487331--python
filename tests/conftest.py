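import numpy as np
import pytest

from versatility import Partition, PartitionEnsemble, accumulate, karate_fixture


@pytest.fixture
def toy_ensemble():
    """Two runs over nodes {1,2,3}: {1,2 | 3} then {1 | 2,3}.

    Hand-counted association: p(1,2) = p(2,3) = 0.5, p(1,3) = 0.
    """
    run1 = Partition([1, 2, 3], ["a", "a", "b"])
    run2 = Partition([1, 2, 3], ["x", "y", "y"])
    return PartitionEnsemble([run1, run2], provenance="hand-built toy")


@pytest.fixture
def toy_assoc(toy_ensemble):
    return accumulate(toy_ensemble)


@pytest.fixture(scope="session")
def karate():
    return karate_fixture()


def random_ensemble(rng: np.random.Generator, n_nodes: int, runs: int,
                    max_labels: int = 4) -> PartitionEnsemble:
    nodes = list(range(n_nodes))
    parts = [
        Partition(nodes, rng.integers(max_labels, size=n_nodes))
        for _ in range(runs)
    ]
    return PartitionEnsemble(parts, provenance="uniform random labels")
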
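import os

import numpy as np
import pytest

from netbackbone.graph_core import BipartiteIncidence, Network

SENATE_ENV = "NETBACKBONE_SENATE108"
SENATE_DEFAULT = os.path.join(os.path.dirname(__file__), "..", "data", "senate108.tsv")


def edge_set(net):
    """Edge labels as order-insensitive canonical pairs."""
    return {tuple(sorted(map(str, e))) for e in net.edge_labels()}


def random_unweighted(n, p, seed):
    """Erdos-Renyi G(n, p) as a Network."""
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(iu.size) < p
    return Network(
        [f"n{i}" for i in range(n)],
        list(zip(iu[keep].tolist(), ju[keep].tolist())),
    )


def random_weighted(n, p, seed, integer=False, low=1, high=10):
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(iu.size) < p
    edges = list(zip(iu[keep].tolist(), ju[keep].tolist()))
    if integer:
        w = rng.integers(low, high + 1, size=len(edges)).astype(float)
    else:
        w = rng.uniform(0.1, 10.0, size=len(edges))
    return Network([f"n{i}" for i in range(n)], edges, w)


def random_incidence(m, n, p, seed):
    rng = np.random.default_rng(seed)
    return BipartiteIncidence((rng.random((m, n)) < p).astype(np.int8))


@pytest.fixture
def senate108_path():
    """Path to a user-supplied senate108 bipartite edge list, else skip."""
    path = os.environ.get(SENATE_ENV, SENATE_DEFAULT)
    if not os.path.exists(path):
        pytest.skip(
            "senate108 dataset not available (supply a Senator<TAB>bill edge "
            f"list at {SENATE_DEFAULT} or set ${SENATE_ENV})"
        )
    return path
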
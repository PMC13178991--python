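"""Seeded synthetic-network generators used in examples and tests."""

from __future__ import annotations

import numpy as np

from .graph_core import BipartiteIncidence, Network

__all__ = [
    "gen_sbm",
    "gen_bipartite_blocks",
    "gen_hub_spoke",
    "gen_preferential_attachment",
]

# Bipartite block probabilities are calibrated (pilot simulation) so that
# SDSM/FDSM backbones at alpha=0.05 recover the planted three communities.
DEFAULT_BIPARTITE_P_IN = 0.65
DEFAULT_BIPARTITE_P_OUT = 0.05


def gen_sbm(n_per_block=20, blocks=3, p_in=0.75, p_out=0.25, seed=None):
    """Stochastic block model graph; returns (Network, block labels)."""
    for p in (p_in, p_out):
        if not 0 <= p <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = n_per_block * blocks
    labels = np.repeat(np.arange(blocks), n_per_block)
    iu, ju = np.triu_indices(n, k=1)
    p_edge = np.where(labels[iu] == labels[ju], p_in, p_out)
    present = rng.random(iu.size) < p_edge
    edges = list(zip(iu[present].tolist(), ju[present].tolist()))
    net = Network([f"n{i}" for i in range(n)], edges)
    return net, labels


def gen_bipartite_blocks(
    agents=30,
    artifacts=75,
    blocks=3,
    p_in=DEFAULT_BIPARTITE_P_IN,
    p_out=DEFAULT_BIPARTITE_P_OUT,
    seed=None,
):
    """Bipartite incidence with planted agent/artifact blocks.

    Agent i holds artifact k with probability ``p_in`` when they belong to
    the same block and ``p_out`` otherwise.  Returns
    (BipartiteIncidence, agent block labels, artifact block labels).
    """
    if not p_in > p_out:
        raise ValueError("p_in must exceed p_out")
    if agents < blocks or artifacts < blocks:
        raise ValueError("need at least one agent and artifact per block")
    rng = np.random.default_rng(seed)
    a_labels = np.repeat(np.arange(blocks), agents // blocks)
    a_labels = np.concatenate([a_labels, np.arange(agents - a_labels.size) % blocks])
    b_labels = np.repeat(np.arange(blocks), artifacts // blocks)
    b_labels = np.concatenate([b_labels, np.arange(artifacts - b_labels.size) % blocks])
    P = np.where(a_labels[:, None] == b_labels[None, :], p_in, p_out)
    M = (rng.random((agents, artifacts)) < P).astype(np.int8)
    B = BipartiteIncidence(M)
    return B, a_labels, b_labels


def gen_hub_spoke(spokes_per_hub=4, high_weight=10.0, low_weight=1.0, seed=None, jitter=0.05):
    """Two-hub weighted toy: one high-volume and one low-volume region.

    Hub A serves ``spokes_per_hub`` spokes with weight ≈ ``high_weight``,
    hub B serves the same number with weight ≈ ``low_weight``, and the two
    hubs are joined by an edge of weight (high+low)/2.  ``jitter`` adds a
    small seeded relative perturbation to the spoke weights.
    """
    if high_weight <= 0 or low_weight <= 0:
        raise ValueError("weights must be positive")
    rng = np.random.default_rng(seed)
    nodes = ["hubA", "hubB"]
    nodes += [f"a{i}" for i in range(spokes_per_hub)]
    nodes += [f"b{i}" for i in range(spokes_per_hub)]
    triples = [("hubA", "hubB", (high_weight + low_weight) / 2.0)]
    for i in range(spokes_per_hub):
        wa = high_weight * (1.0 + jitter * (2.0 * rng.random() - 1.0))
        wb = low_weight * (1.0 + jitter * (2.0 * rng.random() - 1.0))
        triples.append(("hubA", f"a{i}", wa))
        triples.append(("hubB", f"b{i}", wb))
    return Network.from_edge_iter(triples, nodes=nodes)


def gen_preferential_attachment(n=60, m_per_step=3, seed=None):
    """Barabási–Albert-style growth graph with ``m_per_step`` edges per node.

    Starts from a clique on ``m_per_step + 1`` nodes; each subsequent node
    attaches to ``m_per_step`` distinct existing nodes chosen with
    probability proportional to current degree.
    """
    if not n > m_per_step >= 1:
        raise ValueError("need n > m_per_step >= 1")
    rng = np.random.default_rng(seed)
    edges = set()
    targets_pool = []  # degree-weighted multiset of endpoints
    n0 = m_per_step + 1
    for i in range(n0):
        for j in range(i + 1, n0):
            edges.add((i, j))
            targets_pool += [i, j]
    for new in range(n0, n):
        chosen = set()
        while len(chosen) < m_per_step:
            chosen.add(targets_pool[rng.integers(0, len(targets_pool))])
        for t in chosen:
            edges.add((t, new) if t < new else (new, t))
            targets_pool += [t, new]
    net = Network([f"n{i}" for i in range(n)], sorted(edges))
    return net
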
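"""Structural backbones of unweighted networks.

Every model is a combination of four steps:

1. ``escore``    — score each edge with a structural metric;
2. ``normalize`` — optionally replace scores with per-node local ranks;
3. ``filter``    — keep edges by threshold, global proportion, or per-node
                   degree-dependent nomination;
4. ``umst``      — optionally union with the maximum-spanning-forest edges
                   so the backbone stays connected.

Named presets (lspar, gspar, degree, skeleton, simmelian, quadrilateral,
jaccard, meetmin, geometric, hyper) are fixed combinations of these steps.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps

from .graph_core import Network
from .result import BackboneResult
from .retain import EdgeStatistics

__all__ = [
    "escore",
    "normalize_scores",
    "filter_edges",
    "umst",
    "simmelian_redundancy",
    "backbone_from_unweighted",
]

ESCORE_METRICS = (
    "jaccard", "triangles", "degree", "meetmin", "geometric",
    "hyper", "quadrangles", "random",
)
UNWEIGHTED_MODELS = (
    "lspar", "gspar", "degree", "skeleton", "simmelian", "quadrilateral",
    "jaccard", "meetmin", "geometric", "hyper",
)


def _require_unweighted(net: Network):
    if not isinstance(net, Network):
        raise ValueError("expected a Network")
    if net.is_weighted:
        raise ValueError("this model requires an unweighted Network")


def _quadrangles_exact(net: Network, nb):
    """Direct count of 4-cycles through each edge (b in N(u)\\{v}, a in N(v)\\{u})."""
    E = net.n_edges
    Q = np.zeros(E, dtype=np.int64)
    for e, (u, v) in enumerate(net.edges):
        count = 0
        for b in nb[u]:
            if b == v:
                continue
            for a in nb[b]:
                if a != u and a != v and a != b and a in nb[v]:
                    count += 1
        Q[e] = count
    return Q


def escore(net: Network, metric: str = "jaccard", seed=None) -> EdgeStatistics:
    """Score every edge with a structural metric.

    Symmetric metrics fill ``scores``; the directional ``degree`` metric
    fills ``endpoint_scores`` where the u→v view is the degree of v.
    Neighborhood-overlap metrics (jaccard, meetmin, geometric) use closed
    neighborhoods N[i] (the node itself included); ``hyper`` uses the
    open-neighborhood overlap with population = node count and returns
    1 − p (its p-values are stashed in ``p_upper``).
    """
    _require_unweighted(net)
    if metric not in ESCORE_METRICS:
        raise ValueError(f"unknown escore metric {metric!r}")
    nb = net.neighbor_sets()
    k = net.degrees()
    E = net.n_edges
    n = net.n_nodes
    stats = EdgeStatistics(edges=list(net.edges), model=metric, network=net)

    if metric == "degree":
        es = np.zeros((E, 2))
        for e, (u, v) in enumerate(net.edges):
            es[e, 0] = k[v]  # u's view of the edge: how big is the neighbor
            es[e, 1] = k[u]
        stats.endpoint_scores = es
        stats.scores = es.max(axis=1)
        return stats

    if metric == "random":
        rng = np.random.default_rng(seed)
        stats.scores = rng.random(E)
        return stats

    if metric == "quadrangles":
        Q = _quadrangles_exact(net, nb)
        Qnode = np.zeros(n, dtype=np.int64)
        for e, (u, v) in enumerate(net.edges):
            Qnode[u] += Q[e]
            Qnode[v] += Q[e]
        scores = np.zeros(E)
        for e, (u, v) in enumerate(net.edges):
            denom = Qnode[u] * Qnode[v]
            scores[e] = Q[e] / math.sqrt(denom) if denom > 0 else 0.0
        stats.scores = scores
        return stats

    scores = np.zeros(E)
    if metric == "hyper":
        p = np.zeros(E)
    for e, (u, v) in enumerate(net.edges):
        common_open = len(nb[u] & nb[v])
        if metric == "triangles":
            scores[e] = common_open
        elif metric == "hyper":
            p[e] = sps.hypergeom.sf(common_open - 1, n, k[v], k[u])
            scores[e] = 1.0 - p[e]
        else:
            closed_u = nb[u] | {u}
            closed_v = nb[v] | {v}
            inter = len(closed_u & closed_v)
            if metric == "jaccard":
                scores[e] = inter / len(closed_u | closed_v)
            elif metric == "meetmin":
                scores[e] = inter / min(k[u], k[v])
            elif metric == "geometric":
                scores[e] = inter * inter / (k[u] * k[v])
    stats.scores = scores
    if metric == "hyper":
        stats.p_upper = p
    return stats


def normalize_scores(stats: EdgeStatistics, method: str = "rank") -> EdgeStatistics:
    """Optionally replace scores with local (per-node) ranks.

    ``rank``: within each node's incident edges, sort by the node's view of
    the score descending — ties broken by neighbor label order — and assign
    ranks 1..k_i into ``endpoint_scores`` (smaller rank = better edge).
    ``none``: identity.
    """
    if method == "none":
        return stats
    if method != "rank":
        raise ValueError(f"unknown normalization {method!r}")
    net = stats.network
    if net is None or stats.scores is None and stats.endpoint_scores is None:
        raise ValueError("rank normalization requires scores on a network")
    E = stats.n_edges
    view = stats.endpoint_scores
    if view is None:
        view = np.stack([stats.scores, stats.scores], axis=1)
    ranks = np.zeros((E, 2))
    inc = net.incident_edges()
    side_of = {}
    for e, (u, v) in enumerate(stats.edges):
        side_of[(u, e)] = 0
        side_of[(v, e)] = 1
    for node in range(net.n_nodes):
        entries = []
        for e, other in inc[node]:
            s = view[e, side_of[(node, e)]]
            entries.append((-s, other, e))
        entries.sort()
        for rank, (_, _, e) in enumerate(entries, start=1):
            ranks[e, side_of[(node, e)]] = rank
    out = EdgeStatistics(
        edges=stats.edges, model=stats.model, network=net,
        scores=stats.scores, endpoint_scores=ranks,
        p_upper=stats.p_upper, p_lower=stats.p_lower,
        meta={**stats.meta, "normalized": "rank"},
    )
    return out


def filter_edges(stats: EdgeStatistics, method: str, parameter: float):
    """Select edge indices to keep.

    * ``threshold``  — keep edges with score >= parameter.
    * ``pvalue``     — keep edges with p_upper < parameter (hyper preset).
    * ``proportion`` — keep the top ⌊parameter·E⌋ edges globally by score
                       (ties broken by stable edge order).
    * ``degree``     — after rank normalization, node i nominates its top
                       ⌈k_i^parameter⌉ edges; an edge is kept iff nominated
                       by at least one endpoint.
    """
    E = stats.n_edges
    if method == "threshold":
        return np.nonzero(stats.scores >= parameter)[0]
    if method == "pvalue":
        if stats.p_upper is None:
            raise ValueError("pvalue filtering requires p_upper")
        return np.nonzero(stats.p_upper < parameter)[0]
    if method == "proportion":
        if not 0 <= parameter <= 1:
            raise ValueError("proportion parameter must lie in [0, 1]")
        keep_n = int(math.floor(parameter * E))
        order = np.argsort(-stats.scores, kind="stable")
        return np.sort(order[:keep_n])
    if method == "degree":
        if not 0 <= parameter <= 1:
            raise ValueError("degree parameter must lie in [0, 1]")
        if stats.meta.get("normalized") != "rank" or stats.endpoint_scores is None:
            raise ValueError("degree filtering requires rank-normalized scores")
        net = stats.network
        k = net.degrees()
        keep = np.zeros(E, dtype=bool)
        for e, (u, v) in enumerate(stats.edges):
            quota_u = math.ceil(k[u] ** parameter)
            quota_v = math.ceil(k[v] ** parameter)
            if stats.endpoint_scores[e, 0] <= quota_u or stats.endpoint_scores[e, 1] <= quota_v:
                keep[e] = True
        return np.nonzero(keep)[0]
    raise ValueError(f"unknown filter method {method!r}")


class _DSU:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, a):
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def umst(net: Network, stats: EdgeStatistics) -> np.ndarray:
    """Indices of edges in the union of all maximum spanning trees/forests.

    An edge with score s belongs to some maximum spanning tree iff its
    endpoints lie in different components of the subgraph of edges with
    score strictly greater than s.
    """
    scores = stats.scores
    if scores is None:
        scores = stats.endpoint_scores.max(axis=1)
    order = np.argsort(-scores, kind="stable")
    dsu = _DSU(net.n_nodes)
    kept = []
    i = 0
    E = len(order)
    while i < E:
        j = i
        while j < E and scores[order[j]] == scores[order[i]]:
            j += 1
        tier = order[i:j]
        for e in tier:
            u, v = stats.edges[e]
            if dsu.find(u) != dsu.find(v):
                kept.append(e)
        for e in tier:
            u, v = stats.edges[e]
            dsu.union(u, v)
        i = j
    return np.sort(np.array(kept, dtype=int))


def simmelian_redundancy(net: Network) -> EdgeStatistics:
    """Simmelian redundancy scores based on triadic tie strengths.

    Each edge's tie strength is its triangle count; each node ranks its
    neighbors by strength (ties by label order).  The redundancy of edge
    (i, j) is the maximum over prefix sizes k >= 1 of the Jaccard
    coefficient between i's and j's top-k neighbor sets, with the partner
    endpoint excluded from each ranking.
    """
    _require_unweighted(net)
    nb = net.neighbor_sets()
    tri = {}
    for u, v in net.edges:
        tri[(u, v)] = len(nb[u] & nb[v])
    ranked = []
    for node in range(net.n_nodes):
        strengths = []
        for other in nb[node]:
            key = (node, other) if node < other else (other, node)
            strengths.append((-tri[key], other))
        strengths.sort()
        ranked.append([other for _, other in strengths])
    scores = np.zeros(net.n_edges)
    for e, (u, v) in enumerate(net.edges):
        list_u = [x for x in ranked[u] if x != v]
        list_v = [x for x in ranked[v] if x != u]
        best = 0.0
        top_u, top_v = set(), set()
        for size in range(1, max(len(list_u), len(list_v)) + 1):
            if size <= len(list_u):
                top_u.add(list_u[size - 1])
            if size <= len(list_v):
                top_v.add(list_v[size - 1])
            union = len(top_u | top_v)
            if union:
                best = max(best, len(top_u & top_v) / union)
        scores[e] = best
    return EdgeStatistics(edges=list(net.edges), model="simmelian", network=net, scores=scores)


def _quadrilateral_redundancy(net: Network) -> EdgeStatistics:
    """Simmelian-style redundancy with 4-cycle counts as tie strengths."""
    _require_unweighted(net)
    nb = net.neighbor_sets()
    Q = _quadrangles_exact(net, nb)
    strength = {edge: Q[e] for e, edge in enumerate(net.edges)}
    ranked = []
    for node in range(net.n_nodes):
        entries = []
        for other in nb[node]:
            key = (node, other) if node < other else (other, node)
            entries.append((-strength[key], other))
        entries.sort()
        ranked.append([other for _, other in entries])
    scores = np.zeros(net.n_edges)
    for e, (u, v) in enumerate(net.edges):
        list_u = [x for x in ranked[u] if x != v]
        list_v = [x for x in ranked[v] if x != u]
        best = 0.0
        top_u, top_v = set(), set()
        for size in range(1, max(len(list_u), len(list_v)) + 1):
            if size <= len(list_u):
                top_u.add(list_u[size - 1])
            if size <= len(list_v):
                top_v.add(list_v[size - 1])
            union = len(top_u | top_v)
            if union:
                best = max(best, len(top_u & top_v) / union)
        scores[e] = best
    return EdgeStatistics(
        edges=list(net.edges), model="quadrilateral", network=net, scores=scores
    )


# preset name -> (escore metric or callable, normalize, filter, umst)
_PRESETS = {
    "lspar": ("jaccard", "rank", "degree", False),
    "degree": ("degree", "rank", "degree", False),
    "gspar": ("jaccard", "none", "proportion", False),
    "skeleton": ("random", "none", "proportion", False),
    "jaccard": ("jaccard", "none", "threshold", False),
    "meetmin": ("meetmin", "none", "threshold", False),
    "geometric": ("geometric", "none", "threshold", False),
    "hyper": ("hyper", "none", "pvalue", False),
    "simmelian": (simmelian_redundancy, "none", "threshold", False),
    "quadrilateral": (_quadrilateral_redundancy, "none", "threshold", False),
}


def backbone_from_unweighted(
    net: Network,
    model: str = "lspar",
    parameter: float = 0.5,
    seed=None,
    escore_metric: str | None = None,
    normalize: str | None = None,
    filter: str | None = None,
    umst_flag: bool | None = None,
) -> BackboneResult:
    """Extract a structural backbone from an unweighted network.

    Either pass a preset ``model`` (see :data:`UNWEIGHTED_MODELS`) or build
    a custom pipeline by giving ``escore_metric``/``normalize``/``filter``
    (and optionally ``umst_flag``), in which case ``model`` is ignored.
    """
    _require_unweighted(net)
    custom = escore_metric is not None or normalize is not None or filter is not None
    if custom:
        if escore_metric is None or filter is None:
            raise ValueError("custom pipelines require at least escore_metric and filter")
        metric, norm, filt, use_umst = (
            escore_metric, normalize or "none", filter, bool(umst_flag),
        )
        model_name = "custom"
    else:
        if model not in _PRESETS:
            raise ValueError(f"unknown unweighted model {model!r}")
        metric, norm, filt, use_umst = _PRESETS[model]
        if umst_flag is not None:
            use_umst = bool(umst_flag)
        model_name = model
    if parameter is None:
        raise ValueError("parameter is required")

    if callable(metric):
        stats = metric(net)
    else:
        stats = escore(net, metric, seed=seed)
    normed = normalize_scores(stats, norm)
    keep = filter_edges(normed, filt, parameter)
    if use_umst:
        keep = np.union1d(keep, umst(net, stats))
    bb = Network(net.nodes, [net.edges[i] for i in keep])
    return BackboneResult(
        backbone=bb,
        model=model_name,
        original_nodes=net.n_nodes,
        original_edges=net.n_edges,
        original_type="unweighted",
        parameter=float(parameter),
        seed=seed,
        meta={
            "escore": metric if isinstance(metric, str) else stats.model,
            "normalize": norm,
            "filter": filt,
            "umst": use_umst,
        },
    )
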
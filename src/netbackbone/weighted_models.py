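"""Backbone models for weighted networks.

One structural model (``global`` threshold) and three statistical models:

* ``disparity`` — per-endpoint null in which a node's strength is split
  uniformly at random among its edges; p = (1 − w/s)^(k−1).
* ``lans`` — empirical CDF of fractional edge weights at each endpoint.
* ``mlf`` — marginal likelihood filter: each of the T integer weight units
  joins nodes (i, j) with probability s_i·s_j / (2T²); binomial tails.

Edge-level p-values combine the two endpoint views with the min rule
(an edge is significant if it is significant from either side), matching
common disparity-filter practice; a max rule is available via ``combine``.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .graph_core import Network
from .result import BackboneResult
from .retain import EdgeStatistics, retain_edges

__all__ = [
    "global_threshold",
    "disparity_pvalues",
    "lans_pvalues",
    "mlf_pvalues",
    "backbone_from_weighted",
]

WEIGHTED_MODELS = ("global", "disparity", "lans", "mlf")


def _require_weighted(net: Network):
    if not isinstance(net, Network) or not net.is_weighted:
        raise ValueError("this model requires a weighted Network")


def _combine(pu_ends, pl_ends, combine):
    if combine == "min":
        return pu_ends.min(axis=1), pl_ends.min(axis=1)
    if combine == "max":
        return pu_ends.max(axis=1), pl_ends.max(axis=1)
    raise ValueError(f"unknown endpoint combination rule {combine!r}")


def global_threshold(net: Network, threshold: float) -> BackboneResult:
    """Retain exactly the edges with weight strictly greater than ``threshold``."""
    _require_weighted(net)
    keep = np.nonzero(net.weights > threshold)[0]
    bb = Network(net.nodes, [net.edges[i] for i in keep])
    return BackboneResult(
        backbone=bb,
        model="global",
        original_nodes=net.n_nodes,
        original_edges=net.n_edges,
        original_type="weighted",
        parameter=float(threshold),
    )


def disparity_pvalues(net: Network, combine="min") -> EdgeStatistics:
    """Disparity-filter tail probabilities for every edge.

    At endpoint i with degree k_i and strength s_i, the upper tail of edge
    (i, j) is (1 − w_ij/s_i)^(k_i − 1); degree-1 endpoints give p = 1
    (0⁰ convention), so pendant edges are never retained on statistical
    grounds.  The null is continuous, so the lower tail is 1 − upper.
    """
    _require_weighted(net)
    w = net.weights
    if np.any(w <= 0):
        raise ValueError("disparity filter requires strictly positive weights")
    k = net.degrees()
    s = net.strengths()
    E = net.n_edges
    pu = np.ones((E, 2))
    for e, (u, v) in enumerate(net.edges):
        for side, node in enumerate((u, v)):
            if k[node] > 1:
                f = w[e] / s[node]
                pu[e, side] = (1.0 - f) ** (k[node] - 1)
    pl = 1.0 - pu
    p_upper, p_lower = _combine(pu, pl, combine)
    return EdgeStatistics(
        edges=list(net.edges), model="disparity", network=net,
        p_upper=p_upper, p_lower=p_lower,
    )


def lans_pvalues(net: Network, combine="min") -> EdgeStatistics:
    """Locally adaptive sparsification: empirical endpoint tails.

    p_upper at endpoint i is the fraction of i's incident edges whose
    fractional weight f_il = w_il/s_i is ≥ f_ij (includes the edge itself,
    so p ≥ 1/k_i); p_lower counts f_il ≤ f_ij.
    """
    _require_weighted(net)
    w = net.weights
    s = net.strengths()
    inc = net.incident_edges()
    E = net.n_edges
    pu = np.ones((E, 2))
    pl = np.ones((E, 2))
    frac = [np.array([w[e] / s[node] for e, _ in inc[node]]) for node in range(net.n_nodes)]
    pos_in_node = {}
    for node in range(net.n_nodes):
        for slot, (e, _) in enumerate(inc[node]):
            pos_in_node[(node, e)] = slot
    for e, (u, v) in enumerate(net.edges):
        for side, node in enumerate((u, v)):
            f_here = frac[node][pos_in_node[(node, e)]]
            kn = len(frac[node])
            pu[e, side] = np.count_nonzero(frac[node] >= f_here) / kn
            pl[e, side] = np.count_nonzero(frac[node] <= f_here) / kn
    p_upper, p_lower = _combine(pu, pl, combine)
    return EdgeStatistics(
        edges=list(net.edges), model="lans", network=net,
        p_upper=p_upper, p_lower=p_lower,
    )


def mlf_pvalues(net: Network) -> EdgeStatistics:
    """Marginal likelihood filter: binomial tails for integer edge weights.

    Each of the T = Σ w_ij weight units independently lands on the node
    pair (i, j) with probability q_ij = s_i·s_j/(2T²); inclusive tails of
    Binomial(T, q_ij) at the observed weight.

    Unlike the other models, an all-ones weight vector is accepted: the
    null is well defined for any integer counts.
    """
    if not isinstance(net, Network) or net.weights is None:
        raise ValueError("mlf requires a Network with edge weights")
    w = net.weights
    if np.any(np.abs(w - np.round(w)) > 1e-9) or np.any(w < 1):
        raise ValueError(
            "mlf requires integer edge weights >= 1; rescale your weights "
            "to counts before applying this model"
        )
    wi = np.round(w).astype(np.int64)
    T = int(wi.sum())
    s = net.strengths()
    q = np.array([s[u] * s[v] for u, v in net.edges]) / (2.0 * T * T)
    p_upper = sps.binom.sf(wi - 1, T, q)
    p_lower = sps.binom.cdf(wi, T, q)
    return EdgeStatistics(
        edges=list(net.edges), model="mlf", network=net,
        p_upper=p_upper, p_lower=p_lower,
    )


def backbone_from_weighted(
    net: Network,
    model: str = "disparity",
    alpha: float | None = None,
    parameter: float | None = None,
    mtc: str = "none",
    signed: bool = False,
    combine: str = "min",
) -> BackboneResult:
    """Extract a backbone from a weighted network.

    ``model`` ∈ {'global', 'disparity', 'lans', 'mlf'}.  Statistical models
    use ``alpha`` (default 0.05); the global threshold uses ``parameter``.
    """
    _require_weighted(net)
    if model == "global":
        if alpha is not None:
            raise ValueError("the global threshold model takes parameter=, not alpha=")
        if parameter is None:
            raise ValueError("the global threshold model requires parameter= (the threshold)")
        return global_threshold(net, parameter)
    if model not in WEIGHTED_MODELS:
        raise ValueError(f"unknown weighted model {model!r}")
    if parameter is not None:
        raise ValueError(f"statistical model {model!r} takes alpha=, not parameter=")
    alpha = 0.05 if alpha is None else alpha
    if model == "disparity":
        stats = disparity_pvalues(net, combine=combine)
    elif model == "lans":
        stats = lans_pvalues(net, combine=combine)
    else:
        stats = mlf_pvalues(net)
    idx, signs = retain_edges(stats, alpha=alpha, mtc=mtc, signed=signed)
    bb = Network(
        net.nodes,
        [net.edges[i] for i in idx],
        signs=signs if signed else None,
    )
    return BackboneResult(
        backbone=bb,
        model=model,
        original_nodes=net.n_nodes,
        original_edges=net.n_edges,
        original_type="weighted",
        alpha=alpha,
        mtc=mtc,
        signed=signed,
    )
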
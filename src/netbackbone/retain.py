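"""Edge retention: multiple-test correction and one-/two-tailed thresholding.

Statistical backbone models produce per-edge tail probabilities
(:class:`EdgeStatistics`); :func:`retain_edges` converts them into a retained
edge set, optionally signed (+1 for significantly strong edges, −1 for
significantly weak edges under a two-tailed test with alpha/2 per tail).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EdgeStatistics", "adjust_pvalues", "retain_edges"]

MTC_METHODS = ("none", "bonferroni", "holm", "bh", "by")
# alias used by the R ecosystem
_MTC_ALIASES = {"fdr": "bh"}


@dataclass
class EdgeStatistics:
    """Per-edge scores or tail p-values produced by a backbone model.

    ``edges`` is aligned with ``network.edges`` for weighted/unweighted
    models, or lists agent-index pairs of the projection for bipartite
    models.  Structural models fill ``scores`` (and, for directional
    metrics, ``endpoint_scores`` of shape (E, 2) giving the u→v and v→u
    views); statistical models fill ``p_upper`` and usually ``p_lower``.
    """

    edges: list
    model: str
    network: object | None = None
    scores: np.ndarray | None = None
    endpoint_scores: np.ndarray | None = None
    p_upper: np.ndarray | None = None
    p_lower: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def adjust_pvalues(p, method="none"):
    """Adjust a p-value vector for multiple testing.

    Methods: ``none`` (identity), ``bonferroni``, ``holm`` (step-down),
    ``bh`` (Benjamini–Hochberg step-up, FDR), ``by`` (Benjamini–Yekutieli).
    Output order matches input order; adjusted values are capped at 1.
    """
    method = _MTC_ALIASES.get(method, method)
    if method not in MTC_METHODS:
        raise ValueError(f"unknown multiple-test correction {method!r}")
    p = np.asarray(p, dtype=float)
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if method == "none" or n == 0:
        return p.copy()
    if method == "bonferroni":
        return np.minimum(p * n, 1.0)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adj = np.empty(n)
    if method == "holm":
        # step-down: cumulative max of (n - i) * p_(i)
        stepped = np.maximum.accumulate((n - np.arange(n)) * ranked)
        adj[order] = np.minimum(stepped, 1.0)
        return adj
    denom = np.arange(1, n + 1)
    factor = 1.0 if method == "bh" else np.sum(1.0 / denom)
    # step-up: running min from the largest p downwards
    stepped = np.minimum.accumulate((n * factor / denom * ranked)[::-1])[::-1]
    adj[order] = np.minimum(stepped, 1.0)
    return adj


def retain_edges(stats: EdgeStatistics, alpha=0.05, mtc="none", signed=False):
    """Select edges for retention from tail p-values.

    Returns ``(indices, signs)`` where ``indices`` indexes ``stats.edges``
    and ``signs`` is +1/−1 per retained edge.  Unsigned mode retains an edge
    iff its (adjusted) upper-tail p-value is below ``alpha``.  Signed mode
    splits ``alpha`` across the two tails: +1 iff adjusted ``p_upper`` <
    alpha/2, −1 iff adjusted ``p_lower`` < alpha/2.  For discrete inclusive
    tails ``p_upper + p_lower >= 1``, so at most one sign can fire.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if stats.p_upper is None:
        raise ValueError(f"model {stats.model!r} produced no p-values")
    p_up = adjust_pvalues(stats.p_upper, mtc)
    if not signed:
        idx = np.nonzero(p_up < alpha)[0]
        return idx, np.ones(idx.size, dtype=int)
    if stats.p_lower is None:
        raise ValueError("signed retention requires lower-tail p-values")
    p_lo = adjust_pvalues(stats.p_lower, mtc)
    pos = p_up < alpha / 2.0
    neg = (p_lo < alpha / 2.0) & ~pos
    idx = np.nonzero(pos | neg)[0]
    signs = np.where(pos[idx], 1, -1)
    return idx, signs
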
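"""Statistical backbones of bipartite projections.

The null models here evaluate the observed projection weight (number of
shared artifacts) of each agent pair against a distribution obtained by
constraining the bipartite incidence matrix B:

* ``sdsm``    — marginals constrained on average via the bipartite
                configuration model (BiCM); Poisson-binomial tails.
* ``fdsm``    — marginals constrained exactly; Monte-Carlo tails from
                fixed-marginal samples generated with curveball trades
                (the "fastball" sampler).
* ``fixedrow``  — row marginals constrained; exact hypergeometric tails.
* ``fixedcol``  — column marginals constrained; Poisson-binomial tails.
* ``fixedfill`` — only the total fill constrained; binomial tails.

``bicm_fit`` and ``fastball_sample`` are exported as standalone utilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import stats as sps

from .graph_core import BipartiteIncidence, Network, project_bipartite
from .result import BackboneResult
from .retain import EdgeStatistics, retain_edges

__all__ = [
    "BicmFit",
    "bicm_fit",
    "poisson_binomial_tail",
    "sdsm_pvalues",
    "fastball_sample",
    "fdsm_pvalues",
    "fixedrow_pvalues",
    "fixedcol_pvalues",
    "fixedfill_pvalues",
    "backbone_from_projection",
]

PROJECTION_MODELS = ("sdsm", "fdsm", "fixedrow", "fixedcol", "fixedfill")

#: above this many Bernoulli terms the Poisson-binomial tails switch from the
#: exact dynamic-programming convolution to a refined normal approximation
EXACT_PB_LIMIT = 8192


# ---------------------------------------------------------------------- #
# bipartite configuration model
# ---------------------------------------------------------------------- #
@dataclass
class BicmFit:
    """Solution of the bipartite configuration model.

    ``probs[i, k] = x_i·y_k / (1 + x_i·y_k)`` with expected marginals equal
    to the observed ones within ``residual``.  Degenerate (empty or full)
    rows/columns carry exact 0/1 probabilities and factor inf/0 markers.
    """

    probs: np.ndarray
    row_factors: np.ndarray
    col_factors: np.ndarray
    residual: float
    iterations: int


def bicm_fit(B: BipartiteIncidence, tol: float = 1e-8, max_iter: int = 10000) -> BicmFit:
    """Fit the bipartite configuration model to an incidence matrix.

    Solves the maximum-entropy cell probabilities with expected row/column
    sums matching the observed marginals, via fixed-point iteration on the
    reduced system of distinct marginal values.  All-zero / all-one rows
    and columns are peeled off first and assigned exact probabilities.
    """
    M = B.matrix.astype(np.int64)
    m, n = M.shape
    P = np.zeros((m, n))
    r = M.sum(axis=1).astype(float)
    c = M.sum(axis=0).astype(float)
    rows = list(range(m))
    cols = list(range(n))

    # peel degenerate rows/columns (marginal 0 or full) until stable
    changed = True
    while changed:
        changed = False
        for i in list(rows):
            if r[i] == 0:
                rows.remove(i)
                changed = True
            elif r[i] == len(cols):
                P[i, cols] = 1.0
                for k in cols:
                    c[k] -= 1
                rows.remove(i)
                changed = True
        for k in list(cols):
            if c[k] == 0:
                cols.remove(k)
                changed = True
            elif c[k] == len(rows):
                P[rows, k] = 1.0
                for i in rows:
                    r[i] -= 1
                cols.remove(k)
                changed = True

    iters = 0
    if rows and cols:
        rr = r[rows]
        cc = c[cols]
        # reduced system over distinct marginal values
        r_vals, r_inv, r_mult = np.unique(rr, return_inverse=True, return_counts=True)
        c_vals, c_inv, c_mult = np.unique(cc, return_inverse=True, return_counts=True)
        f = rr.sum()
        x = r_vals / np.sqrt(f)
        y = c_vals / np.sqrt(f)
        residual = np.inf
        for iters in range(1, max_iter + 1):
            xy = np.outer(x, y)
            x = r_vals / ((c_mult * y) / (1.0 + xy)).sum(axis=1)
            xy = np.outer(x, y)
            y = c_vals / ((r_mult[:, None] * x[:, None]) / (1.0 + xy)).sum(axis=0)
            xy = np.outer(x, y)
            p = xy / (1.0 + xy)
            res_r = np.abs((c_mult * p).sum(axis=1) - r_vals).max()
            res_c = np.abs((r_mult[:, None] * p).sum(axis=0) - c_vals).max()
            residual = max(res_r, res_c)
            if residual <= tol:
                break
        else:
            raise RuntimeError(
                f"bicm failed to converge after {max_iter} iterations "
                f"(residual {residual:.3e} > tol {tol:.1e})"
            )
        P[np.ix_(rows, cols)] = p[np.ix_(r_inv, c_inv)]
        xf = np.full(m, np.nan)
        yf = np.full(n, np.nan)
        xf[rows] = x[r_inv]
        yf[cols] = y[c_inv]
    else:
        residual = 0.0
        xf = np.full(m, np.nan)
        yf = np.full(n, np.nan)

    full_res = max(
        np.abs(P.sum(axis=1) - B.row_marginals).max() if m else 0.0,
        np.abs(P.sum(axis=0) - B.col_marginals).max() if n else 0.0,
    )
    return BicmFit(
        probs=P, row_factors=xf, col_factors=yf,
        residual=float(full_res), iterations=iters,
    )


# ---------------------------------------------------------------------- #
# Poisson-binomial tails
# ---------------------------------------------------------------------- #
@njit(cache=True)
def _pb_lower_cdfs(q, observed):
    """(P(X <= observed), P(X <= observed-1)) for X ~ PoissonBinomial(q).

    Truncated dynamic-programming convolution: only counts 0..observed are
    tracked, which leaves the lower tail exact.
    """
    L = observed + 1
    dp = np.zeros(L)
    dp[0] = 1.0
    for j in range(q.shape[0]):
        p = q[j]
        top = min(j + 1, observed)
        for t in range(top, 0, -1):
            dp[t] = dp[t] * (1.0 - p) + dp[t - 1] * p
        dp[0] *= 1.0 - p
    cdf = 0.0
    for t in range(L - 1):
        cdf += dp[t]
    return cdf + dp[L - 1], cdf


@njit(cache=True)
def _pb_pair_tails(probs, pairs, obs):
    """Poisson-binomial inclusive tails for agent pairs under cellwise probs.

    probs: (m, n) per-cell probabilities; for pair (i, j) the null overlap
    is a sum of Bernoulli(probs[i,k] * probs[j,k]).
    """
    npairs = pairs.shape[0]
    pu = np.empty(npairs)
    pl = np.empty(npairs)
    for e in range(npairs):
        i, j = pairs[e, 0], pairs[e, 1]
        q = probs[i] * probs[j]
        cdf_obs, cdf_prev = _pb_lower_cdfs(q, obs[e])
        pl[e] = min(cdf_obs, 1.0)
        pu[e] = min(max(1.0 - cdf_prev, 0.0), 1.0)
    return pu, pl


def _pb_refined_normal(q, observed, tail):
    """Refined (skewness-corrected, continuity-corrected) normal tail."""
    mu = q.sum()
    var = (q * (1.0 - q)).sum()
    if var <= 0:
        exact = float(observed <= mu) if tail == "upper" else float(observed >= mu)
        return exact
    sigma = np.sqrt(var)
    gamma = (q * (1.0 - q) * (1.0 - 2.0 * q)).sum() / sigma**3

    def cdf(k):
        x = (k + 0.5 - mu) / sigma
        val = sps.norm.cdf(x) + gamma * (1.0 - x * x) * sps.norm.pdf(x) / 6.0
        return min(max(val, 0.0), 1.0)

    if tail == "upper":
        return 1.0 - cdf(observed - 1)
    return cdf(observed)


def poisson_binomial_tail(probs, observed: int, tail: str = "upper") -> float:
    """Inclusive tail probability of a Poisson-binomial distribution.

    Exact dynamic-programming convolution for up to ``EXACT_PB_LIMIT``
    Bernoulli terms, refined normal approximation beyond.  ``upper`` gives
    P(X >= observed), ``lower`` gives P(X <= observed).
    """
    q = np.asarray(probs, dtype=float)
    if q.ndim != 1 or np.any(q < 0) or np.any(q > 1):
        raise ValueError("probs must be a vector of probabilities in [0, 1]")
    observed = int(observed)
    if not 0 <= observed <= q.size:
        raise ValueError(f"observed count {observed} out of range [0, {q.size}]")
    if tail not in ("upper", "lower"):
        raise ValueError("tail must be 'upper' or 'lower'")
    if q.size > EXACT_PB_LIMIT:
        return _pb_refined_normal(q, observed, tail)
    cdf_obs, cdf_prev = _pb_lower_cdfs(q, observed)
    if tail == "lower":
        return float(min(cdf_obs, 1.0))
    return float(min(max(1.0 - cdf_prev, 0.0), 1.0))


# ---------------------------------------------------------------------- #
# helpers shared by the five nulls
# ---------------------------------------------------------------------- #
def _projection_pairs(B: BipartiteIncidence):
    """Agent pairs with nonzero observed overlap, and their overlaps."""
    P = B.matrix.astype(np.int64) @ B.matrix.astype(np.int64).T
    iu, ju = np.nonzero(np.triu(P, k=1))
    pairs = np.stack([iu, ju], axis=1).astype(np.int64)
    obs = P[iu, ju].astype(np.int64)
    return pairs, obs


def _stats_from_tails(B, model, pairs, obs, pu, pl, meta=None):
    edges = [(int(i), int(j)) for i, j in pairs]
    return EdgeStatistics(
        edges=edges, model=model, network=None,
        p_upper=np.asarray(pu, dtype=float), p_lower=np.asarray(pl, dtype=float),
        meta={"observed": np.asarray(obs), **(meta or {})},
    )


# ---------------------------------------------------------------------- #
# the five null models
# ---------------------------------------------------------------------- #
def sdsm_pvalues(B: BipartiteIncidence, tol: float = 1e-8) -> EdgeStatistics:
    """Stochastic degree sequence model tails.

    Cell probabilities come from :func:`bicm_fit`; the null overlap of pair
    (i, j) is a Poisson-binomial sum over artifacts k of
    Bernoulli(p_ik·p_jk), evaluated at the observed overlap.
    """
    fit = bicm_fit(B, tol=tol)
    pairs, obs = _projection_pairs(B)
    if B.n_artifacts <= EXACT_PB_LIMIT:
        pu, pl = _pb_pair_tails(fit.probs, pairs, obs)
    else:  # pragma: no cover - very wide matrices only
        pu = np.empty(len(pairs))
        pl = np.empty(len(pairs))
        for e, (i, j) in enumerate(pairs):
            q = fit.probs[i] * fit.probs[j]
            pu[e] = _pb_refined_normal(q, obs[e], "upper")
            pl[e] = _pb_refined_normal(q, obs[e], "lower")
    return _stats_from_tails(B, "sdsm", pairs, obs, pu, pl, {"bicm_residual": fit.residual})


def _curveball_trades(row_sets, trades, rng):
    """In-place curveball trades on a list of per-row column-index sets."""
    m = len(row_sets)
    ij = rng.integers(0, m, size=(trades, 2))
    for t in range(trades):
        i, j = ij[t]
        if i == j:
            j = (j + 1 + rng.integers(0, m - 1)) % m
        ri, rj = row_sets[i], row_sets[j]
        inter = ri & rj
        swappable = np.array(sorted((ri | rj) - inter))
        if swappable.size == 0:
            continue
        take_i = len(ri) - len(inter)
        perm = rng.permutation(swappable.size)
        row_sets[i] = inter | set(swappable[perm[:take_i]].tolist())
        row_sets[j] = inter | set(swappable[perm[take_i:]].tolist())


def _rows_to_matrix(row_sets, n):
    M = np.zeros((len(row_sets), n), dtype=np.int8)
    for i, cols in enumerate(row_sets):
        if cols:
            M[i, list(cols)] = 1
    return M


def fastball_sample(B: BipartiteIncidence, trades: int, seed=None) -> BipartiteIncidence:
    """Randomize an incidence matrix with marginal-preserving curveball trades.

    Each trade picks two distinct rows uniformly at random and redistributes
    the symmetric difference of their one-sets uniformly at random, keeping
    both row sums (and hence all column sums) fixed.  Deterministic given
    ``seed``.
    """
    if B.n_agents < 2:
        raise ValueError("fastball requires at least 2 rows")
    if trades < 1:
        raise ValueError("trades must be >= 1")
    rng = np.random.default_rng(seed)
    row_sets = [set(np.nonzero(B.matrix[i])[0].tolist()) for i in range(B.n_agents)]
    _curveball_trades(row_sets, trades, rng)
    return BipartiteIncidence(
        _rows_to_matrix(row_sets, B.n_artifacts), B.agent_labels, B.artifact_labels
    )


def fdsm_pvalues(
    B: BipartiteIncidence,
    trials: int = 1000,
    seed=None,
    trades_per_sample: int | None = None,
) -> EdgeStatistics:
    """Fixed degree sequence model tails by Monte-Carlo sampling.

    A serial Markov chain starts at B; each retained sample applies
    ``trades_per_sample`` curveball trades (default max(100, 5·m)) to the
    previous state.  Add-one tail estimates:
    p_upper = (1 + #{samples with overlap >= observed}) / (1 + trials).
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if B.n_agents < 2:
        raise ValueError("fdsm requires at least 2 agents")
    if trades_per_sample is None:
        trades_per_sample = max(100, 5 * B.n_agents)
    rng = np.random.default_rng(seed)
    pairs, obs = _projection_pairs(B)
    iu, ju = pairs[:, 0], pairs[:, 1]
    row_sets = [set(np.nonzero(B.matrix[i])[0].tolist()) for i in range(B.n_agents)]
    cge = np.zeros(len(pairs), dtype=np.int64)
    cle = np.zeros(len(pairs), dtype=np.int64)
    for _ in range(trials):
        _curveball_trades(row_sets, trades_per_sample, rng)
        M = _rows_to_matrix(row_sets, B.n_artifacts).astype(np.int64)
        Pstar = (M @ M.T)[iu, ju]
        cge += Pstar >= obs
        cle += Pstar <= obs
    pu = (1.0 + cge) / (1.0 + trials)
    pl = (1.0 + cle) / (1.0 + trials)
    return _stats_from_tails(B, "fdsm", pairs, obs, pu, pl, {"trials": trials})


def fixedrow_pvalues(B: BipartiteIncidence) -> EdgeStatistics:
    """Fixed row model: exact hypergeometric tails.

    Conditioning on the row marginals, the overlap of pair (i, j) follows
    Hypergeometric(population = n artifacts, successes = r_j, draws = r_i);
    symmetric in (i, j).
    """
    pairs, obs = _projection_pairs(B)
    r = B.row_marginals
    n = B.n_artifacts
    ri = r[pairs[:, 0]]
    rj = r[pairs[:, 1]]
    pu = sps.hypergeom.sf(obs - 1, n, rj, ri)
    pl = sps.hypergeom.cdf(obs, n, rj, ri)
    return _stats_from_tails(B, "fixedrow", pairs, obs, pu, pl)


def fixedcol_pvalues(B: BipartiteIncidence) -> EdgeStatistics:
    """Fixed column model: Poisson-binomial tails over per-artifact odds.

    Artifact k contributes a shared artifact to any given pair with
    probability c_k(c_k−1)/(m(m−1)); identical for all pairs, so a single
    distribution serves every pair.
    """
    m = B.n_agents
    if m < 2:
        raise ValueError("fixedcol requires at least 2 agents")
    pairs, obs = _projection_pairs(B)
    c = B.col_marginals.astype(float)
    q = c * (c - 1.0) / (m * (m - 1.0))
    # one shared null distribution: full DP once, tails by lookup
    pmf = np.zeros(B.n_artifacts + 1)
    pmf[0] = 1.0
    for p in q:
        pmf[1:] = pmf[1:] * (1.0 - p) + pmf[:-1] * p
        pmf[0] *= 1.0 - p
    cdf = np.cumsum(pmf)
    pl = np.minimum(cdf[obs], 1.0)
    prev = np.where(obs > 0, cdf[np.maximum(obs - 1, 0)], 0.0)
    pu = np.clip(1.0 - prev, 0.0, 1.0)
    return _stats_from_tails(B, "fixedcol", pairs, obs, pu, pl)


def fixedfill_pvalues(B: BipartiteIncidence) -> EdgeStatistics:
    """Fixed fill model: binomial tails with cell probability f/(mn).

    Every artifact is shared by a given pair with probability (f/(mn))²;
    the null overlap is Binomial(n, (f/(mn))²).
    """
    pairs, obs = _projection_pairs(B)
    m, n = B.n_agents, B.n_artifacts
    q = (B.fill / (m * n)) ** 2
    pu = sps.binom.sf(obs - 1, n, q)
    pl = sps.binom.cdf(obs, n, q)
    return _stats_from_tails(B, "fixedfill", pairs, obs, pu, pl)


# ---------------------------------------------------------------------- #
# dispatcher
# ---------------------------------------------------------------------- #
def backbone_from_projection(
    B: BipartiteIncidence,
    model: str = "sdsm",
    alpha: float = 0.05,
    mtc: str = "none",
    signed: bool = False,
    trials: int = 1000,
    seed=None,
    trades_per_sample: int | None = None,
) -> BackboneResult:
    """Extract the backbone of the weighted projection of a bipartite network.

    The input is the incidence structure B (not its projection P); the
    result is an unweighted (optionally signed) network on the agents.
    """
    if not isinstance(B, BipartiteIncidence):
        raise ValueError("backbone_from_projection requires a BipartiteIncidence input")
    if B.n_agents < 2:
        raise ValueError("projection backbones require at least 2 agents")
    if model not in PROJECTION_MODELS:
        raise ValueError(f"unknown projection model {model!r}")
    if model == "sdsm":
        stats = sdsm_pvalues(B)
    elif model == "fdsm":
        stats = fdsm_pvalues(B, trials=trials, seed=seed, trades_per_sample=trades_per_sample)
    elif model == "fixedrow":
        stats = fixedrow_pvalues(B)
    elif model == "fixedcol":
        stats = fixedcol_pvalues(B)
    else:
        stats = fixedfill_pvalues(B)
    idx, signs = retain_edges(stats, alpha=alpha, mtc=mtc, signed=signed)
    kept = [stats.edges[i] for i in idx]  # already in lexicographic pair order
    bb = Network(B.agent_labels, kept, signs=signs if signed else None)
    return BackboneResult(
        backbone=bb,
        model=model,
        original_nodes=B.n_agents,
        original_edges=len(stats.edges),
        original_type="bipartite",
        alpha=alpha,
        mtc=mtc,
        signed=signed,
        seed=seed,
        trials=trials if model == "fdsm" else None,
        meta={"n_agents": B.n_agents, "n_artifacts": B.n_artifacts},
    )
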
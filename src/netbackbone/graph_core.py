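"""Core network data types, file I/O, type detection, and bipartite projection.

Two container types are used throughout the package:

* :class:`Network` — an undirected, optionally weighted unipartite graph.
* :class:`BipartiteIncidence` — a binary agents × artifacts incidence matrix.

Both are deliberately lightweight (label lists + index arrays) so that the
statistical models can operate on plain numpy arrays.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Network",
    "BipartiteIncidence",
    "LoadReport",
    "read_network",
    "write_backbone",
    "detect_network_type",
    "project_bipartite",
]

_SYMMETRY_TOL = 1e-12


@dataclass
class LoadReport:
    """Bookkeeping for edges dropped or merged during ingestion."""

    dropped_loops: int = 0
    deduplicated_edges: int = 0

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"LoadReport(dropped_loops={self.dropped_loops}, "
            f"deduplicated_edges={self.deduplicated_edges})"
        )


class Network:
    """Undirected unipartite network with optional nonnegative edge weights.

    Nodes are kept in first-appearance order; edges are stored once as
    ``(u, v)`` index pairs with ``u < v``.  Self-loops are dropped at
    construction time (counted in :attr:`load_report`) and duplicate edges
    are merged, erroring if their weights disagree.
    """

    def __init__(self, nodes, edges, weights=None, signs=None, load_report=None):
        self.nodes = list(nodes)
        self._index = {n: i for i, n in enumerate(self.nodes)}
        if len(self._index) != len(self.nodes):
            raise ValueError("duplicate node labels")
        self.edges = [(int(u), int(v)) for u, v in edges]
        for u, v in self.edges:
            if u >= v:
                raise ValueError("edges must be stored as (u, v) with u < v")
            if v >= len(self.nodes):
                raise ValueError("edge endpoint out of range")
        self.weights = None if weights is None else np.asarray(weights, dtype=float)
        if self.weights is not None:
            if len(self.weights) != len(self.edges):
                raise ValueError("weights length mismatch")
            if np.any(self.weights < 0):
                raise ValueError("negative edge weights are not supported")
        self.signs = None if signs is None else np.asarray(signs, dtype=int)
        if self.signs is not None and len(self.signs) != len(self.edges):
            raise ValueError("signs length mismatch")
        self.load_report = load_report or LoadReport()

    # ------------------------------------------------------------------ #
    # construction helpers
    # ------------------------------------------------------------------ #
    @classmethod
    def from_edge_iter(cls, triples, nodes=None):
        """Build from an iterable of ``(label_u, label_v[, weight])``.

        Node order is first-appearance; loops dropped; duplicates merged
        (weights must agree).
        """
        order: list = list(nodes) if nodes is not None else []
        index = {n: i for i, n in enumerate(order)}
        report = LoadReport()
        seen: dict = {}
        any_weight = False
        for t in triples:
            if len(t) == 2:
                a, b = t
                w = None
            else:
                a, b, w = t[0], t[1], float(t[2])
                any_weight = True
                if w < 0:
                    raise ValueError(f"negative weight on edge ({a}, {b})")
            for lab in (a, b):
                if lab not in index:
                    index[lab] = len(order)
                    order.append(lab)
            if a == b:
                report.dropped_loops += 1
                continue
            u, v = index[a], index[b]
            key = (u, v) if u < v else (v, u)
            if key in seen:
                report.deduplicated_edges += 1
                if seen[key] != w:
                    raise ValueError(f"duplicate edge ({a}, {b}) with conflicting weights")
            else:
                seen[key] = w
        edges = sorted(seen)
        weights = None
        if any_weight:
            weights = np.array([1.0 if seen[e] is None else seen[e] for e in edges])
        return cls(order, edges, weights, load_report=report)

    @classmethod
    def from_adjacency(cls, matrix, labels=None):
        """Build from a square symmetric adjacency matrix (0 = no edge)."""
        A = np.asarray(matrix, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency matrix must be square")
        if np.max(np.abs(A - A.T)) > _SYMMETRY_TOL:
            raise ValueError("directed input unsupported: adjacency matrix is asymmetric")
        if np.any(A < 0):
            raise ValueError("negative edge weights are not supported")
        n = A.shape[0]
        labels = list(labels) if labels is not None else [str(i) for i in range(n)]
        report = LoadReport(dropped_loops=int(np.count_nonzero(np.diag(A))))
        iu, ju = np.nonzero(np.triu(A, k=1))
        edges = list(zip(iu.tolist(), ju.tolist()))
        weights = A[iu, ju]
        net = cls(labels, edges, weights if len(weights) else None, load_report=report)
        return net

    # ------------------------------------------------------------------ #
    # derived quantities
    # ------------------------------------------------------------------ #
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def is_weighted(self) -> bool:
        """True iff at least one stored weight lies outside {0, 1}."""
        if self.weights is None:
            return False
        return bool(np.any((self.weights != 0.0) & (self.weights != 1.0)))

    def degrees(self) -> np.ndarray:
        k = np.zeros(self.n_nodes, dtype=int)
        for u, v in self.edges:
            k[u] += 1
            k[v] += 1
        return k

    def strengths(self) -> np.ndarray:
        s = np.zeros(self.n_nodes, dtype=float)
        w = self.weights if self.weights is not None else np.ones(self.n_edges)
        for e, (u, v) in enumerate(self.edges):
            s[u] += w[e]
            s[v] += w[e]
        return s

    def neighbor_sets(self) -> list:
        """Open neighborhoods as a list of sets of node indices."""
        nb = [set() for _ in range(self.n_nodes)]
        for u, v in self.edges:
            nb[u].add(v)
            nb[v].add(u)
        return nb

    def incident_edges(self) -> list:
        """Per node, list of (edge_index, other_endpoint)."""
        inc = [[] for _ in range(self.n_nodes)]
        for e, (u, v) in enumerate(self.edges):
            inc[u].append((e, v))
            inc[v].append((e, u))
        return inc

    def edge_labels(self):
        return [(self.nodes[u], self.nodes[v]) for u, v in self.edges]

    def adjacency(self) -> np.ndarray:
        A = np.zeros((self.n_nodes, self.n_nodes))
        w = self.weights if self.weights is not None else np.ones(self.n_edges)
        for e, (u, v) in enumerate(self.edges):
            A[u, v] = A[v, u] = w[e]
        return A

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kind = "weighted" if self.is_weighted else "unweighted"
        return f"<Network {kind}, {self.n_nodes} nodes, {self.n_edges} edges>"


class BipartiteIncidence:
    """Binary agents (rows) × artifacts (columns) incidence matrix."""

    def __init__(self, matrix, agent_labels=None, artifact_labels=None):
        B = np.asarray(matrix)
        if B.ndim != 2:
            raise ValueError("incidence matrix must be 2-dimensional")
        vals = np.unique(B)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("incidence matrix must be binary (cells in {0, 1})")
        self.matrix = B.astype(np.int8)
        m, n = B.shape
        self.agent_labels = (
            list(agent_labels) if agent_labels is not None else [f"a{i}" for i in range(m)]
        )
        self.artifact_labels = (
            list(artifact_labels) if artifact_labels is not None else [f"b{k}" for k in range(n)]
        )
        if len(self.agent_labels) != m or len(self.artifact_labels) != n:
            raise ValueError("label count does not match matrix shape")

    @property
    def n_agents(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_artifacts(self) -> int:
        return self.matrix.shape[1]

    @property
    def row_marginals(self) -> np.ndarray:
        return self.matrix.sum(axis=1, dtype=np.int64)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.matrix.sum(axis=0, dtype=np.int64)

    @property
    def fill(self) -> int:
        return int(self.matrix.sum(dtype=np.int64))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<BipartiteIncidence {self.n_agents} agents × "
            f"{self.n_artifacts} artifacts, fill={self.fill}>"
        )


# ---------------------------------------------------------------------- #
# type detection and projection
# ---------------------------------------------------------------------- #
def detect_network_type(net) -> str:
    """Classify an input object as 'bipartite', 'weighted' or 'unweighted'."""
    if isinstance(net, BipartiteIncidence):
        return "bipartite"
    if isinstance(net, Network):
        return "weighted" if net.is_weighted else "unweighted"
    raise TypeError(f"cannot detect network type of {type(net).__name__}")


def project_bipartite(B: BipartiteIncidence) -> Network:
    """Weighted unipartite projection onto agents.

    ``weight(i, j) = Σ_k B_ik · B_jk`` (number of shared artifacts);
    zero-weight pairs and the diagonal are omitted.
    """
    if B.n_agents < 2:
        raise ValueError("projection requires at least 2 agents")
    P = B.matrix.astype(np.int64) @ B.matrix.astype(np.int64).T
    iu, ju = np.nonzero(np.triu(P, k=1))
    edges = list(zip(iu.tolist(), ju.tolist()))
    weights = P[iu, ju].astype(float)
    return Network(B.agent_labels, edges, weights if len(weights) else None)


# ---------------------------------------------------------------------- #
# file I/O
# ---------------------------------------------------------------------- #
def _infer_format(path: str) -> str:
    lower = str(path).lower()
    if lower.endswith(".mtx"):
        return "mtx"
    if lower.endswith(".graphml") or lower.endswith(".xml"):
        return "graphml"
    if lower.endswith((".adj", ".mat")):
        return "adjacency"
    return "edgelist"


def _parse_edgelist_lines(lines):
    for ln, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) == 2:
            yield (parts[0], parts[1])
        elif len(parts) >= 3:
            try:
                w = float(parts[2])
            except ValueError as exc:
                raise ValueError(f"line {ln}: bad weight {parts[2]!r}") from exc
            yield (parts[0], parts[1], w)
        else:
            raise ValueError(f"line {ln}: expected 2 or 3 columns")


def _bipartite_from_pairs(pairs):
    agents, artifacts = [], []
    a_index, b_index = {}, {}
    cells = set()
    for t in pairs:
        a, b = t[0], t[1]
        if len(t) == 3 and float(t[2]) not in (0.0, 1.0):
            raise ValueError("bipartite edge list must be binary (weights in {0,1})")
        if a not in a_index:
            a_index[a] = len(agents)
            agents.append(a)
        if b not in b_index:
            b_index[b] = len(artifacts)
            artifacts.append(b)
        if len(t) == 3 and float(t[2]) == 0.0:
            continue
        cells.add((a_index[a], b_index[b]))
    M = np.zeros((len(agents), len(artifacts)), dtype=np.int8)
    for i, k in cells:
        M[i, k] = 1
    return BipartiteIncidence(M, agents, artifacts)


def read_network(path, format=None, bipartite=False):
    """Read a :class:`Network` or :class:`BipartiteIncidence` from a file.

    Parameters
    ----------
    path : str
        Input file path.
    format : {'edgelist', 'adjacency', 'mtx', 'graphml'}, optional
        Inferred from the extension when omitted.
    bipartite : bool
        Interpret the input as an agents × artifacts incidence structure.
    """
    fmt = format or _infer_format(path)
    if fmt == "edgelist":
        with open(path) as fh:
            lines = fh.readlines()
        signed = any(
            ln.lstrip().startswith("#") and "sign" in ln.lower() for ln in lines[:1]
        )
        pairs = list(_parse_edgelist_lines(lines))
        if bipartite:
            return _bipartite_from_pairs(pairs)
        if signed:
            triples = [(a, b) for a, b, *_ in pairs]
            net = Network.from_edge_iter(triples)
            signs = np.zeros(net.n_edges, dtype=int)
            for t in pairs:
                u, v = net._index[t[0]], net._index[t[1]]
                key = (u, v) if u < v else (v, u)
                signs[net.edges.index(key)] = int(t[2]) if len(t) == 3 else 1
            net.signs = signs
            return net
        return Network.from_edge_iter(pairs)
    if fmt == "adjacency":
        A = np.loadtxt(path, ndmin=2)
        return _matrix_to_object(A, bipartite)
    if fmt == "mtx":
        from scipy.io import mmread

        A = mmread(path)
        if hasattr(A, "todense"):
            A = A.todense()
        return _matrix_to_object(np.asarray(A, dtype=float), bipartite)
    if fmt == "graphml":
        import networkx as nx

        G = nx.read_graphml(path)
        triples = []
        for a, b, data in G.edges(data=True):
            if "weight" in data:
                triples.append((a, b, float(data["weight"])))
            else:
                triples.append((a, b))
        nodes = list(G.nodes())
        if triples:
            return Network.from_edge_iter(triples, nodes=nodes)
        return Network(nodes, [])
    raise ValueError(f"unknown format {fmt!r}")


def _matrix_to_object(A, bipartite):
    square = A.ndim == 2 and A.shape[0] == A.shape[1]
    if bipartite or not square:
        return BipartiteIncidence(A)
    if np.max(np.abs(A - A.T)) > _SYMMETRY_TOL:
        raise ValueError("directed input unsupported: adjacency matrix is asymmetric")
    return Network.from_adjacency(A)


def _format_weight(w: float) -> str:
    if float(w).is_integer() and abs(w) < 1e15:
        return str(int(w))
    return repr(float(w))


def write_network(net: Network, path, format="edgelist"):
    """Write a network as an edge list (TSV) or GraphML file."""
    if format == "edgelist":
        with open(path, "w") as fh:
            fh.write(_edgelist_text(net))
    elif format == "graphml":
        import networkx as nx

        G = nx.Graph()
        G.add_nodes_from(net.nodes)
        for e, (u, v) in enumerate(net.edges):
            attrs = {}
            if net.weights is not None:
                attrs["weight"] = float(net.weights[e])
            if net.signs is not None:
                attrs["sign"] = int(net.signs[e])
            G.add_edge(net.nodes[u], net.nodes[v], **attrs)
        nx.write_graphml(G, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _edgelist_text(net: Network) -> str:
    out = io.StringIO()
    if net.signs is not None and net.weights is None:
        out.write("# node1\tnode2\tsign\n")
    for e, (u, v) in enumerate(net.edges):
        cols = [str(net.nodes[u]), str(net.nodes[v])]
        if net.weights is not None:
            cols.append(_format_weight(net.weights[e]))
        elif net.signs is not None:
            cols.append(str(int(net.signs[e])))
        out.write("\t".join(cols) + "\n")
    return out.getvalue()


def write_backbone(result, path, format="edgelist"):
    """Write a backbone (from a BackboneResult or Network) to disk.

    Edge-list output carries a third ``sign`` column only when the backbone
    is signed; a write→read round trip returns an identical edge set.
    """
    net = getattr(result, "backbone", result)
    write_network(net, path, format=format)
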
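"""Backbone result container and narrative report generation."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np

from .graph_core import Network

__all__ = ["BackboneResult", "render_narrative", "format_pct", "CITATIONS"]

PACKAGE_NAME = "netbackbone"
PACKAGE_VERSION = "0.1.0"

# Citation registry: model -> (display name, citation string) for narratives.
CITATIONS = {
    "global": ("a global weight threshold", None),
    "disparity": ("the disparity filter", "Serrano, Boguna, and Vespignani, 2009"),
    "lans": ("locally adaptive network sparsification", "Foti, Hughes, and Rockmore, 2011"),
    "mlf": ("the marginal likelihood filter", "Dianati, 2016"),
    "sdsm": ("the stochastic degree sequence model (SDSM)", "Neal, Domagalski, and Sagan, 2021"),
    "fdsm": ("the fixed degree sequence model (FDSM)", "Zweig and Kaufmann, 2011"),
    "fixedrow": ("the fixed row model", "Neal, Domagalski, and Sagan, 2021"),
    "fixedcol": ("the fixed column model", "Neal, Domagalski, and Sagan, 2021"),
    "fixedfill": ("the fixed fill model", "Neal, Domagalski, and Sagan, 2021"),
    "lspar": ("Local Sparsification", "Satuluri, Parthasarathy, and Ruan, 2011"),
    "gspar": ("Global Sparsification", "Satuluri, Parthasarathy, and Ruan, 2011"),
    "degree": ("Local Degree", "Hamann, Lindner, Meyerhenke, Staudt, and Wagner, 2016"),
    "skeleton": ("random skeleton sparsification", "Karger, 1999"),
    "simmelian": ("the Simmelian backbone", "Nick, Lee, Cunningham, and Brandes, 2013"),
    "quadrilateral": ("the quadrilateral Simmelian backbone", "Nocaj, Ortmann, and Brandes, 2015"),
    "jaccard": ("jaccard-coefficient thresholding", "Goldberg and Roth, 2003"),
    "meetmin": ("meet/min-coefficient thresholding", "Goldberg and Roth, 2003"),
    "geometric": ("geometric-coefficient thresholding", "Goldberg and Roth, 2003"),
    "hyper": ("the hypergeometric backbone", "Goldberg and Roth, 2003"),
    "custom": ("a custom escore/normalize/filter pipeline", None),
}

STATISTICAL_MODELS = {
    "disparity", "lans", "mlf", "sdsm", "fdsm", "fixedrow", "fixedcol", "fixedfill",
}


def format_pct(x: float) -> str:
    """Format a percentage: round-half-even to 2 decimals, trim zeros.

    82.93 → '82.93', 70.40 → '70.4', 50.00 → '50'.
    """
    q = Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN)
    s = format(q, "f")
    if "." in s:
        s = s.rstrip("0").rstrip(".")
    return s


@dataclass
class BackboneResult:
    """A backbone network plus provenance metadata and a narrative summary."""

    backbone: Network
    model: str
    original_nodes: int
    original_edges: int
    original_type: str
    alpha: float | None = None
    parameter: float | None = None
    mtc: str = "none"
    signed: bool = False
    seed: int | None = None
    trials: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def edges_removed_pct(self) -> float:
        if self.original_edges == 0:
            return 0.0
        return 100.0 * (1.0 - self.backbone.n_edges / self.original_edges)

    @property
    def narrative(self) -> str:
        return render_narrative(self)

    def to_dict(self) -> dict:
        """Lossless JSON-serializable description of the result."""
        d = {
            "model": self.model,
            "alpha": self.alpha,
            "parameter": self.parameter,
            "mtc": self.mtc,
            "signed": self.signed,
            "seed": self.seed,
            "trials": self.trials,
            "original_nodes": self.original_nodes,
            "original_edges": self.original_edges,
            "original_type": self.original_type,
            "nodes": [str(n) for n in self.backbone.nodes],
            "edges": [
                [str(self.backbone.nodes[u]), str(self.backbone.nodes[v])]
                for u, v in self.backbone.edges
            ],
            "signs": None
            if self.backbone.signs is None
            else [int(s) for s in self.backbone.signs],
            "edges_removed_pct": self.edges_removed_pct,
            "narrative": self.narrative,
        }
        return d

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "BackboneResult":
        nodes = list(d["nodes"])
        index = {n: i for i, n in enumerate(nodes)}
        edges = sorted(tuple(sorted((index[a], index[b]))) for a, b in d["edges"])
        signs = None if d.get("signs") is None else np.asarray(d["signs"], dtype=int)
        net = Network(nodes, edges, signs=signs)
        return cls(
            backbone=net,
            model=d["model"],
            original_nodes=d["original_nodes"],
            original_edges=d["original_edges"],
            original_type=d["original_type"],
            alpha=d.get("alpha"),
            parameter=d.get("parameter"),
            mtc=d.get("mtc", "none"),
            signed=bool(d.get("signed", False)),
            seed=d.get("seed"),
            trials=d.get("trials"),
        )


def _type_phrase(result: BackboneResult) -> str:
    if result.original_type == "bipartite":
        m = result.meta.get("n_agents", result.original_nodes)
        n = result.meta.get("n_artifacts", "?")
        return (
            "the unweighted backbone of the weighted projection of a bipartite "
            f"network containing {m} agents and {n} artifacts"
        )
    kind = "a weighted" if result.original_type == "weighted" else "an unweighted"
    return (
        f"the unweighted backbone of {kind} network containing "
        f"{result.original_nodes} nodes"
    )


def render_narrative(result: BackboneResult) -> str:
    """Deterministic narrative text describing a backbone extraction."""
    name, cite = CITATIONS.get(result.model, (result.model, None))
    cited = f"{name} ({cite})" if cite else name
    pct = format_pct(result.edges_removed_pct)
    head = (
        f"The {PACKAGE_NAME} package (v{PACKAGE_VERSION}) was used to extract "
        f"{_type_phrase(result)}. "
    )
    if result.model in STATISTICAL_MODELS:
        tail_kind = "two-tailed" if result.signed else "one-tailed"
        body = (
            f"An edge was retained in the backbone if its weight was statistically "
            f"significant (alpha = {result.alpha:g}, {tail_kind}"
        )
        if result.mtc != "none":
            body += f", {result.mtc} multiple-test correction"
        body += f") using {cited}, which reduced the number of edges by {pct}%."
    elif result.model == "global":
        body = (
            f"An edge was retained in the backbone if its weight exceeded a global "
            f"threshold of {result.parameter:g}, which removed {pct}% of the edges."
        )
    else:
        body = (
            f"Edges were selected for retention in the backbone using {cited} "
            f"(filtering parameter = {result.parameter:g}), which removed "
            f"{pct}% of the edges."
        )
    return head + body
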
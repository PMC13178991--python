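"""Auto-detecting wrapper around the three model families."""

from __future__ import annotations

from .graph_core import BipartiteIncidence, Network, detect_network_type
from .projection_models import backbone_from_projection
from .result import BackboneResult, render_narrative
from .unweighted_models import backbone_from_unweighted
from .weighted_models import backbone_from_weighted

__all__ = ["backbone", "render_narrative", "BackboneResult"]


def backbone(net, alpha=None, parameter=None, **kwargs) -> BackboneResult:
    """Detect the input type and extract a backbone with default models.

    * bipartite incidence → :func:`backbone_from_projection` (sdsm, α=0.05)
    * weighted network    → :func:`backbone_from_weighted` (disparity, α=0.05)
    * unweighted network  → :func:`backbone_from_unweighted` (lspar, 0.5)

    Extra keyword arguments are forwarded to the dispatched function.
    """
    kind = detect_network_type(net)
    if kind == "bipartite":
        if parameter is not None:
            raise ValueError("bipartite inputs use statistical models: pass alpha=")
        return backbone_from_projection(net, alpha=0.05 if alpha is None else alpha, **kwargs)
    if kind == "weighted":
        model = kwargs.pop("model", "disparity")
        if model == "global":
            return backbone_from_weighted(net, model="global", parameter=parameter, **kwargs)
        if parameter is not None:
            raise ValueError("statistical weighted models use alpha=, not parameter=")
        return backbone_from_weighted(net, model=model, alpha=alpha, **kwargs)
    if alpha is not None:
        if kwargs.get("model") == "hyper" and parameter is None:
            parameter = alpha  # the hyper preset's threshold is a significance level
        else:
            raise ValueError("unweighted structural models use parameter=, not alpha=")
    return backbone_from_unweighted(
        net, parameter=0.5 if parameter is None else parameter, **kwargs
    )
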
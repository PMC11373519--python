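"""Deterministic summary statistics for a gARG."""

from __future__ import annotations

from typing import Dict, Iterable, Optional

from .ancestry import coalescence_span
from .graph import GraphARG, NodeId, breakpoints
from .trees import distinct_tree_count

__all__ = ["graph_stats"]


def _quantiles(values, qs=(0.0, 0.25, 0.5, 0.75, 1.0)) -> Dict[str, float]:
    values = sorted(values)
    out = {}
    for q in qs:
        if not values:
            out[f"q{int(q * 100)}"] = 0.0
            continue
        idx = min(len(values) - 1, int(round(q * (len(values) - 1))))
        out[f"q{int(q * 100)}"] = values[idx]
    return out


def graph_stats(
    g: GraphARG, samples: Optional[Iterable[NodeId]] = None
) -> Dict[str, object]:
    """Node/edge/breakpoint/tree counts plus coalescence-span quantiles.

    ``breakpoint_count`` counts interior breakpoints (region boundaries
    strictly inside the genome); ``region_count`` the genomic regions they
    delimit.
    """
    bps = breakpoints(g)
    samples = list(samples) if samples is not None else sorted(
        g.samples, key=lambda s: str(s)
    )
    out: Dict[str, object] = {
        "sequence_length": g.sequence_length,
        "node_count": len(g.nodes),
        "edge_count": len(g.edges),
        "sample_count": len(samples),
        "breakpoint_count": max(0, len(bps) - 2),
        "region_count": max(0, len(bps) - 1),
        "distinct_tree_count": distinct_tree_count(g) if g.nodes else 0,
    }
    if samples:
        spans = coalescence_span(g, samples)
        out["coalescence_span"] = _quantiles(spans.values())
    return out
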
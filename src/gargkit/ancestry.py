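"""Ancestral material, sample resolution, and the simplification ladder.

The ancestral material of a sample set is the collection of genomic
intervals through which at least one sample inherits.  It is computed by
Hudson-style segment propagation: starting from one [0, L) segment per
sample, segments travel pastwards along inheritance edges, splitting at
interval boundaries.  Where two or more child edges of a node carry
overlapping segments there is a local coalescence and the segments merge,
summing their sample counts.  A segment whose count reaches the full sample
size has fully coalesced: it is recorded at the node where this happens but
is not propagated further, so ancestors above the position-wise MRCA (such
as a grand MRCA reached after every region has coalesced) carry no
ancestral material and are pruned by resolution.

Resolution ("simplify" level a) intersects every edge annotation with the
open ancestral material of its child.  The higher rungs of the ladder
optionally remove singly connected pass-through chains, remove nodes that
are unary everywhere, and finally rewrite edges to bypass nodes in every
local tree in which they are unary ("fully simplified").  All levels leave
the samples' local genealogies - in particular every pairwise MRCA at every
position - unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

from .graph import (
    GenomeNode,
    GraphARG,
    InheritanceEdge,
    NodeId,
    _id_key,
    processing_order,
    validate,
)
from .intervals import Interval, IntervalSet

__all__ = [
    "AncestrySegment",
    "SimplifyOptions",
    "SimplifyResult",
    "ancestral_material",
    "ancestry_segments",
    "resolve",
    "simplify",
    "coalescence_span",
    "coalescence_intervals",
]


@dataclass(frozen=True)
class AncestrySegment:
    """A run of ancestral material at a node: where, and for how many samples."""

    interval: Interval
    node: NodeId
    sample_count: int


# ---------------------------------------------------------------------------
# The propagation engine


def _check_samples(g: GraphARG, samples: Optional[Iterable[NodeId]]) -> List[NodeId]:
    if samples is None:
        samples = g.samples
    samples = sorted(set(samples), key=_id_key)
    known = {n.id for n in g.nodes}
    missing = [s for s in samples if s not in known]
    if missing:
        raise ValueError(f"sample ids not in graph: {missing}")
    if not samples:
        raise ValueError("empty sample set")
    return samples


def _sweep(contribs: List[Tuple[float, float, int]]):
    """Split contributions into elementary intervals.

    Yields (left, right, members) where members indexes into ``contribs``.
    """
    bounds = sorted({b for seg in contribs for b in (seg[0], seg[1])})
    for left, right in zip(bounds, bounds[1:]):
        members = [
            i for i, seg in enumerate(contribs) if seg[0] <= left and right <= seg[1]
        ]
        if members:
            yield left, right, members


def _coalesce_adjacent(segs):
    """Merge adjacent segments with identical payload (everything past l, r)."""
    out = []
    for seg in segs:
        if out and out[-1][1] == seg[0] and out[-1][2:] == seg[2:]:
            out[-1] = (out[-1][0], seg[1], *seg[2:])
        else:
            out.append(tuple(seg))
    return out


def _propagate(g: GraphARG, samples: List[NodeId]):
    """Run segment propagation.

    Returns (material, coalescent, open_material), each a dict keyed by node
    id: material and open_material map to lists of (left, right, count),
    coalescent to lists of (left, right) where >= 2 child edges carry
    material.
    """
    n = len(samples)
    sample_set = set(samples)
    order = processing_order(g)
    by_child = g.edges_by_child()
    incoming: Dict[NodeId, List[Tuple[float, float, int]]] = {}
    material: Dict[NodeId, List[Tuple[float, float, int]]] = {}
    coalescent: Dict[NodeId, List[Tuple[float, float]]] = {}
    open_mat: Dict[NodeId, List[Tuple[float, float, int]]] = {}
    for u in order:
        contribs = incoming.pop(u, [])
        if u in sample_set:
            contribs = contribs + [(0.0, g.sequence_length, 1)]
        if not contribs:
            material[u] = []
            coalescent[u] = []
            open_mat[u] = []
            continue
        mat: List[Tuple[float, float, int]] = []
        coal: List[Tuple[float, float]] = []
        for left, right, members in _sweep(contribs):
            count = sum(contribs[i][2] for i in members)
            mat.append((left, right, count))
            if len(members) >= 2:
                coal.append((left, right))
        mat = _coalesce_adjacent(mat)
        material[u] = mat
        coalescent[u] = [(iv.left, iv.right) for iv in IntervalSet(coal)]
        open_segs = _coalesce_adjacent([s for s in mat if s[2] < n])
        open_mat[u] = open_segs
        for e in by_child.get(u, []):
            for iv in e.inherits:
                for l, r, c in open_segs:
                    ol, orr = max(l, iv.left), min(r, iv.right)
                    if ol < orr:
                        incoming.setdefault(e.parent, []).append((ol, orr, c))
    return material, coalescent, open_mat


def _to_intervalset(segs) -> IntervalSet:
    return IntervalSet([(s[0], s[1]) for s in segs])


def ancestral_material(
    g: GraphARG, samples: Optional[Iterable[NodeId]] = None
) -> Dict[NodeId, IntervalSet]:
    """Per-node intervals through which at least one sample inherits.

    Segments that have fully coalesced are recorded at the node where the
    final merge happens and not beyond it.
    """
    samples = _check_samples(g, samples)
    material, _, _ = _propagate(g, samples)
    return {u: _to_intervalset(segs) for u, segs in material.items()}


def ancestry_segments(
    g: GraphARG, samples: Optional[Iterable[NodeId]] = None
) -> Dict[NodeId, List[AncestrySegment]]:
    """As :func:`ancestral_material`, with per-segment sample counts."""
    samples = _check_samples(g, samples)
    material, _, _ = _propagate(g, samples)
    return {
        u: [AncestrySegment(Interval(l, r), u, c) for l, r, c in segs]
        for u, segs in material.items()
    }


def coalescence_intervals(
    g: GraphARG, samples: Optional[Iterable[NodeId]] = None
) -> Dict[NodeId, IntervalSet]:
    """Per-node positions where >= 2 distinct child edges carry ancestral material."""
    samples = _check_samples(g, samples)
    _, coalescent, _ = _propagate(g, samples)
    return {u: IntervalSet(pairs) for u, pairs in coalescent.items()}


def coalescence_span(
    g: GraphARG, samples: Optional[Iterable[NodeId]] = None
) -> Dict[NodeId, float]:
    """Fraction of the genome (in [0, 1]) over which each node is locally
    coalescent."""
    spans = coalescence_intervals(g, samples)
    return {u: ivs.span / g.sequence_length for u, ivs in spans.items()}


# ---------------------------------------------------------------------------
# Resolution


def resolve(g: GraphARG, samples: Optional[Iterable[NodeId]] = None) -> GraphARG:
    """Sample-resolve: strip nonancestral material from every edge.

    Each edge's interval set is intersected with the open ancestral material
    of its child; edges left empty are dropped, and nodes left with no
    incident edges (and not samples) are removed.  Local trees restricted to
    the samples are unchanged at every position.  Idempotent.
    """
    samples = _check_samples(g, samples)
    _, _, open_mat = _propagate(g, samples)
    open_sets = {u: _to_intervalset(segs) for u, segs in open_mat.items()}
    new_edges = []
    for e in g.edges:
        trimmed = e.inherits.intersect(open_sets.get(e.child, IntervalSet()))
        if trimmed:
            new_edges.append(InheritanceEdge(e.child, e.parent, trimmed))
    used: Set[NodeId] = set(samples)
    for e in new_edges:
        used.add(e.child)
        used.add(e.parent)
    new_nodes = tuple(n for n in g.nodes if n.id in used)
    return GraphARG(g.sequence_length, new_nodes, new_edges, samples)


# ---------------------------------------------------------------------------
# Simplification ladder


@dataclass
class SimplifyOptions:
    """Which classes of non-coalescent structure to remove.

    Nonancestral material is always removed.  ``bypass_locally_unary``
    implies ``remove_everywhere_unary`` (a node kept nowhere it is unary is
    in particular removed when unary everywhere).
    """

    remove_singly_connected: bool = False
    remove_everywhere_unary: bool = False
    bypass_locally_unary: bool = False
    keep_recombination_passthrough: bool = False  # retain 2-parent unary nodes

    def __post_init__(self) -> None:
        if self.bypass_locally_unary:
            self.remove_everywhere_unary = True

    LEVELS = ("resolve", "prune-diamonds", "prune-unary", "full")

    @classmethod
    def from_level(cls, level: str) -> "SimplifyOptions":
        if level == "resolve":
            return cls()
        if level == "prune-diamonds":
            return cls(remove_singly_connected=True)
        if level == "prune-unary":
            return cls(remove_singly_connected=True, remove_everywhere_unary=True)
        if level == "full":
            return cls(
                remove_singly_connected=True,
                remove_everywhere_unary=True,
                bypass_locally_unary=True,
            )
        raise ValueError(f"unknown simplify level {level!r}; use one of {cls.LEVELS}")


@dataclass
class SimplifyResult:
    graph: GraphARG
    node_map: Dict[NodeId, int]
    coalescent_span: Dict[int, IntervalSet]


class _EdgeSet:
    """Mutable edge collection supporting node bypass with interval composition."""

    def __init__(self, edges: Iterable[InheritanceEdge]):
        self.by_pair: Dict[Tuple[NodeId, NodeId], IntervalSet] = {}
        for e in edges:
            self._add(e.child, e.parent, e.inherits)

    def _add(self, child: NodeId, parent: NodeId, ivs: IntervalSet) -> None:
        key = (child, parent)
        if key in self.by_pair:
            self.by_pair[key] = self.by_pair[key].union(ivs)
        else:
            self.by_pair[key] = ivs

    def child_edges(self, u: NodeId):
        return [(c, ivs) for (c, p), ivs in self.by_pair.items() if p == u]

    def parent_edges(self, u: NodeId):
        return [(p, ivs) for (c, p), ivs in self.by_pair.items() if c == u]

    def bypass(self, u: NodeId) -> None:
        """Remove u, re-attaching each child to each parent by intersection."""
        ces = self.child_edges(u)
        pes = self.parent_edges(u)
        for c, ci in ces:
            del self.by_pair[(c, u)]
        for p, pi in pes:
            del self.by_pair[(u, p)]
        for c, ci in ces:
            for p, pi in pes:
                ivs = ci.intersect(pi)
                if ivs:
                    self._add(c, p, ivs)

    def edges(self) -> List[InheritanceEdge]:
        return [
            InheritanceEdge(c, p, ivs) for (c, p), ivs in self.by_pair.items()
        ]


def _prune_pass_through(
    g: GraphARG,
    samples: List[NodeId],
    singly_connected: bool,
    everywhere_unary: bool,
    keep_recombination: bool,
) -> GraphARG:
    """Bypass non-sample nodes with no coalescent span (optionally only
    those with a single child edge and a single parent edge)."""
    spans = coalescence_intervals(g, samples)
    edges = _EdgeSet(g.edges)
    sample_set = set(samples)
    for u in processing_order(g):
        if u in sample_set:
            continue
        if spans.get(u) and spans[u].span > 0:
            continue
        ces = edges.child_edges(u)
        pes = edges.parent_edges(u)
        if not ces and not pes:
            continue
        if singly_connected and not everywhere_unary:
            if len(ces) != 1 or len(pes) != 1:
                continue
        if everywhere_unary and keep_recombination and len(pes) >= 2:
            continue
        edges.bypass(u)
    new_edges = edges.edges()
    used: Set[NodeId] = set(samples)
    for e in new_edges:
        used.add(e.child)
        used.add(e.parent)
    nodes = tuple(n for n in g.nodes if n.id in used)
    return GraphARG(g.sequence_length, nodes, new_edges, samples)


def _fully_simplify(g: GraphARG, samples: List[NodeId]) -> GraphARG:
    """Rebuild the graph keeping nodes only where they are locally coalescent.

    Segment propagation tracks, for each run of ancestral material, the
    youngest surviving node subtending it; edges are emitted only at merges,
    so every surviving non-sample node appears in a local tree only where it
    has >= 2 children there.
    """
    L = g.sequence_length
    n = len(samples)
    sample_set = set(samples)
    order = processing_order(g)
    by_child = g.edges_by_child()
    incoming: Dict[NodeId, List[Tuple[float, float, NodeId, int]]] = {}
    out_edges: Dict[Tuple[NodeId, NodeId], List[Tuple[float, float]]] = {}
    kept: Set[NodeId] = set(samples)
    for u in order:
        contribs = incoming.pop(u, [])
        if u in sample_set:
            contribs = contribs + [(0.0, L, u, 1)]
        if not contribs:
            continue
        bounds = sorted({b for seg in contribs for b in (seg[0], seg[1])})
        segs: List[Tuple[float, float, NodeId, int]] = []
        for left, right in zip(bounds, bounds[1:]):
            active = [s for s in contribs if s[0] <= left and right <= s[1]]
            if not active:
                continue
            if len(active) == 1:
                rep, count = active[0][2], active[0][3]
            else:
                kept.add(u)
                for s in active:
                    out_edges.setdefault((s[2], u), []).append((left, right))
                rep, count = u, sum(s[3] for s in active)
            if count < n:
                segs.append((left, right, rep, count))
        segs = _coalesce_adjacent(segs)
        for e in by_child.get(u, []):
            for iv in e.inherits:
                for l, r, rep, c in segs:
                    ol, orr = max(l, iv.left), min(r, iv.right)
                    if ol < orr:
                        incoming.setdefault(e.parent, []).append((ol, orr, rep, c))
    edges = [
        InheritanceEdge(c, p, IntervalSet(pairs))
        for (c, p), pairs in out_edges.items()
    ]
    nodes = tuple(n_ for n_ in g.nodes if n_.id in kept)
    return GraphARG(L, nodes, edges, samples)


def simplify(
    g: GraphARG,
    samples: Optional[Iterable[NodeId]] = None,
    opts: Optional[SimplifyOptions] = None,
) -> SimplifyResult:
    """Resolve, optionally prune non-coalescent structure, and renumber.

    Surviving nodes receive dense integer ids in processing order;
    ``node_map`` records old -> new for survivors so identity is always
    recoverable.  Sample-restricted local genealogies are invariant at every
    position, and node/edge counts are non-increasing in option strength.
    """
    opts = opts or SimplifyOptions()
    samples = _check_samples(g, samples)
    r = resolve(g, samples)
    if opts.bypass_locally_unary:
        r = _fully_simplify(r, samples)
    elif opts.remove_singly_connected or opts.remove_everywhere_unary:
        r = _prune_pass_through(
            r,
            samples,
            singly_connected=opts.remove_singly_connected,
            everywhere_unary=opts.remove_everywhere_unary,
            keep_recombination=opts.keep_recombination_passthrough,
        )
    order = [u for u in processing_order(r)]
    node_map = {u: i for i, u in enumerate(order)}
    from .graph import relabel

    renumbered = relabel(r.canonical(), node_map).canonical()
    spans = coalescence_intervals(renumbered, [node_map[s] for s in samples])
    spans = {u: ivs for u, ivs in spans.items() if ivs}
    return SimplifyResult(graph=renumbered, node_map=node_map, coalescent_span=spans)
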
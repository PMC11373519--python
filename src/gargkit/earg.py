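"""The classical event-ARG encoding and its conversion to a gARG.

An event ARG (eARG) maps the history of a sample onto typed event nodes:
sampling events at the tips, common-ancestor events where lineages merge,
and recombination events where a single lineage splits into two parent
lineages.  A recombination node carries its crossover breakpoint, and its
two out-edges must be explicitly side-labelled (left / right): a breakpoint
alone does not determine the local trees, so this implementation requires
the explicit form rather than inventing ordering rules.

The conversion to a gARG is purely mechanical and information-preserving:
every out-edge of a sample or common-ancestor node is annotated with the
whole genome [0, L); the left-side out-edge of a recombination node with
breakpoint x is annotated [0, x) and the right-side out-edge [x, L).
Resolving the result against the sample set then yields a sample-resolved
gARG (see :mod:`gargkit.ancestry`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Tuple

from .graph import (
    GenomeNode,
    GraphARG,
    InheritanceEdge,
    NodeId,
    ValidationReport,
    _id_key,
)
from .intervals import IntervalSet, point_region
from .trees import LocalForest

SAMPLE = "sample"
COMMON_ANCESTOR = "common_ancestor"
RECOMBINATION = "recombination"
KINDS = (SAMPLE, COMMON_ANCESTOR, RECOMBINATION)

LEFT = "L"
RIGHT = "R"
NO_SIDE = "-"

__all__ = [
    "EventNode",
    "EventEdge",
    "EventARG",
    "validate_earg",
    "earg_to_garg",
    "recover_earg",
    "earg_tree_at",
    "SAMPLE",
    "COMMON_ANCESTOR",
    "RECOMBINATION",
]


@dataclass(frozen=True)
class EventNode:
    id: NodeId
    kind: str
    breakpoint: Optional[float] = None  # present iff kind == recombination
    time: Optional[float] = None


@dataclass(frozen=True)
class EventEdge:
    child: NodeId
    parent: NodeId
    side: str = NO_SIDE  # L / R iff the child is a recombination node


@dataclass(frozen=True)
class EventARG:
    sequence_length: float
    nodes: Tuple[EventNode, ...]
    edges: Tuple[EventEdge, ...]
    samples: FrozenSet[NodeId]

    def __init__(
        self,
        sequence_length: float,
        nodes: Iterable[EventNode],
        edges: Iterable[EventEdge],
        samples: Iterable[NodeId] = (),
    ):
        object.__setattr__(self, "sequence_length", float(sequence_length))
        object.__setattr__(self, "nodes", tuple(nodes))
        object.__setattr__(self, "edges", tuple(edges))
        samples = frozenset(samples)
        if not samples:
            samples = frozenset(n.id for n in nodes if n.kind == SAMPLE)
        object.__setattr__(self, "samples", samples)

    def node_map(self) -> Dict[NodeId, EventNode]:
        return {n.id: n for n in self.nodes}

    def out_edges(self) -> Dict[NodeId, List[EventEdge]]:
        out: Dict[NodeId, List[EventEdge]] = {n.id: [] for n in self.nodes}
        for e in self.edges:
            out.setdefault(e.child, []).append(e)
        return out

    def in_edges(self) -> Dict[NodeId, List[EventEdge]]:
        out: Dict[NodeId, List[EventEdge]] = {n.id: [] for n in self.nodes}
        for e in self.edges:
            out.setdefault(e.parent, []).append(e)
        return out


def validate_earg(e: EventARG) -> ValidationReport:
    """Check the eARG invariants; returns an empty report iff all hold."""
    report = ValidationReport()
    nodes = {}
    for n in e.nodes:
        if n.id in nodes:
            report.add("duplicate-node-id", (n.id,))
        nodes[n.id] = n
        if n.kind not in KINDS:
            report.add("unknown-kind", (n.id,), f"kind {n.kind!r}")
        if n.kind == RECOMBINATION:
            if n.breakpoint is None:
                report.add("missing-breakpoint", (n.id,))
            elif not 0 < n.breakpoint < e.sequence_length:
                report.add(
                    "breakpoint-out-of-range",
                    (n.id,),
                    f"breakpoint {n.breakpoint} not inside (0, {e.sequence_length})",
                )
        elif n.breakpoint is not None:
            report.add("unexpected-breakpoint", (n.id,), f"on {n.kind} node")

    for edge in e.edges:
        for end in (edge.child, edge.parent):
            if end not in nodes:
                report.add("unknown-node", (end,), "edge endpoint not in node table")
    for s in sorted(e.samples, key=_id_key):
        if s not in nodes:
            report.add("unknown-sample", (s,))

    out = e.out_edges()
    inn = e.in_edges()
    rootless = []
    for n in e.nodes:
        mine_out = out.get(n.id, [])
        mine_in = inn.get(n.id, [])
        sides = [ed.side for ed in mine_out]
        if n.kind == RECOMBINATION:
            if len(mine_out) != 2:
                report.add(
                    "recombination-parents", (n.id,), f"{len(mine_out)} parents, need 2"
                )
            elif sorted(sides) != [LEFT, RIGHT]:
                report.add(
                    "side-uniqueness",
                    (n.id,),
                    f"out-edge sides {sides!r} must be one L and one R",
                )
            if len(mine_in) != 1:
                report.add(
                    "recombination-children",
                    (n.id,),
                    f"{len(mine_in)} children, a recombination splits one lineage",
                )
        else:
            for ed in mine_out:
                if ed.side != NO_SIDE:
                    report.add(
                        "side-on-non-recombination",
                        (n.id, ed.parent),
                        f"side {ed.side!r} on {n.kind} out-edge",
                    )
            if len(mine_out) > 1:
                report.add(
                    "multiple-parents", (n.id,), f"{n.kind} node with {len(mine_out)} parents"
                )
            if n.kind == COMMON_ANCESTOR:
                if len(mine_in) < 2:
                    report.add(
                        "common-ancestor-children",
                        (n.id,),
                        f"{len(mine_in)} children, need at least 2",
                    )
                if not mine_out:
                    rootless.append(n.id)
            elif n.kind == SAMPLE and mine_in:
                report.add("sample-with-children", (n.id,))
        tc = n.time
        for ed in mine_out:
            p = nodes.get(ed.parent)
            if p is not None and tc is not None and p.time is not None and not tc < p.time:
                report.add(
                    "time-order",
                    (n.id, ed.parent),
                    f"child time {tc} not strictly younger than parent time {p.time}",
                )
    if len(rootless) > 1:
        # Whether the grand MRCA must be unique is not pinned down; warn only.
        report.warn(
            "multiple-roots",
            tuple(sorted(rootless, key=_id_key)),
            "more than one parentless internal node",
        )
    return report


def earg_to_garg(e: EventARG) -> GraphARG:
    """Convert an eARG to the equivalent interval-annotated gARG.

    The node set and topology are duplicated; inheritance annotations follow
    the breakpoint rule described in the module docstring.  Node kind and
    breakpoint are preserved in metadata so the eARG is recoverable
    (:func:`recover_earg`).
    """
    report = validate_earg(e)
    if not report.ok:
        raise ValueError(f"invalid eARG: {report.violations[0]}")
    L = e.sequence_length
    nodes = []
    for n in e.nodes:
        meta = f"kind={n.kind}"
        if n.kind == RECOMBINATION:
            meta += f" breakpoint={n.breakpoint}"
        nodes.append(
            GenomeNode(n.id, time=n.time, is_sample=n.id in e.samples, metadata=meta)
        )
    kinds = e.node_map()
    edges = []
    for ed in e.edges:
        child = kinds[ed.child]
        if child.kind == RECOMBINATION:
            x = child.breakpoint
            iv = (0.0, x) if ed.side == LEFT else (x, L)
        else:
            iv = (0.0, L)
        edges.append(InheritanceEdge(ed.child, ed.parent, IntervalSet([iv])))
    return GraphARG(L, nodes, edges, e.samples)


def recover_earg(g: GraphARG) -> EventARG:
    """Reconstruct the eARG from a converted gARG (inverse of earg_to_garg)."""
    L = g.sequence_length
    nodes = []
    edges = []
    for n in g.nodes:
        fields = dict(
            part.split("=", 1) for part in n.metadata.split() if "=" in part
        )
        kind = fields.get("kind", SAMPLE if n.is_sample else COMMON_ANCESTOR)
        bp = float(fields["breakpoint"]) if "breakpoint" in fields else None
        nodes.append(EventNode(n.id, kind, breakpoint=bp, time=n.time))
    kinds = {n.id: n for n in nodes}
    for e in g.edges:
        child = kinds[e.child]
        if child.kind == RECOMBINATION:
            side = LEFT if e.inherits.left == 0.0 else RIGHT
        else:
            side = NO_SIDE
        edges.append(EventEdge(e.child, e.parent, side))
    return EventARG(L, nodes, edges, g.samples)


def earg_tree_at(e: EventARG, x: float) -> LocalForest:
    """Local genealogy at position x by direct pastwards traversal.

    From each sample, follow the unique pastwards path; at a recombination
    node with breakpoint b take the left parent iff x < b (a position equal
    to the breakpoint belongs to the right parent, consistent with the
    half-open convention).  Used as the conversion-correctness oracle.
    """
    if not 0 <= x < e.sequence_length:
        raise ValueError(f"position {x} outside [0, {e.sequence_length})")
    kinds = e.node_map()
    out = e.out_edges()
    parent_of: Dict[NodeId, NodeId] = {}
    covered = set()
    for s in sorted(e.samples, key=_id_key):
        u = s
        covered.add(u)
        while u not in parent_of:
            node = kinds[u]
            mine = out.get(u, [])
            if not mine:
                break
            if node.kind == RECOMBINATION:
                want = LEFT if x < node.breakpoint else RIGHT
                nxt = next(ed.parent for ed in mine if ed.side == want)
            else:
                nxt = mine[0].parent
            parent_of[u] = nxt
            covered.add(nxt)
            u = nxt
    bps = sorted(
        {0.0, e.sequence_length}
        | {n.breakpoint for n in e.nodes if n.kind == RECOMBINATION and n.breakpoint}
    )
    left, right = point_region(bps, x)
    from .intervals import Interval

    return LocalForest(
        region=Interval(left, right), parent_of=parent_of, covered_nodes=covered
    )
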
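"""The genome-ARG data model.

A genome ARG (gARG) is a directed acyclic graph whose nodes are haploid
genomes and whose edges record genetic inheritance: each edge ``(c, p, I)``
says that child genome ``c`` inherited the set of genomic intervals ``I``
from parent genome ``p``.  Interval annotations, not node types, carry the
effects of recombination, so a single encoding covers crossover, gene
conversion and multi-event transmissions.

Node times, when present, increase pastwards.  Times are optional: the
directed topology alone defines the ordering, and many inferred graphs are
undated.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Hashable, Iterable, List, Optional, Sequence, Tuple

from .intervals import Interval, IntervalSet, _fmt

NodeId = Hashable  # int in the formal definition; str labels in figure fixtures

__all__ = [
    "GenomeNode",
    "InheritanceEdge",
    "GraphARG",
    "Violation",
    "ValidationReport",
    "validate",
    "breakpoints",
    "to_dot",
]


@dataclass(frozen=True)
class GenomeNode:
    """A haploid genome: an identifier plus optional time and metadata."""

    id: NodeId
    time: Optional[float] = None
    is_sample: bool = False
    metadata: str = ""


@dataclass(frozen=True)
class InheritanceEdge:
    """Child genome ``child`` inherits the intervals ``inherits`` from ``parent``."""

    child: NodeId
    parent: NodeId
    inherits: IntervalSet

    def __post_init__(self) -> None:
        if not self.inherits:
            raise ValueError(
                f"edge {self.child}->{self.parent} carries no inheritance interval"
            )


def _id_key(node_id: NodeId) -> Tuple[int, object]:
    # Type-aware ordering so int and str identifiers can coexist.
    if isinstance(node_id, bool):
        return (2, str(node_id))
    if isinstance(node_id, (int, float)):
        return (0, node_id)
    return (1, str(node_id))


@dataclass(frozen=True)
class GraphARG:
    """A gARG: sequence length, node table, edge table and sample set."""

    sequence_length: float
    nodes: Tuple[GenomeNode, ...]
    edges: Tuple[InheritanceEdge, ...]
    samples: FrozenSet[NodeId]

    def __init__(
        self,
        sequence_length: float,
        nodes: Iterable[GenomeNode],
        edges: Iterable[InheritanceEdge],
        samples: Iterable[NodeId] = (),
    ):
        if not sequence_length > 0:
            raise ValueError("sequence_length must be positive")
        object.__setattr__(self, "sequence_length", float(sequence_length))
        object.__setattr__(self, "nodes", tuple(nodes))
        object.__setattr__(self, "edges", tuple(edges))
        object.__setattr__(self, "samples", frozenset(samples))

    # -- basic indexes -------------------------------------------------

    @property
    def node_ids(self) -> Tuple[NodeId, ...]:
        return tuple(n.id for n in self.nodes)

    def node(self, node_id: NodeId) -> GenomeNode:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(node_id)

    def node_map(self) -> Dict[NodeId, GenomeNode]:
        return {n.id: n for n in self.nodes}

    def edges_by_child(self) -> Dict[NodeId, List[InheritanceEdge]]:
        out: Dict[NodeId, List[InheritanceEdge]] = {}
        for e in self.edges:
            out.setdefault(e.child, []).append(e)
        return out

    def edges_by_parent(self) -> Dict[NodeId, List[InheritanceEdge]]:
        out: Dict[NodeId, List[InheritanceEdge]] = {}
        for e in self.edges:
            out.setdefault(e.parent, []).append(e)
        return out

    def canonical(self) -> "GraphARG":
        """Deterministically ordered copy (the serialization order)."""
        times = {n.id: n.time for n in self.nodes}

        def edge_key(e: InheritanceEdge):
            t = times.get(e.child)
            return (
                (0, t) if t is not None else (1, 0),
                _id_key(e.child),
                _id_key(e.parent),
                e.inherits.left,
            )

        nodes = tuple(sorted(self.nodes, key=lambda n: _id_key(n.id)))
        edges = tuple(sorted(self.edges, key=edge_key))
        return GraphARG(self.sequence_length, nodes, edges, self.samples)


# ---------------------------------------------------------------------------
# Validation


@dataclass(frozen=True)
class Violation:
    """One broken invariant: its kind plus the node/edge ids involved."""

    kind: str
    ids: Tuple[NodeId, ...]
    detail: str = ""

    def __str__(self) -> str:
        ids = ", ".join(str(i) for i in self.ids)
        return f"{self.kind} [{ids}]" + (f": {self.detail}" if self.detail else "")


@dataclass
class ValidationReport:
    violations: List[Violation] = field(default_factory=list)
    warnings: List[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, kind: str, ids: Sequence[NodeId], detail: str = "") -> None:
        self.violations.append(Violation(kind, tuple(ids), detail))

    def warn(self, kind: str, ids: Sequence[NodeId], detail: str = "") -> None:
        self.warnings.append(Violation(kind, tuple(ids), detail))

    def __str__(self) -> str:
        if self.ok and not self.warnings:
            return "OK"
        buf = io.StringIO()
        for v in self.violations:
            buf.write(f"violation: {v}\n")
        for w in self.warnings:
            buf.write(f"warning: {w}\n")
        return buf.getvalue().rstrip("\n")


def topological_order(g: GraphARG) -> Optional[List[NodeId]]:
    """Children-before-parents order, or None if the graph has a cycle.

    Deterministic: ties are broken by node id.  When every node is dated the
    order agrees with sorting by (time, id) on valid graphs.
    """
    ids = [n.id for n in g.nodes]
    known = set(ids)
    out_deg: Dict[NodeId, int] = {i: 0 for i in ids}  # unprocessed children
    parents_of: Dict[NodeId, List[NodeId]] = {i: [] for i in ids}
    for e in g.edges:
        if e.child not in known or e.parent not in known:
            continue
        out_deg[e.parent] += 1
        parents_of[e.child].append(e.parent)
    ready = sorted((i for i in ids if out_deg[i] == 0), key=_id_key)
    order: List[NodeId] = []
    import heapq

    heap = [(_id_key(i), i) for i in ready]
    heapq.heapify(heap)
    while heap:
        _, u = heapq.heappop(heap)
        order.append(u)
        for p in parents_of[u]:
            out_deg[p] -= 1
            if out_deg[p] == 0:
                heapq.heappush(heap, (_id_key(p), p))
    if len(order) != len(ids):
        return None
    return order


def processing_order(g: GraphARG) -> List[NodeId]:
    """Node order used by segment propagation: by time when fully dated,
    otherwise topological; ties broken by id."""
    if g.nodes and all(n.time is not None for n in g.nodes):
        return [
            n.id for n in sorted(g.nodes, key=lambda n: (n.time, _id_key(n.id)))
        ]
    order = topological_order(g)
    if order is None:
        raise ValueError("graph contains a cycle; cannot order nodes")
    return order


def validate(g: GraphARG) -> ValidationReport:
    """Check every gARG invariant; malformed input yields violations, not errors."""
    report = ValidationReport()
    seen: set = set()
    for n in g.nodes:
        if n.id in seen:
            report.add("duplicate-node-id", (n.id,))
        seen.add(n.id)
    for s in sorted(g.samples, key=_id_key):
        if s not in seen:
            report.add("unknown-sample", (s,), "sample id not in node table")

    times = {n.id: n.time for n in g.nodes}
    for e in g.edges:
        if e.child == e.parent:
            report.add("self-edge", (e.child,))
        for end, role in ((e.child, "child"), (e.parent, "parent")):
            if end not in seen:
                report.add("unknown-node", (end,), f"edge {role} not in node table")
        if e.inherits.left < 0 or e.inherits.right > g.sequence_length:
            report.add(
                "interval-out-of-bounds",
                (e.child, e.parent),
                f"{e.inherits} outside [0, {_fmt(g.sequence_length)})",
            )
        tc, tp = times.get(e.child), times.get(e.parent)
        if tc is not None and tp is not None and not tc < tp:
            report.add(
                "time-order",
                (e.child, e.parent),
                f"child time {tc} not strictly younger than parent time {tp}",
            )

    if topological_order(g) is None:
        in_cycle = _cycle_members(g)
        report.add("cycle", tuple(sorted(in_cycle, key=_id_key)))

    # Per-child functional inheritance: at any position at most one parent.
    for child, edges in sorted(g.edges_by_child().items(), key=lambda kv: _id_key(kv[0])):
        pieces = []
        for e in edges:
            for iv in e.inherits:
                pieces.append((iv.left, iv.right, e.parent))
        pieces.sort(key=lambda t: (t[0], t[1]))
        for (l1, r1, p1), (l2, r2, p2) in zip(pieces, pieces[1:]):
            if l2 < r1:
                report.add(
                    "multiple-parents-at-position",
                    (child, p1, p2),
                    f"child {child} has two parents over "
                    f"[{_fmt(l2)}, {_fmt(min(r1, r2))})",
                )
    return report


def _cycle_members(g: GraphARG) -> set:
    ids = {n.id for n in g.nodes}
    out_deg = {i: 0 for i in ids}
    parents_of: Dict[NodeId, List[NodeId]] = {i: [] for i in ids}
    for e in g.edges:
        if e.child in ids and e.parent in ids:
            out_deg[e.parent] += 1
            parents_of[e.child].append(e.parent)
    ready = [i for i in ids if out_deg[i] == 0]
    remaining = set(ids)
    while ready:
        u = ready.pop()
        remaining.discard(u)
        for p in parents_of[u]:
            out_deg[p] -= 1
            if out_deg[p] == 0:
                ready.append(p)
    return remaining


def breakpoints(g: GraphARG) -> Tuple[float, ...]:
    """Sorted union of {0, L} with every interval endpoint on any edge.

    Consecutive pairs delimit the regions within which the child-to-parent
    mapping is constant.
    """
    pts = {0.0, g.sequence_length}
    for e in g.edges:
        pts.update(e.inherits.endpoints())
    return tuple(sorted(p for p in pts if 0.0 <= p <= g.sequence_length))


def to_dot(g: GraphARG) -> str:
    """GraphViz DOT rendering: node label = id, edge label = interval set."""
    lines = ["digraph gARG {", "  rankdir=BT;"]
    for n in sorted(g.nodes, key=lambda n: _id_key(n.id)):
        shape = "doublecircle" if n.id in g.samples else "circle"
        lines.append(f'  "{n.id}" [shape={shape}];')
    for e in g.canonical().edges:
        lines.append(f'  "{e.child}" -> "{e.parent}" [label="{e.inherits}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def relabel(g: GraphARG, mapping: Dict[NodeId, NodeId]) -> GraphARG:
    """Copy of ``g`` with node ids rewritten through ``mapping``."""
    nodes = tuple(replace(n, id=mapping[n.id]) for n in g.nodes)
    edges = tuple(
        InheritanceEdge(mapping[e.child], mapping[e.parent], e.inherits)
        for e in g.edges
    )
    samples = frozenset(mapping[s] for s in g.samples)
    return GraphARG(g.sequence_length, nodes, edges, samples)
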
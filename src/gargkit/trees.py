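"""Recovery of the local (marginal) trees along the genome.

Between two consecutive breakpoints every genome inherits each position
from the same parent, so the child-to-parent mapping restricted to that
region is a forest: the genealogy of that stretch of genome.  The sweep in
:func:`trees` recovers the whole sequence of local forests with edge
insertions and removals at breakpoints; :func:`tree_at` reconstructs a
single region independently and serves as the oracle for the sweep.

Regions where the samples have not fully coalesced yield several local
roots; no virtual super-root is invented.  Unary suppression reduces a
forest to the conventional form in which only nodes that are locally
coalescent (or samples) appear.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

from .graph import GraphARG, NodeId, _id_key, breakpoints
from .intervals import Interval, point_region

__all__ = [
    "LocalForest",
    "tree_at",
    "trees",
    "distinct_tree_count",
    "to_newick",
    "pairwise_mrca",
]


@dataclass(frozen=True)
class LocalForest:
    """The genealogy over one genomic region.

    ``parent_of`` maps each node to its unique local parent; nodes absent
    from the mapping are local roots.  ``covered_nodes`` are the nodes
    present in this region (incident to a local edge, or samples).
    """

    region: Interval
    parent_of: Dict[NodeId, NodeId]
    covered_nodes: FrozenSet[NodeId]

    def __init__(
        self,
        region: Interval,
        parent_of: Dict[NodeId, NodeId],
        covered_nodes: Iterable[NodeId],
    ):
        object.__setattr__(self, "region", region)
        object.__setattr__(self, "parent_of", dict(parent_of))
        object.__setattr__(self, "covered_nodes", frozenset(covered_nodes))

    def children_of(self) -> Dict[NodeId, List[NodeId]]:
        out: Dict[NodeId, List[NodeId]] = {}
        for c, p in self.parent_of.items():
            out.setdefault(p, []).append(c)
        for p in out:
            out[p].sort(key=_id_key)
        return out

    def roots(self) -> Tuple[NodeId, ...]:
        rs = [u for u in self.covered_nodes if u not in self.parent_of]
        return tuple(sorted(rs, key=_id_key))

    def path_to_root(self, u: NodeId) -> List[NodeId]:
        path = [u]
        seen = {u}
        while path[-1] in self.parent_of:
            nxt = self.parent_of[path[-1]]
            if nxt in seen:
                raise ValueError(f"cycle in local forest at {nxt}")
            path.append(nxt)
            seen.add(nxt)
        return path

    def same_topology(self, other: "LocalForest") -> bool:
        """Identity of the child-to-parent mapping (shared node identity)."""
        return self.parent_of == other.parent_of

    def restrict_to_ancestry(self, samples: Iterable[NodeId]) -> "LocalForest":
        """Keep only nodes on a path from one of ``samples`` to its local root."""
        keep: Set[NodeId] = set()
        for s in samples:
            if s in self.covered_nodes:
                keep.update(self.path_to_root(s))
        parent_of = {
            c: p for c, p in self.parent_of.items() if c in keep and p in keep
        }
        return LocalForest(self.region, parent_of, keep)


def _forest_from_active(
    g: GraphARG, region: Interval, active: Dict[NodeId, NodeId]
) -> LocalForest:
    covered = set(g.samples)
    for c, p in active.items():
        covered.add(c)
        covered.add(p)
    return LocalForest(region, dict(active), covered)


def _suppress_unary(forest: LocalForest, samples: FrozenSet[NodeId]) -> LocalForest:
    """Conventional form: keep samples and locally-coalescent nodes only.

    A node survives iff it is a sample or at least two of its local children
    subtend a sample; surviving non-roots re-attach to their nearest
    surviving ancestor.  Sample nodes are never suppressed, even when
    locally unary.
    """
    children = forest.children_of()
    subtends: Dict[NodeId, bool] = {}

    def has_sample(u: NodeId) -> bool:
        if u in subtends:
            return subtends[u]
        val = u in samples or any(has_sample(c) for c in children.get(u, ()))
        subtends[u] = val
        return val

    keep: Set[NodeId] = set()
    for u in forest.covered_nodes:
        if u in samples:
            keep.add(u)
        elif sum(1 for c in children.get(u, ()) if has_sample(c)) >= 2:
            keep.add(u)
    parent_of: Dict[NodeId, NodeId] = {}
    for u in keep:
        p = forest.parent_of.get(u)
        while p is not None and p not in keep:
            p = forest.parent_of.get(p)
        if p is not None:
            parent_of[u] = p
    return LocalForest(forest.region, parent_of, keep)


def tree_at(g: GraphARG, x: float, suppress_unary: bool = False) -> LocalForest:
    """The local forest at position x, reconstructed independently."""
    if not 0 <= x < g.sequence_length:
        raise ValueError(f"position {x} outside [0, {g.sequence_length})")
    active: Dict[NodeId, NodeId] = {}
    for e in g.edges:
        if x in e.inherits:
            active[e.child] = e.parent
    left, right = point_region(breakpoints(g), x)
    forest = _forest_from_active(g, Interval(left, right), active)
    if suppress_unary:
        forest = _suppress_unary(forest, g.samples)
    return forest


def trees(g: GraphARG, suppress_unary: bool = False) -> List[LocalForest]:
    """All local forests, left to right, by an incremental breakpoint sweep.

    Edge pieces are inserted and removed at their interval endpoints; the
    active child-to-parent mapping is maintained between breakpoints rather
    than rebuilt per region.  The regions tile [0, L) exactly.
    """
    bps = breakpoints(g)
    starts: Dict[float, List[Tuple[NodeId, NodeId]]] = {}
    ends: Dict[float, List[NodeId]] = {}
    for e in g.edges:
        for iv in e.inherits:
            starts.setdefault(iv.left, []).append((e.child, e.parent))
            ends.setdefault(iv.right, []).append(e.child)
    active: Dict[NodeId, NodeId] = {}
    out: List[LocalForest] = []
    for left, right in zip(bps, bps[1:]):
        for child in ends.get(left, ()):
            active.pop(child, None)
        for child, parent in starts.get(left, ()):
            active[child] = parent
        forest = _forest_from_active(g, Interval(left, right), active)
        if suppress_unary:
            forest = _suppress_unary(forest, g.samples)
        out.append(forest)
    return out


def distinct_tree_count(g: GraphARG) -> int:
    """Number of maximal runs of adjacent regions with identical local trees.

    Identity compares the child-to-parent mapping after unary suppression
    (shared node identity across local trees, not label-free topology).
    """
    forests = trees(g, suppress_unary=True)
    if not forests:
        return 0
    count = 1
    for prev, cur in zip(forests, forests[1:]):
        if not cur.same_topology(prev):
            count += 1
    return count


def _newick_node(u: NodeId, children: Dict[NodeId, List[NodeId]]) -> str:
    kids = children.get(u, [])
    if not kids:
        return str(u)
    inner = ",".join(_newick_node(c, children) for c in kids)
    return f"({inner}){u}"


def to_newick(f: LocalForest) -> str:
    """One Newick string per local root, internal labels included."""
    children = f.children_of()
    lines = [f"{_newick_node(r, children)};" for r in f.roots()]
    return "\n".join(lines)


def pairwise_mrca(
    forest: LocalForest, a: NodeId, b: NodeId
) -> Optional[NodeId]:
    """The most recent common ancestor of a and b in a local forest, if any."""
    if a not in forest.covered_nodes or b not in forest.covered_nodes:
        return None
    path_a = forest.path_to_root(a)
    on_a = set(path_a)
    u = b
    while u not in on_a:
        if u not in forest.parent_of:
            return None
        u = forest.parent_of[u]
    return u
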
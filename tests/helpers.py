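"""Independent brute-force oracles used to check the library.

Everything here works position by position, by scanning raw edge tables and
climbing parent chains, deliberately sharing no code with the package's
segment-propagation engine or breakpoint sweep.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Optional, Set, Tuple

from gargkit import GraphARG


def local_parent(g: GraphARG, u, x) -> Optional[object]:
    """The unique parent of u at position x by scanning the edge table."""
    hits = [e.parent for e in g.edges if e.child == u and x in e.inherits]
    assert len(hits) <= 1, f"node {u} has {len(hits)} parents at {x}"
    return hits[0] if hits else None


def climb_path(g: GraphARG, s, x) -> List[object]:
    """The pastwards path of s at position x, sample first."""
    path = [s]
    seen = {s}
    while True:
        p = local_parent(g, path[-1], x)
        if p is None:
            return path
        assert p not in seen, "cycle while climbing"
        path.append(p)
        seen.add(p)


def truncated_forest(g: GraphARG, samples, x) -> Dict[object, object]:
    """Sample-restricted genealogy at x as a child -> parent mapping.

    Paths are truncated at the first node shared by all sample paths (the
    position-wise MRCA of the whole sample set); lineages above it are not
    part of the samples' genealogy at x.
    """
    paths = [climb_path(g, s, x) for s in samples]
    common = set(paths[0])
    for p in paths[1:]:
        common &= set(p)
    mrca = None
    for node in paths[0]:
        if node in common:
            mrca = node
            break
    parent_of: Dict[object, object] = {}
    for path in paths:
        if mrca is not None:
            path = path[: path.index(mrca) + 1]
        for child, parent in zip(path, path[1:]):
            parent_of[child] = parent
    return parent_of


def ancestral_nodes_at(g: GraphARG, samples, x) -> Set[object]:
    """All nodes carrying material ancestral to ``samples`` at position x."""
    paths = [climb_path(g, s, x) for s in samples]
    common = set(paths[0])
    for p in paths[1:]:
        common &= set(p)
    out: Set[object] = set()
    for path in paths:
        cut = len(path)
        for i, node in enumerate(path):
            if node in common:
                cut = i + 1
                break
        out.update(path[:cut])
    return out


def mrca_at(g: GraphARG, a, b, x):
    """MRCA of samples a and b at position x by path comparison."""
    pa = climb_path(g, a, x)
    pb = set(climb_path(g, b, x))
    for node in pa:
        if node in pb:
            return node
    return None


def mrca_table(g: GraphARG, samples, positions):
    """(position, a, b) -> MRCA id for every sample pair and position."""
    out = {}
    for x in positions:
        for a, b in itertools.combinations(samples, 2):
            out[(x, a, b)] = mrca_at(g, a, b, x)
    return out


def region_midpoints(g: GraphARG) -> List[float]:
    from gargkit import breakpoints

    bps = breakpoints(g)
    return [(l + r) / 2 for l, r in zip(bps, bps[1:])]


def brute_force_breakpoints(g: GraphARG) -> Tuple[float, ...]:
    pts = {0.0, g.sequence_length}
    for e in g.edges:
        for iv in e.inherits:
            pts.add(iv.left)
            pts.add(iv.right)
    return tuple(sorted(pts))
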
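"""Worked-example graphs used throughout the tests and documentation.

Three small hand-encoded graphs, frozen as packaged TSV data, plus a
pinned-seed Wright-Fisher graph:

* :func:`fig1_garg` - a gARG embedded in a highly inbred pedigree of 8
  diploid individuals (16 genomes ``A``-``P``, L = 10).  The four current-
  generation genomes ``A``-``D`` are the samples.  ``A`` and ``C`` are
  recombinant products of the parental genomes ``E`` and ``F`` (crossovers
  at positions 2 and 7), ``B`` comes unrecombined from ``G`` and ``D`` from
  ``H``; deeper generations funnel all ancestry to a common ancestor in
  ``N``.  In the region [2,7) the samples' ancestral material occupies only
  ``F``, ``G`` and ``H`` - ``A`` and ``C`` have already coalesced in ``F``
  and ``E`` carries nonancestral material there.

* :func:`fig2_earg` - the minimal classical event ARG: samples ``A, B, C``,
  one recombination node ``D`` (breakpoint 5 on a length-10 genome, left
  parent ``E``, right parent ``F``) and common-ancestor nodes ``E``, ``F``
  and root ``G``.

* :func:`fig3_earg` - a Wiuf-Hein-style event history of three samples on a
  length-7 genome with six recombination events (breakpoints 2, 4 and 5).
  The recombination at position 5 (node ``G``) falls entirely inside
  nonancestral material, so resolution removes its right-parent edge
  ``G -> J``; every genomic segment fully coalesces in ``K`` ([0,2)) or
  ``P`` ([2,7)), so the grand MRCA ``Q`` disappears as well.

* :func:`fig5a_wf_garg` - a small prospective diploid Wright-Fisher gARG
  regenerated from a pinned seed, in the style used to illustrate the
  simplification ladder.
"""

from __future__ import annotations

from pathlib import Path

from .earg import (
    COMMON_ANCESTOR,
    LEFT,
    NO_SIDE,
    RECOMBINATION,
    RIGHT,
    SAMPLE,
    EventARG,
    EventEdge,
    EventNode,
)
from .graph import GenomeNode, GraphARG, InheritanceEdge
from .intervals import IntervalSet
from .simulate import WFParams, sim_wf
from .tableio import read_earg, read_garg

__all__ = ["fig1_garg", "fig2_earg", "fig3_earg", "fig5a_wf_garg"]

_DATA = Path(__file__).parent / "data"

# Pinned parameters for the Wright-Fisher illustration graph: small enough
# to draw, large enough to contain diamonds and everywhere-unary nodes.
FIG5A_PARAMS = WFParams(
    population_size=5,
    generations=6,
    sequence_length=10.0,
    crossover_rate=1.0,
    seed=5,
)


def fig1_garg() -> GraphARG:
    """The pedigree-embedded gARG (16 genomes A-P, L = 10)."""
    return read_garg(_DATA / "fig1.nodes.tsv", _DATA / "fig1.edges.tsv")


def fig2_earg() -> EventARG:
    """The minimal classical eARG (samples A-C, recombination D, CAs E-G)."""
    return read_earg(_DATA / "fig2.enodes.tsv", _DATA / "fig2.eedges.tsv")


def fig3_earg() -> EventARG:
    """The Wiuf-Hein-style eARG (17 nodes A-Q, L = 7)."""
    return read_earg(_DATA / "fig3.enodes.tsv", _DATA / "fig3.eedges.tsv")


def fig5a_wf_garg() -> GraphARG:
    """Prospective Wright-Fisher gARG regenerated from a pinned seed."""
    return sim_wf(FIG5A_PARAMS)


# ---------------------------------------------------------------------------
# Hand-encoded sources of the frozen data files.  The packaged TSVs are the
# canonical serialization of these tables; a regression test keeps them in
# sync.


def build_fig1_garg() -> GraphARG:
    L = 10.0

    def node(nid, time, sample=False, ind=""):
        return GenomeNode(nid, time=time, is_sample=sample, metadata=ind)

    nodes = [
        # current generation: individuals d1 = {A, B}, d2 = {C, D}
        node("A", 0.0, True, "individual=d1"),
        node("B", 0.0, True, "individual=d1"),
        node("C", 0.0, True, "individual=d2"),
        node("D", 0.0, True, "individual=d2"),
        # parents: d3 = {E, F}, d4 = {G, H}
        node("E", 1.0, ind="individual=d3"),
        node("F", 1.0, ind="individual=d3"),
        node("G", 1.0, ind="individual=d4"),
        node("H", 1.0, ind="individual=d4"),
        # grandparents: d5 = {I, J}, d6 = {K, L}
        node("I", 2.0, ind="individual=d5"),
        node("J", 2.0, ind="individual=d5"),
        node("K", 2.0, ind="individual=d6"),
        node("L", 2.0, ind="individual=d6"),
        # great-grandparents: d7 = {M, N}, d8 = {O, P}
        node("M", 3.0, ind="individual=d7"),
        node("N", 3.0, ind="individual=d7"),
        node("O", 3.0, ind="individual=d8"),
        node("P", 3.0, ind="individual=d8"),
    ]

    def edge(c, p, *pairs):
        return InheritanceEdge(c, p, IntervalSet(pairs))

    edges = [
        # A is the recombinant of E and F crossing over at position 2
        edge("A", "E", (0, 2)),
        edge("A", "F", (2, 10)),
        # B inherited directly from G without recombination
        edge("B", "G", (0, 10)),
        # C is the other recombinant of E and F, crossing over at position 7
        edge("C", "F", (0, 7)),
        edge("C", "E", (7, 10)),
        edge("D", "H", (0, 10)),
        # earlier generations transmit without recombination; all ancestry
        # funnels to the common ancestor N (K, M, O, P are nonancestral)
        edge("E", "I", (0, 10)),
        edge("F", "J", (0, 10)),
        edge("G", "J", (0, 10)),
        edge("H", "L", (0, 10)),
        edge("I", "N", (0, 10)),
        edge("J", "N", (0, 10)),
        edge("K", "N", (0, 10)),
        edge("L", "N", (0, 10)),
    ]
    return GraphARG(L, nodes, edges, samples="ABCD")


def build_fig2_earg(breakpoint: float = 5.0, L: float = 10.0) -> EventARG:
    nodes = [
        EventNode("A", SAMPLE, time=0.0),
        EventNode("B", SAMPLE, time=0.0),
        EventNode("C", SAMPLE, time=0.0),
        EventNode("D", RECOMBINATION, breakpoint=breakpoint, time=1.0),
        EventNode("E", COMMON_ANCESTOR, time=2.0),
        EventNode("F", COMMON_ANCESTOR, time=3.0),
        EventNode("G", COMMON_ANCESTOR, time=4.0),
    ]
    edges = [
        EventEdge("A", "D", NO_SIDE),
        # D inherits to the left of the breakpoint from E, to the right from F
        EventEdge("D", "E", LEFT),
        EventEdge("D", "F", RIGHT),
        EventEdge("B", "E", NO_SIDE),
        EventEdge("C", "F", NO_SIDE),
        EventEdge("E", "G", NO_SIDE),
        EventEdge("F", "G", NO_SIDE),
    ]
    return EventARG(L, nodes, edges, samples="ABC")


def build_fig3_earg() -> EventARG:
    L = 7.0
    nodes = [
        EventNode("A", SAMPLE, time=0.0),
        EventNode("B", SAMPLE, time=0.0),
        EventNode("C", SAMPLE, time=0.0),
        EventNode("D", RECOMBINATION, breakpoint=2.0, time=1.0),
        EventNode("E", RECOMBINATION, breakpoint=2.0, time=2.0),
        EventNode("F", COMMON_ANCESTOR, time=3.0),
        # the breakpoint of G falls in nonancestral material: F carries
        # sample material only on [0,2), entirely left of position 5
        EventNode("G", RECOMBINATION, breakpoint=5.0, time=4.0),
        EventNode("H", COMMON_ANCESTOR, time=5.0),
        EventNode("I", RECOMBINATION, breakpoint=2.0, time=6.0),
        EventNode("J", COMMON_ANCESTOR, time=7.0),
        EventNode("K", COMMON_ANCESTOR, time=8.0),  # full coalescence of [0,2)
        EventNode("L", RECOMBINATION, breakpoint=4.0, time=9.0),
        EventNode("M", RECOMBINATION, breakpoint=4.0, time=10.0),
        EventNode("N", COMMON_ANCESTOR, time=11.0),
        EventNode("O", COMMON_ANCESTOR, time=12.0),
        EventNode("P", COMMON_ANCESTOR, time=13.0),  # full coalescence of [2,7)
        EventNode("Q", COMMON_ANCESTOR, time=14.0),  # grand MRCA
    ]
    edges = [
        EventEdge("A", "D", NO_SIDE),
        EventEdge("B", "E", NO_SIDE),
        EventEdge("C", "I", NO_SIDE),
        EventEdge("D", "F", LEFT),
        EventEdge("D", "H", RIGHT),
        EventEdge("E", "F", LEFT),
        EventEdge("E", "H", RIGHT),
        EventEdge("F", "G", NO_SIDE),
        EventEdge("G", "K", LEFT),
        EventEdge("G", "J", RIGHT),  # removed by resolution
        EventEdge("H", "J", NO_SIDE),
        EventEdge("I", "K", LEFT),
        EventEdge("I", "M", RIGHT),
        EventEdge("J", "L", NO_SIDE),
        EventEdge("K", "Q", NO_SIDE),
        EventEdge("L", "N", LEFT),
        EventEdge("L", "O", RIGHT),
        EventEdge("M", "O", LEFT),
        EventEdge("M", "N", RIGHT),
        EventEdge("N", "P", NO_SIDE),
        EventEdge("O", "P", NO_SIDE),
        EventEdge("P", "Q", NO_SIDE),
    ]
    return EventARG(L, nodes, edges, samples="ABC")
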
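"""Synthetic ARG generators.

Two complementary fixture simulators:

* :func:`sim_wf` - a prospective diploid Wright-Fisher forward simulation.
  Every transmitted genome and every inheritance interval is recorded
  generation by generation, pedigree included, producing the redundant
  "everything recorded" graphs that resolution and simplification prune.

* :func:`sim_earg` - a retrospective coalescent-with-recombination run in
  the classical event encoding: lineages coalesce pairwise and split at
  uniform crossover breakpoints until a grand MRCA is reached.  Breakpoints
  are drawn on the whole genome, so they can fall in nonancestral material,
  which is what sample resolution later detects and removes.

Both simulators draw from a single seeded generator in a fixed documented
order, so a given seed reproduces bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

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

__all__ = ["WFParams", "CwRParams", "sim_wf", "sim_earg", "meiosis_mosaic"]


@dataclass(frozen=True)
class WFParams:
    """Diploid Wright-Fisher forward simulation parameters.

    Rates are per meiosis (per transmitted genome): ``crossover_rate`` is
    the expected number of crossovers, ``gene_conversion_rate`` the expected
    number of conversion events, each inserting a tract of exponential mean
    length ``gc_tract_length`` copied from the homologous genome.
    """

    population_size: int
    generations: int
    sequence_length: float
    crossover_rate: float = 1.0
    gene_conversion_rate: float = 0.0
    gc_tract_length: float = 1.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.sequence_length <= 0:
            raise ValueError("sequence_length must be positive")
        for name in ("crossover_rate", "gene_conversion_rate", "gc_tract_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class CwRParams:
    """Backwards coalescent-with-recombination parameters.

    ``recombination_rate`` is the per-lineage event rate relative to the
    pairwise coalescence rate; breakpoints are uniform on (0, L).
    """

    sample_size: int
    sequence_length: float
    recombination_rate: float = 0.3
    seed: int = 1
    max_lineages: int = 200  # safety valve: no splits while at the cap

    def __post_init__(self) -> None:
        if self.sample_size < 2:
            raise ValueError("sample_size must be >= 2")
        if self.sequence_length <= 0:
            raise ValueError("sequence_length must be positive")
        if self.recombination_rate < 0:
            raise ValueError("recombination_rate must be >= 0")


def meiosis_mosaic(
    rng: np.random.Generator,
    L: float,
    crossover_rate: float,
    gene_conversion_rate: float = 0.0,
    gc_tract_length: float = 1.0,
) -> List[Tuple[float, float, int]]:
    """One meiosis: the transmitted genome as a mosaic of the two parental
    genomes.

    Returns a list of (left, right, which) runs tiling [0, L), where
    ``which`` is 0 or 1 (which parental genome the run comes from).  Draw
    order: crossover count, breakpoints, starting genome, conversion count,
    then per conversion its start and tract length.
    """
    n_x = rng.poisson(crossover_rate)
    breaks = np.sort(rng.uniform(0.0, L, size=n_x))
    start = int(rng.integers(2))
    cuts = [0.0, *[float(b) for b in breaks], L]
    runs: List[Tuple[float, float, int]] = []
    which = start
    for left, right in zip(cuts, cuts[1:]):
        if left < right:
            runs.append((left, right, which))
        which = 1 - which
    n_gc = rng.poisson(gene_conversion_rate)
    for _ in range(n_gc):
        s = float(rng.uniform(0.0, L))
        tract = float(rng.exponential(gc_tract_length))
        lo, hi = s, min(s + tract, L)
        if lo >= hi:
            continue
        flipped: List[Tuple[float, float, int]] = []
        for left, right, w in runs:
            pieces = [
                (left, min(right, lo), w),
                (max(left, lo), min(right, hi), 1 - w),
                (max(left, hi), right, w),
            ]
            flipped.extend((a, b, ww) for a, b, ww in pieces if a < b)
        runs = flipped
    # merge adjacent runs from the same genome
    merged: List[Tuple[float, float, int]] = []
    for left, right, w in runs:
        if merged and merged[-1][2] == w and merged[-1][1] == left:
            merged[-1] = (merged[-1][0], right, w)
        else:
            merged.append((left, right, w))
    return merged


def sim_wf(params: WFParams) -> GraphARG:
    """Simulate a pedigree-embedded prospective gARG.

    Generation 0 is the founding generation (oldest, parentless); the final
    generation's genomes are the samples.  Each non-founder genome picks a
    parent individual uniformly (selfing permitted) and is transmitted by
    one meiosis over that individual's two genomes, so its inbound edges
    partition [0, L).  Node metadata records individual and generation.
    """
    rng = np.random.default_rng(params.seed)
    N, G, L = params.population_size, params.generations, params.sequence_length

    def genome_id(gen: int, ind: int, which: int) -> int:
        return 2 * (gen * N + ind) + which

    nodes = []
    edges = []
    for gen in range(G + 1):
        time = float(G - gen)
        for ind in range(N):
            for which in range(2):
                gid = genome_id(gen, ind, which)
                nodes.append(
                    GenomeNode(
                        gid,
                        time=time,
                        is_sample=(gen == G),
                        metadata=f"individual={gen}.{ind}",
                    )
                )
    for gen in range(1, G + 1):
        for ind in range(N):
            for which in range(2):
                parent_ind = int(rng.integers(N))
                runs = meiosis_mosaic(
                    rng,
                    L,
                    params.crossover_rate,
                    params.gene_conversion_rate,
                    params.gc_tract_length,
                )
                child = genome_id(gen, ind, which)
                per_parent: dict[int, list] = {0: [], 1: []}
                for left, right, w in runs:
                    per_parent[w].append((left, right))
                for w, pairs in per_parent.items():
                    if pairs:
                        edges.append(
                            InheritanceEdge(
                                child,
                                genome_id(gen - 1, parent_ind, w),
                                IntervalSet(pairs),
                            )
                        )
    samples = [genome_id(G, i, w) for i in range(N) for w in range(2)]
    return GraphARG(L, nodes, edges, samples)


def sim_earg(params: CwRParams) -> EventARG:
    """Simulate a classical eARG backwards in time.

    With k open lineages, pairs coalesce at rate k(k-1)/2 and each lineage
    splits at rate ``recombination_rate``; events run until the grand MRCA.
    Draw order per event: waiting time, event type, participant(s), then the
    breakpoint for a split.
    """
    rng = np.random.default_rng(params.seed)
    n, L, rho = params.sample_size, params.sequence_length, params.recombination_rate
    nodes = [EventNode(i, SAMPLE, time=0.0) for i in range(n)]
    edges: List[EventEdge] = []
    # open lineage = (head node id, side label required on its out-edge)
    lineages: List[Tuple[int, str]] = [(i, NO_SIDE) for i in range(n)]
    t = 0.0
    next_id = n
    while len(lineages) > 1:
        k = len(lineages)
        coal_rate = k * (k - 1) / 2.0
        rec_rate = k * rho if k < params.max_lineages else 0.0
        total = coal_rate + rec_rate
        t += float(rng.exponential(1.0 / total))
        if rng.random() < rec_rate / total:
            i = int(rng.integers(k))
            head, side = lineages.pop(i)
            bp = float(rng.uniform(0.0, L))
            while bp == 0.0:
                bp = float(rng.uniform(0.0, L))
            node = EventNode(next_id, RECOMBINATION, breakpoint=bp, time=t)
            nodes.append(node)
            edges.append(EventEdge(head, next_id, side))
            lineages.append((next_id, LEFT))
            lineages.append((next_id, RIGHT))
        else:
            i, j = sorted(rng.choice(k, size=2, replace=False).tolist())
            head_j, side_j = lineages.pop(j)
            head_i, side_i = lineages.pop(i)
            node = EventNode(next_id, COMMON_ANCESTOR, time=t)
            nodes.append(node)
            edges.append(EventEdge(head_i, next_id, side_i))
            edges.append(EventEdge(head_j, next_id, side_j))
            lineages.append((next_id, NO_SIDE))
        next_id += 1
    return EventARG(L, nodes, edges, samples=range(n))
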
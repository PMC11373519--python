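"""Plain-text tables for gARGs and eARGs.

Two TSV tables per graph, UTF-8, with a single ``#``-prefixed header line.

gARG:
  ``nodes.tsv``  columns: id, time (empty if unknown), is_sample (0/1), metadata
  ``edges.tsv``  columns: child, parent, intervals - semicolon-separated
  ``left,right`` pairs, e.g. ``0,2;7,10``

eARG:
  ``enodes.tsv`` columns: id, kind (sample / common_ancestor /
  recombination), breakpoint (empty unless recombination), time (empty if
  unknown)
  ``eedges.tsv`` columns: child, parent, side (L / R / -)

Writers emit canonical order, so write-then-read and read-then-write are
identities (bit-exact) on canonical tables.  Malformed input raises
:class:`FormatError` naming the file, line and column.
"""

from __future__ import annotations

import os
from typing import Iterable, List, Optional, Tuple, Union

from .earg import KINDS, NO_SIDE, RECOMBINATION, EventARG, EventEdge, EventNode
from .graph import GenomeNode, GraphARG, InheritanceEdge, NodeId, _id_key
from .intervals import IntervalSet, _fmt

__all__ = [
    "FormatError",
    "read_garg",
    "write_garg",
    "read_earg",
    "write_earg",
]

PathLike = Union[str, os.PathLike]

GARG_NODE_HEADER = "# id\ttime\tis_sample\tmetadata"
GARG_EDGE_HEADER = "# child\tparent\tintervals"
EARG_NODE_HEADER = "# id\tkind\tbreakpoint\ttime"
EARG_EDGE_HEADER = "# child\tparent\tside"


class FormatError(ValueError):
    """A malformed table line, with file/line/column context."""

    def __init__(self, path: PathLike, line: int, column: str, message: str):
        super().__init__(f"{path}:{line}: column {column!r}: {message}")
        self.path = str(path)
        self.line = line
        self.column = column


def _parse_id(token: str) -> NodeId:
    try:
        return int(token)
    except ValueError:
        return token


def _parse_time(token: str, path: PathLike, line: int) -> Optional[float]:
    if token == "":
        return None
    try:
        return float(token)
    except ValueError:
        raise FormatError(path, line, "time", f"not a number: {token!r}") from None


def _rows(path: PathLike, n_columns: int, column_names: Tuple[str, ...]):
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != n_columns:
                raise FormatError(
                    path,
                    lineno,
                    "/".join(column_names),
                    f"expected {n_columns} tab-separated fields, got {len(fields)}",
                )
            yield lineno, fields


def _read_sequence_length(path: PathLike) -> Optional[float]:
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            if raw.startswith("## sequence_length="):
                return float(raw.split("=", 1)[1])
            if not raw.startswith("#"):
                break
    return None


def _parse_intervals(token: str, path: PathLike, line: int) -> IntervalSet:
    pairs = []
    for part in token.split(";"):
        bits = part.split(",")
        if len(bits) != 2:
            raise FormatError(
                path, line, "intervals", f"expected 'left,right', got {part!r}"
            )
        try:
            left, right = float(bits[0]), float(bits[1])
        except ValueError:
            raise FormatError(
                path, line, "intervals", f"non-numeric endpoint in {part!r}"
            ) from None
        if not left < right:
            raise FormatError(
                path,
                line,
                "intervals",
                f"inverted or empty interval [{bits[0]}, {bits[1]})",
            )
        pairs.append((left, right))
    return IntervalSet(pairs)


def read_garg(
    nodes_path: PathLike, edges_path: PathLike, sequence_length: Optional[float] = None
) -> GraphARG:
    """Read a gARG from its two tables.

    ``sequence_length`` defaults to the largest interval endpoint seen.
    """
    nodes = []
    samples = []
    for lineno, (i, t, s, meta) in _rows(
        nodes_path, 4, ("id", "time", "is_sample", "metadata")
    ):
        node_id = _parse_id(i)
        time = _parse_time(t, nodes_path, lineno)
        if s not in ("0", "1"):
            raise FormatError(nodes_path, lineno, "is_sample", f"expected 0 or 1, got {s!r}")
        nodes.append(GenomeNode(node_id, time=time, is_sample=s == "1", metadata=meta))
        if s == "1":
            samples.append(node_id)
    edges = []
    for lineno, (c, p, ivs) in _rows(edges_path, 3, ("child", "parent", "intervals")):
        edges.append(
            InheritanceEdge(
                _parse_id(c), _parse_id(p), _parse_intervals(ivs, edges_path, lineno)
            )
        )
    if sequence_length is None:
        sequence_length = _read_sequence_length(edges_path)
    if sequence_length is None:
        sequence_length = max((e.inherits.right for e in edges), default=1.0)
    return GraphARG(sequence_length, nodes, edges, samples)


def write_garg(g: GraphARG, nodes_path: PathLike, edges_path: PathLike) -> None:
    g = g.canonical()
    with open(nodes_path, "w", encoding="utf-8") as fh:
        fh.write(GARG_NODE_HEADER + "\n")
        for n in g.nodes:
            time = "" if n.time is None else _fmt(n.time)
            fh.write(f"{n.id}\t{time}\t{int(n.id in g.samples or n.is_sample)}\t{n.metadata}\n")
    with open(edges_path, "w", encoding="utf-8") as fh:
        fh.write(GARG_EDGE_HEADER + "\n")
        fh.write(f"## sequence_length={_fmt(g.sequence_length)}\n")
        for e in g.edges:
            ivs = ";".join(f"{_fmt(iv.left)},{_fmt(iv.right)}" for iv in e.inherits)
            fh.write(f"{e.child}\t{e.parent}\t{ivs}\n")


def read_earg(
    nodes_path: PathLike, edges_path: PathLike, sequence_length: Optional[float] = None
) -> EventARG:
    """Read an eARG from its two tables.

    ``sequence_length`` defaults to the largest breakpoint rounded up to the
    next integer (1.0 when there are no recombination nodes); pass it
    explicitly for fixed-length genomes.
    """
    nodes = []
    for lineno, (i, kind, bp, t) in _rows(
        nodes_path, 4, ("id", "kind", "breakpoint", "time")
    ):
        if kind not in KINDS:
            raise FormatError(
                nodes_path, lineno, "kind", f"expected one of {KINDS}, got {kind!r}"
            )
        breakpoint = None
        if bp != "":
            try:
                breakpoint = float(bp)
            except ValueError:
                raise FormatError(
                    nodes_path, lineno, "breakpoint", f"not a number: {bp!r}"
                ) from None
        nodes.append(
            EventNode(
                _parse_id(i),
                kind,
                breakpoint=breakpoint,
                time=_parse_time(t, nodes_path, lineno),
            )
        )
    edges = []
    for lineno, (c, p, side) in _rows(edges_path, 3, ("child", "parent", "side")):
        if side not in ("L", "R", "-"):
            raise FormatError(
                edges_path, lineno, "side", f"expected L, R or -, got {side!r}"
            )
        edges.append(EventEdge(_parse_id(c), _parse_id(p), side))
    if sequence_length is None:
        sequence_length = _read_sequence_length(nodes_path)
    if sequence_length is None:
        bps = [n.breakpoint for n in nodes if n.breakpoint is not None]
        sequence_length = float(int(max(bps)) + 1) if bps else 1.0
    return EventARG(sequence_length, nodes, edges)


def write_earg(e: EventARG, nodes_path: PathLike, edges_path: PathLike) -> None:
    nodes = sorted(e.nodes, key=lambda n: _id_key(n.id))
    edges = sorted(e.edges, key=lambda ed: (_id_key(ed.child), _id_key(ed.parent), ed.side))
    with open(nodes_path, "w", encoding="utf-8") as fh:
        fh.write(EARG_NODE_HEADER + "\n")
        fh.write(f"## sequence_length={_fmt(e.sequence_length)}\n")
        for n in nodes:
            bp = "" if n.breakpoint is None else _fmt(n.breakpoint)
            time = "" if n.time is None else _fmt(n.time)
            fh.write(f"{n.id}\t{n.kind}\t{bp}\t{time}\n")
    with open(edges_path, "w", encoding="utf-8") as fh:
        fh.write(EARG_EDGE_HEADER + "\n")
        for ed in edges:
            fh.write(f"{ed.child}\t{ed.parent}\t{ed.side}\n")
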
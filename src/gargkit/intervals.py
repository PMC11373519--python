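"""Half-open genomic intervals and canonical interval sets.

Coordinates are real-valued and 0-based.  An :class:`Interval` ``[left,
right)`` includes ``left`` and excludes ``right``; empty intervals are not
representable.  An :class:`IntervalSet` is the canonical form of a union of
intervals: sorted by left endpoint, pairwise disjoint, with abutting
intervals merged, so that two interval sets covering the same positions
compare equal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence, Tuple

__all__ = [
    "Interval",
    "IntervalSet",
    "interval_union",
    "interval_intersect",
    "interval_subtract",
]


@dataclass(frozen=True, order=True)
class Interval:
    """A non-empty half-open interval ``[left, right)``."""

    left: float
    right: float

    def __post_init__(self) -> None:
        if not self.left < self.right:
            raise ValueError(
                f"empty or inverted interval [{self.left}, {self.right})"
            )

    @property
    def span(self) -> float:
        return self.right - self.left

    def __contains__(self, x: float) -> bool:
        return self.left <= x < self.right

    def intersects(self, other: "Interval") -> bool:
        return self.left < other.right and other.left < self.right

    def __str__(self) -> str:
        return f"[{_fmt(self.left)}, {_fmt(self.right)})"


def _fmt(x: float) -> str:
    """Render a coordinate, dropping the decimal part when integral."""
    x = float(x)
    return str(int(x)) if x.is_integer() else repr(x)


def _merge(pairs: Iterable[Tuple[float, float]]) -> Tuple[Interval, ...]:
    out: list[Tuple[float, float]] = []
    for left, right in sorted(pairs):
        if out and left <= out[-1][1]:
            if right > out[-1][1]:
                out[-1] = (out[-1][0], right)
        else:
            out.append((left, right))
    return tuple(Interval(l, r) for l, r in out)


@dataclass(frozen=True)
class IntervalSet:
    """A canonical, possibly empty, union of disjoint half-open intervals."""

    intervals: Tuple[Interval, ...] = ()

    def __init__(self, intervals: Iterable[Interval | Tuple[float, float]] = ()):
        pairs = []
        for iv in intervals:
            if isinstance(iv, Interval):
                pairs.append((float(iv.left), float(iv.right)))
            else:
                left, right = iv
                Interval(float(left), float(right))  # reject empty/inverted
                pairs.append((float(left), float(right)))
        object.__setattr__(self, "intervals", _merge(pairs))

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __bool__(self) -> bool:
        return bool(self.intervals)

    def __contains__(self, x: float) -> bool:
        return any(x in iv for iv in self.intervals)

    @property
    def span(self) -> float:
        """Total length covered."""
        return sum(iv.span for iv in self.intervals)

    @property
    def left(self) -> float:
        return self.intervals[0].left

    @property
    def right(self) -> float:
        return self.intervals[-1].right

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet(tuple(self.intervals) + tuple(other.intervals))

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out = []
        a, b = self.intervals, other.intervals
        i = j = 0
        while i < len(a) and j < len(b):
            left = max(a[i].left, b[j].left)
            right = min(a[i].right, b[j].right)
            if left < right:
                out.append((left, right))
            if a[i].right <= b[j].right:
                i += 1
            else:
                j += 1
        return IntervalSet(out)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        out = []
        cuts = other.intervals
        for iv in self.intervals:
            lo = iv.left
            for c in cuts:
                if c.right <= lo or c.left >= iv.right:
                    continue
                if c.left > lo:
                    out.append((lo, c.left))
                lo = max(lo, c.right)
                if lo >= iv.right:
                    break
            if lo < iv.right:
                out.append((lo, iv.right))
        return IntervalSet(out)

    def endpoints(self) -> Tuple[float, ...]:
        pts: list[float] = []
        for iv in self.intervals:
            pts.append(iv.left)
            pts.append(iv.right)
        return tuple(pts)

    def __str__(self) -> str:
        return "{" + ", ".join(str(iv) for iv in self.intervals) + "}"


def interval_union(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Set union of two canonical interval sets."""
    return a.union(b)


def interval_intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Set intersection of two canonical interval sets."""
    return a.intersect(b)


def interval_subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Positions of ``a`` not covered by ``b``."""
    return a.subtract(b)


def single(left: float, right: float) -> IntervalSet:
    """Convenience constructor for a one-interval set."""
    return IntervalSet([(left, right)])


def point_region(
    breakpoints: Sequence[float], x: float
) -> Tuple[float, float]:
    """The half-open region between consecutive ``breakpoints`` containing x.

    ``breakpoints`` must be sorted and bracket ``x``.
    """
    for left, right in zip(breakpoints, breakpoints[1:]):
        if left <= x < right:
            return (left, right)
    raise ValueError(f"position {x} outside [{breakpoints[0]}, {breakpoints[-1]})")
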
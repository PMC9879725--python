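"""Maximal influence intervals, the all-pairs prefilter and supremal
representations.

The maximal influence interval of a variant is the hull, over all minimal
alignments, of the reference positions its operations can touch: a deletion
at position ``i`` spans ``[i, i+1)`` and an insertion anchored at ``p``
spans the degenerate ``[p, p)``.  Two variants can only be non-disjoint
when their intervals intersect, which makes interval intersection a sound
(never falsely negative) prefilter for batch comparison.

The supremal representation rewrites a variant as a single deletion-
insertion whose deletion spans the entire influence interval; the inserted
string may re-include reference symbols.  It captures every minimal
alignment at once, which makes it a convenient database key (sorted and
indexed on the deleted interval).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alignment import LcsGraph, build_lcs_graph
from .errors import EmptyVariantError
from .relations import observed_sequence
from .variant_model import Deletion, Insertion, Representation

__all__ = [
    "Interval",
    "SupremalVariant",
    "influence_interval",
    "influence_interval_of",
    "intervals_intersect",
    "prefilter_pairs",
    "supremal_variant",
]


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open interval ``[start, end)`` over reference positions;
    ``[p, p)`` is the valid degenerate interval of an insertion-only
    variant.

    ``start_is_anchor``/``end_is_anchor`` record whether an insertion
    anchored exactly at the endpoint occurs in some minimal alignment.  A
    deletion changes a position strictly inside the interval, but an
    insertion anchored at an endpoint changes the flanking gap, which
    matters when two intervals merely touch.  The flags are provenance
    metadata filled in by :func:`influence_interval`; they do not take part
    in equality.
    """

    start: int
    end: int
    start_is_anchor: bool = field(default=False, compare=False)
    end_is_anchor: bool = field(default=False, compare=False)

    def __post_init__(self):
        if not 0 <= self.start <= self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def degenerate(self) -> bool:
        return self.start == self.end

    def intersects(self, other: "Interval") -> bool:
        return intervals_intersect(self, other)

    def __str__(self) -> str:
        return f"[{self.start},{self.end})"


def influence_interval(graph: LcsGraph) -> Interval:
    """Hull of the per-operation spans over all edges on source→sink paths.

    A deletion at position ``i`` spans ``[i, i+1)``; an insertion anchored
    at ``p`` spans the degenerate ``[p, p)``.  Endpoints coinciding with an
    insertion anchor are flagged on the returned interval so the
    intersection test stays conservative when two hulls merely touch.
    """
    lo = hi = None
    anchor_lo = anchor_hi = None

    def widen(a: int, b: int):
        nonlocal lo, hi
        lo = a if lo is None or a < lo else lo
        hi = b if hi is None or b > hi else hi

    def widen_anchor(a: int, b: int):
        nonlocal anchor_lo, anchor_hi
        anchor_lo = a if anchor_lo is None or a < anchor_lo else anchor_lo
        anchor_hi = b if anchor_hi is None or b > anchor_hi else anchor_hi

    for _, e in graph.iter_edges():
        if e.has_deletions:
            widen(e.del_start, e.del_end + 1)
        if e.has_insertions:
            # anchors range over [del_start - 1, del_end]; for a pure
            # insertion gap this degenerates to the single point del_start-1
            widen(e.del_start - 1, e.del_start - 1)
            widen_anchor(e.del_start - 1, e.del_start - 1)
            if e.has_deletions:
                widen(e.del_end, e.del_end)
                widen_anchor(e.del_end, e.del_end)
    if lo is None:
        raise EmptyVariantError(
            "influence interval is undefined for an empty variant")
    return Interval(lo, hi,
                    start_is_anchor=anchor_lo == lo,
                    end_is_anchor=anchor_hi == hi)


def influence_interval_of(reference: str,
                          variant: Representation | str) -> Interval:
    """Convenience wrapper building the LCS-graph for ``variant`` first."""
    observed = observed_sequence(reference, variant)
    return influence_interval(
        build_lcs_graph(reference, observed, record_waves=False))


def intervals_intersect(a: Interval, b: Interval) -> bool:
    """Conservative intersection test: a ``False`` answer guarantees the
    corresponding variants are disjoint.

    Non-degenerate intervals intersect under the strict half-open rule;
    a degenerate ``[p, p)`` intersects ``[s, e)`` when ``s <= p <= e``
    (inclusive at both boundaries, so an insertion point touching either
    edge of a deletion span is kept for full comparison) and another
    degenerate point only when equal.  Non-degenerate hulls that merely
    touch are kept only when both touching endpoints carry insertion
    anchors (the one configuration in which a shared element is possible
    at the boundary gap).
    """
    if a.degenerate and b.degenerate:
        return a.start == b.start
    if a.degenerate:
        return b.start <= a.start <= b.end
    if b.degenerate:
        return a.start <= b.start <= a.end
    if max(a.start, b.start) < min(a.end, b.end):
        return True
    if a.end == b.start:
        return a.end_is_anchor and b.start_is_anchor
    if b.end == a.start:
        return b.end_is_anchor and a.start_is_anchor
    return False


def prefilter_pairs(intervals: list[tuple[object, Interval]]
                    ) -> list[tuple[object, object]]:
    """All id-pairs whose influence intervals intersect.

    Sorted sweep over interval starts: O(n log n + k) for k candidate
    pairs.  Pairs are returned with ids in input order.
    """
    indexed = sorted(
        ((iv.start, idx) for idx, (_, iv) in enumerate(intervals)))
    pairs: list[tuple[int, int]] = []
    active: list[int] = []
    for start, idx in indexed:
        iv = intervals[idx][1]
        # anything ending strictly before this start can never intersect later
        active = [a for a in active if intervals[a][1].end >= start]
        for a in active:
            if intervals_intersect(intervals[a][1], iv):
                pairs.append((a, idx) if a < idx else (idx, a))
        active.append(idx)
    pairs.sort()
    return [(intervals[i][0], intervals[j][0]) for i, j in pairs]


@dataclass(frozen=True)
class SupremalVariant:
    """A single delins whose deletion spans the maximal influence interval;
    ``inserted`` may contain redundant reference symbols."""

    deletion_span: Interval
    inserted: str

    def to_representation(self) -> Representation:
        s = max(self.deletion_span.start, 1)
        ops: list = [Deletion(p) for p in range(s, self.deletion_span.end)]
        anchor = self.deletion_span.end - 1 if ops else self.deletion_span.start
        ops.extend(Insertion(anchor, c) for c in self.inserted)
        return Representation(tuple(ops))

    def to_hgvs(self) -> str:
        s, e = self.deletion_span.start, self.deletion_span.end
        if self.deletion_span.degenerate:
            return f"{s}_{s + 1}ins{self.inserted}"
        s = max(s, 1)
        span = f"{s}" if s == e - 1 else f"{s}_{e - 1}"
        if not self.inserted:
            return f"{span}del"
        return f"{span}delins{self.inserted}"

    def __str__(self) -> str:
        return self.to_hgvs()


def supremal_variant(reference: str,
                     variant: Representation | str) -> SupremalVariant:
    """Normalized supremal representation of ``variant``.

    With influence interval ``[s, e)`` the reference positions
    ``max(s, 1)..e-1`` are deleted and the observed span between the matched
    prefix (length ``s - 1``) and matched suffix (length ``|R| - e + 1``) is
    inserted.  When some minimal alignment inserts before position 1
    (``s = 0``) the deletion start is clamped to 1 with the inserted string
    extended accordingly, preserving patch-equivalence.
    """
    observed = observed_sequence(reference, variant)
    graph = build_lcs_graph(reference, observed, record_waves=False)
    interval = influence_interval(graph)
    s, e = interval.start, interval.end
    if interval.degenerate:
        inserted = observed[s:s + len(observed) - len(reference)]
        return SupremalVariant(interval, inserted)
    if interval.end_is_anchor:
        # an insertion anchored at the hull end changes the gap after
        # position e, so the deletion must extend one position further for
        # the matched suffix to be intact
        e += 1
    lo = max(s, 1)
    inserted = observed[lo - 1:len(observed) - len(reference) + e - 1]
    return SupremalVariant(Interval(s, e), inserted)
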
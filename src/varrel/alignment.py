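"""Simple edit distance and the LCS-graph of all minimal alignments.

The simple edit distance is the Levenshtein distance without substitutions,
weighing deletions and insertions as 1.  It is computed here with a wave
expansion of the dynamic-programming matrix guided by the admissible A*
heuristic ``h(i, j) = |(|R| - i) - (|O| - j)|``: cells are expanded in waves
of constant total cost ``f = D(i, j) + h(i, j)``, starting at
``f = ||R| - |O||`` and increasing in steps of 2 (orthogonal steps change
``D`` by +1 and ``h`` by ±1; diagonal match steps are free), so ``f`` keeps a
constant parity and the distance is the ``f``-value of the wave that reaches
the bottom-right cell.  The frontier is held in two linear arrays ``rows``
(per row, the right-most expanded column) and ``cols`` (per column, the
bottom-most expanded row); temporary space is O(|R| + |O|) beyond the
output.

Matching cells encountered during expansion become the nodes of the
LCS-graph: a DAG whose source→sink paths spell exactly the minimal
alignments.  Each match ``(i, j)`` sits on LCS level
``⌊(i + j - D(i, j)) / 2⌋``; edges run from level ``ℓ`` to level ``ℓ+1``
whenever both coordinates strictly increase, labelled with the skipped
(deleted) reference run and the skipped (inserted) observed run.  Matches on
no optimal path are removed by a reachability sweep from both virtual ends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations_with_replacement, product
from typing import Iterator, NamedTuple

from .errors import EnumerationCapError
from .variant_model import Deletion, Insertion, Representation

__all__ = [
    "WaveSnapshot",
    "Edge",
    "LcsGraph",
    "edit_distance",
    "lcs_length",
    "node_level",
    "build_lcs_graph",
    "enumerate_minimal",
    "element_set",
    "to_dot",
]

Node = tuple[int, int]


@dataclass(frozen=True)
class WaveSnapshot:
    """Frontier state after one expansion wave of constant ``f``."""

    f: int
    rows: list[int]  # rows[i] = right-most expanded column in row i
    cols: list[int]  # cols[j] = bottom-most expanded row in column j


class Edge(NamedTuple):
    """Edge to ``target`` whose gap deletes reference run
    ``del_start..del_end`` and inserts observed run ``ins_start..ins_end``
    (1-based inclusive; an empty run has start > end)."""

    target: Node
    del_start: int
    del_end: int
    ins_start: int
    ins_end: int

    @property
    def has_deletions(self) -> bool:
        return self.del_start <= self.del_end

    @property
    def has_insertions(self) -> bool:
        return self.ins_start <= self.ins_end


def node_level(i: int, j: int, d_ij: int) -> int:
    """LCS level of an expanded cell: ``⌊(i + j - D(i, j)) / 2⌋``."""
    return (i + j - d_ij) // 2


def _wave_expand(ref: str, obs: str, *, collect_matches: bool = True,
                 record_waves: bool = False):
    """Expand DP cells in waves of constant f.

    Per diagonal ``k = i - j`` only the furthest covered row is kept
    (coverage is a prefix of every diagonal because D is non-decreasing along
    diagonals); a cell first covered at wave ``f`` on diagonal ``k`` has
    ``D = f - |Δ - k|`` exactly.  Returns ``(matches, distance, waves)``
    where ``matches`` maps match cells to their D-value.
    """
    n, m = len(ref), len(obs)
    delta = n - m
    reach: dict[int, int] = {}
    matches: dict[Node, int] = {}
    rows: list[int] = []
    cols: list[int] = []
    waves: list[WaveSnapshot] = []

    f = abs(delta)
    distance = None
    while distance is None:
        # Process diagonals from both ends towards Δ so that same-wave
        # propagation (deletions k-1→k below Δ, insertions k+1→k above)
        # sees already-updated neighbours; the opposite neighbour is
        # correctly taken from the previous wave.
        order = list(range(delta - f, delta)) \
            + list(range(delta + f, delta, -1)) + [delta]
        for k in order:
            budget = f - abs(delta - k)
            if budget < abs(k):
                continue  # no cell of this diagonal is affordable yet
            i0 = max(k, 0)
            limit = min(n, m + k)
            if limit < i0:
                continue  # diagonal carries no cells
            old = reach.get(k, i0 - 1)
            cand = old + 1  # boundary cell, or previous reach plus one indel pair
            r = reach.get(k - 1)
            if r is not None and r + 1 > cand:
                cand = r + 1  # deletion step from diagonal k-1
            r = reach.get(k + 1)
            if r is not None and r > cand:
                cand = r  # insertion step from diagonal k+1
            if cand > limit:
                cand = limit
            i, j = cand, cand - k
            while i < n and j < m and ref[i] == obs[j]:
                i += 1
                j += 1
            if i <= old:
                reach.setdefault(k, old)
                continue
            reach[k] = i
            for ci in range(old + 1, i + 1):
                cj = ci - k
                if collect_matches and ci >= 1 and cj >= 1 \
                        and ref[ci - 1] == obs[cj - 1]:
                    matches[(ci, cj)] = budget
                if record_waves:
                    while len(rows) <= ci:
                        rows.append(-1)
                    if cj > rows[ci]:
                        rows[ci] = cj
                    while len(cols) <= cj:
                        cols.append(-1)
                    if ci > cols[cj]:
                        cols[cj] = ci
            if k == delta and reach[k] >= n:
                distance = f
        if record_waves:
            waves.append(WaveSnapshot(f, rows.copy(), cols.copy()))
        if distance is None:
            f += 2
    return matches, distance, waves


def edit_distance(a: str, b: str) -> int:
    """Simple edit distance (deletions and insertions only, unit weight)."""
    _, distance, _ = _wave_expand(a, b, collect_matches=False)
    return distance


def lcs_length(a: str, b: str) -> int:
    """Length of the longest common subsequence,
    ``(|a| + |b| - d(a, b)) / 2``."""
    return (len(a) + len(b) - edit_distance(a, b)) // 2


@dataclass
class LcsGraph:
    """DAG spanning every minimal alignment of ``observed`` against
    ``reference``.

    ``nodes`` maps match coordinates (plus the virtual source ``(0, 0)`` and
    sink ``(|R|+1, |O|+1)``) to LCS levels; ``edges`` holds the outgoing
    adjacency with gap labels.  Only nodes on at least one source→sink path
    are retained, so every path spells a minimal representation.
    """

    reference: str
    observed: str
    distance: int
    nodes: dict[Node, int]
    level_nodes: list[list[Node]]
    edges: dict[Node, list[Edge]]
    waves: list[WaveSnapshot] = field(default_factory=list)

    @property
    def source(self) -> Node:
        return (0, 0)

    @property
    def sink(self) -> Node:
        return (len(self.reference) + 1, len(self.observed) + 1)

    def iter_edges(self) -> Iterator[tuple[Node, Edge]]:
        for u, out in self.edges.items():
            for e in out:
                yield u, e


def build_lcs_graph(reference: str, observed: str,
                    record_waves: bool = True) -> LcsGraph:
    """Construct the LCS-graph of all minimal alignments via wave expansion."""
    matches, distance, waves = _wave_expand(
        reference, observed, collect_matches=True, record_waves=record_waves)
    n, m = len(reference), len(observed)
    lcs = (n + m - distance) // 2

    buckets: list[list[Node]] = [[] for _ in range(lcs + 2)]
    buckets[0].append((0, 0))
    buckets[lcs + 1].append((n + 1, m + 1))
    for (i, j), d_ij in matches.items():
        buckets[node_level(i, j, d_ij)].append((i, j))
    for bucket in buckets:
        bucket.sort()

    # forward reachability from the source, then backward from the sink:
    # a node survives iff it lies on some source→sink path, and every such
    # path holds exactly one match per level, hence is minimal.
    forward: list[list[Node]] = [buckets[0]]
    for lvl in range(1, lcs + 2):
        prev = forward[-1]
        forward.append([
            v for v in buckets[lvl]
            if any(u[0] < v[0] and u[1] < v[1] for u in prev)
        ])
    kept: list[list[Node]] = [[] for _ in range(lcs + 2)]
    kept[lcs + 1] = forward[lcs + 1]
    for lvl in range(lcs, -1, -1):
        nxt = kept[lvl + 1]
        kept[lvl] = [
            u for u in forward[lvl]
            if any(u[0] < v[0] and u[1] < v[1] for v in nxt)
        ]

    nodes: dict[Node, int] = {}
    edges: dict[Node, list[Edge]] = {}
    for lvl, bucket in enumerate(kept):
        for u in bucket:
            nodes[u] = lvl
            edges[u] = []
    for lvl in range(lcs + 1):
        for u in kept[lvl]:
            for v in kept[lvl + 1]:
                if u[0] < v[0] and u[1] < v[1]:
                    edges[u].append(
                        Edge(v, u[0] + 1, v[0] - 1, u[1] + 1, v[1] - 1))
    return LcsGraph(reference, observed, distance, nodes, kept, edges, waves)


def _gap_options(edge: Edge, observed: str) -> list[tuple]:
    """All monotone interleavings of one gap's deletions and insertions:
    each inserted symbol may be anchored after any prefix of the gap's
    deletions, anchors non-decreasing in insertion order."""
    a, b = edge.del_start, edge.del_end
    dels = [Deletion(p) for p in range(a, b + 1)]
    if not edge.has_insertions:
        return [tuple(dels)]
    symbols = [observed[q - 1] for q in range(edge.ins_start, edge.ins_end + 1)]
    options = []
    for anchors in combinations_with_replacement(range(a - 1, b + 1),
                                                 len(symbols)):
        ops: list = []
        ins = [Insertion(p, s) for p, s in zip(anchors, symbols)]
        di = ii = 0
        while di < len(dels) or ii < len(ins):
            if ii >= len(ins) or (di < len(dels)
                                  and dels[di].position <= ins[ii].anchor):
                ops.append(dels[di])
                di += 1
            else:
                ops.append(ins[ii])
                ii += 1
        options.append(tuple(ops))
    return options


def _count_gap_options(edge: Edge) -> int:
    ndel = max(0, edge.del_end - edge.del_start + 1)
    nins = max(0, edge.ins_end - edge.ins_start + 1)
    return math.comb(ndel + nins, nins)


def enumerate_minimal(graph: LcsGraph, cap: int = 10000) -> list[Representation]:
    """Enumerate Φ(R, O), the set of all minimal representations.

    Walks every source→sink path and expands every monotone interleaving of
    each gap.  Raises :class:`EnumerationCapError` as soon as the total would
    exceed ``cap`` (the element set is the scalable alternative).
    """
    observed = graph.observed
    reps: dict[tuple, Representation] = {}
    total = 0
    # iterative DFS over paths, carrying the gap edges seen so far
    stack: list[tuple[Node, tuple[Edge, ...]]] = [(graph.source, ())]
    while stack:
        u, gaps = stack.pop()
        if u == graph.sink:
            count = 1
            for e in gaps:
                count *= _count_gap_options(e)
            total += count
            if total > cap:
                raise EnumerationCapError(
                    f"more than {cap} minimal representations")
            pools = [_gap_options(e, observed) for e in gaps]
            for combo in product(*pools):
                ops = tuple(op for gap_ops in combo for op in gap_ops)
                reps.setdefault(ops, Representation(ops))
            continue
        for e in graph.edges[u]:
            if e.has_deletions or e.has_insertions:
                stack.append((e.target, gaps + (e,)))
            else:
                stack.append((e.target, gaps))
    return list(reps.values())


def element_set(graph: LcsGraph) -> frozenset:
    """Ψ(R, O): every atomic operation occurring in any minimal
    representation, computed from the graph edges without enumeration.

    A gap deleting run ``a..b`` and inserting observed run ``u..v``
    contributes deletions ``{a..b}`` and insertions ``{(p, O_q)}`` for every
    anchor ``p ∈ [a-1, b]`` (after any number of the gap's deletions) and
    every ``q ∈ [u, v]``.  Repeated insertions of one symbol at one anchor
    collapse; only emptiness of Ψ-intersections is ever consumed.
    """
    observed = graph.observed
    elements: set = set()
    for _, e in graph.iter_edges():
        for p in range(e.del_start, e.del_end + 1):
            elements.add(Deletion(p))
        if e.has_insertions:
            symbols = {observed[q - 1]
                       for q in range(e.ins_start, e.ins_end + 1)}
            for p in range(e.del_start - 1, e.del_end + 1):
                for s in symbols:
                    elements.add(Insertion(p, s))
    return frozenset(elements)


def to_dot(graph: LcsGraph) -> str:
    """GraphViz DOT rendering of the LCS-graph (debugging/teaching aid)."""
    def name(node: Node) -> str:
        if node == graph.source:
            return "source"
        if node == graph.sink:
            return "sink"
        return f"n{node[0]}_{node[1]}"

    def gap_label(e: Edge) -> str:
        parts = []
        if e.has_deletions:
            span = (f"{e.del_start}" if e.del_start == e.del_end
                    else f"{e.del_start}_{e.del_end}")
            parts.append(f"{span}del")
        if e.has_insertions:
            seq = graph.observed[e.ins_start - 1:e.ins_end]
            parts.append(f"ins{seq}")
        return " ".join(parts)

    lines = ["digraph lcs {", "  rankdir=LR;"]
    for node, lvl in graph.nodes.items():
        label = name(node) if node in (graph.source, graph.sink) \
            else f"({node[0]},{node[1]})/{lvl}"
        lines.append(f'  {name(node)} [label="{label}"];')
    for u, e in graph.iter_edges():
        label = gap_label(e)
        attr = f' [label="{label}"]' if label else ""
        lines.append(f"  {name(u)} -> {name(e.target)}{attr};")
    lines.append("}")
    return "\n".join(lines)
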
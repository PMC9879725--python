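"""Independent brute-force oracle and seeded random-case generator.

Deliberately naive: the full quadratic DP matrix, exhaustive traceback of
every minimal alignment, and literal evaluation of the relation definitions
on the enumerated representation sets.  Size guards convert exponential
blowup into clean errors.  This module is the acceptance surface for every
fast algorithm in the package and must stay independent of them.
"""

from __future__ import annotations

import random
from functools import lru_cache

import numpy as np

from .errors import EmptyVariantError, EnumerationCapError, SizeGuardError
from .variant_model import (
    Deletion,
    Insertion,
    Relation,
    Representation,
    patch,
)

__all__ = [
    "dp_full_matrix",
    "enumerate_paths",
    "relation_by_definition",
    "random_case",
    "MAX_ORACLE_LENGTH",
    "MAX_ORACLE_PATHS",
]

MAX_ORACLE_LENGTH = 64
MAX_ORACLE_PATHS = 100_000


def dp_full_matrix(a: str, b: str) -> np.ndarray:
    """Full ``(|a|+1) x (|b|+1)`` matrix of the simple edit distance
    recurrence (deletions and insertions cost 1, matches are free)."""
    n, m = len(a), len(b)
    if n > MAX_ORACLE_LENGTH or m > MAX_ORACLE_LENGTH:
        raise SizeGuardError(
            f"oracle limited to strings of length {MAX_ORACLE_LENGTH}")
    d = np.zeros((n + 1, m + 1), dtype=np.int64)
    d[:, 0] = np.arange(n + 1)
    d[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if a[i - 1] == b[j - 1]:
                d[i, j] = d[i - 1, j - 1]
            else:
                d[i, j] = min(d[i - 1, j], d[i, j - 1]) + 1
    return d


def enumerate_paths(matrix: np.ndarray, a: str, b: str,
                    cap: int = MAX_ORACLE_PATHS) -> list[Representation]:
    """Φ(a, b) by exhaustive backtrace of the full matrix.

    Vertical steps are deletions, horizontal steps insertions of the
    observed symbol anchored at the current reference position; diagonal
    steps are allowed only on matches that keep the value.
    """
    n, m = len(a), len(b)
    reps: list[Representation] = []

    def walk(i: int, j: int, ops: list):
        if len(reps) > cap:
            raise EnumerationCapError(f"more than {cap} minimal paths")
        if i == 0 and j == 0:
            reps.append(Representation(tuple(reversed(ops))))
            return
        if i > 0 and j > 0 and a[i - 1] == b[j - 1] \
                and matrix[i - 1, j - 1] == matrix[i, j]:
            walk(i - 1, j - 1, ops)
        if i > 0 and matrix[i - 1, j] == matrix[i, j] - 1:
            ops.append(Deletion(i))
            walk(i - 1, j, ops)
            ops.pop()
        if j > 0 and matrix[i, j - 1] == matrix[i, j] - 1:
            ops.append(Insertion(i, b[j - 1]))
            walk(i, j - 1, ops)
            ops.pop()

    walk(n, m, [])
    return reps


def _rep_profile(rep: Representation):
    """A representation as (deletion-position set, per-anchor inserted
    strings); the order of insertions sharing an anchor is part of the
    representation, so it is kept as a string."""
    dels = frozenset(op.position for op in rep.operations
                     if isinstance(op, Deletion))
    ins: dict[int, str] = {}
    for op in rep.operations:
        if isinstance(op, Insertion):
            ins[op.anchor] = ins.get(op.anchor, "") + op.symbol
    return dels, tuple(sorted(ins.items()))


def _is_subsequence(short: str, long: str) -> bool:
    it = iter(long)
    return all(c in it for c in short)


def _is_subrepresentation(sub, sup) -> bool:
    """Whether ``sub``'s operations can be obtained by removing operations
    from ``sup``: deletion positions by set inclusion, inserted strings at a
    shared anchor by subsequence inclusion (removing an insertion from an
    anchor string must leave the remaining symbols in order)."""
    sub_dels, sub_ins = sub
    sup_dels, sup_ins = sup
    if not sub_dels <= sup_dels:
        return False
    sup_map = dict(sup_ins)
    return all(_is_subsequence(s, sup_map.get(anchor, ""))
               for anchor, s in sub_ins)


def _raw_elements(profile) -> frozenset:
    dels, ins = profile
    out = {("del", p) for p in dels}
    for anchor, s in ins:
        out.update(("ins", anchor, c) for c in s)
    return frozenset(out)


@lru_cache(maxsize=16384)
def _minimal_profiles(reference: str, observed: str, cap: int):
    """(distance, tuple of representation profiles, union of elements)."""
    matrix = dp_full_matrix(reference, observed)
    reps = enumerate_paths(matrix, reference, observed, cap=cap)
    profiles = tuple(_rep_profile(r) for r in reps)
    raw = frozenset(e for p in profiles for e in _raw_elements(p))
    return int(matrix[-1, -1]), profiles, raw


def relation_by_definition(reference: str, o: str, p: str,
                           cap: int = MAX_ORACLE_PATHS) -> Relation:
    """Literal evaluation of the relation definitions over the enumerated
    minimal representation sets (small inputs only)."""
    if o == reference or p == reference:
        raise EmptyVariantError(
            "relations are undefined for empty variants")
    if o == p:
        return Relation.EQUIVALENT
    d_o, phi_o, raw_o = _minimal_profiles(reference, o, cap)
    d_p, phi_p, raw_p = _minimal_profiles(reference, p, cap)
    if raw_o.isdisjoint(raw_p):
        return Relation.DISJOINT
    if d_p < d_o and any(_is_subrepresentation(sp, so)
                         for sp in phi_p for so in phi_o):
        return Relation.CONTAINS
    if d_o < d_p and any(_is_subrepresentation(so, sp)
                         for so in phi_o for sp in phi_p):
        return Relation.IS_CONTAINED
    return Relation.OVERLAP


def random_case(seed: int, ref_length: int = 24, alphabet: str = "ACGT",
                op_count: int = 3, n_variants: int = 1,
                require_change: bool = False):
    """Deterministic random ``(reference, variants)`` pair generator.

    References are repeat-rich (homopolymer runs and short tandem repeats
    interleaved with random stretches), the structure that maximizes
    co-optimal alignment ambiguity.  Each variant mixes deletions,
    insertions and SNVs (``op_count`` edit events) and always patches
    cleanly; with ``require_change`` variants whose patched sequence equals
    the reference are resampled.
    """
    rng = random.Random(seed)
    alphabet = "".join(sorted(set(alphabet)))
    chunks: list[str] = []
    length = 0
    while length < ref_length:
        kind = rng.random()
        if kind < 0.4:
            run = rng.choice(alphabet) * rng.randint(2, 6)
        elif kind < 0.7:
            unit = "".join(rng.choice(alphabet)
                           for _ in range(rng.randint(2, 3)))
            run = unit * rng.randint(2, 4)
        else:
            run = "".join(rng.choice(alphabet)
                          for _ in range(rng.randint(1, 4)))
        chunks.append(run)
        length += len(run)
    reference = "".join(chunks)[:ref_length]

    def sample_variant() -> Representation:
        ops: list = []
        used_del: set[int] = set()
        for _ in range(op_count):
            kind = rng.choice(("del", "ins", "snv"))
            if kind in ("del", "snv"):
                free = [p for p in range(1, ref_length + 1)
                        if p not in used_del]
                if not free:
                    kind = "ins"
                else:
                    pos = rng.choice(free)
                    used_del.add(pos)
                    ops.append(Deletion(pos, reference[pos - 1]))
                    if kind == "snv":
                        ops.append(Insertion(pos, rng.choice(alphabet)))
                    continue
            ops.append(Insertion(rng.randint(0, ref_length),
                                 rng.choice(alphabet)))
        return Representation(tuple(ops)).sorted()

    variants: list[Representation] = []
    for _ in range(n_variants):
        for _attempt in range(100):
            rep = sample_variant()
            if not require_change or op_count == 0 \
                    or patch(reference, rep) != reference:
                break
        variants.append(rep)
    return reference, variants
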
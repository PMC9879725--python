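"""Core variant data model.

A variant is described against a reference sequence ``R`` as a collection of
atomic operations: single-symbol deletions at 1-based reference positions and
single-symbol insertions anchored *after* a reference position (anchor 0
inserts before the first symbol).  A :class:`Representation` bundles such
operations, all indexed on the *original* reference coordinates, and
:func:`patch` applies them deterministically to produce the observed
sequence, in the spirit of the Unix ``diff``/``patch`` pair.

A small genomic (g.) HGVS subset is supported for text input and output:
``NdelS?``, ``N_MdelS?``, ``N_MinsSEQ``, ``N_MdelinsSEQ`` (and the
single-position ``NdelinsSEQ``), SNVs ``NX>Y`` and bracketed alleles
``[op1;op2;...]``.  Everything else (dup, inv, repeats, uncertainty, c./p.
coordinates) raises :class:`~varrel.errors.UnsupportedVariantError` rather
than being silently misread.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator

from .errors import (
    ParseError,
    PositionError,
    UnsupportedVariantError,
    VariantError,
)

__all__ = [
    "Deletion",
    "Insertion",
    "AtomicOperation",
    "Representation",
    "Relation",
    "parse_variant",
    "format_variant",
    "patch",
]


@dataclass(frozen=True)
class Deletion:
    """Deletion of the reference symbol at 1-based ``position``.

    The optional ``symbol`` is an annotation (the ``T`` in ``7delT``); it is
    validated against the reference during :func:`patch` when present but is
    excluded from equality, so element-set membership depends on the position
    only.
    """

    position: int
    symbol: str | None = field(default=None, compare=False)

    def __repr__(self) -> str:
        return f"Deletion({self.position}{', ' + self.symbol if self.symbol else ''})"


@dataclass(frozen=True)
class Insertion:
    """Insertion of ``symbol`` after reference position ``anchor`` (0-based
    gap: anchor 0 is before the first symbol, anchor |R| after the last)."""

    anchor: int
    symbol: str

    def __repr__(self) -> str:
        return f"Insertion({self.anchor}, {self.symbol})"


AtomicOperation = Deletion | Insertion


def _op_sort_key(index_op):
    index, op = index_op
    if isinstance(op, Deletion):
        return (op.position, 0, index)
    return (op.anchor, 1, index)


@dataclass(frozen=True)
class Representation:
    """An ordered collection of atomic operations on original reference
    coordinates.

    Deletion positions must be pairwise distinct (deletions commute); the
    relative order of insertions sharing an anchor is significant and is
    preserved.
    """

    operations: tuple[AtomicOperation, ...]

    def __post_init__(self):
        ops = tuple(self.operations)
        object.__setattr__(self, "operations", ops)
        seen = set()
        for op in ops:
            if isinstance(op, Deletion):
                if op.position in seen:
                    raise VariantError(
                        f"duplicate deletion of position {op.position}"
                    )
                seen.add(op.position)
            elif not isinstance(op, Insertion):
                raise VariantError(f"not an atomic operation: {op!r}")

    def __len__(self) -> int:
        return len(self.operations)

    def __iter__(self) -> Iterator[AtomicOperation]:
        return iter(self.operations)

    def __bool__(self) -> bool:
        return bool(self.operations)

    @property
    def deletions(self) -> tuple[Deletion, ...]:
        return tuple(op for op in self.operations if isinstance(op, Deletion))

    @property
    def insertions(self) -> tuple[Insertion, ...]:
        return tuple(op for op in self.operations if isinstance(op, Insertion))

    def sorted(self) -> "Representation":
        """Canonical operation order: ascending coordinate, deletions before
        insertions at the same coordinate, stable among equal anchors."""
        ordered = sorted(enumerate(self.operations), key=_op_sort_key)
        return Representation(tuple(op for _, op in ordered))


class Relation(Enum):
    """Five-valued outcome of comparing two variants over one reference;
    exactly one value holds for every admissible pair."""

    EQUIVALENT = "equivalent"
    CONTAINS = "contains"
    IS_CONTAINED = "is_contained"
    OVERLAP = "overlap"
    DISJOINT = "disjoint"

    def __str__(self) -> str:
        return self.value


def patch(reference: str, rep: Representation | Iterable[AtomicOperation]) -> str:
    """Apply ``rep`` to ``reference`` and return the observed sequence.

    Reference symbols at non-deleted positions are emitted in order;
    insertions are emitted immediately after their anchor position, multiple
    insertions at one anchor in list order.
    """
    ops = rep.operations if isinstance(rep, Representation) else tuple(rep)
    n = len(reference)
    deleted: dict[int, Deletion] = {}
    inserted: dict[int, list[str]] = {}
    for op in ops:
        if isinstance(op, Deletion):
            if not 1 <= op.position <= n:
                raise PositionError(
                    f"deletion position {op.position} outside [1, {n}]"
                )
            if op.position in deleted:
                raise VariantError(f"duplicate deletion of position {op.position}")
            if op.symbol is not None and reference[op.position - 1] != op.symbol:
                raise VariantError(
                    f"deleted symbol {op.symbol!r} does not match reference "
                    f"{reference[op.position - 1]!r} at position {op.position}"
                )
            deleted[op.position] = op
        elif isinstance(op, Insertion):
            if not 0 <= op.anchor <= n:
                raise PositionError(
                    f"insertion anchor {op.anchor} outside [0, {n}]"
                )
            inserted.setdefault(op.anchor, []).append(op.symbol)
        else:
            raise VariantError(f"not an atomic operation: {op!r}")
    out: list[str] = []
    out.extend(inserted.get(0, ()))
    for pos in range(1, n + 1):
        if pos not in deleted:
            out.append(reference[pos - 1])
        out.extend(inserted.get(pos, ()))
    return "".join(out)


_ALLELE_RE = re.compile(r"^\[(.*)\]$")
_SNV_RE = re.compile(r"^(\d+)([A-Za-z])>([A-Za-z])$")
_DELINS_RE = re.compile(r"^(\d+)(?:_(\d+))?delins([A-Za-z]+)$")
_DEL_RE = re.compile(r"^(\d+)(?:_(\d+))?del([A-Za-z]*)$")
_INS_RE = re.compile(r"^(\d+)_(\d+)ins([A-Za-z]+)$")

#: recognizable HGVS features that are deliberately outside the supported
#: genomic subset; matching any of these raises UnsupportedVariantError.
_UNSUPPORTED_MARKERS = ("dup", "inv", "con", "ext", "fs", "(", ")", "?", "=")


def _check_position(pos: int, reference_length: int | None, *, what: str,
                    lowest: int = 1) -> None:
    if pos < lowest:
        raise PositionError(f"{what} {pos} below {lowest}")
    if reference_length is not None and pos > reference_length:
        raise PositionError(
            f"{what} {pos} outside [1, {reference_length}]"
        )


def _parse_single(text: str, reference_length: int | None) -> list[AtomicOperation]:
    m = _SNV_RE.match(text)
    if m:
        pos, ref_sym, alt_sym = int(m.group(1)), m.group(2), m.group(3)
        _check_position(pos, reference_length, what="SNV position")
        return [Deletion(pos, ref_sym.upper()), Insertion(pos, alt_sym.upper())]
    m = _DELINS_RE.match(text)
    if m:
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        seq = m.group(3).upper()
        if end < start:
            raise ParseError(f"inverted range {start}_{end}", text)
        _check_position(start, reference_length, what="delins start")
        _check_position(end, reference_length, what="delins end")
        ops: list[AtomicOperation] = [Deletion(p) for p in range(start, end + 1)]
        # all inserted symbols are anchored at the end of the deleted run
        ops.extend(Insertion(end, s) for s in seq)
        return ops
    m = _DEL_RE.match(text)
    if m:
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        seq = m.group(3).upper() or None
        if end < start:
            raise ParseError(f"inverted range {start}_{end}", text)
        _check_position(start, reference_length, what="deletion start")
        _check_position(end, reference_length, what="deletion end")
        if seq is not None and len(seq) != end - start + 1:
            raise ParseError(
                f"deleted sequence {seq} does not span {start}_{end}", text
            )
        return [
            Deletion(p, seq[p - start] if seq else None)
            for p in range(start, end + 1)
        ]
    m = _INS_RE.match(text)
    if m:
        left, right, seq = int(m.group(1)), int(m.group(2)), m.group(3).upper()
        if right != left + 1:
            raise ParseError(
                f"insertion flanks {left}_{right} must be adjacent", text
            )
        _check_position(left, reference_length, what="insertion anchor", lowest=0)
        return [Insertion(left, s) for s in seq]
    if any(marker in text for marker in _UNSUPPORTED_MARKERS):
        raise UnsupportedVariantError(
            f"unsupported HGVS feature in {text!r} (only the genomic "
            "del/ins/delins/SNV/allele subset is accepted)", text
        )
    raise ParseError(f"cannot parse variant description {text!r}", text)


def parse_variant(text: str, reference_length: int | None = None) -> Representation:
    """Parse an HGVS-subset description into a :class:`Representation`.

    ``text`` is a single description or a bracketed ``;``-separated allele.
    Positions are validated against ``reference_length`` when given.  An SNV
    ``NX>Y`` expands to a deletion of ``N`` plus an insertion of ``Y``
    anchored at ``N``; ``N_MdelinsSEQ`` expands to deletions ``N..M`` plus
    per-symbol insertions anchored at ``M`` (a starting representation only;
    relations never depend on the expansion choice).
    """
    text = text.strip()
    if text.startswith("g."):
        text = text[2:]
    if text.startswith(("c.", "n.", "m.", "p.", "r.")):
        raise UnsupportedVariantError(
            f"only genomic (g.) coordinates are supported: {text!r}", text
        )
    if not text:
        raise ParseError("empty variant description", text)
    allele = _ALLELE_RE.match(text)
    parts = allele.group(1).split(";") if allele else [text]
    ops: list[AtomicOperation] = []
    for part in parts:
        part = part.strip()
        if not part:
            raise ParseError("empty description inside allele", text)
        ops.extend(_parse_single(part, reference_length))
    return Representation(tuple(ops)).sorted()


def _format_run(dels: list[Deletion], ins: list[Insertion],
                reference: str | None) -> str:
    """One collapsed description for a run of consecutive deletions plus the
    insertions anchored at the run's end."""
    start, end = dels[0].position, dels[-1].position
    span = f"{start}" if start == end else f"{start}_{end}"
    ins_seq = "".join(i.symbol for i in ins)
    if not ins:
        if start == end:
            sym = dels[0].symbol or (reference[start - 1] if reference else None)
            return f"{start}del{sym}" if sym else f"{start}del"
        return f"{span}del"
    if start == end and len(ins) == 1:
        ref_sym = dels[0].symbol or (reference[start - 1] if reference else None)
        if ref_sym:
            return f"{start}{ref_sym}>{ins[0].symbol}"
    return f"{span}delins{ins_seq}"


def format_variant(rep: Representation | Iterable[AtomicOperation],
                   reference: str | None = None) -> str:
    """Canonical textual form of a representation.

    Adjacent runs are collapsed to del/ins/delins/SNV shorthand; a single
    operation is written without brackets, multiple operations as
    ``[a;b;...]`` sorted by position, the empty representation as ``""``.
    ``parse_variant(format_variant(rep))`` patches to the same observed
    sequence as ``rep``.  If ``reference`` is given, deletion symbols are
    annotated from it.
    """
    if not isinstance(rep, Representation):
        rep = Representation(tuple(rep))
    rep = rep.sorted()
    if not rep:
        return ""
    dels = sorted(rep.deletions, key=lambda d: d.position)
    ins_at: dict[int, list[Insertion]] = {}
    for i in rep.insertions:
        ins_at.setdefault(i.anchor, []).append(i)

    descriptions: list[tuple[int, str]] = []
    run: list[Deletion] = []
    consumed_anchors: set[int] = set()

    def flush(run: list[Deletion]):
        if not run:
            return
        end = run[-1].position
        attached = ins_at.get(end, [])
        consumed_anchors.add(end)
        descriptions.append((run[0].position, _format_run(run, attached, reference)))

    for d in dels:
        if run and d.position == run[-1].position + 1:
            run.append(d)
        else:
            flush(run)
            run = [d]
    flush(run)

    for anchor in sorted(ins_at):
        if anchor in consumed_anchors:
            continue
        seq = "".join(i.symbol for i in ins_at[anchor])
        descriptions.append((anchor, f"{anchor}_{anchor + 1}ins{seq}"))

    descriptions.sort(key=lambda t: t[0])
    texts = [t for _, t in descriptions]
    if len(texts) == 1:
        return texts[0]
    return "[" + ";".join(texts) + "]"
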
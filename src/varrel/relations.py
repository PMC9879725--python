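"""Boolean relation between two variants over a shared reference.

The five relations partition all pairs of non-empty variants.  Equivalence
is plain string equality of the observed sequences.  Containment and the
easy disjoint case follow from the three pairwise simple edit distances
alone: with ``dO = d(R, O)``, ``dP = d(R, P)`` and ``dOP = d(O, P)``,
``dO - dP = dOP`` holds iff O contains P (a minimal path from R to O passes
through P), and ``dO + dP = dOP`` forces disjointness.  The converse of the
latter fails (R=CT, O=TG, P=GC is disjoint with all three distances equal
to 2), so the remaining pairs are separated by intersecting the element
sets Ψ(R, O) and Ψ(R, P) over all minimal alignments.
"""

from __future__ import annotations

from typing import NamedTuple

from .alignment import build_lcs_graph, edit_distance, element_set
from .errors import EmptyVariantError
from .variant_model import Relation, Representation, patch

__all__ = ["compare", "relation_table_row", "RelationProperties"]


def observed_sequence(reference: str,
                      variant: Representation | str) -> str:
    """Resolve a variant given as a representation (patched) or as an
    observed sequence (returned as-is, uppercased)."""
    if isinstance(variant, Representation):
        return patch(reference, variant)
    return str(variant).upper()


def compare(reference: str, lhs: Representation | str,
            rhs: Representation | str) -> Relation:
    """Classify the pair ``(lhs, rhs)`` against ``reference``.

    Arguments may be representations (non-minimal ones are fine: relations
    are functions of the observed sequences only, so inputs are implicitly
    minimized) or observed sequences.  Raises
    :class:`EmptyVariantError` when either observed sequence equals the
    reference, for which the relations are undefined.
    """
    if not reference:
        raise EmptyVariantError("reference sequence must be non-empty")
    o = observed_sequence(reference, lhs)
    p = observed_sequence(reference, rhs)
    if o == reference or p == reference:
        raise EmptyVariantError(
            "relations are undefined for empty variants (observed equals "
            "reference)")
    if o == p:
        return Relation.EQUIVALENT
    d_o = edit_distance(reference, o)
    d_p = edit_distance(reference, p)
    d_op = edit_distance(o, p)
    if d_o - d_p == d_op:
        return Relation.CONTAINS
    if d_p - d_o == d_op:
        return Relation.IS_CONTAINED
    if d_o + d_p == d_op:
        return Relation.DISJOINT
    psi_o = element_set(build_lcs_graph(reference, o, record_waves=False))
    psi_p = element_set(build_lcs_graph(reference, p, record_waves=False))
    if psi_o.isdisjoint(psi_p):
        return Relation.DISJOINT
    return Relation.OVERLAP


class RelationProperties(NamedTuple):
    symmetry: str      # "symmetric" | "asymmetric"
    reflexivity: str   # "reflexive" | "irreflexive"
    transitivity: str  # "transitive" | "intransitive"


_TABLE: dict[Relation, RelationProperties] = {
    Relation.EQUIVALENT: RelationProperties("symmetric", "reflexive",
                                            "transitive"),
    Relation.CONTAINS: RelationProperties("asymmetric", "irreflexive",
                                          "transitive"),
    Relation.IS_CONTAINED: RelationProperties("asymmetric", "irreflexive",
                                              "transitive"),
    Relation.OVERLAP: RelationProperties("symmetric", "irreflexive",
                                         "intransitive"),
    Relation.DISJOINT: RelationProperties("symmetric", "irreflexive",
                                          "intransitive"),
}


def relation_table_row(relation: Relation) -> RelationProperties:
    """Algebraic properties of a relation (the converse of "contains" is
    "is contained" and vice versa)."""
    return _TABLE[relation]
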
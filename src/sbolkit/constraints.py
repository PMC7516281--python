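"""Restriction vocabularies and constraint evaluation.

SBOL3 Constraints relate two Features through a restriction drawn from three
closed families:

* **identity** — verifyIdentical, differentFrom, replaces;
* **sequential** — positions on a sequence, covering the full Allen interval
  algebra plus the orientation relations inherited from SBOL2;
* **topological** — spatial relations between physical regions (Egenhofer):
  disjointness, containment, boundary contact, overlap.

Sequential and identity constraints are *evaluated* against the design when
the ground data (Ranges, external definitions) exists.  Topological
restrictions and ``replaces`` are representable and vocabulary-checked but
never computed: no geometry exists in a design document, and ``replaces`` is
an instruction for derivation, not a testable state.

Coordinates are 1-based inclusive integers, so adjacent intervals share no
point: ``meets(a, b)`` holds iff ``a.end + 1 == b.start``.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import SbolError, VocabularyError
from .model import (Component, ComponentReference, Constraint, Document,
                    ExternallyDefined, Feature, Range, Sequence, SubComponent,
                    resolve_reference)
from .terms import SBOL3

#: topological restrictions get their own IRI namespace so that the names
#: shared with the sequential family (contains, meets, overlaps,
#: strictlyContains) remain distinct terms
SBOL3_TOPOLOGY = "http://sbols.org/v3/topology#"

IDENTITY_RESTRICTIONS = frozenset({
    SBOL3 + "verifyIdentical",
    SBOL3 + "differentFrom",
    SBOL3 + "replaces",
})

SEQUENTIAL_RESTRICTIONS = frozenset({
    SBOL3 + name for name in (
        "precedes", "strictlyPrecedes", "meets", "overlaps", "contains",
        "strictlyContains", "equals", "finishes", "starts",
        "sameOrientationAs", "oppositeOrientationAs",
    )
})

TOPOLOGICAL_RESTRICTIONS = frozenset({
    SBOL3_TOPOLOGY + name for name in (
        "isDisjointFrom", "strictlyContains", "contains", "meets",
        "covers", "overlaps",
    )
})

ALL_RESTRICTIONS = (IDENTITY_RESTRICTIONS | SEQUENTIAL_RESTRICTIONS
                    | TOPOLOGICAL_RESTRICTIONS)


# --------------------------------------------------------------------------
# Allen interval algebra on 1-based inclusive integer Ranges
# --------------------------------------------------------------------------

#: the relation names returned by :func:`allen_relation`.  The 13 Allen cells
#: map onto 12 names: ``contains`` covers both one-shared-boundary cells
#: (started-by and finished-by), matching the restriction vocabulary's
#: boundary-sharing reading of containment.
ALLEN_RELATIONS = (
    "strictlyPrecedes", "meets", "overlaps", "starts", "finishes", "equals",
    "contains", "strictlyContains",
    "precededBy", "metBy", "overlappedBy", "strictlyContainedBy",
)

#: converse names under argument swap; ``contains`` maps to the pair of
#: possible converses (starts when the shared boundary is the start,
#: finishes when it is the end)
CONVERSES = {
    "equals": ("equals",),
    "strictlyPrecedes": ("precededBy",),
    "precededBy": ("strictlyPrecedes",),
    "meets": ("metBy",),
    "metBy": ("meets",),
    "overlaps": ("overlappedBy",),
    "overlappedBy": ("overlaps",),
    "starts": ("contains",),
    "finishes": ("contains",),
    "contains": ("starts", "finishes"),
    "strictlyContains": ("strictlyContainedBy",),
    "strictlyContainedBy": ("strictlyContains",),
}


def allen_relation(a: Range, b: Range) -> str:
    """The unique interval relation of *a* with respect to *b*.

    Both Ranges must lie on the same Sequence.  Exactly one name is returned
    for every pair of well-formed Ranges.
    """
    if a.sequence is not None and b.sequence is not None \
            and a.sequence != b.sequence:
        raise SbolError(
            f"ranges lie on different sequences: {a.sequence} vs {b.sequence}")
    s1, e1, s2, e2 = a.start, a.end, b.start, b.end
    if e1 + 1 < s2:
        return "strictlyPrecedes"
    if e1 + 1 == s2:
        return "meets"
    if e2 + 1 < s1:
        return "precededBy"
    if e2 + 1 == s1:
        return "metBy"
    if s1 == s2 and e1 == e2:
        return "equals"
    if s1 == s2:
        return "starts" if e1 < e2 else "contains"
    if e1 == e2:
        return "finishes" if s1 > s2 else "contains"
    if s1 < s2 and e1 > e2:
        return "strictlyContains"
    if s1 > s2 and e1 < e2:
        return "strictlyContainedBy"
    return "overlaps" if s1 < s2 else "overlappedBy"


#: which relation cells satisfy each sequential restriction; ``precedes``
#: (the non-strict SBOL2 legacy term) is the union of its two strict
#: refinements, and ``contains`` admits boundary sharing
_SEQUENTIAL_SATISFIED_BY = {
    "strictlyPrecedes": {"strictlyPrecedes"},
    "precedes": {"strictlyPrecedes", "meets"},
    "meets": {"meets"},
    "overlaps": {"overlaps"},
    "contains": {"contains", "strictlyContains"},
    "strictlyContains": {"strictlyContains"},
    "equals": {"equals"},
    "starts": {"starts"},
    "finishes": {"finishes"},
}


@dataclass(frozen=True)
class EvaluationResult:
    """Outcome of checking one Constraint against the design data."""

    status: str  # holds | violated | notEvaluable
    detail: str = ""

    HOLDS = "holds"
    VIOLATED = "violated"
    NOT_EVALUABLE = "notEvaluable"


def _holds(detail=""):
    return EvaluationResult(EvaluationResult.HOLDS, detail)


def _violated(detail=""):
    return EvaluationResult(EvaluationResult.VIOLATED, detail)


def _not_evaluable(detail=""):
    return EvaluationResult(EvaluationResult.NOT_EVALUABLE, detail)


def _concrete(doc: Document, feature: Feature) -> Feature:
    if isinstance(feature, ComponentReference):
        return resolve_reference(doc, feature)
    return feature


def _identity_target(doc: Document, feature: Feature) -> Optional[str]:
    """The IRI a feature's identity resolves to: the external definition for
    an ExternallyDefined feature, the instantiated Component for a
    SubComponent."""
    if isinstance(feature, ExternallyDefined):
        return feature.definition
    if isinstance(feature, SubComponent):
        return feature.instance_of
    return None


def _sequence_elements(doc: Document, definition_uri: str) -> Optional[str]:
    obj = doc.lookup(definition_uri)
    if isinstance(obj, Component) and obj.sequences:
        seq = doc.lookup(obj.sequences[0])
        if isinstance(seq, Sequence):
            return seq.elements
    return None


def _single_range(feature: Feature) -> Optional[Range]:
    ranges = [loc for loc in feature.locations if isinstance(loc, Range)]
    return ranges[0] if len(ranges) == 1 else None


def evaluate_constraint(doc: Document, c: Constraint) -> EvaluationResult:
    """Check one Constraint; unknown restriction IRIs raise."""
    restriction = c.restriction
    if restriction not in ALL_RESTRICTIONS:
        raise VocabularyError(f"unknown restriction IRI: {restriction!r}")
    subj = doc.lookup(c.subject) if c.subject else None
    obj = doc.lookup(c.object) if c.object else None
    if not isinstance(subj, Feature) or not isinstance(obj, Feature):
        return _not_evaluable("subject or object does not resolve to a Feature")
    try:
        subj = _concrete(doc, subj)
        obj = _concrete(doc, obj)
    except SbolError as exc:
        return _not_evaluable(f"reference resolution failed: {exc}")

    if restriction in TOPOLOGICAL_RESTRICTIONS:
        return _not_evaluable(
            "topological restrictions describe physical space; a design "
            "document carries no geometry to compute them from")

    name = restriction.rsplit("#", 1)[-1]

    if restriction in IDENTITY_RESTRICTIONS:
        if name == "replaces":
            return _not_evaluable(
                "replaces is an instruction for derivation, not a testable "
                "state")
        t1 = _identity_target(doc, subj)
        t2 = _identity_target(doc, obj)
        if t1 is None or t2 is None:
            return _not_evaluable(
                "one of the features has no definition to compare")
        same = t1 == t2
        if same:
            e1 = _sequence_elements(doc, t1)
            e2 = _sequence_elements(doc, t2)
            if e1 is not None and e2 is not None and e1 != e2:
                same = False
        if name == "verifyIdentical":
            return _holds(f"both resolve to {t1}") if same else _violated(
                f"{t1} != {t2}")
        # differentFrom
        return _violated(f"both resolve to {t1}") if same else _holds(
            f"{t1} != {t2}")

    # sequential family
    if name in ("sameOrientationAs", "oppositeOrientationAs"):
        o1, o2 = subj.orientation, obj.orientation
        if o1 is None or o2 is None:
            return _not_evaluable("orientation not set on both features")
        same = o1 == o2
        want_same = name == "sameOrientationAs"
        return _holds() if same == want_same else _violated(
            f"orientations {o1} / {o2}")

    r1, r2 = _single_range(subj), _single_range(obj)
    if r1 is None or r2 is None:
        return _not_evaluable(
            "both features need exactly one Range location to compare")
    if r1.sequence != r2.sequence:
        return _not_evaluable("ranges lie on different sequences")
    rel = allen_relation(r1, r2)
    if rel in _SEQUENTIAL_SATISFIED_BY[name]:
        return _holds(f"observed relation: {rel}")
    return _violated(f"observed relation: {rel}")


def check_all(doc: Document) -> list[tuple[str, EvaluationResult]]:
    """Evaluate every Constraint in the document, in deterministic order
    (top-levels by URI, constraints in declaration order).  Violations are
    reported, never raised."""
    results: list[tuple[str, EvaluationResult]] = []
    for top in sorted(doc.top_levels, key=lambda o: o.uri):
        if isinstance(top, Component):
            for con in top.constraints:
                results.append((con.uri, evaluate_constraint(doc, con)))
    return results
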
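"""Allen interval algebra and constraint evaluation."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from helpers import all_range_pairs, allen_oracle
from sbolkit import terms
from sbolkit.constraints import (ALL_RESTRICTIONS, ALLEN_RELATIONS,
                                 CONVERSES, IDENTITY_RESTRICTIONS,
                                 SBOL3_TOPOLOGY, SEQUENTIAL_RESTRICTIONS,
                                 TOPOLOGICAL_RESTRICTIONS, EvaluationResult,
                                 allen_relation, check_all,
                                 evaluate_constraint)
from sbolkit.errors import SbolError, VocabularyError
from sbolkit.model import (Document, LocalSubComponent, Range, Sequence,
                           SubComponent, create_component)
from sbolkit.terms import SBOL3

SEQ = "http://example.com/s/seq"


def R(start, end, seq=SEQ):
    return Range(seq, start, end)


class TestAllenRelation:
    @pytest.mark.parametrize("a, b, expected", [
        ((1, 10), (1, 10), "equals"),
        ((1, 5), (6, 10), "meets"),
        ((1, 10), (3, 5), "strictlyContains"),
        ((1, 4), (8, 9), "strictlyPrecedes"),
        ((1, 5), (3, 9), "overlaps"),
        ((1, 3), (1, 9), "starts"),
        ((4, 9), (1, 9), "finishes"),
        ((1, 9), (1, 5), "contains"),
        ((8, 9), (1, 4), "precededBy"),
        ((6, 10), (1, 5), "metBy"),
        ((3, 9), (1, 5), "overlappedBy"),
        ((3, 5), (1, 10), "strictlyContainedBy"),
    ])
    def test_named_cases_match_oracle(self, a, b, expected):
        assert allen_relation(R(*a), R(*b)) == expected
        assert allen_oracle(*a, *b) == expected

    def test_partition_exhaustive(self):
        """Exactly one relation holds per ordered pair — the implementation
        agrees with the set-semantics oracle on every pair with endpoints
        in 1..8."""
        count = 0
        for (s1, e1), (s2, e2) in all_range_pairs(1, 8):
            assert allen_relation(R(s1, e1), R(s2, e2)) == \
                allen_oracle(s1, e1, s2, e2)
            count += 1
        assert count == 36 * 36

    def test_inversion_exhaustive(self):
        for (s1, e1), (s2, e2) in all_range_pairs(1, 8):
            forward = allen_relation(R(s1, e1), R(s2, e2))
            backward = allen_relation(R(s2, e2), R(s1, e1))
            assert backward in CONVERSES[forward]

    @given(st.integers(1, 50), st.integers(1, 50),
           st.integers(1, 50), st.integers(1, 50))
    def test_always_returns_a_known_name(self, s1, l1, s2, l2):
        rel = allen_relation(R(s1, s1 + l1), R(s2, s2 + l2))
        assert rel in ALLEN_RELATIONS

    def test_different_sequences_rejected(self):
        with pytest.raises(SbolError):
            allen_relation(R(1, 5), R(1, 5, "http://example.com/s/other"))


class TestVocabularies:
    def test_families_are_disjoint_iri_sets(self):
        assert not IDENTITY_RESTRICTIONS & SEQUENTIAL_RESTRICTIONS
        assert not SEQUENTIAL_RESTRICTIONS & TOPOLOGICAL_RESTRICTIONS
        # shared names exist but as distinct IRIs per family
        sequential_names = {u.rsplit("#", 1)[-1]
                            for u in SEQUENTIAL_RESTRICTIONS}
        topological_names = {u.rsplit("#", 1)[-1]
                             for u in TOPOLOGICAL_RESTRICTIONS}
        assert {"contains", "meets", "overlaps", "strictlyContains"} <= \
            sequential_names & topological_names

    def test_unknown_restriction_raises(self, multicellular_doc):
        system = multicellular_doc.lookup(
            "http://example.com/multicellular/multicellular_system")
        con = system.constraints[0]
        con.restriction = "http://ex/frobnicates"
        with pytest.raises(VocabularyError):
            evaluate_constraint(multicellular_doc, con)


def _sequential_doc(range_a, range_b):
    doc = Document()
    ns = "http://example.com/s"
    seq = Sequence(ns, "seq", elements="A" * 60,
                   encoding=terms.ENC_IUPAC_DNA)
    doc.add(seq)
    comp = create_component(ns, "c", {terms.SBO_DNA})
    a = LocalSubComponent("a", types={terms.SBO_DNA})
    b = LocalSubComponent("b", types={terms.SBO_DNA})
    comp.add_feature(a)
    comp.add_feature(b)
    a.add_location(Range(seq, *range_a))
    b.add_location(Range(seq, *range_b))
    doc.add(comp)
    return doc, comp, a, b


class TestEvaluateConstraint:
    def test_identity_holds_on_multicellular_fixture(self, multicellular_doc):
        system = multicellular_doc.lookup(
            "http://example.com/multicellular/multicellular_system")
        shared = next(c for c in system.constraints
                      if c.display_id == "shared_ahl")
        result = evaluate_constraint(multicellular_doc, shared)
        assert result.status == EvaluationResult.HOLDS

    def test_different_from_same_definition_violated(self):
        doc = Document()
        ns = "http://example.com/d"
        part = create_component(ns, "part", {terms.SBO_DNA})
        doc.add(part)
        comp = create_component(ns, "c", {terms.SBO_DNA})
        s1 = comp.add_feature(SubComponent("use1", instance_of=part))
        s2 = comp.add_feature(SubComponent("use2", instance_of=part))
        con = comp.add_constraint(SBOL3 + "differentFrom", s1, s2)
        doc.add(comp)
        assert evaluate_constraint(doc, con).status == \
            EvaluationResult.VIOLATED

    def test_verify_identical_compares_sequence_elements(self):
        doc = Document()
        ns = "http://example.com/d"
        comp = create_component(ns, "c", {terms.SBO_DNA})
        parts = []
        for name, elements in (("p1", "ACGT"), ("p2", "TTTT")):
            part = create_component(ns, name, {terms.SBO_DNA})
            seq = Sequence(ns, name + "_seq", elements=elements,
                           encoding=terms.ENC_IUPAC_DNA)
            part.add_sequence(seq)
            doc.add(seq)
            doc.add(part)
            parts.append(part)
        # two uses of *different* parts: identity cannot hold
        s1 = comp.add_feature(SubComponent("u1", instance_of=parts[0]))
        s2 = comp.add_feature(SubComponent("u2", instance_of=parts[1]))
        con = comp.add_constraint(SBOL3 + "verifyIdentical", s1, s2)
        doc.add(comp)
        assert evaluate_constraint(doc, con).status == \
            EvaluationResult.VIOLATED

    def test_topological_containment_not_evaluable(self, multicellular_doc):
        sender = multicellular_doc.lookup(
            "http://example.com/multicellular/sender_system")
        con = sender.constraints[0]
        assert con.restriction == SBOL3_TOPOLOGY + "contains"
        result = evaluate_constraint(multicellular_doc, con)
        assert result.status == EvaluationResult.NOT_EVALUABLE
        assert result.detail

    def test_strictly_precedes_violated_by_overlap(self):
        doc, comp, a, b = _sequential_doc((1, 5), (3, 9))
        con = comp.add_constraint(SBOL3 + "strictlyPrecedes", a, b)
        result = evaluate_constraint(doc, con)
        assert result.status == EvaluationResult.VIOLATED
        assert "overlaps" in result.detail

    @pytest.mark.parametrize("ranges, restriction, status", [
        (((1, 5), (6, 10)), "precedes", "holds"),        # meets counts
        (((1, 5), (8, 10)), "precedes", "holds"),        # gap counts
        (((1, 5), (5, 10)), "precedes", "violated"),
        (((1, 10), (1, 5)), "contains", "holds"),        # shared boundary
        (((1, 10), (3, 5)), "strictlyContains", "holds"),
        (((1, 10), (1, 5)), "strictlyContains", "violated"),
        (((2, 4), (2, 9)), "starts", "holds"),
    ])
    def test_sequential_semantics(self, ranges, restriction, status):
        doc, comp, a, b = _sequential_doc(*ranges)
        con = comp.add_constraint(SBOL3 + restriction, a, b)
        assert evaluate_constraint(doc, con).status == status

    def test_unlocated_feature_not_evaluable(self):
        doc, comp, a, b = _sequential_doc((1, 5), (6, 10))
        b.locations.clear()
        con = comp.add_constraint(SBOL3 + "meets", a, b)
        assert evaluate_constraint(doc, con).status == \
            EvaluationResult.NOT_EVALUABLE

    def test_orientation_restrictions(self):
        doc, comp, a, b = _sequential_doc((1, 5), (6, 10))
        con = comp.add_constraint(SBOL3 + "sameOrientationAs", a, b)
        assert evaluate_constraint(doc, con).status == \
            EvaluationResult.NOT_EVALUABLE  # orientations unset
        a.orientation = terms.INLINE
        b.orientation = terms.REVERSE_COMPLEMENT
        assert evaluate_constraint(doc, con).status == \
            EvaluationResult.VIOLATED
        con2 = comp.add_constraint(SBOL3 + "oppositeOrientationAs", a, b)
        assert evaluate_constraint(doc, con2).status == \
            EvaluationResult.HOLDS

    def test_replaces_not_evaluable(self):
        doc, comp, a, b = _sequential_doc((1, 5), (6, 10))
        con = comp.add_constraint(SBOL3 + "replaces", a, b)
        assert evaluate_constraint(doc, con).status == \
            EvaluationResult.NOT_EVALUABLE


class TestCheckAll:
    def test_toggle_has_no_constraints(self, toggle_doc):
        assert check_all(toggle_doc) == []

    def test_single_satisfied_sequential_constraint(self):
        doc, comp, a, b = _sequential_doc((1, 5), (6, 10))
        comp.add_constraint(SBOL3 + "meets", a, b)
        results = check_all(doc)
        assert len(results) == 1
        assert results[0][1].status == EvaluationResult.HOLDS

    def test_violations_reported_not_raised(self):
        doc, comp, a, b = _sequential_doc((1, 5), (3, 9))
        comp.add_constraint(SBOL3 + "equals", a, b)
        results = check_all(doc)
        assert [res.status for _, res in results] == ["violated"]

    def test_order_is_deterministic(self, multicellular_doc):
        assert check_all(multicellular_doc) == check_all(multicellular_doc)


def test_restriction_vocabulary_closure():
    assert len(ALL_RESTRICTIONS) == 3 + 11 + 6
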
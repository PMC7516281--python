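"""Core object model: construction operations, ownership, lookup,
reference resolution."""

import pytest

from sbolkit import terms
from sbolkit.errors import (IdentityError, OwnershipError, ResolutionError,
                            VocabularyError)
from sbolkit.model import (MAIN_TOP_LEVEL_CLASSES, TOP_LEVEL_CLASSES,
                           Component, ComponentReference, Document,
                           LocalSubComponent, Sequence, SequenceFeature,
                           SubComponent, create_component, document_lookup,
                           resolve_reference)

NS = "http://example.com/toggleswitch"


def test_registry_exposes_ten_main_top_level_types():
    names = {cls.__name__ for cls in MAIN_TOP_LEVEL_CLASSES}
    assert len(MAIN_TOP_LEVEL_CLASSES) == 10
    assert names == {"Component", "Sequence", "CombinatorialDerivation",
                     "Implementation", "Experiment", "ExperimentalData",
                     "Model", "Collection", "Attachment", "Activity"}
    # the Namespace utility class is a top level but not one of the ten
    assert len(TOP_LEVEL_CLASSES) == 11


class TestCreateComponent:
    def test_uri_is_prefix_slash_display_id(self):
        comp = create_component(NS, "lacI", {terms.SBO_DNA})
        assert comp.uri == "http://example.com/toggleswitch/lacI"
        assert comp.features == [] and comp.interactions == []
        assert comp.constraints == [] and comp.interface is None

    def test_empty_types_rejected(self):
        with pytest.raises(VocabularyError):
            create_component("http://example.com", "x", set())

    def test_leading_digit_display_id_rejected(self):
        with pytest.raises(IdentityError):
            create_component("http://example.com", "1abc", {terms.SBO_DNA})


class TestAddFeature:
    def test_child_uri_extends_parent(self):
        comp = create_component("http://ex.org", "tu", {terms.SBO_DNA})
        sub = comp.add_feature(SubComponent("pTet"))
        assert sub.uri == "http://ex.org/tu/pTet"
        assert sub.owner is comp

    def test_unlocated_sequence_feature_rejected(self):
        comp = create_component("http://ex.org", "tu", {terms.SBO_DNA})
        with pytest.raises(OwnershipError):
            comp.add_feature(SequenceFeature("naked"))

    def test_duplicate_display_id_rejected(self):
        comp = create_component("http://ex.org", "tu", {terms.SBO_DNA})
        comp.add_feature(LocalSubComponent("f1", types={terms.SBO_DNA}))
        with pytest.raises(OwnershipError):
            comp.add_feature(LocalSubComponent("f1", types={terms.SBO_DNA}))


class TestAddInteraction:
    def _component_with_parts(self):
        comp = create_component(NS, "unit", {terms.SBO_DNA})
        cds = comp.add_feature(LocalSubComponent("cds", types={terms.SBO_DNA}))
        promoter = comp.add_feature(
            LocalSubComponent("promoter", types={terms.SBO_DNA}))
        return comp, cds, promoter

    def test_repression_interaction(self):
        comp, cds, promoter = self._component_with_parts()
        inter = comp.add_interaction(
            types={terms.SBO_INHIBITION},
            participations=[({terms.SBO_INHIBITOR}, cds),
                            ({terms.SBO_INHIBITED}, promoter)])
        assert len(inter.participations) == 2
        assert {p.participant for p in inter.participations} == \
            {cds.uri, promoter.uri}

    def test_foreign_participant_rejected(self):
        comp, cds, _ = self._component_with_parts()
        other = create_component(NS, "other", {terms.SBO_DNA})
        foreign = other.add_feature(
            LocalSubComponent("x", types={terms.SBO_DNA}))
        with pytest.raises(OwnershipError):
            comp.add_interaction(types={terms.SBO_INHIBITION},
                                 participations=[({terms.SBO_INHIBITOR},
                                                  foreign)])

    def test_empty_participations_allowed(self):
        comp, _, _ = self._component_with_parts()
        inter = comp.add_interaction(types={terms.SBO_INHIBITION})
        assert inter.participations == []

    def test_empty_types_rejected(self):
        comp, _, _ = self._component_with_parts()
        with pytest.raises(VocabularyError):
            comp.add_interaction(types=set())


class TestSetInterface:
    def test_nor_gate_shape(self, nor_gate_doc):
        gate = nor_gate_doc.lookup("http://example.com/norgate/nor_gate")
        assert len(gate.interface.inputs) == 2
        assert len(gate.interface.outputs) == 1

    def test_empty_interface_is_valid(self):
        comp = create_component(NS, "empty", {terms.SBO_DNA})
        iface = comp.set_interface()
        assert comp.interface is iface
        assert not (iface.inputs or iface.outputs or iface.nondirectionals)

    def test_foreign_reference_rejected(self):
        comp = create_component(NS, "c1", {terms.SBO_DNA})
        other = create_component(NS, "c2", {terms.SBO_DNA})
        foreign = other.add_feature(
            LocalSubComponent("x", types={terms.SBO_DNA}))
        with pytest.raises(OwnershipError):
            comp.set_interface(inputs=[foreign])

    def test_nondirectional_overlap_rejected(self):
        comp = create_component(NS, "c3", {terms.SBO_DNA})
        f = comp.add_feature(LocalSubComponent("x", types={terms.SBO_DNA}))
        with pytest.raises(OwnershipError):
            comp.set_interface(inputs=[f], nondirectionals=[f])


class TestResolveReference:
    def test_multicellular_ahl_reference(self, multicellular_doc):
        system = multicellular_doc.lookup(
            "http://example.com/multicellular/multicellular_system")
        ref = system.find_feature(system.uri + "/sender_ahl")
        target = resolve_reference(multicellular_doc, ref)
        assert target.uri == \
            "http://example.com/multicellular/sender_system/AHL"
        assert target.definition == terms.CHEBI("51451")

    def test_multi_layer_chain(self):
        doc = Document()
        ns = "http://example.com/layers"
        inner = create_component(ns, "inner", {terms.SBO_DNA})
        leaf = inner.add_feature(
            LocalSubComponent("leaf", types={terms.SBO_DNA}))
        middle = create_component(ns, "middle", {terms.SBO_DNA})
        inner_sub = middle.add_feature(SubComponent("inner_sub",
                                                    instance_of=inner))
        mid_ref = middle.add_feature(ComponentReference(
            "leaf_ref", in_child_of=inner_sub, refers_to=leaf))
        outer = create_component(ns, "outer", {terms.SBO_DNA})
        middle_sub = outer.add_feature(SubComponent("middle_sub",
                                                    instance_of=middle))
        outer_ref = outer.add_feature(ComponentReference(
            "deep_ref", in_child_of=middle_sub, refers_to=mid_ref))
        for obj in (inner, middle, outer):
            doc.add(obj)
        assert resolve_reference(doc, outer_ref) is leaf

    def test_cycle_detected(self):
        doc = Document()
        ns = "http://example.com/cycle"
        a = create_component(ns, "a", {terms.SBO_DNA})
        b = create_component(ns, "b", {terms.SBO_DNA})
        a_sub_b = a.add_feature(SubComponent("b_sub", instance_of=b))
        b_sub_a = b.add_feature(SubComponent("a_sub", instance_of=a))
        ref_in_a = a.add_feature(ComponentReference(
            "ref", in_child_of=a_sub_b,
            refers_to=ns + "/b/ref"))
        b.add_feature(ComponentReference(
            "ref", in_child_of=b_sub_a, refers_to=ref_in_a))
        doc.add(a)
        doc.add(b)
        with pytest.raises(ResolutionError):
            resolve_reference(doc, ref_in_a)


class TestDocumentLookup:
    def test_finds_top_level_and_descendants(self, autoreg_doc):
        tu = document_lookup(autoreg_doc,
                             "http://example.com/autoreg/autoreg_unit")
        assert isinstance(tu, Component)
        child = document_lookup(
            autoreg_doc, "http://example.com/autoreg/autoreg_unit/pTF_sub")
        assert isinstance(child, SubComponent)

    def test_unknown_uri_returns_none(self, autoreg_doc):
        assert document_lookup(autoreg_doc, "http://nowhere/x") is None

    def test_duplicate_uri_rejected(self):
        doc = Document()
        doc.add(create_component(NS, "dup", {terms.SBO_DNA}))
        with pytest.raises(IdentityError):
            doc.add(create_component(NS, "dup", {terms.SBO_DNA}))


def test_child_uri_closure(any_fixture_doc):
    """Every owned descendant's URI starts with its owner's URI + '/'."""
    checked = 0
    for obj in any_fixture_doc.walk():
        for child in obj.children():
            assert child.uri.startswith(obj.uri + "/")
            checked += 1
    assert checked > 0


def test_reference_closure(any_fixture_doc):
    """Every internal reference in a fixture resolves by lookup."""
    doc = any_fixture_doc
    namespaces = {ns for ns in doc.namespaces()}

    def internal(uri):
        return any(uri.startswith(ns + "/") or uri == ns
                   for ns in namespaces)

    refs = []
    for comp in doc.components:
        refs.extend(comp.sequences)
        for f in comp.features:
            if isinstance(f, SubComponent) and f.instance_of:
                refs.append(f.instance_of)
            if isinstance(f, ComponentReference):
                refs.extend([f.in_child_of, f.refers_to])
        for inter in comp.interactions:
            refs.extend(p.participant for p in inter.participations)
        for con in comp.constraints:
            refs.extend([con.subject, con.object])
    internal_refs = [r for r in refs if internal(r)]
    assert internal_refs, "fixture should contain internal references"
    for ref in internal_refs:
        assert doc.lookup(ref) is not None, ref


def test_toggle_single_occurrence(toggle_doc):
    """Each design element occurs exactly once; no identity mappings."""
    part_uses = {}
    for comp in toggle_doc.components:
        for f in comp.features:
            assert not isinstance(f, ComponentReference)
            if isinstance(f, SubComponent):
                part_uses[f.instance_of] = part_uses.get(f.instance_of, 0) + 1
    assert part_uses and all(n == 1 for n in part_uses.values())


def test_type_totality(any_fixture_doc):
    for comp in any_fixture_doc.components:
        assert comp.types
        for f in comp.features:
            if isinstance(f, SequenceFeature):
                assert len(f.locations) >= 1


def test_sequences_are_encoded(any_fixture_doc):
    for top in any_fixture_doc:
        if isinstance(top, Sequence) and top.elements is not None:
            assert top.encoding is not None
            assert set(top.elements) <= terms.ENCODING_ALPHABETS[top.encoding]
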
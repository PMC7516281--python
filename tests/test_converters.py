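"""GenBank/FASTA import, GenBank export round-trip, SBOL2 migration."""

import warnings

import pytest

from sbolkit import terms
from sbolkit.convert import (component_to_genbank, fasta_to_sequence,
                             genbank_to_component, read_sbol2,
                             sbol2_to_sbol3, write_genbank)
from sbolkit.convert.genbank import GENBANK_KEY_PRED, ConversionWarning
from sbolkit.convert.sbol2 import (S2ComponentDefinition,
                                   S2FunctionalComponent,
                                   S2ModuleDefinition,
                                   S2SequenceAnnotation, Sbol2Snapshot)
from sbolkit.errors import ConversionError
from sbolkit.fixtures import build_sbol2_toggle_switch
from sbolkit.model import (ComponentReference, Document, SequenceFeature,
                           SubComponent)
from sbolkit.validator import errors_only, validate_document

GENBANK_ONE_CDS = """LOCUS       demo                      50 bp    DNA     linear   SYN 01-JAN-2020
DEFINITION  synthetic demo construct.
ACCESSION   demo
FEATURES             Location/Qualifiers
     CDS             10..30
                     /label=demo_cds
ORIGIN
        1 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac
//
"""

GENBANK_DIALECTS = """LOCUS       dialects                  60 bp    DNA     linear   SYN 01-JAN-2020
DEFINITION  location dialect exercise.
FEATURES             Location/Qualifiers
     promoter        complement(5..8)
     misc_feature    join(35..40,45..48)
     CDS             <10..30
     weird_key       50..55
ORIGIN
        1 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac
       51 acgtacgtac
//
"""

GENBANK_NO_FEATURES = """LOCUS       plain                     20 bp    DNA     linear   SYN 01-JAN-2020
DEFINITION  featureless record.
ORIGIN
        1 acgtacgtac gtacgtacgt
//
"""


class TestGenbankImport:
    def test_single_cds_record(self):
        comp, seq = genbank_to_component(GENBANK_ONE_CDS)
        assert seq.elements == ("ACGT" * 13)[:50]
        assert seq.encoding == terms.ENC_IUPAC_DNA
        assert comp.types == {terms.SBO_DNA}
        assert len(comp.features) == 1
        feature = comp.features[0]
        assert feature.roles == {terms.SO_CDS}
        (rng,) = feature.locations
        assert (rng.start, rng.end) == (10, 30)

    def test_location_dialects(self):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            comp, _ = genbank_to_component(GENBANK_DIALECTS)
        by_key = {str(dict(f.annotations)[GENBANK_KEY_PRED]): f
                  for f in comp.features}
        promoter = by_key["promoter"]
        assert promoter.orientation == terms.REVERSE_COMPLEMENT
        assert [(l.start, l.end) for l in promoter.locations] == [(5, 8)]
        join = by_key["misc_feature"]
        assert [(l.start, l.end) for l in join.locations] == \
            [(35, 40), (45, 48)]
        fuzzy = by_key["CDS"]
        assert [(l.start, l.end) for l in fuzzy.locations] == [(10, 30)]
        unknown = by_key["weird_key"]
        assert unknown.roles == {terms.SO_SEQUENCE_FEATURE}
        messages = [str(w.message) for w in caught
                    if issubclass(w.category, ConversionWarning)]
        assert any("fuzzy" in m for m in messages)
        assert any("weird_key" in m for m in messages)

    def test_record_without_features(self):
        comp, seq = genbank_to_component(GENBANK_NO_FEATURES)
        assert comp.features == []
        assert len(seq.elements) == 20

    def test_import_validates_cleanly(self):
        comp, seq = genbank_to_component(GENBANK_ONE_CDS)
        doc = Document()
        doc.add(seq)
        doc.add(comp)
        assert errors_only(validate_document(doc)) == []


def _feature_table(comp):
    return [
        (str(dict(f.annotations).get(GENBANK_KEY_PRED)),
         tuple((l.start, l.end) for l in f.locations),
         f.orientation)
        for f in comp.features
    ]


class TestGenbankRoundTrip:
    @pytest.mark.parametrize("text", [GENBANK_ONE_CDS, GENBANK_DIALECTS,
                                      GENBANK_NO_FEATURES])
    def test_feature_table_identical(self, text):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            comp, seq = genbank_to_component(text)
            doc = Document()
            doc.add(seq)
            doc.add(comp)
            comp2, seq2 = genbank_to_component(
                write_genbank(component_to_genbank(comp, doc)))
        assert _feature_table(comp) == _feature_table(comp2)
        assert seq.elements == seq2.elements

    def test_unlocated_subcomponent_omitted_with_warning(self, autoreg_doc):
        tu = autoreg_doc.lookup("http://example.com/autoreg/autoreg_unit")
        tu.features[0].locations.clear()
        with pytest.warns(ConversionWarning):
            record = component_to_genbank(tu, autoreg_doc)
        assert len(record.features) == 3

    def test_protein_component_rejected(self):
        from sbolkit.model import create_component
        comp = create_component("http://x.org", "prot",
                                {terms.SBO_PROTEIN})
        with pytest.raises(ConversionError):
            component_to_genbank(comp, Document())


class TestFasta:
    def test_dna_record(self):
        seq = fasta_to_sequence(">x\nacgt\n")
        assert seq.elements == "ACGT"
        assert seq.encoding == terms.ENC_IUPAC_DNA

    def test_protein_record(self):
        seq = fasta_to_sequence(">p\nMKV\n")
        assert seq.encoding == terms.ENC_IUPAC_PROTEIN

    def test_rna_record(self):
        seq = fasta_to_sequence(">r\nacgu\n")
        assert seq.encoding == terms.ENC_IUPAC_RNA

    def test_empty_record_rejected(self):
        with pytest.raises(ConversionError):
            fasta_to_sequence(">e\n\n")

    def test_explicit_encoding_override(self):
        seq = fasta_to_sequence(">amb\nMKWSN\n",
                                encoding=terms.ENC_IUPAC_PROTEIN)
        assert seq.encoding == terms.ENC_IUPAC_PROTEIN


class TestSbol2Migration:
    def test_toggle_collapse(self):
        """The classic toggle-switch migration: all MapsTo links collapse,
        no ComponentReference objects are created, every promoter/CDS
        survives exactly once."""
        snapshot = build_sbol2_toggle_switch()
        doc, report = sbol2_to_sbol3(snapshot)
        assert [o for o in doc.walk()
                if isinstance(o, ComponentReference)] == []
        uses = [o.instance_of for o in doc.walk()
                if isinstance(o, SubComponent)]
        assert len(uses) == len(set(uses)) == 4
        assert len(report.collapsed_maps_tos) == 4
        assert report.component_references == []
        assert errors_only(validate_document(doc)) == []

    def test_element_conservation(self):
        snapshot = build_sbol2_toggle_switch()
        before = {inst.definition
                  for cd in snapshot.component_definitions
                  for inst in cd.components}
        doc, _ = sbol2_to_sbol3(snapshot)
        after = {o.instance_of for o in doc.walk()
                 if isinstance(o, SubComponent)}
        assert before == after

    def test_maps_to_accounting(self):
        snapshot = build_sbol2_toggle_switch()
        total_maps_tos = sum(len(fc.maps_tos)
                             for md in snapshot.module_definitions
                             for fc in md.functional_components)
        _, report = sbol2_to_sbol3(snapshot)
        assert total_maps_tos == (len(report.collapsed_maps_tos)
                                  + len(report.component_references))

    def test_report_arithmetic(self):
        snapshot = build_sbol2_toggle_switch()
        _, report = sbol2_to_sbol3(snapshot)
        assert report.converted_total + len(report.unconvertible) == \
            snapshot.total_objects()

    def test_lone_cd_with_unlinked_annotation(self):
        cd = S2ComponentDefinition(
            uri="http://ex.org/cd", display_id="cd",
            types={terms.SBO_DNA},
            sequence_annotations=[S2SequenceAnnotation(
                uri="http://ex.org/cd/sa", display_id="sa",
                roles={terms.SO_CDS}, ranges=[(10, 30)])],
            sequence_elements="ACGT" * 10)
        doc, report = sbol2_to_sbol3(Sbol2Snapshot(
            component_definitions=[cd]))
        comp = doc.lookup("http://ex.org/cd")
        feats = [f for f in comp.features if isinstance(f, SequenceFeature)]
        assert len(feats) == 1
        assert [(l.start, l.end) for l in feats[0].locations] == [(10, 30)]
        assert report.converted["SequenceAnnotation->SequenceFeature"] == 1

    def test_direction_becomes_interface_membership(self):
        cd_in = S2ComponentDefinition("http://ex.org/sig_in", "sig_in",
                                      types={terms.SBO_PROTEIN})
        cd_out = S2ComponentDefinition("http://ex.org/sig_out", "sig_out",
                                       types={terms.SBO_PROTEIN})
        md = S2ModuleDefinition(
            uri="http://ex.org/gate", display_id="gate",
            functional_components=[
                S2FunctionalComponent("http://ex.org/gate/in_fc", "in_fc",
                                      definition=cd_in.uri, direction="in"),
                S2FunctionalComponent("http://ex.org/gate/out_fc", "out_fc",
                                      definition=cd_out.uri,
                                      direction="out"),
            ])
        doc, _ = sbol2_to_sbol3(Sbol2Snapshot(
            component_definitions=[cd_in, cd_out],
            module_definitions=[md]))
        gate = doc.lookup("http://ex.org/gate")
        assert gate.interface is not None
        assert {u.split("/")[-1] for u in gate.interface.inputs} == {"in_fc"}
        assert {u.split("/")[-1] for u in gate.interface.outputs} == \
            {"out_fc"}

    def test_access_dropped_with_report_entry(self):
        snapshot = build_sbol2_toggle_switch()
        _, report = sbol2_to_sbol3(snapshot)
        assert report.dropped_access  # SBOL2 access has no SBOL3 home

    def test_dangling_reference_rejected(self):
        cd = S2ComponentDefinition("http://ex.org/cd", "cd")
        md = S2ModuleDefinition(
            uri="http://ex.org/md", display_id="md",
            functional_components=[S2FunctionalComponent(
                "http://ex.org/md/fc", "fc",
                definition="http://ex.org/missing")])
        with pytest.raises(ConversionError):
            sbol2_to_sbol3(Sbol2Snapshot(component_definitions=[cd],
                                         module_definitions=[md]))


class TestSbol2Reader:
    RDF = """<?xml version="1.0"?>
<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
         xmlns:sbol="http://sbols.org/v2#">
  <sbol:ComponentDefinition rdf:about="http://ex.org/cd1/1">
    <sbol:persistentIdentity rdf:resource="http://ex.org/cd1"/>
    <sbol:version>1</sbol:version>
    <sbol:displayId>cd1</sbol:displayId>
    <sbol:type rdf:resource="https://identifiers.org/SBO:0000251"/>
    <sbol:sequenceAnnotation>
      <sbol:SequenceAnnotation rdf:about="http://ex.org/cd1/1/sa1">
        <sbol:displayId>sa1</sbol:displayId>
        <sbol:role rdf:resource="https://identifiers.org/SO:0000316"/>
        <sbol:location>
          <sbol:Range rdf:about="http://ex.org/cd1/1/sa1/r1">
            <sbol:start>10</sbol:start>
            <sbol:end>30</sbol:end>
            <sbol:orientation
                rdf:resource="http://sbols.org/v2#reverseComplement"/>
          </sbol:Range>
        </sbol:location>
      </sbol:SequenceAnnotation>
    </sbol:sequenceAnnotation>
  </sbol:ComponentDefinition>
</rdf:RDF>"""

    def test_reader_folds_version_into_prefix(self):
        snapshot = read_sbol2(self.RDF)
        cd = snapshot.component_definitions[0]
        assert cd.uri == "http://ex.org/1/cd1"
        sa = cd.sequence_annotations[0]
        assert sa.ranges == [(10, 30)] and sa.reverse

    def test_reader_output_migrates(self):
        doc, report = sbol2_to_sbol3(read_sbol2(self.RDF))
        comp = doc.lookup("http://ex.org/1/cd1")
        assert comp is not None
        assert report.converted["ComponentDefinition->Component"] == 1
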
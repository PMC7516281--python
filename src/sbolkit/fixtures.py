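"""Programmatic builders for a small corpus of canonical genetic designs.

These cover the classic demonstration systems for a multi-scale design
standard: an auto-regulatory transcription unit, the Gardner toggle switch,
a two-organism sender/receiver signaling system, a CRISPRi NOR logic gate,
and a combinatorial promoter library template.  Each builder is
deterministic — fixed URIs under ``http://example.com/…``, no randomness —
so repeated builds produce graph-identical documents.

Part sequences are short synthetic placeholder DNA (20–60 nt per part),
enough to exercise Range bookkeeping without real accessions.
"""
from __future__ import annotations

from . import terms
from .constraints import SBOL3_TOPOLOGY
from .model import (CombinatorialDerivation, Component, ComponentReference,
                    Document, ExternallyDefined, LocalSubComponent, Range,
                    Sequence, SequenceFeature, SubComponent, VariableFeature,
                    create_component)
from .terms import SBOL3

#: representative ChEBI record for an N-acyl homoserine lactone signal
CHEBI_AHL = terms.CHEBI("51451")

_PART_SEQS = {
    "promoter": "TTGACAATTAATCATCGGCTCGTATAATGT",           # 30 nt
    "rbs": "AAAGAGGAGAAATACTAG",                            # 18 nt
    "cds": "ATGGCTAGCAAAGGAGAAGAACTTTTCACTGGAGTTGTCCCAATT",  # 45 nt
    "terminator": "CCAGGCATCAAATAAAACGAAAGGCTCAGTCG",       # 32 nt
}


def _add_part(doc: Document, ns: str, display_id: str, role: str,
              elements: str, types=None) -> Component:
    part = create_component(ns, display_id, types or {terms.SBO_DNA})
    part.roles.add(role)
    seq = Sequence(ns, display_id + "_seq", elements=elements,
                   encoding=terms.ENC_IUPAC_DNA)
    part.add_sequence(seq)
    doc.add(seq)
    doc.add(part)
    return part


def _layout(parent: Component, parent_seq: Sequence,
            parts: list[tuple[str, Component, str]]) -> dict[str, SubComponent]:
    """Concatenate part sequences onto the parent sequence and place one
    located SubComponent per part."""
    subs: dict[str, SubComponent] = {}
    offset = 0
    elements = []
    for display_id, part, part_elements in parts:
        start = offset + 1
        end = offset + len(part_elements)
        sub = SubComponent(display_id, instance_of=part,
                           orientation=terms.INLINE)
        parent.add_feature(sub)
        sub.add_location(Range(parent_seq, start, end))
        subs[display_id] = sub
        elements.append(part_elements)
        offset = end
    parent_seq.elements = "".join(elements)
    return subs


def build_autoregulatory_device() -> Document:
    """A transcription unit — promoter, RBS, CDS, terminator — whose encoded
    transcription factor represses its own promoter: one Component, four
    SubComponents, one repression Interaction."""
    doc = Document()
    ns = "http://example.com/autoreg"
    promoter = _add_part(doc, ns, "pTF", terms.SO_PROMOTER,
                         _PART_SEQS["promoter"])
    rbs = _add_part(doc, ns, "rbs", terms.SO_RBS, _PART_SEQS["rbs"])
    cds = _add_part(doc, ns, "tf_cds", terms.SO_CDS, _PART_SEQS["cds"])
    terminator = _add_part(doc, ns, "term", terms.SO_TERMINATOR,
                           _PART_SEQS["terminator"])

    tu = create_component(ns, "autoreg_unit", {terms.SBO_DNA})
    tu.roles.add(terms.SO_ENGINEERED_REGION)
    tu_seq = Sequence(ns, "autoreg_unit_seq", encoding=terms.ENC_IUPAC_DNA)
    tu.add_sequence(tu_seq)
    subs = _layout(tu, tu_seq, [
        ("pTF_sub", promoter, _PART_SEQS["promoter"]),
        ("rbs_sub", rbs, _PART_SEQS["rbs"]),
        ("tf_cds_sub", cds, _PART_SEQS["cds"]),
        ("term_sub", terminator, _PART_SEQS["terminator"]),
    ])
    tu.add_interaction(
        types={terms.SBO_INHIBITION},
        participations=[
            ({terms.SBO_INHIBITOR}, subs["tf_cds_sub"]),
            ({terms.SBO_INHIBITED}, subs["pTF_sub"]),
        ],
        display_id="autorepression")
    doc.add(tu_seq)
    doc.add(tu)
    return doc


def build_toggle_switch() -> Document:
    """The Gardner genetic toggle switch: two transcription units whose CDS
    products mutually repress each other's promoter.

    Structure and function co-exist in one parent Component: every design
    element (each promoter, RBS, CDS, terminator) appears exactly once as a
    directly-owned SubComponent, both repression Interactions use local
    participants, and no identity-mapping objects exist.
    """
    doc = Document()
    ns = "http://example.com/toggleswitch"
    parts = {
        "pLac": _add_part(doc, ns, "pLac", terms.SO_PROMOTER,
                          _PART_SEQS["promoter"]),
        "lacI_rbs": _add_part(doc, ns, "lacI_rbs", terms.SO_RBS,
                              _PART_SEQS["rbs"]),
        "lacI_cds": _add_part(doc, ns, "lacI_cds", terms.SO_CDS,
                              _PART_SEQS["cds"]),
        "lacI_term": _add_part(doc, ns, "lacI_term", terms.SO_TERMINATOR,
                               _PART_SEQS["terminator"]),
        "pTet": _add_part(doc, ns, "pTet", terms.SO_PROMOTER,
                          _PART_SEQS["promoter"]),
        "tetR_rbs": _add_part(doc, ns, "tetR_rbs", terms.SO_RBS,
                              _PART_SEQS["rbs"]),
        "tetR_cds": _add_part(doc, ns, "tetR_cds", terms.SO_CDS,
                              _PART_SEQS["cds"]),
        "tetR_term": _add_part(doc, ns, "tetR_term", terms.SO_TERMINATOR,
                               _PART_SEQS["terminator"]),
    }
    toggle = create_component(ns, "toggle_switch", {terms.SBO_DNA})
    toggle.roles.add(terms.SO_ENGINEERED_REGION)
    toggle_seq = Sequence(ns, "toggle_switch_seq",
                          encoding=terms.ENC_IUPAC_DNA)
    toggle.add_sequence(toggle_seq)
    order = ["pTet", "lacI_rbs", "lacI_cds", "lacI_term",
             "pLac", "tetR_rbs", "tetR_cds", "tetR_term"]
    seq_key = {"pLac": "promoter", "pTet": "promoter",
               "lacI_rbs": "rbs", "tetR_rbs": "rbs",
               "lacI_cds": "cds", "tetR_cds": "cds",
               "lacI_term": "terminator", "tetR_term": "terminator"}
    subs = _layout(toggle, toggle_seq,
                   [(name, parts[name], _PART_SEQS[seq_key[name]])
                    for name in order])
    toggle.add_interaction(
        types={terms.SBO_INHIBITION},
        participations=[({terms.SBO_INHIBITOR}, subs["lacI_cds"]),
                        ({terms.SBO_INHIBITED}, subs["pLac"])],
        display_id="lacI_represses_pLac")
    toggle.add_interaction(
        types={terms.SBO_INHIBITION},
        participations=[({terms.SBO_INHIBITOR}, subs["tetR_cds"]),
                        ({terms.SBO_INHIBITED}, subs["pTet"])],
        display_id="tetR_represses_pTet")
    doc.add(toggle_seq)
    doc.add(toggle)
    return doc


def _signaling_subsystem(doc: Document, ns: str, display_id: str) -> Component:
    system = create_component(ns, display_id, {terms.SBO_FUNCTIONAL_ENTITY})
    system.roles.add(terms.SBO_FUNCTIONAL_COMPARTMENT)
    cell = LocalSubComponent("cell", types={terms.GO_CELL},
                             roles={terms.SBO_PHYSICAL_COMPARTMENT})
    system.add_feature(cell)
    ahl = ExternallyDefined("AHL", types={terms.SBO_SIMPLE_CHEMICAL},
                            definition=CHEBI_AHL)
    system.add_feature(ahl)
    # spatial structure: the cell contains the signaling molecule
    system.add_constraint(SBOL3_TOPOLOGY + "contains", cell, ahl,
                          display_id="cell_contains_ahl")
    doc.add(system)
    return system


def build_multicellular_system() -> Document:
    """Two organisms communicating through a small molecule (AHL): sender
    and receiver subsystems, each a functional compartment containing a
    cell, with a verifyIdentical constraint recording that the AHL leaving
    the sender is the AHL entering the receiver."""
    doc = Document()
    ns = "http://example.com/multicellular"
    sender = _signaling_subsystem(doc, ns, "sender_system")
    receiver = _signaling_subsystem(doc, ns, "receiver_system")

    system = create_component(ns, "multicellular_system",
                              {terms.SBO_FUNCTIONAL_ENTITY})
    sender_sub = SubComponent("sender", instance_of=sender)
    receiver_sub = SubComponent("receiver", instance_of=receiver)
    system.add_feature(sender_sub)
    system.add_feature(receiver_sub)
    sender_ahl = ComponentReference(
        "sender_ahl", in_child_of=sender_sub,
        refers_to=sender.find_feature(sender.uri + "/AHL"))
    receiver_ahl = ComponentReference(
        "receiver_ahl", in_child_of=receiver_sub,
        refers_to=receiver.find_feature(receiver.uri + "/AHL"))
    system.add_feature(sender_ahl)
    system.add_feature(receiver_ahl)
    system.add_constraint(SBOL3 + "verifyIdentical", sender_ahl,
                          receiver_ahl, display_id="shared_ahl")
    doc.add(system)
    return doc


def build_nor_gate() -> Document:
    """A CRISPRi NOR gate: two gRNA inputs regulate a DNA component (two
    binding sites, a promoter, a gRNA coding sequence) that produces the
    gRNA output; the Interface declares two inputs and one output."""
    doc = Document()
    ns = "http://example.com/norgate"

    grnas = {}
    for name in ("gRNA_in1_def", "gRNA_in2_def", "gRNA_out_def"):
        grna = create_component(ns, name, {terms.SBO_RNA})
        grna.roles.add(terms.SO_SGRNA)
        doc.add(grna)
        grnas[name] = grna

    dna = create_component(ns, "nor_dna", {terms.SBO_DNA})
    dna.roles.add(terms.SO_ENGINEERED_REGION)
    dna_seq = Sequence(
        ns, "nor_dna_seq",
        elements=("GCTAGCTAGCTAGCTAGCTA" "TTGACAATTAATCATCGGCTCGTATAATGT"
                  "TAGCTAGCTAGCTAGCTAGC"
                  "ATGGCTAGCAAAGGAGAAGAACTTTTCACT"),
        encoding=terms.ENC_IUPAC_DNA)
    dna.add_sequence(dna_seq)
    for display_id, role, start, end in (
            ("binding_site_1", terms.SO_OPERATOR, 1, 20),
            ("promoter", terms.SO_PROMOTER, 21, 50),
            ("binding_site_2", terms.SO_OPERATOR, 51, 70),
            ("gRNA_out_cds", terms.SO_CDS, 71, 100)):
        dna.add_feature(SequenceFeature(
            display_id, roles={role},
            locations=[Range(dna_seq, start, end)]))
    doc.add(dna_seq)
    doc.add(dna)

    gate = create_component(ns, "nor_gate", {terms.SBO_FUNCTIONAL_ENTITY})
    in1 = SubComponent("gRNA_in1", instance_of=grnas["gRNA_in1_def"])
    in2 = SubComponent("gRNA_in2", instance_of=grnas["gRNA_in2_def"])
    dna_sub = SubComponent("regulated_dna", instance_of=dna)
    out = SubComponent("gRNA_out", instance_of=grnas["gRNA_out_def"])
    for sub in (in1, in2, dna_sub, out):
        gate.add_feature(sub)
    gate.add_interaction(
        types={terms.SBO_INHIBITION},
        participations=[({terms.SBO_INHIBITOR}, in1),
                        ({terms.SBO_INHIBITOR}, in2),
                        ({terms.SBO_INHIBITED}, dna_sub)],
        display_id="inputs_repress_dna")
    gate.add_interaction(
        types={terms.SBO_GENETIC_PRODUCTION},
        participations=[({terms.SBO_TEMPLATE}, dna_sub),
                        ({terms.SBO_PRODUCT}, out)],
        display_id="dna_produces_output")
    gate.set_interface(inputs=[in1, in2], outputs=[out])
    doc.add(gate)
    return doc


def build_combinatorial_template() -> Document:
    """A combinatorial library template: a placeholder promoter slot
    ("put a promoter in this location") bound to three variant promoters."""
    doc = Document()
    ns = "http://example.com/library"
    variants = []
    for i, elements in enumerate((
            "TTGACAATTAATCATCGGCTCGTATAATGT",
            "TTTACAGCTAGCTCAGTCCTAGGTATAATG",
            "CTGACAGCTAGCTCAGTCCTAGGTATTGTG"), start=1):
        variants.append(_add_part(doc, ns, f"promoter_v{i}",
                                  terms.SO_PROMOTER, elements))

    template = create_component(ns, "template", {terms.SBO_DNA})
    slot = LocalSubComponent("promoter_slot", types={terms.SBO_DNA},
                             roles={terms.SO_PROMOTER})
    template.add_feature(slot)
    cds = _add_part(doc, ns, "payload_cds", terms.SO_CDS, _PART_SEQS["cds"])
    payload = SubComponent("payload", instance_of=cds)
    template.add_feature(payload)
    doc.add(template)

    derivation = CombinatorialDerivation(
        ns, "promoter_library", template=template,
        strategy=terms.STRATEGY_ENUMERATE)
    derivation.add_variable_feature(VariableFeature(
        "promoter_choice", variable=slot,
        cardinality=terms.CARDINALITY_ONE, variants=variants))
    doc.add(derivation)
    return doc


def build_sbol2_toggle_switch():
    """The toggle switch the SBOL2 way: two transcription-unit
    ComponentDefinitions, a system ModuleDefinition that re-instantiates
    their promoters and CDSs as FunctionalComponents, and four MapsTo links
    declaring the copies identical — the shape migration collapses."""
    from .convert.sbol2 import (S2ComponentDefinition, S2ComponentInstance,
                                S2FunctionalComponent, S2Interaction,
                                S2MapsTo, S2ModuleDefinition, Sbol2Snapshot)

    ns = "http://example.com/sbol2toggle"

    def cd(name, roles=()):
        return S2ComponentDefinition(
            uri=f"{ns}/{name}", display_id=name,
            types={terms.SBO_DNA}, roles=set(roles))

    parts = {name: cd(name, roles={role}) for name, role in (
        ("pLac", terms.SO_PROMOTER), ("lacI_cds", terms.SO_CDS),
        ("pTet", terms.SO_PROMOTER), ("tetR_cds", terms.SO_CDS))}

    def unit(name, promoter, cds):
        tu = cd(name, roles={terms.SO_ENGINEERED_REGION})
        for part in (promoter, cds):
            tu.components.append(S2ComponentInstance(
                uri=f"{tu.uri}/{part.display_id}", display_id=part.display_id,
                definition=part.uri, access="public"))
        return tu

    lacI_unit = unit("lacI_unit", parts["pLac"], parts["lacI_cds"])
    tetR_unit = unit("tetR_unit", parts["pTet"], parts["tetR_cds"])

    md = S2ModuleDefinition(uri=f"{ns}/toggle_module",
                            display_id="toggle_module")
    fc_by_name = {}
    for name in ("pLac", "lacI_cds", "pTet", "tetR_cds"):
        fc = S2FunctionalComponent(
            uri=f"{md.uri}/{name}_fc", display_id=f"{name}_fc",
            definition=parts[name].uri, access="public", direction="none")
        fc_by_name[name] = fc
        md.functional_components.append(fc)
    for tu, names in ((lacI_unit, ("pLac", "lacI_cds")),
                      (tetR_unit, ("pTet", "tetR_cds"))):
        holder = S2FunctionalComponent(
            uri=f"{md.uri}/{tu.display_id}_fc",
            display_id=f"{tu.display_id}_fc",
            definition=tu.uri, access="public", direction="none")
        for name in names:
            holder.maps_tos.append(S2MapsTo(
                uri=f"{holder.uri}/map_{name}",
                local=fc_by_name[name].uri,
                remote=f"{tu.uri}/{name}"))
        md.functional_components.append(holder)
    md.interactions = [
        S2Interaction(
            uri=f"{md.uri}/lacI_represses_pLac",
            display_id="lacI_represses_pLac",
            types={terms.SBO_INHIBITION},
            participations=[({terms.SBO_INHIBITOR}, fc_by_name["lacI_cds"].uri),
                            ({terms.SBO_INHIBITED}, fc_by_name["pLac"].uri)]),
        S2Interaction(
            uri=f"{md.uri}/tetR_represses_pTet",
            display_id="tetR_represses_pTet",
            types={terms.SBO_INHIBITION},
            participations=[({terms.SBO_INHIBITOR}, fc_by_name["tetR_cds"].uri),
                            ({terms.SBO_INHIBITED}, fc_by_name["pTet"].uri)]),
    ]
    return Sbol2Snapshot(
        component_definitions=[*parts.values(), lacI_unit, tetR_unit],
        module_definitions=[md], namespace=ns)


FIXTURE_BUILDERS = {
    "autoregulatory_device": build_autoregulatory_device,
    "toggle_switch": build_toggle_switch,
    "multicellular_system": build_multicellular_system,
    "nor_gate": build_nor_gate,
    "combinatorial_template": build_combinatorial_template,
}


def export_fixtures(directory, format: str = "turtle") -> list[str]:
    """Write the whole corpus to *directory*; returns the paths written."""
    import os

    from . import rdf_io

    extension = {"turtle": ".ttl", "ntriples": ".nt",
                 "jsonld": ".jsonld", "rdfxml": ".rdf"}
    os.makedirs(directory, exist_ok=True)
    written = []
    for name, builder in FIXTURE_BUILDERS.items():
        path = os.path.join(directory, name + extension.get(format, ".ttl"))
        rdf_io.write_file(builder(), path, format)
        written.append(path)
    return written
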
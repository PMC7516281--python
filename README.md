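# sbolkit

Work with **SBOL3** — the third major version of the Synthetic Biology Open
Language, the RDF-based data standard for engineered biological designs.

Synthetic biologists need to exchange far more than sequences: a design is a
hierarchy of parts (promoters, RBSs, CDSs, terminators, whole plasmids,
strains, even multicellular consortia) together with the *functional* intent —
which transcription factor represses which promoter, which molecule carries a
signal between cells.  Flat annotation formats (FASTA, GenBank) cannot carry
that structure; SBOL3 captures it as an ontology-backed knowledge graph, with
structure and function unified in a single `Component` class.  sbolkit is a
Python library and command-line tool for building, serializing, validating,
checking, and migrating such documents.

## What is in the box

- **Object model** (`sbolkit.model`) — the ten main top-level classes of the
  standard (`Component`, `Sequence`, `CombinatorialDerivation`,
  `Implementation`, `Experiment`, `ExperimentalData`, `Model`, `Collection`,
  `Attachment`, `Activity`) plus the `Namespace` utility, the five `Feature`
  subtypes (`SubComponent`, `SequenceFeature`, `LocalSubComponent`,
  `ExternallyDefined`, `ComponentReference`), locations, interactions,
  constraints, and interfaces.  Every object is IRI-named under the required
  `<prefix>/<displayId>` structure; owned children extend their owner's URI.
- **RDF I/O** (`sbolkit.rdf_io`) — lossless mapping onto an RDF graph and
  serialization in Turtle, canonical (sorted) N-Triples, JSON-LD, and
  RDF/XML, with round-trip preservation of foreign annotations and unknown
  extension classes.
- **Validator** (`sbolkit.validator`) — 19 structural and vocabulary rules
  with stable ids (`SBOL3-URI-001`, …), deterministic ordered findings, and a
  strict mode that escalates vocabulary warnings.
- **Constraint engine** (`sbolkit.constraints`) — the three restriction
  families (identity / sequential / topological).  Sequential restrictions are
  evaluated with the Allen interval algebra over 1-based inclusive ranges
  (`meets(a, b) ⇔ a.end + 1 = b.start`); identity restrictions compare the
  resolved definitions of the two features; topological restrictions are
  representable but not computable from a design document.
- **Converters** (`sbolkit.convert`) — GenBank import/export (`a..b`,
  `complement(...)`, `join(...)` dialects; exact feature-table round-trip),
  FASTA import with alphabet inference, and an SBOL2→SBOL3 migrator that
  collapses `ModuleDefinition`/`MapsTo` scaffolding into unified Components.
- **Design corpus** (`sbolkit.fixtures`) — deterministic builders for five
  canonical designs: an auto-regulatory transcription unit, the Gardner
  toggle switch, an AHL sender/receiver multicellular system, a CRISPRi NOR
  gate, and a combinatorial promoter-library template.
- **CLI** (`sbolkit`) — `validate`, `convert`, `stats`, `check`,
  `rewrite-ns`, `fixtures export`, `explain`.

## Worked example

Build a small reporter unit — a promoter placed before a GFP CDS on one
sequence, with a `precedes` constraint and a genetic-production interaction —
then validate it and evaluate its constraints:

```python
from sbolkit import (create_component, terms, Document, SubComponent,
                     Sequence, Range, validate_document)
from sbolkit.constraints import check_all

doc = Document()
ns = "http://example.com/demo"
pTet = create_component(ns, "pTet", {terms.SBO_DNA})
pTet.roles.add(terms.SO_PROMOTER)
gfp = create_component(ns, "gfp_cds", {terms.SBO_DNA})
gfp.roles.add(terms.SO_CDS)

unit = create_component(ns, "reporter_unit", {terms.SBO_DNA})
seq = Sequence(ns, "reporter_unit_seq",
               elements=("TTGACAATTAATCATCGGCTCGTATAATGT"
                         "ATGCGTAAAGGAGAAGAACTTTTCACTGGA"),
               encoding=terms.ENC_IUPAC_DNA)
unit.add_sequence(seq)
p_sub = unit.add_feature(SubComponent("pTet_sub", instance_of=pTet,
                                      locations=[Range(seq, 1, 30)]))
g_sub = unit.add_feature(SubComponent("gfp_sub", instance_of=gfp,
                                      locations=[Range(seq, 31, 60)]))
unit.add_constraint(terms.SBOL3 + "precedes", p_sub, g_sub)
unit.add_interaction(types={terms.SBO_GENETIC_PRODUCTION},
                     participations=[({terms.SBO_TEMPLATE}, g_sub)])
for obj in (pTet, gfp, seq, unit):
    doc.add(obj)

print("validation findings:", len(validate_document(doc)))
for uri, result in check_all(doc):
    print(uri.rsplit("/", 1)[-1], "->", result.status, "|", result.detail)
```

This prints:

```
validation findings: 0
constraint_1 -> holds | observed relation: meets
```

The document is fully conformant (zero findings), and the `precedes`
constraint holds because the observed interval relation between the two
located features is `meets` — the promoter's range ends exactly one base
before the CDS's range begins, which satisfies non-strict precedence.

Serialize it in any of the four syntaxes:

```python
from sbolkit import rdf_io
print(rdf_io.serialize(doc, "turtle").decode())   # or ntriples/jsonld/rdfxml
```

From the shell:

```sh
sbolkit fixtures export --format turtle --out corpus/
sbolkit validate corpus/toggle_switch.ttl          # exit 0: conformant
sbolkit stats corpus/nor_gate.ttl --json           # {"SubComponent": 4, ...}
sbolkit check corpus/multicellular_system.ttl      # constraint evaluation
sbolkit rewrite-ns corpus/toggle_switch.ttl \
    http://example.com/toggleswitch https://hub.org/designs moved.ttl
```

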
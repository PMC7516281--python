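# Methods

This note records the modeling conventions, interpretation choices, and
numerical details behind sbolkit, in the order a maintainer is likely to
meet them.

## The data model

SBOL3 documents are sets of IRI-named objects forming a strict ownership
tree: a top-level object lives at `<namespace>(/<path>)/<displayId>` and
every owned child extends its owner's URI by one `/<displayId>` segment.
The library enforces this at the operation layer (`create_component`,
`add_feature`, `add_interaction`, `set_interface`, `add_constraint`), while
raw constructors stay permissive: a parsed document may be non-conformant
and still needs an in-memory representation for the validator to describe.
Validation is therefore the single authority on conformance; construction
operations are a convenience that make it hard to *produce* a broken
document.

Ten main top-level classes cover the design/build/test/learn workflow —
`Component`, `Sequence`, and `CombinatorialDerivation` (design),
`Implementation` (build), `Experiment` and `ExperimentalData` (test),
`Model` (learn), plus `Collection`, `Attachment`, and the PROV-O `Activity`.
`Namespace` is an eleventh, utility top-level whose URI *is* the prefix it
names; it exists solely to make namespace membership explicit for
re-homing.  `MAIN_TOP_LEVEL_CLASSES` and `TOP_LEVEL_CLASSES` expose the two
registries separately.

Component types come from SBO for molecular species (DNA = SBO:0000251) and
GO for cells (GO:0005623); roles come from SO for sequence parts and SBO
for compartments.  One curated-list caveat: the term list labels
SBO:0000254 "non-covalent complex", following the usage this library
standardizes on, and the entry is only ever used for vocabulary membership,
never computed with.

### Locations and coordinates

Three Location subtypes are implemented: `Range`, `Cut`, and
`EntireSequence`.  This inventory, like the structure of
`CombinatorialDerivation`/`VariableFeature`, is specification-level detail
rather than something the core class diagram forces; it is the minimal set
that supports annotation, between-residue positions, and whole-sequence
reference.  Ranges are **1-based and inclusive at both ends** so GenBank
coordinates transfer verbatim in both directions; Cut positions are 0-based
between-residue (`at = 0` is before the first residue).  Orientation is a
Feature property (not a Location property) with two values, `inline` and
`reverseComplement`; only the converters interpret reverse-complement
semantics.  `SubComponent` source-location excision (taking a sub-sequence
of the instantiated part) is deliberately not modeled.

### Interfaces

A Component's `Interface` holds input, output, and non-directional feature
references.  Inputs and outputs may intersect (a bidirectional feature);
only the non-directional set must be disjoint from both, since
"non-directional" is the one semantically forced exclusion.  An empty
Interface is valid — declaring one is always optional.

### Versioning

Deliberately not modeled.  A version embedded in the URI prefix
(`…/toggleswitch/1/lacI`), embedded in the displayId (`lacI_1`), or absent
are all accepted, stored verbatim, and never interpreted.  The SBOL2
reader's URI folding (below) is the only place versions are touched, and
there only to normalize identifier *shape*.

## Interval relations and constraint evaluation

Sequential restrictions are grounded in the Allen interval algebra.  On
discrete 1-based inclusive intervals there is no shared boundary point
between adjacent ranges, so adjacency is defined arithmetically:
`meets(a, b) ⇔ a.end + 1 = b.start`, and `strictlyPrecedes` requires a gap
(`a.end + 1 < b.start`).

`allen_relation(a, b)` classifies every ordered pair of well-formed ranges
into exactly one of 12 names covering the 13 Allen base cells:

| forward | converse |
|---|---|
| `equals` | `equals` |
| `strictlyPrecedes` | `precededBy` |
| `meets` | `metBy` |
| `overlaps` | `overlappedBy` |
| `starts` | `contains` |
| `finishes` | `contains` |
| `strictlyContains` | `strictlyContainedBy` |
| `contains` | `starts` / `finishes` |

`contains` names *boundary-sharing* proper containment and therefore covers
two Allen cells (started-by and finished-by); `strictlyContains` is
containment sharing no boundary.  This folding matches the restriction
vocabulary, where `contains` explicitly admits boundary sharing.  The
partition and converse properties are verified exhaustively over all 1296
ordered range pairs with endpoints in 1..8 against an independent
set-semantics oracle (a deliberately small, fully enumerable universe; the
classifier is pure endpoint arithmetic, so exhaustiveness at this size is
exhaustiveness everywhere up to order isomorphism).

The legacy non-strict `precedes` restriction predates the refined list and
needs an interpretation.  It is evaluated as the union
`strictlyPrecedes ∪ meets` — the only reading consistent with its two
strict refinements.  A considered and discarded alternative ("starts no
later and ends no later, without containment") would overlap `overlaps` and
break the refinement relationship.

Evaluation semantics per family:

* **sequential** — both features must carry exactly one `Range` on the same
  Sequence (otherwise `notEvaluable`); the observed Allen cell is tested
  against the restriction's satisfying set (`contains` accepts
  `strictlyContains`; `equals` is its own restriction and does not satisfy
  `contains`).  `sameOrientationAs`/`oppositeOrientationAs` compare
  `Feature.orientation` when both are set.  Circular sequences are not
  supported by the evaluator.
* **identity** — each side resolves (through `ComponentReference` chains
  where necessary) to its definition: the external IRI of an
  `ExternallyDefined` feature or the `instanceOf` target of a
  `SubComponent`.  `verifyIdentical` holds iff the definitions agree and,
  when both definitions carry sequence elements, the elements agree too;
  `differentFrom` is its negation; `replaces` is an instruction for
  derivation, not a testable state, and returns `notEvaluable`.
* **topological** — always `notEvaluable` with an explanatory detail: a
  design document carries no geometry.  The family exists so spatial intent
  ("this cell contains this plasmid") is representable and
  vocabulary-checked.

The three families are closed IRI sets.  Names shared between the
sequential and topological families (`contains`, `meets`, `overlaps`,
`strictlyContains`) are kept as distinct IRIs by giving the topological
family its own namespace (`…/v3/topology#`), so family membership is always
decidable from the IRI alone.

## Validation

Nineteen rules with stable ids run unconditionally — findings never abort a
run — and the result list is sorted by subject URI then rule id, making
output deterministic and diffable.  The severity split is library policy
(the standard states rules, not a severity taxonomy): structural-invariant
violations are errors; recommended-practice findings are warnings.  Two
warnings exist: an Interaction with no participations (permitted but almost
certainly unintended) and a type/role term outside the recognized ontology
namespaces.  Strict mode escalates the *vocabulary* warning to an error and
leaves the structural warning alone; lenient is the default.

Ontology membership is checked against shipped namespace prefixes
(identifiers.org forms of SO/SBO/GO/ChEBI/EDAM) rather than live ontology
services — validation must work offline and reproducibly.  The cost is
granularity: a well-formed identifiers.org IRI for a nonexistent term
passes.  References are classified internal/external by namespace: a
reference into one of the document's own namespaces must resolve within the
document; anything else is treated as a resolvable external IRI and not
chased over the network.

## RDF mapping and serialization

One `rdf:type` triple per object, one triple per field value, ownership via
`has…`-prefixed singular predicates (`hasFeature`, `hasInteraction`, …).
Value-like properties keep lowercase single-word names (`type`, `role`,
`elements`); external ontology terms (`prov:wasDerivedFrom`,
`prov:endedAtTime`) are used under their own IRIs, never aliased.  Entity
IRIs start uppercase, property IRIs lowercase; a test audits the whole
vocabulary table against these rules.

Serialization choices:

* **Canonical N-Triples** (lexicographically sorted lines) is the normative
  form for diffing and version control.
* **JSON-LD** uses the single context document shipped at
  `sbolkit/data/context.jsonld` (prefix declarations only).  No framing is
  applied; the output is ordinary context-compacted JSON-LD that any
  conformant processor can parse.  "JSON" is interpreted as JSON-LD — the
  one JSON dialect with defined RDF semantics.
* `Component.sequences` is the one ordered list in the model; RDF triples
  are unordered, so when the list has more than one entry an ordering
  annotation (`sbolkit:sequenceOrder`, a space-joined URI list in the
  library's own annotation namespace) is emitted and consumed on parse.
  Single-entry lists need no annotation.
* UTF-8 everywhere.

Parsing is tolerant by design: unknown predicates on known subjects become
annotations (and are re-emitted verbatim), and top-level subjects with
unrecognized `rdf:type` become opaque extension objects that survive
round-trips untouched.  Two graph shapes are hard errors: a subject with no
`rdf:type` at all, and cyclic ownership (detected both along the recursion
path and for owned-object clusters unreachable from any top level).

## Converters

**GenBank.**  One record maps to one DNA-typed Component plus one Sequence;
each feature-table entry becomes a `SequenceFeature` whose ranges copy the
GenBank coordinates verbatim.  Supported location dialects: `a..b`,
`complement(a..b)` (reverse-complement orientation), and `join(...)`
(multiple Ranges on one feature); fuzzy `<a..b>` bounds are clamped to
their exact coordinate with a warning.  Feature keys map to SO roles
through a shipped table; unmapped keys get the generic sequence_feature
role plus a warning.  The original key is retained as a
`sbolkit:genbankKey` annotation, which is what makes export reproduce the
feature table exactly (keys, locations, strands) even for keys outside the
table.  Export flattens located SubComponents alongside SequenceFeatures,
omits unlocated features with a warning, and refuses non-nucleotide
Components.  Feature qualifiers other than `label`/`gene` (kept as the
feature name) are not preserved.

**FASTA.**  Residues are upper-cased; the alphabet is inferred
conservatively — plain `ACGT(N)` is DNA, `ACGU(N)` is RNA, clearly
proteinaceous strings are protein.  Sequences written entirely in
nucleotide ambiguity codes are also valid protein strings, so an ambiguous
alphabet without an explicit `encoding=` override is an error, not a guess.

**SBOL2 migration.**  The mapping follows the class correspondence:
ComponentDefinition → Component, ModuleDefinition → Component typed/roled
as an SBO functional entity, instance classes → SubComponents,
SequenceAnnotation → locations (when linked to an instance) or a
SequenceFeature (when not), MapsTo → deleted or ComponentReference,
FunctionalComponent direction → Interface membership (`inout` joins both
sets).  The merge policy is the load-bearing choice: a ModuleDefinition
absorbs every ComponentDefinition whose internals are mapped out of it via
MapsTo; the absorbed definition's instances are hoisted into the merged
parent and unified with their module-level duplicates.  This is what makes
the classic toggle-switch migration collapse all four MapsTo links with
zero ComponentReferences while conserving the set of leaf part definitions.
The merged Component keeps the ComponentDefinition's identity when exactly
one definition is absorbed, otherwise the ModuleDefinition's.  SBOL2
`access` has no SBOL3 home and is dropped with a report entry.  The
snapshot reader consumes RDF with SBOL2 predicates directly (only the
surface migration needs, not a full SBOL2 implementation) and folds
trailing URI version segments into the prefix
(`<prefix>/<id>/<v>` → `<prefix>/<v>/<id>`), per the convention that
identifiers, not versions, end a URI.

## The design corpus

The fixtures module builds five canonical designs deterministically — fixed
URIs under `http://example.com/…`, no randomness — so repeated builds are
graph-identical and the corpus doubles as the serialization/validation test
bed.  Part sequences are short synthetic placeholder DNA (a 30 nt
consensus-like promoter, 18 nt RBS, 45 nt CDS stub, 32 nt terminator),
enough to exercise Range bookkeeping and sequence-length validation.  What
the corpus does **not** emulate: real accessions, realistic gene lengths,
sequence biology of any kind, or large documents.  Passing the corpus
demonstrates structural and serialization correctness of the machinery, not
biological validity of any design, and says nothing about performance on
repository-scale files.

Layout note on the toggle switch: the parent Component owns all eight part
SubComponents directly (two promoter/RBS/CDS/terminator sets) with both
repression Interactions at the same level.  A nested
transcription-unit-per-Component layout cannot express the interactions
with purely local participants — a participant must be a feature of the
Component owning the Interaction — so the flat layout is the one that
realizes "every element appears exactly once, with no identity mappings".

The multicellular system uses a representative ChEBI record
(CHEBI:51451, an N-acyl homoserine lactone class) as the shared external
definition of the AHL signal in both subsystems; the identity constraint
between the two ComponentReferences evaluates to `holds` because both
resolve to that same IRI.

## Determinism and tie-breaks

* Namespace decomposition: longest registered prefix wins.
* Validator findings: sorted (subject, ruleId).  `check_all`: top-levels by
  URI, constraints in declaration order.
* Auto-assigned child displayIds (`interaction_1`, `participation_2`, …)
  take the smallest free index under their parent.
* `from_graph` materializes children in URI-sorted order; model-level list
  order is therefore canonical after any parse, and graph comparison (the
  round-trip criterion) is order-free anyway.
* Namespace rewriting operates on the RDF graph (every URIRef with the old
  prefix is rewritten, references included), which makes the operation
  exactly invertible; collisions with existing URIs in the target namespace
  are detected before any mutation.

## Known limitations

* No SPARQL endpoint, named-graph/quads support, or streaming parse.
* No OWL/description-logic reasoning; validation is rule-based.
* Topological restrictions and `replaces` are never evaluated (by design).
* `enumerate_combinations` handles `one` and `zeroOrOne` cardinalities and
  flat variant sets/collections; `oneOrMore`/`zeroOrMore` and nested
  variant derivations raise.
* Ontology term checking is prefix-based against shipped lists, not a live
  ontology lookup.
* URIs are ASCII-only; internationalized identifiers are rejected with a
  clear error rather than half-supported.
* GenBank export drops qualifiers other than the label, and circular
  molecule topology is not modeled anywhere.
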
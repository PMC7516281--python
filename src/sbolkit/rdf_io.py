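"""Bidirectional mapping between the object model and an RDF graph.

SBOL3 does not define a bespoke file format: it defines how objects map to an
RDF graph, which standard tooling then serializes.  Four concrete syntaxes
are supported — Turtle, N-Triples, JSON-LD, and RDF/XML.  N-Triples output is
emitted in canonical (lexicographically sorted) form, the normative
representation for diffing documents under version control.

Every SBOL object is IRI-named (no blank-node subjects).  SBOL-owned
predicates follow the standard's naming convention: ownership/reference
properties use ``has``-prefixed singular names (``hasFeature``,
``hasInteraction``); entity (class) IRIs start with an uppercase letter and
property IRIs with a lowercase one.  Terms borrowed from external ontologies
(``prov:wasDerivedFrom`` and friends) keep their own names — they are never
given SBOL aliases.

Unknown predicates on known subjects survive round-trips as annotations, and
top-level subjects with unrecognized ``rdf:type`` are preserved as opaque
extension objects.
"""
from __future__ import annotations

import json
from importlib import resources
from typing import Optional, Union

from rdflib import RDF, XSD, Graph, Literal, URIRef
from rdflib import Namespace as NS

from . import terms
from .errors import OwnershipError, SerializationError
from .model import (Activity, Attachment, Collection,
                    CombinatorialDerivation, Component, ComponentReference,
                    Constraint, Cut, Document, EntireSequence, Experiment,
                    ExperimentalData, ExternallyDefined, Feature, Identified,
                    Implementation, Interaction, Interface,
                    LocalSubComponent, Location, Model, Namespace,
                    Participation, Range, Sequence, SequenceFeature,
                    SubComponent, TopLevel, Usage, VariableFeature)

SBOL = NS(terms.SBOL3)
PROV = NS(terms.PROV)
SBOLKIT = NS(terms.SBOLKIT_NS)

FORMATS = {
    "turtle": "turtle",
    "ntriples": "nt",
    "jsonld": "json-ld",
    "rdfxml": "xml",
}

EXTENSION_FORMATS = {
    ".ttl": "turtle",
    ".nt": "ntriples",
    ".jsonld": "jsonld",
    ".rdf": "rdfxml",
    ".xml": "rdfxml",
}

# --------------------------------------------------------------------------
# vocabulary
# --------------------------------------------------------------------------

CLASS_IRIS: dict[type, URIRef] = {
    Component: SBOL.Component,
    Sequence: SBOL.Sequence,
    SubComponent: SBOL.SubComponent,
    SequenceFeature: SBOL.SequenceFeature,
    LocalSubComponent: SBOL.LocalSubComponent,
    ExternallyDefined: SBOL.ExternallyDefined,
    ComponentReference: SBOL.ComponentReference,
    Range: SBOL.Range,
    Cut: SBOL.Cut,
    EntireSequence: SBOL.EntireSequence,
    Interaction: SBOL.Interaction,
    Participation: SBOL.Participation,
    Constraint: SBOL.Constraint,
    Interface: SBOL.Interface,
    CombinatorialDerivation: SBOL.CombinatorialDerivation,
    VariableFeature: SBOL.VariableFeature,
    Implementation: SBOL.Implementation,
    Experiment: SBOL.Experiment,
    ExperimentalData: SBOL.ExperimentalData,
    Model: SBOL.Model,
    Collection: SBOL.Collection,
    Attachment: SBOL.Attachment,
    Activity: PROV.Activity,
    Usage: PROV.Usage,
    Namespace: SBOL.Namespace,
}
CLASS_BY_IRI = {iri: cls for cls, iri in CLASS_IRIS.items()}

#: model field -> predicate IRI (the PropertyVocabulary); audited by tests
#: against the naming convention
PROPERTY_VOCABULARY: dict[str, URIRef] = {
    "displayId": SBOL.displayId,
    "name": SBOL.name,
    "description": SBOL.description,
    "namespace": SBOL.hasNamespace,
    "derivedFrom": PROV.wasDerivedFrom,
    "generatedBy": PROV.wasGeneratedBy,
    "type": SBOL.type,
    "role": SBOL.role,
    "sequences": SBOL.hasSequence,
    "features": SBOL.hasFeature,
    "interactions": SBOL.hasInteraction,
    "constraints": SBOL.hasConstraint,
    "interface": SBOL.hasInterface,
    "models": SBOL.hasModel,
    "elements": SBOL.elements,
    "encoding": SBOL.encoding,
    "orientation": SBOL.orientation,
    "instanceOf": SBOL.instanceOf,
    "locations": SBOL.hasLocation,
    "definition": SBOL.definition,
    "inChildOf": SBOL.inChildOf,
    "refersTo": SBOL.refersTo,
    "locationSequence": SBOL.hasSequence,
    "start": SBOL.start,
    "end": SBOL.end,
    "at": SBOL.at,
    "participations": SBOL.hasParticipation,
    "participant": SBOL.participant,
    "restriction": SBOL.restriction,
    "subject": SBOL.subject,
    "object": SBOL.object,
    "input": SBOL.input,
    "output": SBOL.output,
    "nondirectional": SBOL.nondirectional,
    "template": SBOL.template,
    "strategy": SBOL.strategy,
    "variableFeatures": SBOL.hasVariableFeature,
    "variable": SBOL.variable,
    "cardinality": SBOL.cardinality,
    "variant": SBOL.variant,
    "variantCollection": SBOL.variantCollection,
    "variantDerivation": SBOL.variantDerivation,
    "built": SBOL.built,
    "member": SBOL.member,
    "attachments": SBOL.hasAttachment,
    "source": SBOL.source,
    "language": SBOL.language,
    "framework": SBOL.framework,
    "format": SBOL["format"],
    "size": SBOL.size,
    "hash": SBOL.hash,
    "hashAlgorithm": SBOL.hashAlgorithm,
    "endedAt": PROV.endedAtTime,
    "usages": PROV.qualifiedUsage,
    "usageEntity": PROV.entity,
    "usageRole": PROV.hadRole,
}

#: SBOL-owned lowercase property names that are deliberate exceptions to the
#: ``has…`` pattern (value-like properties, not ownership/containment)
APPROVED_LOWERCASE = frozenset({
    "displayId", "name", "description", "type", "role", "elements",
    "encoding", "orientation", "instanceOf", "definition", "inChildOf",
    "refersTo", "start", "end", "at", "participant", "restriction",
    "subject", "object", "input", "output", "nondirectional", "template",
    "strategy", "variable", "cardinality", "variant", "variantCollection",
    "variantDerivation", "built", "member", "source", "language",
    "framework", "format", "size", "hash", "hashAlgorithm",
})

_OWNERSHIP_PREDICATES = frozenset({
    SBOL.hasFeature, SBOL.hasInteraction, SBOL.hasConstraint,
    SBOL.hasInterface, SBOL.hasLocation, SBOL.hasParticipation,
    SBOL.hasVariableFeature, PROV.qualifiedUsage,
})


class OpaqueTopLevel(TopLevel):
    """Preserved top-level object of a type this library does not model.

    All of its property triples are carried verbatim in ``annotations`` and
    re-emitted on serialization, so extension data is never dropped.
    """

    def __init__(self, uri: str, rdf_type: str, namespace: Optional[str] = None):
        super().__init__(namespace=namespace, uri=uri)
        self.rdf_type = rdf_type


# --------------------------------------------------------------------------
# model -> graph
# --------------------------------------------------------------------------

def _as_term(value):
    if isinstance(value, (URIRef, Literal)):
        return value
    return Literal(value)


def _emit_identified(g: Graph, obj: Identified, s: URIRef) -> None:
    if obj.display_id is not None:
        g.add((s, SBOL.displayId, Literal(obj.display_id)))
    if obj.name is not None:
        g.add((s, SBOL.name, Literal(obj.name)))
    if obj.description is not None:
        g.add((s, SBOL.description, Literal(obj.description)))
    for uri in sorted(obj.derived_from):
        g.add((s, PROV.wasDerivedFrom, URIRef(uri)))
    for uri in sorted(obj.generated_by):
        g.add((s, PROV.wasGeneratedBy, URIRef(uri)))
    for pred, value in obj.annotations:
        g.add((s, URIRef(pred), _as_term(value)))


def _emit_refs(g, s, pred, uris) -> None:
    for uri in sorted(uris):
        g.add((s, pred, URIRef(uri)))


def _emit_child(g: Graph, owner: URIRef, pred: URIRef,
                child: Identified) -> None:
    c = URIRef(child.uri)
    g.add((owner, pred, c))
    _emit_object(g, child)


def _emit_object(g: Graph, obj: Identified) -> None:
    if obj.uri is None:
        raise SerializationError(f"object without URI: {obj!r}")
    s = URIRef(obj.uri)
    if isinstance(obj, OpaqueTopLevel):
        g.add((s, RDF.type, URIRef(obj.rdf_type)))
        if obj.namespace:
            g.add((s, SBOL.hasNamespace, URIRef(obj.namespace)))
        _emit_identified(g, obj, s)
        return
    cls_iri = CLASS_IRIS.get(type(obj))
    if cls_iri is None:
        raise SerializationError(f"unserializable object type: {type(obj)}")
    g.add((s, RDF.type, cls_iri))
    _emit_identified(g, obj, s)

    if isinstance(obj, TopLevel) and obj.namespace:
        g.add((s, SBOL.hasNamespace, URIRef(obj.namespace)))

    if isinstance(obj, Component):
        _emit_refs(g, s, SBOL.type, obj.types)
        _emit_refs(g, s, SBOL.role, obj.roles)
        _emit_refs(g, s, SBOL.hasSequence, set(obj.sequences))
        if len(obj.sequences) > 1:
            # explicit ordering annotation; RDF triples are unordered
            g.add((s, SBOLKIT.sequenceOrder,
                   Literal(" ".join(obj.sequences))))
        _emit_refs(g, s, SBOL.hasModel, obj.models)
        for f in obj.features:
            _emit_child(g, s, SBOL.hasFeature, f)
        for i in obj.interactions:
            _emit_child(g, s, SBOL.hasInteraction, i)
        for c in obj.constraints:
            _emit_child(g, s, SBOL.hasConstraint, c)
        if obj.interface is not None:
            _emit_child(g, s, SBOL.hasInterface, obj.interface)
    elif isinstance(obj, Sequence):
        if obj.elements is not None:
            g.add((s, SBOL.elements, Literal(obj.elements)))
        if obj.encoding is not None:
            g.add((s, SBOL.encoding, URIRef(obj.encoding)))
    elif isinstance(obj, Feature):
        _emit_refs(g, s, SBOL.role, obj.roles)
        if obj.orientation is not None:
            g.add((s, SBOL.orientation, URIRef(obj.orientation)))
        for loc in obj.locations:
            _emit_child(g, s, SBOL.hasLocation, loc)
        if isinstance(obj, SubComponent) and obj.instance_of:
            g.add((s, SBOL.instanceOf, URIRef(obj.instance_of)))
        elif isinstance(obj, LocalSubComponent):
            _emit_refs(g, s, SBOL.type, obj.types)
        elif isinstance(obj, ExternallyDefined):
            _emit_refs(g, s, SBOL.type, obj.types)
            if obj.definition:
                g.add((s, SBOL.definition, URIRef(obj.definition)))
        elif isinstance(obj, ComponentReference):
            if obj.in_child_of:
                g.add((s, SBOL.inChildOf, URIRef(obj.in_child_of)))
            if obj.refers_to:
                g.add((s, SBOL.refersTo, URIRef(obj.refers_to)))
    elif isinstance(obj, Location):
        if obj.sequence:
            g.add((s, SBOL.hasSequence, URIRef(obj.sequence)))
        if isinstance(obj, Range):
            g.add((s, SBOL.start, Literal(obj.start, datatype=XSD.integer)))
            g.add((s, SBOL.end, Literal(obj.end, datatype=XSD.integer)))
        elif isinstance(obj, Cut):
            g.add((s, SBOL.at, Literal(obj.at, datatype=XSD.integer)))
    elif isinstance(obj, Interaction):
        _emit_refs(g, s, SBOL.type, obj.types)
        for p in obj.participations:
            _emit_child(g, s, SBOL.hasParticipation, p)
    elif isinstance(obj, Participation):
        _emit_refs(g, s, SBOL.role, obj.roles)
        if obj.participant:
            g.add((s, SBOL.participant, URIRef(obj.participant)))
    elif isinstance(obj, Constraint):
        if obj.restriction:
            g.add((s, SBOL.restriction, URIRef(obj.restriction)))
        if obj.subject:
            g.add((s, SBOL.subject, URIRef(obj.subject)))
        if obj.object:
            g.add((s, SBOL.object, URIRef(obj.object)))
    elif isinstance(obj, Interface):
        _emit_refs(g, s, SBOL.input, obj.inputs)
        _emit_refs(g, s, SBOL.output, obj.outputs)
        _emit_refs(g, s, SBOL.nondirectional, obj.nondirectionals)
    elif isinstance(obj, CombinatorialDerivation):
        if obj.template:
            g.add((s, SBOL.template, URIRef(obj.template)))
        if obj.strategy:
            g.add((s, SBOL.strategy, URIRef(obj.strategy)))
        for vf in obj.variable_features:
            _emit_child(g, s, SBOL.hasVariableFeature, vf)
    elif isinstance(obj, VariableFeature):
        if obj.variable:
            g.add((s, SBOL.variable, URIRef(obj.variable)))
        g.add((s, SBOL.cardinality, URIRef(obj.cardinality)))
        _emit_refs(g, s, SBOL.variant, obj.variants)
        _emit_refs(g, s, SBOL.variantCollection, obj.variant_collections)
        _emit_refs(g, s, SBOL.variantDerivation, obj.variant_derivations)
    elif isinstance(obj, Implementation):
        if obj.built:
            g.add((s, SBOL.built, URIRef(obj.built)))
    elif isinstance(obj, (Experiment, Collection)):
        _emit_refs(g, s, SBOL.member, obj.members)
    elif isinstance(obj, ExperimentalData):
        _emit_refs(g, s, SBOL.hasAttachment, obj.attachments)
    elif isinstance(obj, Model):
        if obj.source:
            g.add((s, SBOL.source, URIRef(obj.source)))
        if obj.language:
            g.add((s, SBOL.language, URIRef(obj.language)))
        if obj.framework:
            g.add((s, SBOL.framework, URIRef(obj.framework)))
    elif isinstance(obj, Attachment):
        if obj.source:
            g.add((s, SBOL.source, URIRef(obj.source)))
        if obj.format:
            g.add((s, SBOL["format"], URIRef(obj.format)))
        if obj.size is not None:
            g.add((s, SBOL.size, Literal(obj.size, datatype=XSD.integer)))
        if obj.hash is not None:
            g.add((s, SBOL.hash, Literal(obj.hash)))
        if obj.hash_algorithm is not None:
            g.add((s, SBOL.hashAlgorithm, Literal(obj.hash_algorithm)))
    elif isinstance(obj, Activity):
        _emit_refs(g, s, SBOL.type, obj.types)
        if obj.ended_at is not None:
            g.add((s, PROV.endedAtTime,
                   Literal(obj.ended_at, datatype=XSD.dateTime)))
        for u in obj.usages:
            _emit_child(g, s, PROV.qualifiedUsage, u)
    elif isinstance(obj, Usage):
        if obj.entity:
            g.add((s, PROV.entity, URIRef(obj.entity)))
        _emit_refs(g, s, PROV.hadRole, obj.roles)
    elif isinstance(obj, Namespace):
        pass  # its URI is the payload


def to_graph(doc: Document) -> Graph:
    """Map a Document onto an RDF graph: one rdf:type triple per object,
    one triple per field value, ownership via ``has…`` predicates."""
    g = Graph()
    g.bind("sbol", SBOL)
    g.bind("prov", PROV)
    g.bind("sbolkit", SBOLKIT)
    for prefix, ns in doc.prefix_map.items():
        g.bind(prefix, NS(ns), override=False)
    for top in doc.top_levels:
        _emit_object(g, top)
    return g


# --------------------------------------------------------------------------
# graph -> model
# --------------------------------------------------------------------------

def _str_or_none(term) -> Optional[str]:
    return None if term is None else str(term)


class _Props:
    """Consumable view of one subject's predicate/object pairs; whatever is
    not consumed becomes annotations."""

    def __init__(self, graph: Graph, subject: URIRef):
        self.pairs: dict[URIRef, list] = {}
        for p, o in graph.predicate_objects(subject):
            self.pairs.setdefault(p, []).append(o)
        self.pairs.pop(RDF.type, None)

    def one(self, pred):
        values = self.pairs.pop(pred, [])
        return values[0] if values else None

    def all(self, pred) -> list:
        return self.pairs.pop(pred, [])

    def uris(self, pred) -> set[str]:
        return {str(v) for v in self.all(pred)}

    def leftover(self) -> list[tuple[str, object]]:
        out = []
        for pred in sorted(self.pairs):
            for value in sorted(self.pairs[pred], key=str):
                out.append((str(pred), value))
        return out


def _build(graph: Graph, subject: URIRef, visiting: set,
           built: Optional[set] = None) -> Identified:
    if subject in visiting:
        raise OwnershipError(f"ownership cycle through {subject}")
    visiting = visiting | {subject}
    if built is not None:
        built.add(subject)
    types = list(graph.objects(subject, RDF.type))
    if not types:
        raise SerializationError(f"object with no rdf:type: {subject}")
    cls = None
    for t in types:
        cls = CLASS_BY_IRI.get(t)
        if cls is not None:
            break
    props = _Props(graph, subject)
    uri = str(subject)

    def build_children(pred) -> list:
        kids = []
        for child_ref in sorted(props.all(pred), key=str):
            kids.append(_build(graph, child_ref, visiting, built))
        return kids

    if cls is None:
        ns = _str_or_none(props.one(SBOL.hasNamespace))
        obj = OpaqueTopLevel(uri, rdf_type=str(types[0]), namespace=ns)
    elif cls is Namespace:
        obj = Namespace(uri=uri)
        props.one(SBOL.hasNamespace)
    else:
        obj = cls.__new__(cls)
        Identified.__init__(obj, uri=uri)
        if issubclass(cls, TopLevel):
            obj.namespace = _str_or_none(props.one(SBOL.hasNamespace))
        if cls is Component:
            obj.types = props.uris(SBOL.type)
            obj.roles = props.uris(SBOL.role)
            seqs = sorted(props.uris(SBOL.hasSequence))
            order = props.one(SBOLKIT.sequenceOrder)
            if order is not None:
                ordered = str(order).split()
                seqs = [u for u in ordered if u in seqs] + \
                       [u for u in seqs if u not in ordered]
            obj.sequences = seqs
            obj.models = props.uris(SBOL.hasModel)
            obj.features = build_children(SBOL.hasFeature)
            obj.interactions = build_children(SBOL.hasInteraction)
            obj.constraints = build_children(SBOL.hasConstraint)
            ifaces = build_children(SBOL.hasInterface)
            obj.interface = ifaces[0] if ifaces else None
        elif cls is Sequence:
            elements = props.one(SBOL.elements)
            obj.elements = _str_or_none(elements)
            obj.encoding = _str_or_none(props.one(SBOL.encoding))
        elif issubclass(cls, Feature):
            obj.roles = props.uris(SBOL.role)
            obj.orientation = _str_or_none(props.one(SBOL.orientation))
            obj.locations = build_children(SBOL.hasLocation)
            if cls is SubComponent:
                obj.instance_of = _str_or_none(props.one(SBOL.instanceOf))
            elif cls is LocalSubComponent:
                obj.types = props.uris(SBOL.type)
            elif cls is ExternallyDefined:
                obj.types = props.uris(SBOL.type)
                obj.definition = _str_or_none(props.one(SBOL.definition))
            elif cls is ComponentReference:
                obj.in_child_of = _str_or_none(props.one(SBOL.inChildOf))
                obj.refers_to = _str_or_none(props.one(SBOL.refersTo))
        elif issubclass(cls, Location):
            obj.sequence = _str_or_none(props.one(SBOL.hasSequence))
            if cls is Range:
                obj.start = int(props.one(SBOL.start))
                obj.end = int(props.one(SBOL.end))
            elif cls is Cut:
                obj.at = int(props.one(SBOL.at))
        elif cls is Interaction:
            obj.types = props.uris(SBOL.type)
            obj.participations = build_children(SBOL.hasParticipation)
        elif cls is Participation:
            obj.roles = props.uris(SBOL.role)
            obj.participant = _str_or_none(props.one(SBOL.participant))
        elif cls is Constraint:
            obj.restriction = _str_or_none(props.one(SBOL.restriction))
            obj.subject = _str_or_none(props.one(SBOL.subject))
            obj.object = _str_or_none(props.one(SBOL.object))
        elif cls is Interface:
            obj.inputs = props.uris(SBOL.input)
            obj.outputs = props.uris(SBOL.output)
            obj.nondirectionals = props.uris(SBOL.nondirectional)
        elif cls is CombinatorialDerivation:
            obj.template = _str_or_none(props.one(SBOL.template))
            obj.strategy = _str_or_none(props.one(SBOL.strategy))
            obj.variable_features = build_children(SBOL.hasVariableFeature)
        elif cls is VariableFeature:
            obj.variable = _str_or_none(props.one(SBOL.variable))
            obj.cardinality = (_str_or_none(props.one(SBOL.cardinality))
                               or terms.CARDINALITY_ONE)
            obj.variants = props.uris(SBOL.variant)
            obj.variant_collections = props.uris(SBOL.variantCollection)
            obj.variant_derivations = props.uris(SBOL.variantDerivation)
        elif cls is Implementation:
            obj.built = _str_or_none(props.one(SBOL.built))
        elif cls in (Experiment, Collection):
            obj.members = props.uris(SBOL.member)
        elif cls is ExperimentalData:
            obj.attachments = props.uris(SBOL.hasAttachment)
        elif cls is Model:
            obj.source = _str_or_none(props.one(SBOL.source))
            obj.language = _str_or_none(props.one(SBOL.language))
            obj.framework = _str_or_none(props.one(SBOL.framework))
        elif cls is Attachment:
            obj.source = _str_or_none(props.one(SBOL.source))
            obj.format = _str_or_none(props.one(SBOL["format"]))
            size = props.one(SBOL.size)
            obj.size = None if size is None else int(size)
            obj.hash = _str_or_none(props.one(SBOL.hash))
            obj.hash_algorithm = _str_or_none(props.one(SBOL.hashAlgorithm))
        elif cls is Activity:
            obj.types = props.uris(SBOL.type)
            obj.ended_at = _str_or_none(props.one(PROV.endedAtTime))
            obj.usages = build_children(PROV.qualifiedUsage)
        elif cls is Usage:
            obj.entity = _str_or_none(props.one(PROV.entity))
            obj.roles = props.uris(PROV.hadRole)

    # shared Identified metadata + leftover annotations
    did = props.one(SBOL.displayId)
    if did is not None:
        obj.display_id = str(did)
    name = props.one(SBOL.name)
    if name is not None:
        obj.name = str(name)
    desc = props.one(SBOL.description)
    if desc is not None:
        obj.description = str(desc)
    obj.derived_from = props.uris(PROV.wasDerivedFrom)
    obj.generated_by = props.uris(PROV.wasGeneratedBy)
    obj.annotations = props.leftover()
    for child in obj.children():
        child.owner = obj
    return obj


def from_graph(graph: Graph) -> Document:
    """Reconstruct a Document from an RDF graph.

    Subjects with a known top-level rdf:type become model objects; unknown
    top-level types are preserved opaquely; objects reachable through
    ownership predicates become owned children.  An ownership cycle is an
    error.
    """
    doc = Document()
    for prefix, ns in graph.namespaces():
        if prefix and prefix not in ("sbol", "prov", "rdf", "rdfs", "xsd",
                                     "xml", "sbolkit", "brick", "csvw", "dc",
                                     "dcat", "dcmitype", "dcterms", "dcam",
                                     "doap", "foaf", "geo", "odrl", "org",
                                     "owl", "prof", "qb", "schema", "sh",
                                     "skos", "sosa", "ssn", "time", "vann",
                                     "void", "wgs"):
            doc.prefix_map[prefix] = str(ns)
    owned = set()
    for pred in _OWNERSHIP_PREDICATES:
        owned.update(graph.objects(None, pred))
    tops = []
    for subject in sorted(set(graph.subjects()), key=str):
        if subject in owned or not isinstance(subject, URIRef):
            continue
        if (subject, RDF.type, None) not in graph:
            raise SerializationError(f"object with no rdf:type: {subject}")
        tops.append(subject)
    built: set = set()
    for subject in tops:
        obj = _build(graph, subject, set(), built)
        if not isinstance(obj, TopLevel):
            # a child class used as a top level — preserve opaquely
            opaque = OpaqueTopLevel(str(subject),
                                    rdf_type=str(CLASS_IRIS[type(obj)]))
            doc.add(opaque)
        else:
            doc.add(obj)
    # owned subjects never reached from a top level: if their owners are
    # all equally unreached, ownership must be cyclic
    for subject in sorted(owned - built, key=str):
        owners = {s for pred in _OWNERSHIP_PREDICATES
                  for s in graph.subjects(pred, subject)}
        if owners and owners.isdisjoint(built):
            raise OwnershipError(
                f"ownership cycle through {subject}")
    return doc


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

def _canonical_ntriples(graph: Graph) -> str:
    lines = sorted(
        f"{s.n3()} {p.n3()} {o.n3()} ." for s, p, o in graph
    )
    return "\n".join(lines) + ("\n" if lines else "")


def _jsonld_context() -> dict:
    with resources.files("sbolkit.data").joinpath("context.jsonld").open() as fh:
        return json.load(fh)["@context"]


def serialize_graph(graph: Graph, format: str = "turtle") -> bytes:
    if format not in FORMATS:
        raise SerializationError(
            f"unknown format {format!r}; expected one of {sorted(FORMATS)}")
    if format == "ntriples":
        return _canonical_ntriples(graph).encode("utf-8")
    if format == "jsonld":
        out = graph.serialize(format="json-ld", context=_jsonld_context())
        return out.encode("utf-8")
    return graph.serialize(format=FORMATS[format], encoding="utf-8")


def serialize(doc: Document, format: str = "turtle") -> bytes:
    """Serialize a Document; N-Triples output is canonical (sorted)."""
    return serialize_graph(to_graph(doc), format)


def parse_graph(data: Union[bytes, str], format: str = "turtle") -> Graph:
    if format not in FORMATS:
        raise SerializationError(
            f"unknown format {format!r}; expected one of {sorted(FORMATS)}")
    g = Graph()
    try:
        g.parse(data=data, format=FORMATS[format])
    except Exception as exc:  # rdflib raises many parser-specific errors
        raise SerializationError(f"cannot parse {format} input: {exc}") from exc
    return g


def parse(data: Union[bytes, str], format: str = "turtle") -> Document:
    """Parse serialized SBOL3 back into a Document."""
    return from_graph(parse_graph(data, format))


def write_file(doc: Document, path, format: Optional[str] = None) -> None:
    import os

    if format is None:
        format = EXTENSION_FORMATS.get(os.path.splitext(str(path))[1])
        if format is None:
            raise SerializationError(f"cannot infer format from {path!r}")
    with open(path, "wb") as fh:
        fh.write(serialize(doc, format))


def read_file(path, format: Optional[str] = None) -> Document:
    import os

    if format is None:
        format = EXTENSION_FORMATS.get(os.path.splitext(str(path))[1])
        if format is None:
            raise SerializationError(f"cannot infer format from {path!r}")
    with open(path, "rb") as fh:
        return parse(fh.read(), format)
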
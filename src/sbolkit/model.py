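"""The SBOL3 object model.

SBOL3 describes engineered biological designs as a set of *top-level* objects
— most importantly :class:`Component`, the universal design unit that unifies
structural composition (features located on sequences) and function
(interactions between those features).  Ten main top-level classes cover the
design/build/test/learn workflow; a utility :class:`Namespace` class supports
URI management.

Ownership is strict: every owned child's URI extends its owner's URI by one
``/<displayId>`` segment, so a whole design forms a URI-prefix tree rooted at
its top-level objects.  Raw constructors are deliberately permissive (a parsed
document may be non-conformant and still needs an in-memory form for the
validator to report on); the *operations* — :func:`create_component`,
:meth:`Component.add_feature`, etc. — enforce their preconditions.
"""
from __future__ import annotations

from typing import Iterable, Iterator, Optional

from . import terms
from .errors import (IdentityError, OwnershipError, ResolutionError,
                     SbolError, VocabularyError)
from .identity import (compose_uri, require_absolute_iri,
                       require_display_id)


def _uri_of(ref) -> str:
    """Accept either an object with a .uri or a plain URI string."""
    return ref.uri if isinstance(ref, Identified) else str(ref)


def _uri_set(refs) -> set[str]:
    return {_uri_of(r) for r in refs}


class Identified:
    """Base for every SBOL object: a URI-named node in the design graph.

    Carries the shared metadata fields (name, description, provenance links)
    and arbitrary annotations in non-SBOL namespaces, which are preserved
    verbatim through every operation and serialization.
    """

    def __init__(self, display_id: Optional[str] = None, *,
                 name: Optional[str] = None,
                 description: Optional[str] = None,
                 uri: Optional[str] = None):
        if display_id is not None:
            require_display_id(display_id)
        self.display_id = display_id
        self.name = name
        self.description = description
        self.uri: Optional[str] = uri
        self.derived_from: set[str] = set()
        self.generated_by: set[str] = set()
        #: list of (predicate IRI, rdflib term or str) pairs
        self.annotations: list[tuple[str, object]] = []
        self.owner: Optional[Identified] = None

    def children(self) -> Iterator["Identified"]:
        return iter(())

    def descendants(self) -> Iterator["Identified"]:
        for child in self.children():
            yield child
            yield from child.descendants()

    def _adopt(self, child: "Identified", stem: str) -> None:
        """Attach *child*, assigning its URI below this object's URI."""
        taken = {c.display_id for c in self.children()
                 if c is not child and c.display_id}
        if child.display_id is None:
            n = 1
            while f"{stem}_{n}" in taken:
                n += 1
            child.display_id = f"{stem}_{n}"
        if self.uri is None:
            raise OwnershipError(
                f"cannot adopt {child.display_id!r}: owner has no URI yet")
        if child.display_id in taken:
            raise OwnershipError(
                f"duplicate displayId {child.display_id!r} under {self.uri}")
        child.uri = f"{self.uri}/{child.display_id}"
        child.owner = self
        for grand in child.children():
            if grand.uri is None:
                child._adopt(grand, grand.__class__.__name__.lower())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<{self.__class__.__name__} {self.uri or self.display_id}>"


class TopLevel(Identified):
    """An object that a Document can own directly.

    URI structure is ``<namespace>(/<path>)/<displayId>``; the namespace must
    be a prefix of the URI.
    """

    def __init__(self, namespace: Optional[str] = None,
                 display_id: Optional[str] = None, *,
                 uri: Optional[str] = None, **kw):
        if uri is None and namespace is not None and display_id is not None:
            uri = compose_uri(namespace.rstrip("/"), display_id)
        super().__init__(display_id, uri=uri, **kw)
        self.namespace = namespace.rstrip("/") if namespace else namespace


# --------------------------------------------------------------------------
# locations
# --------------------------------------------------------------------------

class Location(Identified):
    """Abstract position of a feature on a Sequence."""

    def __init__(self, sequence, display_id: Optional[str] = None, **kw):
        super().__init__(display_id, **kw)
        self.sequence = _uri_of(sequence) if sequence is not None else None


class Range(Location):
    """Contiguous region, 1-based and inclusive at both ends
    (GenBank-compatible coordinates)."""

    def __init__(self, sequence, start: int, end: int,
                 display_id: Optional[str] = None, **kw):
        super().__init__(sequence, display_id, **kw)
        self.start = int(start)
        self.end = int(end)
        if not 1 <= self.start <= self.end:
            raise SbolError(
                f"Range requires 1 <= start <= end, got {start}..{end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class Cut(Location):
    """Point between residues *at* and *at*+1 (0 = before the first)."""

    def __init__(self, sequence, at: int,
                 display_id: Optional[str] = None, **kw):
        super().__init__(sequence, display_id, **kw)
        self.at = int(at)
        if self.at < 0:
            raise SbolError(f"Cut position must be >= 0, got {at}")


class EntireSequence(Location):
    """The whole of the referenced Sequence."""


# --------------------------------------------------------------------------
# features
# --------------------------------------------------------------------------

class Feature(Identified):
    """Abstract element of interest within a Component."""

    def __init__(self, display_id: Optional[str] = None, *,
                 roles: Iterable[str] = (),
                 orientation: Optional[str] = None, **kw):
        super().__init__(display_id, **kw)
        self.roles: set[str] = set(roles)
        if orientation is not None and orientation not in terms.ORIENTATIONS:
            raise VocabularyError(f"unknown orientation {orientation!r}")
        self.orientation = orientation
        self.locations: list[Location] = []

    def children(self) -> Iterator[Identified]:
        return iter(self.locations)

    def add_location(self, location: Location) -> Location:
        self.locations.append(location)
        if self.uri is not None and location.uri is None:
            self._adopt(location, "location")
        return location


class SubComponent(Feature):
    """Hierarchical part-subpart use of another Component, optionally located
    on the parent's sequence."""

    def __init__(self, display_id: Optional[str] = None, *,
                 instance_of=None, locations: Iterable[Location] = (), **kw):
        super().__init__(display_id, **kw)
        self.instance_of = _uri_of(instance_of) if instance_of is not None else None
        for loc in locations:
            self.add_location(loc)


class SequenceFeature(Feature):
    """Pure annotation: a located feature with no part-subpart meaning.
    Must carry at least one Location."""

    def __init__(self, display_id: Optional[str] = None, *,
                 locations: Iterable[Location] = (), **kw):
        super().__init__(display_id, **kw)
        for loc in locations:
            self.add_location(loc)


class LocalSubComponent(Feature):
    """Placeholder that only makes sense inside its parent (e.g., a variable
    slot in a combinatorial template)."""

    def __init__(self, display_id: Optional[str] = None, *,
                 types: Iterable[str] = (), **kw):
        super().__init__(display_id, **kw)
        self.types: set[str] = set(types)


class ExternallyDefined(Feature):
    """An element whose canonical definition lives outside SBOL, e.g. a
    ChEBI small molecule or UniProt protein record."""

    def __init__(self, display_id: Optional[str] = None, *,
                 types: Iterable[str] = (), definition: Optional[str] = None,
                 **kw):
        super().__init__(display_id, **kw)
        self.types: set[str] = set(types)
        self.definition = definition


class ComponentReference(Feature):
    """Path into a SubComponent's definition, so a nested Feature can take
    part in an Interaction or Constraint of this Component.  ``refers_to``
    may itself be a ComponentReference, giving multi-layer paths."""

    def __init__(self, display_id: Optional[str] = None, *,
                 in_child_of=None, refers_to=None, **kw):
        super().__init__(display_id, **kw)
        self.in_child_of = _uri_of(in_child_of) if in_child_of is not None else None
        self.refers_to = _uri_of(refers_to) if refers_to is not None else None


FEATURE_CLASSES = (SubComponent, SequenceFeature, LocalSubComponent,
                   ExternallyDefined, ComponentReference)


# --------------------------------------------------------------------------
# function: interactions, constraints, interfaces
# --------------------------------------------------------------------------

class Participation(Identified):
    """One Feature's role (SBO participant role) in an Interaction."""

    def __init__(self, display_id: Optional[str] = None, *,
                 roles: Iterable[str] = (), participant=None, **kw):
        super().__init__(display_id, **kw)
        self.roles: set[str] = set(roles)
        self.participant = _uri_of(participant) if participant is not None else None


class Interaction(Identified):
    """A functional relationship (SBO interaction type) between participating
    Features of the owning Component."""

    def __init__(self, display_id: Optional[str] = None, *,
                 types: Iterable[str] = (), **kw):
        super().__init__(display_id, **kw)
        self.types: set[str] = set(types)
        self.participations: list[Participation] = []

    def children(self) -> Iterator[Identified]:
        return iter(self.participations)


class Constraint(Identified):
    """subject–restriction–object relation between two Features; restriction
    comes from the identity, sequential, or topological vocabulary."""

    def __init__(self, display_id: Optional[str] = None, *,
                 restriction: Optional[str] = None,
                 subject=None, object=None, **kw):
        super().__init__(display_id, **kw)
        self.restriction = restriction
        self.subject = _uri_of(subject) if subject is not None else None
        self.object = _uri_of(object) if object is not None else None


class Interface(Identified):
    """Declared inputs, outputs, and non-directional features of a Component.
    Inputs and outputs may intersect (bidirectional features); the
    non-directional set must be disjoint from both."""

    def __init__(self, display_id: Optional[str] = None, *,
                 inputs: Iterable = (), outputs: Iterable = (),
                 nondirectionals: Iterable = (), **kw):
        super().__init__(display_id, **kw)
        self.inputs: set[str] = _uri_set(inputs)
        self.outputs: set[str] = _uri_set(outputs)
        self.nondirectionals: set[str] = _uri_set(nondirectionals)


# --------------------------------------------------------------------------
# the ten main top-level classes (+ the Namespace utility)
# --------------------------------------------------------------------------

class Component(TopLevel):
    """The universal design unit: structure (features, sequences, constraints)
    and function (interactions, interface) in one object.

    ``types`` is a non-empty set of ontology terms — SBO for molecular
    species (e.g. SBO:0000251 for DNA), GO for cells — and ``roles``
    refines the design intent (SO part roles, SBO compartment roles, ...).
    """

    def __init__(self, namespace: Optional[str] = None,
                 display_id: Optional[str] = None, *,
                 types: Iterable[str] = (), roles: Iterable[str] = (), **kw):
        super().__init__(namespace, display_id, **kw)
        self.types: set[str] = set(types)
        self.roles: set[str] = set(roles)
        self.sequences: list[str] = []
        self.features: list[Feature] = []
        self.interactions: list[Interaction] = []
        self.constraints: list[Constraint] = []
        self.interface: Optional[Interface] = None
        self.models: set[str] = set()

    def children(self) -> Iterator[Identified]:
        yield from self.features
        yield from self.interactions
        yield from self.constraints
        if self.interface is not None:
            yield self.interface

    # -- operations --------------------------------------------------------

    def add_sequence(self, sequence) -> None:
        self.sequences.append(_uri_of(sequence))

    def add_feature(self, feature: Feature) -> Feature:
        if not isinstance(feature, Feature):
            raise OwnershipError(f"not a Feature: {feature!r}")
        if isinstance(feature, SequenceFeature) and not feature.locations:
            raise OwnershipError(
                "a SequenceFeature must be associated with at least one "
                "Location")
        self._adopt(feature, "feature")
        self.features.append(feature)
        return feature

    def find_feature(self, ref) -> Optional[Feature]:
        uri = _uri_of(ref)
        for f in self.features:
            if f.uri == uri:
                return f
        return None

    def _require_local(self, ref, what: str) -> str:
        uri = _uri_of(ref)
        if self.find_feature(uri) is None:
            raise OwnershipError(
                f"{what} {uri!r} is not a feature of {self.uri}")
        return uri

    def add_interaction(self, types: Iterable[str],
                        participations: Iterable[tuple] = (),
                        display_id: Optional[str] = None) -> Interaction:
        """Create an Interaction; *participations* is a list of
        ``(roles, feature)`` pairs, each feature belonging to this
        Component."""
        types = set(types)
        if not types:
            raise VocabularyError("an Interaction requires at least one type")
        pairs = []
        for roles, ref in participations:
            roles = set(roles)
            if not roles:
                raise VocabularyError(
                    "a Participation requires at least one role")
            pairs.append((roles, self._require_local(ref, "participant")))
        inter = Interaction(display_id, types=types)
        self._adopt(inter, "interaction")
        self.interactions.append(inter)
        for roles, uri in pairs:
            part = Participation(roles=roles, participant=uri)
            inter._adopt(part, "participation")
            inter.participations.append(part)
        return inter

    def add_constraint(self, restriction: str, subject, object,
                       display_id: Optional[str] = None) -> Constraint:
        from .constraints import ALL_RESTRICTIONS

        if restriction not in ALL_RESTRICTIONS:
            raise VocabularyError(
                f"restriction {restriction!r} is not in the identity, "
                "sequential, or topological vocabulary")
        subj = self._require_local(subject, "constraint subject")
        obj = self._require_local(object, "constraint object")
        if subj == obj:
            raise OwnershipError(
                "constraint subject and object must differ")
        con = Constraint(display_id, restriction=restriction,
                         subject=subj, object=obj)
        self._adopt(con, "constraint")
        self.constraints.append(con)
        return con

    def set_interface(self, inputs: Iterable = (), outputs: Iterable = (),
                      nondirectionals: Iterable = ()) -> Interface:
        """Replace this Component's Interface.  All references must be
        features of this Component; an empty Interface is valid."""
        ins = {self._require_local(r, "interface input") for r in inputs}
        outs = {self._require_local(r, "interface output") for r in outputs}
        nds = {self._require_local(r, "interface nondirectional")
               for r in nondirectionals}
        overlap = nds & (ins | outs)
        if overlap:
            raise OwnershipError(
                "features cannot be both non-directional and directional: "
                + ", ".join(sorted(overlap)))
        iface = Interface("interface", inputs=ins, outputs=outs,
                          nondirectionals=nds)
        self.interface = None
        self._adopt(iface, "interface")
        self.interface = iface
        return iface


class Sequence(TopLevel):
    """Residue string plus the encoding (alphabet) it is written in."""

    def __init__(self, namespace: Optional[str] = None,
                 display_id: Optional[str] = None, *,
                 elements: Optional[str] = None,
                 encoding: Optional[str] = None, **kw):
        super().__init__(namespace, display_id, **kw)
        self.elements = elements
        self.encoding = encoding

    @property
    def length(self) -> Optional[int]:
        return None if self.elements is None else len(self.elements)


class VariableFeature(Identified):
    """Binds one template Feature (usually a LocalSubComponent placeholder)
    to its set of allowed variants."""

    def __init__(self, display_id: Optional[str] = None, *,
                 variable=None, cardinality: str = terms.CARDINALITY_ONE,
                 variants: Iterable = (), variant_collections: Iterable = (),
                 variant_derivations: Iterable = (), **kw):
        super().__init__(display_id, **kw)
        self.variable = _uri_of(variable) if variable is not None else None
        self.cardinality = cardinality
        self.variants: set[str] = _uri_set(variants)
        self.variant_collections: set[str] = _uri_set(variant_collections)
        self.variant_derivations: set[str] = _uri_set(variant_derivations)


class CombinatorialDerivation(TopLevel):
    """A design pattern: a template Component whose variable features range
    over sets of variants."""

    def __init__(self, namespace: Optional[str] = None,
                 display_id: Optional[str] = None, *,
                 template=None, strategy: Optional[str] = None, **kw):
        super().__init__(namespace, display_id, **kw)
        self.template = _uri_of(template) if template is not None else None
        self.strategy = strategy
        self.variable_features: list[VariableFeature] = []

    def children(self) -> Iterator[Identified]:
        return iter(self.variable_features)

    def add_variable_feature(self, vf: VariableFeature) -> VariableFeature:
        self._adopt(vf, "variable")
        self.variable_features.append(vf)
        return vf


class Implementation(TopLevel):
    """A physical artifact (sample, stab, aliquot) realizing a Component."""

    def __init__(self, namespace: Optional[str] = None,
                 display_id: Optional[str] = None, *, built=None, **kw):
        super().__init__(namespace, display_id, **kw)
        self.built = _uri_of(built) if built is not None else None


class Experiment(TopLevel):
    def __init__(self, namespace: Optional[str] = None,
                 display_id: Optional[str] = None, *,
                 members: Iterable = (), **kw):
        super().__init__(namespace, display_id, **kw)
        self.members: set[str] = _uri_set(members)


class ExperimentalData(TopLevel):
    def __init__(self, namespace: Optional[str] = None,
                 display_id: Optional[str] = None, *,
                 attachments: Iterable = (), **kw):
        super().__init__(namespace, display_id, **kw)
        self.attachments: set[str] = _uri_set(attachments)


class Model(TopLevel):
    """Link to an external computational model (e.g. an SBML file)."""

    def __init__(self, namespace: Optional[str] = None,
                 display_id: Optional[str] = None, *,
                 source: Optional[str] = None,
                 language: Optional[str] = None,
                 framework: Optional[str] = None, **kw):
        super().__init__(namespace, display_id, **kw)
        self.source = source
        self.language = language
        self.framework = framework


class Collection(TopLevel):
    def __init__(self, namespace: Optional[str] = None,
                 display_id: Optional[str] = None, *,
                 members: Iterable = (), **kw):
        super().__init__(namespace, display_id, **kw)
        self.members: set[str] = _uri_set(members)


class Attachment(TopLevel):
    def __init__(self, namespace: Optional[str] = None,
                 display_id: Optional[str] = None, *,
                 source: Optional[str] = None, format: Optional[str] = None,
                 size: Optional[int] = None, hash: Optional[str] = None,
                 hash_algorithm: Optional[str] = None, **kw):
        super().__init__(namespace, display_id, **kw)
        self.source = source
        self.format = format
        if size is not None and int(size) < 0:
            raise SbolError("Attachment size must be non-negative")
        self.size = None if size is None else int(size)
        self.hash = hash
        self.hash_algorithm = hash_algorithm


class Usage(Identified):
    """PROV-O qualified usage: an entity plus the roles it played."""

    def __init__(self, display_id: Optional[str] = None, *,
                 entity: Optional[str] = None, roles: Iterable[str] = (),
                 **kw):
        super().__init__(display_id, **kw)
        self.entity = entity
        self.roles: set[str] = set(roles)


class Activity(TopLevel):
    """PROV-O activity linking design/build/test/learn stages."""

    def __init__(self, namespace: Optional[str] = None,
                 display_id: Optional[str] = None, *,
                 types: Iterable[str] = (),
                 ended_at: Optional[str] = None, **kw):
        super().__init__(namespace, display_id, **kw)
        self.types: set[str] = set(types)
        self.ended_at = ended_at  # RFC 3339 text, uninterpreted
        self.usages: list[Usage] = []

    def children(self) -> Iterator[Identified]:
        return iter(self.usages)

    def add_usage(self, entity, roles: Iterable[str] = ()) -> Usage:
        usage = Usage(entity=_uri_of(entity), roles=roles)
        self._adopt(usage, "usage")
        self.usages.append(usage)
        return usage


class Namespace(TopLevel):
    """Utility top-level marking a URI prefix whose members move together
    when a document is re-homed; its own URI *is* the prefix."""

    def __init__(self, uri: Optional[str] = None, **kw):
        if uri is not None and uri.endswith("/"):
            raise IdentityError("Namespace URI may not end with '/'")
        super().__init__(namespace=uri, uri=uri, **kw)


#: the ten main top-level classes of the data model (design: Component,
#: Sequence, CombinatorialDerivation; build: Implementation; test:
#: Experiment, ExperimentalData; learn: Model; plus Collection, Attachment
#: and the PROV-O Activity)
MAIN_TOP_LEVEL_CLASSES: tuple[type, ...] = (
    Component, Sequence, CombinatorialDerivation, Implementation,
    Experiment, ExperimentalData, Model, Collection, Attachment, Activity,
)

#: all concrete top-level classes, including the Namespace utility
TOP_LEVEL_CLASSES: tuple[type, ...] = MAIN_TOP_LEVEL_CLASSES + (Namespace,)


# --------------------------------------------------------------------------
# the document container
# --------------------------------------------------------------------------

class Document:
    """An in-memory set of top-level objects with URI-keyed lookup.

    All URIs must be unique across top-levels and their descendants.
    """

    def __init__(self):
        self._top: dict[str, TopLevel] = {}
        self.prefix_map: dict[str, str] = {}

    @property
    def top_levels(self) -> list[TopLevel]:
        return list(self._top.values())

    def __len__(self) -> int:
        return len(self._top)

    def __iter__(self) -> Iterator[TopLevel]:
        return iter(self._top.values())

    def __contains__(self, ref) -> bool:
        return self.lookup(_uri_of(ref)) is not None

    def add(self, obj: TopLevel) -> TopLevel:
        if not isinstance(obj, TopLevel):
            raise OwnershipError(
                f"only TopLevel objects can be added to a Document: {obj!r}")
        if obj.uri is None:
            raise IdentityError("cannot add an object without a URI")
        require_absolute_iri(obj.uri)
        existing = {o.uri for o in self.walk()}
        new = {obj.uri} | {d.uri for d in obj.descendants() if d.uri}
        clash = existing & new
        if clash:
            raise IdentityError(
                "URI(s) already present in document: " + ", ".join(sorted(clash)))
        self._top[obj.uri] = obj
        return obj

    def extend(self, objs: Iterable[TopLevel]) -> None:
        for obj in objs:
            self.add(obj)

    def remove(self, ref) -> None:
        self._top.pop(_uri_of(ref), None)

    def walk(self) -> Iterator[Identified]:
        """All objects in the document, top-levels and descendants."""
        for top in self._top.values():
            yield top
            yield from top.descendants()

    def lookup(self, uri: str) -> Optional[Identified]:
        """The object with that URI (top-level or descendant), else None."""
        obj = self._top.get(uri)
        if obj is not None:
            return obj
        # descend only into the top-level whose URI prefixes the query
        for top_uri, top in self._top.items():
            if uri.startswith(top_uri + "/"):
                for desc in top.descendants():
                    if desc.uri == uri:
                        return desc
        return None

    @property
    def components(self) -> list[Component]:
        return [o for o in self._top.values() if isinstance(o, Component)]

    def namespaces(self) -> set[str]:
        return {o.namespace for o in self._top.values()
                if getattr(o, "namespace", None)}


# --------------------------------------------------------------------------
# module-level operations
# --------------------------------------------------------------------------

def create_component(namespace: str, display_id: str,
                     types: Iterable[str]) -> Component:
    """Create a Component at ``<namespace>/<displayId>`` with the given
    non-empty set of ontology type terms."""
    require_absolute_iri(namespace)
    require_display_id(display_id)
    types = set(types)
    if not types:
        raise VocabularyError("a Component requires at least one type term")
    return Component(namespace, display_id, types=types)


def document_lookup(doc: Document, uri: str) -> Optional[Identified]:
    """Find the object with *uri* anywhere in *doc*; None when absent."""
    return doc.lookup(uri)


def resolve_reference(doc: Document, ref: ComponentReference) -> Feature:
    """Follow a ComponentReference (possibly through further
    ComponentReferences) to the ultimate concrete Feature."""
    seen: set[str] = set()
    current = ref
    while True:
        if current.uri is not None:
            if current.uri in seen:
                raise ResolutionError(
                    f"cycle in ComponentReference chain at {current.uri}")
            seen.add(current.uri)
        if current.in_child_of is None or current.refers_to is None:
            raise ResolutionError(
                f"ComponentReference {current.uri} is incomplete")
        child = doc.lookup(current.in_child_of)
        if not isinstance(child, SubComponent):
            raise ResolutionError(
                f"inChildOf {current.in_child_of!r} does not resolve to a "
                "SubComponent")
        definition = doc.lookup(child.instance_of) if child.instance_of else None
        if not isinstance(definition, Component):
            raise ResolutionError(
                f"SubComponent {child.uri} has no resolvable definition")
        target = definition.find_feature(current.refers_to)
        if target is None:
            raise ResolutionError(
                f"refersTo {current.refers_to!r} is not a feature of "
                f"{definition.uri}")
        if isinstance(target, ComponentReference):
            current = target
            continue
        return target


def enumerate_combinations(doc: Document,
                           derivation: CombinatorialDerivation
                           ) -> list[dict[str, Optional[str]]]:
    """Exhaustively enumerate a combinatorial derivation.

    Returns one assignment per derived design, mapping each variable
    feature's URI to the chosen variant Component URI (or None for the
    empty choice under zeroOrOne).  Only the ``one`` and ``zeroOrOne``
    cardinalities are enumerable; others raise.
    """
    import itertools

    choice_sets: list[tuple[str, list[Optional[str]]]] = []
    for vf in derivation.variable_features:
        options: list[Optional[str]] = sorted(vf.variants)
        for coll_uri in sorted(vf.variant_collections):
            coll = doc.lookup(coll_uri)
            if isinstance(coll, Collection):
                options.extend(sorted(coll.members))
        if vf.variant_derivations:
            raise SbolError(
                "nested variantDerivations are not enumerable here")
        if vf.cardinality == terms.CARDINALITY_ZERO_OR_ONE:
            options = [None] + options
        elif vf.cardinality != terms.CARDINALITY_ONE:
            raise SbolError(
                f"cardinality {vf.cardinality!r} is not enumerable")
        choice_sets.append((vf.variable, options))
    keys = [k for k, _ in choice_sets]
    return [dict(zip(keys, combo))
            for combo in itertools.product(*(opts for _, opts in choice_sets))]
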
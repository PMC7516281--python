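"""SBOL2-style document migration.

SBOL2 split every design into a structural ComponentDefinition hierarchy and
a parallel functional ModuleDefinition hierarchy, stitched together with
MapsTo identity links.  SBOL3 unifies both sides in the Component class, so
migration is mostly a matter of *collapsing*: where a ModuleDefinition-level
FunctionalComponent and a ComponentDefinition-internal component instance
are declared identical by a MapsTo, only one SubComponent survives.

Mapping summary:

* ComponentDefinition → Component; ModuleDefinition → Component typed as an
  SBO functional entity;
* SBOL2 Component / Module / FunctionalComponent instances → SubComponents;
* SequenceAnnotation with a component link → locations on that SubComponent,
  without one → SequenceFeature;
* MapsTo → deleted when the merge makes its two ends the same object,
  otherwise a ComponentReference;
* FunctionalComponent direction (in/out/inout) → Interface membership;
* the SBOL2 access field has no SBOL3 home and is dropped with a report
  entry.

Merge policy: a ModuleDefinition absorbs every ComponentDefinition whose
internals are mapped out of it via MapsTo — the absorbed definition's
component instances are hoisted into the merged parent and unified with the
module-level duplicates, which is exactly what makes the classic
toggle-switch migration produce zero ComponentReference objects.  When
exactly one definition is absorbed the merged Component keeps that
definition's identity; otherwise it keeps the ModuleDefinition's.

The snapshot reader consumes RDF carrying SBOL2 predicates directly (it is
not a full SBOL2 library — only the surface needed for migration), folding
any trailing URI version segments into the prefix.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

from .. import terms
from ..errors import ConversionError
from ..model import (Component, ComponentReference, Document, Participation,
                     Range, Sequence, SequenceFeature, SubComponent)

# --------------------------------------------------------------------------
# snapshot record forms
# --------------------------------------------------------------------------


@dataclass
class S2MapsTo:
    """Identity link: *local* (an instance in the containing context) is the
    same design element as *remote* (an instance inside the definition of
    the instance owning this link)."""

    uri: str
    local: str
    remote: str
    refinement: Optional[str] = None


@dataclass
class S2ComponentInstance:
    """SBOL2 Component (inside a ComponentDefinition)."""

    uri: str
    display_id: str
    definition: str
    access: Optional[str] = None
    maps_tos: list[S2MapsTo] = field(default_factory=list)


@dataclass
class S2FunctionalComponent(S2ComponentInstance):
    """SBOL2 FunctionalComponent (inside a ModuleDefinition)."""

    direction: Optional[str] = None  # in | out | inout | none


@dataclass
class S2Module:
    """SBOL2 Module: instantiation of another ModuleDefinition."""

    uri: str
    display_id: str
    definition: str
    maps_tos: list[S2MapsTo] = field(default_factory=list)


@dataclass
class S2SequenceAnnotation:
    uri: str
    display_id: str
    component: Optional[str] = None  # link to an S2ComponentInstance
    roles: set[str] = field(default_factory=set)
    ranges: list[tuple[int, int]] = field(default_factory=list)
    reverse: bool = False


@dataclass
class S2ComponentDefinition:
    uri: str
    display_id: str
    types: set[str] = field(default_factory=set)
    roles: set[str] = field(default_factory=set)
    components: list[S2ComponentInstance] = field(default_factory=list)
    sequence_annotations: list[S2SequenceAnnotation] = field(
        default_factory=list)
    sequence_elements: Optional[str] = None


@dataclass
class S2Interaction:
    uri: str
    display_id: str
    types: set[str] = field(default_factory=set)
    #: list of (roles, participant FunctionalComponent URI)
    participations: list[tuple[set[str], str]] = field(default_factory=list)


@dataclass
class S2ModuleDefinition:
    uri: str
    display_id: str
    functional_components: list[S2FunctionalComponent] = field(
        default_factory=list)
    modules: list[S2Module] = field(default_factory=list)
    interactions: list[S2Interaction] = field(default_factory=list)


@dataclass
class Sbol2Snapshot:
    """Minimal, reference-closed SBOL2 document surface."""

    component_definitions: list[S2ComponentDefinition] = field(
        default_factory=list)
    module_definitions: list[S2ModuleDefinition] = field(default_factory=list)
    namespace: str = "http://example.com/sbol2"

    def total_objects(self) -> int:
        n = len(self.component_definitions) + len(self.module_definitions)
        for cd in self.component_definitions:
            n += len(cd.components) + len(cd.sequence_annotations)
            n += sum(len(c.maps_tos) for c in cd.components)
        for md in self.module_definitions:
            n += len(md.functional_components) + len(md.modules)
            n += len(md.interactions)
            n += sum(len(f.maps_tos) for f in md.functional_components)
            n += sum(len(m.maps_tos) for m in md.modules)
        return n

    def check_closed(self) -> None:
        cd_uris = {cd.uri for cd in self.component_definitions}
        md_uris = {md.uri for md in self.module_definitions}
        instance_uris = set()
        for cd in self.component_definitions:
            instance_uris.update(c.uri for c in cd.components)
        for md in self.module_definitions:
            instance_uris.update(f.uri for f in md.functional_components)
            instance_uris.update(m.uri for m in md.modules)
        for cd in self.component_definitions:
            for c in cd.components:
                if c.definition not in cd_uris:
                    raise ConversionError(
                        f"dangling definition reference {c.definition!r}")
        for md in self.module_definitions:
            for f in md.functional_components:
                if f.definition not in cd_uris:
                    raise ConversionError(
                        f"dangling definition reference {f.definition!r}")
                for mt in f.maps_tos:
                    if mt.local not in instance_uris or \
                            mt.remote not in instance_uris:
                        raise ConversionError(
                            f"dangling MapsTo end in {mt.uri!r}")
            for m in md.modules:
                if m.definition not in md_uris:
                    raise ConversionError(
                        f"dangling module definition {m.definition!r}")


@dataclass
class MigrationReport:
    """Accounting of one migration run."""

    converted: dict[str, int] = field(default_factory=dict)
    collapsed_maps_tos: list[str] = field(default_factory=list)
    component_references: list[str] = field(default_factory=list)
    unconvertible: list[str] = field(default_factory=list)
    dropped_access: list[str] = field(default_factory=list)

    def count(self, row: str, n: int = 1) -> None:
        self.converted[row] = self.converted.get(row, 0) + n

    @property
    def converted_total(self) -> int:
        return sum(self.converted.values())


# --------------------------------------------------------------------------
# migration
# --------------------------------------------------------------------------

def _split_uri(uri: str) -> tuple[str, str]:
    prefix, _, display_id = uri.rpartition("/")
    return prefix, display_id


def sbol2_to_sbol3(snapshot: Sbol2Snapshot
                   ) -> tuple[Document, MigrationReport]:
    """Migrate an SBOL2 snapshot to an SBOL3 Document plus a report."""
    snapshot.check_closed()
    report = MigrationReport()
    doc = Document()

    cd_by_uri = {cd.uri: cd for cd in snapshot.component_definitions}
    md_by_uri = {md.uri: md for md in snapshot.module_definitions}

    # which ComponentDefinitions are absorbed into which ModuleDefinition:
    # a CD is absorbed when a MapsTo maps one of its internal instances out
    # to the module level
    instance_home: dict[str, str] = {}  # instance uri -> owning CD/MD uri
    for cd in snapshot.component_definitions:
        for inst in cd.components:
            instance_home[inst.uri] = cd.uri
    for md in snapshot.module_definitions:
        for fc in md.functional_components:
            instance_home[fc.uri] = md.uri

    absorbed_into: dict[str, str] = {}  # CD uri -> MD uri
    for md in snapshot.module_definitions:
        for fc in md.functional_components:
            for mt in fc.maps_tos:
                remote_home = instance_home.get(mt.remote)
                if remote_home in cd_by_uri:
                    absorbed_into[remote_home] = md.uri

    # 1. surviving ComponentDefinitions -> Components
    sub_by_instance: dict[str, SubComponent] = {}
    for cd in snapshot.component_definitions:
        if cd.uri in absorbed_into:
            continue
        comp = _convert_cd(cd, doc, report, sub_by_instance)
        doc.add(comp)
        report.count("ComponentDefinition->Component")

    # 2. ModuleDefinitions -> merged parent Components
    for md in snapshot.module_definitions:
        merged_cds = [cd_by_uri[u] for u, m in sorted(absorbed_into.items())
                      if m == md.uri]
        if len(merged_cds) == 1:
            host = merged_cds[0]
            prefix, display_id = _split_uri(host.uri)
            types = set(host.types) or {terms.SBO_DNA}
            roles = set(host.roles)
        else:
            prefix, display_id = _split_uri(md.uri)
            types = {terms.SBO_FUNCTIONAL_ENTITY}
            roles = {terms.SBO_FUNCTIONAL_ENTITY}
        parent = Component(prefix, display_id, types=types, roles=roles)
        doc.add(parent)
        report.count("ModuleDefinition->Component")
        for cd in merged_cds:
            report.count("ComponentDefinition->Component(merged)")

        # hoist instances of absorbed CDs
        local_annotations: list[S2SequenceAnnotation] = []
        for cd in merged_cds:
            for inst in cd.components:
                sub = SubComponent(inst.display_id,
                                   instance_of=inst.definition)
                parent.add_feature(sub)
                sub_by_instance[inst.uri] = sub
                report.count("Component->SubComponent")
                if inst.access:
                    report.dropped_access.append(inst.uri)
            local_annotations.extend(cd.sequence_annotations)

        # map module-level FunctionalComponents
        direction_by_sub: dict[str, str] = {}
        for fc in md.functional_components:
            if fc.access:
                report.dropped_access.append(fc.uri)
            if fc.definition in absorbed_into \
                    and absorbed_into[fc.definition] == md.uri:
                # the container instance of an absorbed CD disappears
                report.count("FunctionalComponent->merged")
                continue
            collapse_target = None
            for holder in md.functional_components:
                for mt in holder.maps_tos:
                    if mt.local == fc.uri and mt.remote in sub_by_instance:
                        collapse_target = sub_by_instance[mt.remote]
            if collapse_target is not None:
                sub_by_instance[fc.uri] = collapse_target
                report.count("FunctionalComponent->collapsed")
            else:
                sub = SubComponent(fc.display_id, instance_of=fc.definition)
                parent.add_feature(sub)
                sub_by_instance[fc.uri] = sub
                report.count("FunctionalComponent->SubComponent")
            if fc.direction and fc.direction != "none":
                direction_by_sub[sub_by_instance[fc.uri].uri] = fc.direction

        # modules (instantiations of other ModuleDefinitions)
        for module in md.modules:
            target = md_by_uri[module.definition]
            mprefix, mdid = _split_uri(target.uri)
            sub = SubComponent(module.display_id,
                               instance_of=f"{mprefix}/{mdid}")
            parent.add_feature(sub)
            sub_by_instance[module.uri] = sub
            report.count("Module->SubComponent")

        # MapsTo accounting: collapse or emit a ComponentReference
        for holder in md.functional_components + md.modules:
            holder_sub = sub_by_instance.get(holder.uri)
            for mt in holder.maps_tos:
                local_sub = sub_by_instance.get(mt.local)
                remote_sub = sub_by_instance.get(mt.remote)
                if local_sub is not None and local_sub is remote_sub:
                    report.collapsed_maps_tos.append(mt.uri)
                    report.count("MapsTo->collapsed")
                    continue
                if holder_sub is None:
                    report.unconvertible.append(mt.uri)
                    continue
                ref = ComponentReference(
                    in_child_of=holder_sub, refers_to=mt.remote)
                parent.add_feature(ref)
                sub_by_instance[mt.local] = ref
                report.component_references.append(ref.uri)
                report.count("MapsTo->ComponentReference")

        # sequence annotations of absorbed CDs
        for sa in local_annotations:
            _convert_annotation(sa, parent, sub_by_instance, report)

        # interactions
        for inter in md.interactions:
            new = parent.add_interaction(
                types=set(inter.types) or {terms.SBO_FUNCTIONAL_ENTITY},
                display_id=inter.display_id)
            for roles, participant in inter.participations:
                target = sub_by_instance.get(participant)
                if target is None:
                    report.unconvertible.append(participant)
                    continue
                part = Participation(roles=set(roles), participant=target)
                new._adopt(part, "participation")
                new.participations.append(part)
            report.count("Interaction->Interaction")

        # interface from FunctionalComponent directions
        if direction_by_sub:
            inputs = {u for u, d in direction_by_sub.items()
                      if d in ("in", "inout")}
            outputs = {u for u, d in direction_by_sub.items()
                       if d in ("out", "inout")}
            parent.set_interface(inputs=inputs, outputs=outputs)

    return doc, report


def _convert_cd(cd: S2ComponentDefinition, doc: Document,
                report: MigrationReport,
                sub_by_instance: dict[str, SubComponent]) -> Component:
    prefix, display_id = _split_uri(cd.uri)
    comp = Component(prefix, display_id,
                     types=set(cd.types) or {terms.SBO_DNA},
                     roles=set(cd.roles))
    if cd.sequence_elements:
        seq = Sequence(prefix, display_id + "_seq",
                       elements=cd.sequence_elements,
                       encoding=terms.ENC_IUPAC_DNA)
        doc.add(seq)
        comp.add_sequence(seq)
    for inst in cd.components:
        sub = SubComponent(inst.display_id, instance_of=inst.definition)
        comp.add_feature(sub)
        sub_by_instance[inst.uri] = sub
        report.count("Component->SubComponent")
        if inst.access:
            report.dropped_access.append(inst.uri)
    for sa in cd.sequence_annotations:
        _convert_annotation(sa, comp, sub_by_instance, report)
    return comp


def _convert_annotation(sa: S2SequenceAnnotation, parent: Component,
                        sub_by_instance: dict[str, SubComponent],
                        report: MigrationReport) -> None:
    seq_uri = parent.sequences[0] if parent.sequences else None
    ranges = [Range(seq_uri, start, end) for start, end in sa.ranges]
    orientation = terms.REVERSE_COMPLEMENT if sa.reverse else None
    if sa.component is not None and sa.component in sub_by_instance:
        sub = sub_by_instance[sa.component]
        for rng in ranges:
            sub.add_location(rng)
        if orientation:
            sub.orientation = orientation
        report.count("SequenceAnnotation->locations")
    else:
        if not ranges:
            report.unconvertible.append(sa.uri)
            return
        feat = SequenceFeature(sa.display_id,
                               roles=set(sa.roles) or
                               {terms.SO_SEQUENCE_FEATURE},
                               locations=ranges, orientation=orientation)
        parent.add_feature(feat)
        report.count("SequenceAnnotation->SequenceFeature")


# --------------------------------------------------------------------------
# minimal SBOL2 RDF reader
# --------------------------------------------------------------------------

def _fold_version(uri: str, persistent: Optional[str],
                  version: Optional[str]) -> str:
    """Fold a trailing version segment into the URI prefix:
    <prefix>/<displayId>/<version> becomes <prefix>/<version>/<displayId>."""
    if persistent and version and uri == f"{persistent}/{version}":
        prefix, _, display_id = persistent.rpartition("/")
        return f"{prefix}/{version}/{display_id}"
    return uri


def read_sbol2(data: Union[bytes, str],
               format: str = "xml") -> Sbol2Snapshot:
    """Parse RDF carrying SBOL2 predicates into a snapshot."""
    from rdflib import RDF, Graph
    from rdflib import Namespace as NS

    S2 = NS(terms.SBOL2)
    g = Graph()
    g.parse(data=data, format=format)

    uri_map: dict[str, str] = {}
    for s in set(g.subjects()):
        persistent = g.value(s, S2.persistentIdentity)
        version = g.value(s, S2.version)
        uri_map[str(s)] = _fold_version(
            str(s),
            str(persistent) if persistent else None,
            str(version) if version else None)

    def mapped(term) -> str:
        return uri_map.get(str(term), str(term))

    def display_id(s) -> str:
        did = g.value(s, S2.displayId)
        return str(did) if did else mapped(s).rpartition("/")[2]

    def read_maps_tos(s) -> list[S2MapsTo]:
        out = []
        for mt in sorted(g.objects(s, S2.mapsTo), key=str):
            local = g.value(mt, S2.local)
            remote = g.value(mt, S2.remote)
            refinement = g.value(mt, S2.refinement)
            out.append(S2MapsTo(mapped(mt), mapped(local), mapped(remote),
                                str(refinement) if refinement else None))
        return out

    def read_ranges(sa) -> tuple[list[tuple[int, int]], bool]:
        ranges, reverse = [], False
        for loc in sorted(g.objects(sa, S2.location), key=str):
            start, end = g.value(loc, S2.start), g.value(loc, S2.end)
            if start is not None and end is not None:
                ranges.append((int(start), int(end)))
            orient = g.value(loc, S2.orientation)
            if orient is not None and str(orient).endswith(
                    "reverseComplement"):
                reverse = True
        return ranges, reverse

    snapshot = Sbol2Snapshot()
    for s in sorted(g.subjects(RDF.type, S2.ComponentDefinition), key=str):
        cd = S2ComponentDefinition(
            uri=mapped(s), display_id=display_id(s),
            types={str(t) for t in g.objects(s, S2.type)},
            roles={str(r) for r in g.objects(s, S2.role)})
        for c in sorted(g.objects(s, S2.component), key=str):
            inst = S2ComponentInstance(
                uri=mapped(c), display_id=display_id(c),
                definition=mapped(g.value(c, S2.definition)),
                access=_local_name(g.value(c, S2.access)),
                maps_tos=read_maps_tos(c))
            cd.components.append(inst)
        for sa in sorted(g.objects(s, S2.sequenceAnnotation), key=str):
            ranges, reverse = read_ranges(sa)
            link = g.value(sa, S2.component)
            cd.sequence_annotations.append(S2SequenceAnnotation(
                uri=mapped(sa), display_id=display_id(sa),
                component=mapped(link) if link else None,
                roles={str(r) for r in g.objects(sa, S2.role)},
                ranges=ranges, reverse=reverse))
        snapshot.component_definitions.append(cd)

    for s in sorted(g.subjects(RDF.type, S2.ModuleDefinition), key=str):
        md = S2ModuleDefinition(uri=mapped(s), display_id=display_id(s))
        for fc in sorted(g.objects(s, S2.functionalComponent), key=str):
            md.functional_components.append(S2FunctionalComponent(
                uri=mapped(fc), display_id=display_id(fc),
                definition=mapped(g.value(fc, S2.definition)),
                access=_local_name(g.value(fc, S2.access)),
                direction=_local_name(g.value(fc, S2.direction)),
                maps_tos=read_maps_tos(fc)))
        for m in sorted(g.objects(s, S2.module), key=str):
            md.modules.append(S2Module(
                uri=mapped(m), display_id=display_id(m),
                definition=mapped(g.value(m, S2.definition)),
                maps_tos=read_maps_tos(m)))
        for inter in sorted(g.objects(s, S2.interaction), key=str):
            i2 = S2Interaction(
                uri=mapped(inter), display_id=display_id(inter),
                types={str(t) for t in g.objects(inter, S2.type)})
            for p in sorted(g.objects(inter, S2.participation), key=str):
                roles = {str(r) for r in g.objects(p, S2.role)}
                participant = g.value(p, S2.participant)
                i2.participations.append((roles, mapped(participant)))
            md.interactions.append(i2)
        snapshot.module_definitions.append(md)
    return snapshot


def _local_name(term) -> Optional[str]:
    if term is None:
        return None
    text = str(term)
    for sep in ("#", "/"):
        if sep in text:
            text = text.rpartition(sep)[2]
    return text
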
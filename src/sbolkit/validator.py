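"""Structural and vocabulary validation of SBOL3 documents.

Each rule has a stable id, a severity, and a checker; rules always all run
(findings never abort validation) and the finding list is deterministic:
sorted by subject URI, then rule id.  Problems are findings, not exceptions.

Severity policy (artifact-defined — the standard states rules, not a
severity taxonomy): violations of structural invariants are errors;
recommended-practice findings (ontology term provenance, empty interactions)
are warnings.  Strict mode escalates vocabulary warnings to errors; lenient
is the default.

Ontology-term membership is checked against the shipped curated namespace
prefixes (subsets of SO/SBO/GO and friends) — never against live ontology
services.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Iterator

from . import terms
from .constraints import ALL_RESTRICTIONS
from .errors import SbolError
from .identity import validate_display_id
from .model import (Collection, CombinatorialDerivation, Component,
                    ComponentReference, Cut, Document, Experiment,
                    ExternallyDefined, Feature, LocalSubComponent,
                    Namespace, Range, Sequence, SequenceFeature,
                    SubComponent, resolve_reference)

ERROR = "error"
WARNING = "warning"

STRICT = "strict"
LENIENT = "lenient"


@dataclass(frozen=True)
class ValidationFinding:
    """One rule violation: stable rule id, severity, offending subject URI,
    and a human-readable message."""

    rule_id: str
    severity: str
    subject: str
    message: str

    def to_record(self) -> dict:
        return {"ruleId": self.rule_id, "severity": self.severity,
                "subject": self.subject, "message": self.message}

    def __str__(self) -> str:
        return f"{self.severity.upper()} {self.rule_id} {self.subject}: " \
               f"{self.message}"


@dataclass(frozen=True)
class Rule:
    rule_id: str
    severity: str
    vocabulary: bool  # escalates under strict mode
    description: str
    checker: Callable[[Document], Iterator[tuple[str, str]]]


def _components(doc: Document) -> Iterator[Component]:
    for top in doc.top_levels:
        if isinstance(top, Component):
            yield top


def _features(doc: Document) -> Iterator[tuple[Component, Feature]]:
    for comp in _components(doc):
        for f in comp.features:
            yield comp, f


# --- checkers: yield (subject URI, message) pairs ---------------------------

def _check_uri_structure(doc):
    for top in doc.top_levels:
        ns = getattr(top, "namespace", None)
        if not ns:
            yield top.uri, "top-level object has no namespace"
            continue
        if not (top.uri == ns or top.uri.startswith(ns + "/")):
            yield top.uri, f"namespace {ns!r} is not a prefix of the URI"
        if top.display_id and not top.uri.endswith("/" + top.display_id) \
                and top.uri != top.display_id:
            yield top.uri, (
                "URI does not end with '/' + displayId "
                f"({top.display_id!r}); the required structure is "
                "<prefix>/<displayId>")


def _check_child_uris(doc):
    for obj in doc.walk():
        for child in obj.children():
            if child.uri is None or obj.uri is None \
                    or not child.uri.startswith(obj.uri + "/"):
                yield (child.uri or "<no uri>",
                       f"owned child URI does not extend owner URI {obj.uri!r}")


def _check_display_ids(doc):
    for obj in doc.walk():
        if obj.display_id is not None \
                and not validate_display_id(obj.display_id):
            yield obj.uri, f"invalid displayId {obj.display_id!r}"


def _check_component_types(doc):
    for comp in _components(doc):
        if not comp.types:
            yield comp.uri, "Component must have at least one type term"


def _check_feature_types(doc):
    for _, f in _features(doc):
        if isinstance(f, (LocalSubComponent, ExternallyDefined)) \
                and not f.types:
            yield f.uri, (f"{type(f).__name__} must have at least one "
                          "type term")


def _check_sequences(doc):
    for top in doc.top_levels:
        if not isinstance(top, Sequence):
            continue
        if top.elements is not None:
            if top.encoding is None:
                yield top.uri, "Sequence with elements must declare an encoding"
            else:
                alphabet = terms.ENCODING_ALPHABETS.get(top.encoding)
                if alphabet is not None:
                    bad = set(top.elements.upper()) - alphabet
                    if bad:
                        yield top.uri, (
                            "elements contain characters illegal under the "
                            f"declared encoding: {''.join(sorted(bad))}")


def _check_sequence_features(doc):
    for _, f in _features(doc):
        if isinstance(f, SequenceFeature) and not f.locations:
            yield f.uri, ("a SequenceFeature must be associated with at "
                          "least one Location")


def _check_ranges(doc):
    for _, f in _features(doc):
        for loc in f.locations:
            if isinstance(loc, Range):
                if not 1 <= loc.start <= loc.end:
                    yield loc.uri, (f"Range {loc.start}..{loc.end} violates "
                                    "1 <= start <= end")
                elif loc.sequence:
                    seq = doc.lookup(loc.sequence)
                    if isinstance(seq, Sequence) and seq.length is not None \
                            and loc.end > seq.length:
                        yield loc.uri, (
                            f"Range end {loc.end} exceeds sequence length "
                            f"{seq.length}")
            elif isinstance(loc, Cut) and loc.at < 0:
                yield loc.uri, f"Cut position {loc.at} is negative"


def _check_restrictions(doc):
    for comp in _components(doc):
        for con in comp.constraints:
            if con.restriction not in ALL_RESTRICTIONS:
                yield con.uri, (
                    f"restriction {con.restriction!r} is not in the closed "
                    "identity/sequential/topological vocabulary")


def _check_constraint_locality(doc):
    for comp in _components(doc):
        local = {f.uri for f in comp.features}
        for con in comp.constraints:
            if con.subject == con.object:
                yield con.uri, "constraint subject and object must differ"
            for label, ref in (("subject", con.subject),
                               ("object", con.object)):
                if ref not in local:
                    yield con.uri, (f"constraint {label} {ref!r} is not a "
                                    "feature of the owning Component")


def _check_participations(doc):
    for comp in _components(doc):
        local = {f.uri for f in comp.features}
        for inter in comp.interactions:
            for part in inter.participations:
                if not part.roles:
                    yield part.uri, "Participation must have at least one role"
                if part.participant not in local:
                    yield part.uri, (
                        f"participant {part.participant!r} is not a feature "
                        "of the owning Component")


def _check_interaction_types(doc):
    for comp in _components(doc):
        for inter in comp.interactions:
            if not inter.types:
                yield inter.uri, "Interaction must have at least one type term"


def _check_empty_interactions(doc):
    for comp in _components(doc):
        for inter in comp.interactions:
            if inter.types and not inter.participations:
                yield inter.uri, "Interaction has no participations"


def _check_interfaces(doc):
    for comp in _components(doc):
        iface = comp.interface
        if iface is None:
            continue
        local = {f.uri for f in comp.features}
        for label, refs in (("input", iface.inputs),
                            ("output", iface.outputs),
                            ("nondirectional", iface.nondirectionals)):
            for ref in sorted(refs - local):
                yield iface.uri, (f"interface {label} {ref!r} is not a "
                                  "feature of the owning Component")
        overlap = iface.nondirectionals & (iface.inputs | iface.outputs)
        for ref in sorted(overlap):
            yield iface.uri, (f"feature {ref!r} is both non-directional "
                              "and directional")


def _check_vocabulary(doc):
    def foreign(term: str) -> bool:
        return not any(term.startswith(p)
                       for p in terms.RECOGNIZED_TERM_PREFIXES) \
            and not term.startswith(terms.SBOL3)

    for comp in _components(doc):
        for term in sorted(comp.types | comp.roles):
            if foreign(term):
                yield comp.uri, (
                    f"term {term!r} is outside the recognized ontology "
                    "namespaces (SO/SBO/GO et al.)")
    for _, f in _features(doc):
        f_terms = set(f.roles) | set(getattr(f, "types", ()))
        for term in sorted(f_terms):
            if foreign(term):
                yield f.uri, (
                    f"term {term!r} is outside the recognized ontology "
                    "namespaces (SO/SBO/GO et al.)")


def _check_dangling_refs(doc):
    doc_namespaces = {ns.rstrip("/") for ns in doc.namespaces()}

    def internal(uri: str) -> bool:
        return any(uri == ns or uri.startswith(ns + "/")
                   for ns in doc_namespaces)

    for comp in _components(doc):
        for f in comp.features:
            if isinstance(f, SubComponent) and f.instance_of:
                if internal(f.instance_of) and f.instance_of not in doc:
                    yield f.uri, (f"instanceOf {f.instance_of!r} does not "
                                  "resolve within the document")
    for top in doc.top_levels:
        refs: set[str] = set()
        if isinstance(top, (Collection, Experiment)):
            refs = top.members
        elif isinstance(top, CombinatorialDerivation) and top.template:
            refs = {top.template}
        for ref in sorted(refs):
            if internal(ref) and ref not in doc:
                yield top.uri, (f"reference {ref!r} does not resolve within "
                                "the document")


def _check_component_references(doc):
    for comp, f in _features(doc):
        if not isinstance(f, ComponentReference):
            continue
        local = {x.uri for x in comp.features}
        if f.in_child_of not in local:
            yield f.uri, (f"inChildOf {f.in_child_of!r} is not a feature of "
                          "the owning Component")
            continue
        try:
            resolve_reference(doc, f)
        except SbolError as exc:
            yield f.uri, f"reference does not resolve: {exc}"


def _check_namespace_objects(doc):
    for top in doc.top_levels:
        if isinstance(top, Namespace) and top.uri.endswith("/"):
            yield top.uri, "Namespace URI may not end with '/'"


def _check_variable_features(doc):
    for top in doc.top_levels:
        if not isinstance(top, CombinatorialDerivation):
            continue
        template = doc.lookup(top.template) if top.template else None
        template_features = {f.uri for f in template.features} \
            if isinstance(template, Component) else set()
        for vf in top.variable_features:
            if vf.variable not in template_features:
                yield vf.uri, (f"variable {vf.variable!r} does not resolve "
                               "to a feature of the template")
            if not (vf.variants or vf.variant_collections
                    or vf.variant_derivations):
                yield vf.uri, ("at least one of variants, variantCollections "
                               "or variantDerivations must be non-empty")


RULES: tuple[Rule, ...] = (
    Rule("SBOL3-URI-001", ERROR, False,
         "Top-level URIs must follow the required <prefix>/<displayId> "
         "structure, with the namespace a prefix of the URI.",
         _check_uri_structure),
    Rule("SBOL3-URI-002", ERROR, False,
         "Every owned child's URI must extend its owner's URI by one "
         "'/<displayId>' segment.", _check_child_uris),
    Rule("SBOL3-ID-001", ERROR, False,
         "displayId, when present, must match [A-Za-z_][A-Za-z0-9_]*.",
         _check_display_ids),
    Rule("SBOL3-TYPE-001", ERROR, False,
         "A Component must carry at least one ontology type term (SBO for "
         "molecular species, GO for cells).", _check_component_types),
    Rule("SBOL3-TYPE-002", ERROR, False,
         "LocalSubComponent and ExternallyDefined features must carry at "
         "least one type term.", _check_feature_types),
    Rule("SBOL3-SEQ-001", ERROR, False,
         "A Sequence with elements must declare an encoding, and the "
         "elements must be legal under it.", _check_sequences),
    Rule("SBOL3-FEAT-001", ERROR, False,
         "A SequenceFeature must be associated with at least one Location.",
         _check_sequence_features),
    Rule("SBOL3-RANGE-001", ERROR, False,
         "Ranges are 1-based inclusive with start <= end, and must not "
         "extend past the referenced sequence.", _check_ranges),
    Rule("SBOL3-RESTR-001", ERROR, False,
         "A Constraint's restriction must come from the closed identity, "
         "sequential, or topological vocabulary.", _check_restrictions),
    Rule("SBOL3-CONSTR-001", ERROR, False,
         "A Constraint's subject and object must be distinct features of "
         "the owning Component.", _check_constraint_locality),
    Rule("SBOL3-PART-001", ERROR, False,
         "A Participation needs at least one role and its participant must "
         "be a feature of the owning Component.", _check_participations),
    Rule("SBOL3-INT-001", ERROR, False,
         "An Interaction must carry at least one SBO type term.",
         _check_interaction_types),
    Rule("SBOL3-INT-002", WARNING, False,
         "An Interaction without participations expresses nothing "
         "(permitted, but probably unintended).", _check_empty_interactions),
    Rule("SBOL3-IFACE-001", ERROR, False,
         "Interface references must be features of the owning Component, "
         "and non-directional features must not also be directional.",
         _check_interfaces),
    Rule("SBOL3-VOCAB-001", WARNING, True,
         "Type and role terms should come from recognized ontologies "
         "(SO, SBO, GO, ...).", _check_vocabulary),
    Rule("SBOL3-REF-001", ERROR, False,
         "Internal references must resolve within the document; references "
         "outside the document's namespaces are treated as external.",
         _check_dangling_refs),
    Rule("SBOL3-CREF-001", ERROR, False,
         "A ComponentReference's inChildOf must be a local SubComponent and "
         "its refersTo chain must resolve without cycles.",
         _check_component_references),
    Rule("SBOL3-NS-001", ERROR, False,
         "A Namespace object's URI is the prefix itself and may not end "
         "with '/'.", _check_namespace_objects),
    Rule("SBOL3-CD-001", ERROR, False,
         "Each VariableFeature must bind a feature of the template and "
         "offer at least one variant source.", _check_variable_features),
)

_RULES_BY_ID = {rule.rule_id: rule for rule in RULES}


def validate_document(doc: Document,
                      strictness: str = LENIENT) -> list[ValidationFinding]:
    """Run every rule over *doc*; returns deterministic, ordered findings
    (empty iff fully conformant at the given strictness)."""
    if strictness not in (STRICT, LENIENT):
        raise ValueError(f"strictness must be 'strict' or 'lenient', "
                         f"got {strictness!r}")
    findings: list[ValidationFinding] = []
    for rule in RULES:
        severity = rule.severity
        if strictness == STRICT and rule.vocabulary:
            severity = ERROR
        for subject, message in rule.checker(doc):
            findings.append(ValidationFinding(rule.rule_id, severity,
                                              subject or "<no uri>", message))
    findings.sort(key=lambda f: (f.subject, f.rule_id))
    return findings


def errors_only(findings) -> list[ValidationFinding]:
    return [f for f in findings if f.severity == ERROR]


def explain_rule(rule_id: str) -> str:
    """Human-readable description of a registered rule."""
    rule = _RULES_BY_ID.get(rule_id)
    if rule is None:
        raise KeyError(f"unknown rule id: {rule_id!r}")
    return f"{rule.rule_id} [{rule.severity}]: {rule.description}"


def findings_as_text(findings) -> str:
    return "\n".join(str(f) for f in findings)


def findings_as_json(findings) -> str:
    return json.dumps([f.to_record() for f in findings], indent=2)
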
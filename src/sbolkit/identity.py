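"""URI construction, displayId validation, and namespace handling.

SBOL3 requires every top-level object to have a URI of the form
``<namespace prefix>/<displayId>``, with owned children extending their
owner's URI by one ``/<displayId>`` segment.  Versioning is deliberately not
modeled: a version embedded in the prefix, embedded in the displayId, or
absent entirely are all accepted and never interpreted.

Only ASCII URIs are supported; internationalized identifiers are rejected
with a clear error.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING
from urllib.parse import urlsplit

from .errors import IdentityError

if TYPE_CHECKING:  # pragma: no cover
    from .model import Document

DISPLAY_ID_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*\Z")


def validate_display_id(candidate: str) -> bool:
    """True iff *candidate* is a legal displayId (identifier alphabet,
    no leading digit)."""
    return isinstance(candidate, str) and bool(DISPLAY_ID_RE.match(candidate))


def require_display_id(candidate: str) -> str:
    if not validate_display_id(candidate):
        raise IdentityError(f"invalid displayId: {candidate!r}")
    return candidate


def is_absolute_iri(uri: str) -> bool:
    """True iff *uri* is an absolute ASCII URI (has a scheme)."""
    if not isinstance(uri, str) or not uri.isascii():
        return False
    try:
        parts = urlsplit(uri)
    except ValueError:
        return False
    return bool(parts.scheme)


def require_absolute_iri(uri: str) -> str:
    if isinstance(uri, str) and not uri.isascii():
        raise IdentityError(
            f"non-ASCII URI not supported (URIs only, no IRIs): {uri!r}")
    if not is_absolute_iri(uri):
        raise IdentityError(f"not an absolute URI: {uri!r}")
    return uri


def compose_uri(prefix: str, display_id: str) -> str:
    """Join a namespace prefix and a displayId into ``<prefix>/<displayId>``."""
    require_absolute_iri(prefix)
    if prefix.endswith("/"):
        raise IdentityError(f"prefix may not end with '/': {prefix!r}")
    require_display_id(display_id)
    return f"{prefix}/{display_id}"


@dataclass(frozen=True)
class UriParts:
    """Decomposition of a URI against a registered namespace.

    Recomposing ``namespace + '/' + '/'.join(local_path + [display_id])``
    yields the original URI.
    """

    namespace: str
    local_path: tuple[str, ...] = field(default_factory=tuple)
    display_id: str = ""

    @property
    def uri(self) -> str:
        return "/".join((self.namespace, *self.local_path, self.display_id))


def decompose_uri(uri: str, namespaces) -> UriParts:
    """Split *uri* on the longest matching registered namespace.

    The remainder is split on "/" into a (possibly empty) local path and the
    final displayId segment.
    """
    require_absolute_iri(uri)
    matches = [ns for ns in namespaces
               if uri == ns or uri.startswith(ns.rstrip("/") + "/")]
    if not matches:
        raise IdentityError(f"no registered namespace matches {uri!r}")
    ns = max(matches, key=len).rstrip("/")
    rest = uri[len(ns):].lstrip("/")
    if not rest:
        raise IdentityError(f"{uri!r} has no path below namespace {ns!r}")
    segments = rest.split("/")
    return UriParts(namespace=ns, local_path=tuple(segments[:-1]),
                    display_id=segments[-1])


def _registered_namespaces(doc: "Document") -> set[str]:
    from .model import Namespace

    found: set[str] = set()
    for obj in doc.top_levels:
        ns = getattr(obj, "namespace", None)
        if ns:
            found.add(ns)
        if isinstance(obj, Namespace):
            found.add(obj.uri)
    found.update(doc.prefix_map.values())
    return {ns.rstrip("/") for ns in found}


def rewrite_namespace(doc: "Document", old_ns: str, new_ns: str) -> "Document":
    """Move every object under *old_ns* to *new_ns*, preserving the local
    path and displayId of each URI and updating all internal references.

    Returns a new Document; URIs in other namespaces are untouched.  Raises
    on a collision with an existing URI in the target namespace.
    """
    from rdflib import Literal, URIRef

    from . import rdf_io

    require_absolute_iri(new_ns)
    old_ns = old_ns.rstrip("/")
    new_ns = new_ns.rstrip("/")
    if old_ns not in _registered_namespaces(doc):
        raise IdentityError(f"namespace not registered in document: {old_ns!r}")

    def moved(uri: str) -> str | None:
        if uri == old_ns:
            return new_ns
        if uri.startswith(old_ns + "/"):
            return new_ns + uri[len(old_ns):]
        return None

    # collision check against URIs that are not themselves being rewritten
    all_uris = {obj.uri for obj in doc.walk()}
    for uri in all_uris:
        target = moved(uri)
        if target is not None and target in all_uris and moved(target) is None:
            raise IdentityError(
                f"rewrite collision: {uri!r} -> {target!r} already exists")

    graph = rdf_io.to_graph(doc)
    out = type(graph)()
    for prefix, ns in graph.namespaces():
        out.bind(prefix, ns)

    def map_term(term):
        if isinstance(term, URIRef) and not isinstance(term, Literal):
            target = moved(str(term))
            if target is not None:
                return URIRef(target)
        return term

    for s, p, o in graph:
        out.add((map_term(s), map_term(p), map_term(o)))
    new_doc = rdf_io.from_graph(out)
    new_doc.prefix_map = {
        k: (moved(v.rstrip("/")) or v) for k, v in doc.prefix_map.items()
    }
    return new_doc
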
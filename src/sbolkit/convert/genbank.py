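"""GenBank flat-file import and export.

A GenBank record is a flat feature table over one sequence; it becomes one
DNA-typed Component plus one Sequence, with one SequenceFeature per table
entry.  Coordinates transfer verbatim: GenBank and sbolkit Ranges are both
1-based and inclusive at both ends.  ``complement(...)`` becomes the
reverse-complement orientation, ``join(...)`` becomes multiple Ranges on one
feature, and fuzzy ``<a..b>`` coordinates are clamped to their exact bound
with a warning.

Feature keys map to Sequence Ontology roles through a shipped table; keys the
table does not know get the generic sequence_feature role plus a warning.
The original key is kept as an annotation so export reproduces the feature
table exactly.
"""
from __future__ import annotations

import io
import warnings
from typing import Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import (AfterPosition, BeforePosition, CompoundLocation,
                            SeqFeature, SimpleLocation)
from Bio.SeqRecord import SeqRecord
from rdflib import Literal

from .. import terms
from ..errors import ConversionError
from ..model import (Component, Document, Range, Sequence, SequenceFeature,
                     SubComponent)


class ConversionWarning(UserWarning):
    """Lossy or defaulted step during format conversion."""


#: GenBank feature key -> SO role term
GENBANK_KEY_TO_SO = {
    "source": terms.SO_REGION,
    "gene": terms.SO_GENE,
    "CDS": terms.SO_CDS,
    "promoter": terms.SO_PROMOTER,
    "terminator": terms.SO_TERMINATOR,
    "RBS": terms.SO_RBS,
    "ribosome_binding_site": terms.SO_RBS,
    "rep_origin": terms.SO_ORIGIN_OF_REPLICATION,
    "primer_bind": terms.SO_PRIMER_BINDING_SITE,
    "misc_feature": terms.SO_SEQUENCE_FEATURE,
}

#: preferred inverse mapping for export
SO_TO_GENBANK_KEY = {
    terms.SO_REGION: "source",
    terms.SO_GENE: "gene",
    terms.SO_CDS: "CDS",
    terms.SO_PROMOTER: "promoter",
    terms.SO_TERMINATOR: "terminator",
    terms.SO_RBS: "RBS",
    terms.SO_ORIGIN_OF_REPLICATION: "rep_origin",
    terms.SO_PRIMER_BINDING_SITE: "primer_bind",
    terms.SO_SEQUENCE_FEATURE: "misc_feature",
}

#: annotation predicate carrying the original GenBank feature key
GENBANK_KEY_PRED = terms.SBOLKIT_NS + "genbankKey"


def read_genbank(source: Union[str, io.IOBase]) -> SeqRecord:
    """Read one GenBank record from a path, text, or handle."""
    if isinstance(source, str):
        handle = io.StringIO(source) if "\n" in source else open(source)
    else:
        handle = source
    try:
        return next(SeqIO.parse(handle, "genbank"))
    except StopIteration:
        raise ConversionError("no GenBank record found in input") from None
    finally:
        if handle is not source:
            handle.close()


def _sanitize(text: str) -> str:
    out = "".join(ch if ch.isalnum() or ch == "_" else "_" for ch in text)
    if not out or out[0].isdigit():
        out = "f_" + out
    return out


def _part_to_range(part, seq_uri: str, length: int) -> Range:
    start_pos, end_pos = part.start, part.end
    if isinstance(start_pos, (BeforePosition, AfterPosition)) or \
            isinstance(end_pos, (BeforePosition, AfterPosition)):
        warnings.warn(
            f"fuzzy coordinates in {part} clamped to exact bounds",
            ConversionWarning, stacklevel=4)
    start = max(1, int(start_pos) + 1)  # biopython is 0-based half-open
    end = min(length, int(end_pos))
    if start > end:
        raise ConversionError(f"unusable location {part}")
    return Range(seq_uri, start, end)


def genbank_to_component(
        record: Union[SeqRecord, str, io.IOBase],
        namespace: str = "http://example.com/genbank",
) -> tuple[Component, Sequence]:
    """Convert one GenBank record into a DNA Component and its Sequence."""
    if not isinstance(record, SeqRecord):
        record = read_genbank(record)
    residues = str(record.seq).upper()
    if not residues:
        raise ConversionError("GenBank record has an empty sequence")
    display_id = _sanitize(record.name or record.id or "record")
    seq = Sequence(namespace, display_id + "_seq", elements=residues,
                   encoding=terms.ENC_IUPAC_DNA)
    comp = Component(namespace, display_id, types={terms.SBO_DNA})
    if record.description and record.description != ".":
        comp.description = record.description
    comp.add_sequence(seq)

    used_ids: set[str] = set()
    for idx, gb_feature in enumerate(record.features, start=1):
        key = gb_feature.type
        role = GENBANK_KEY_TO_SO.get(key)
        if role is None:
            role = terms.SO_SEQUENCE_FEATURE
            warnings.warn(
                f"GenBank feature key {key!r} has no SO mapping; using the "
                "generic sequence_feature role", ConversionWarning,
                stacklevel=2)
        fid = _sanitize(f"{key}_{idx}")
        while fid in used_ids:
            fid += "_"
        used_ids.add(fid)
        location = gb_feature.location
        if location is None:
            raise ConversionError(f"feature {key} has no location")
        ranges = [_part_to_range(part, seq.uri, len(residues))
                  for part in location.parts]
        orientation = (terms.REVERSE_COMPLEMENT if location.strand == -1
                       else terms.INLINE)
        feat = SequenceFeature(fid, roles={role}, locations=ranges,
                               orientation=orientation)
        feat.annotations.append((GENBANK_KEY_PRED, Literal(key)))
        label = gb_feature.qualifiers.get("label") or \
            gb_feature.qualifiers.get("gene")
        if label:
            feat.name = label[0]
        comp.add_feature(feat)
    return comp, seq


def component_to_genbank(component: Component, doc: Document) -> SeqRecord:
    """Flatten a Component back into a GenBank record.

    Requires a nucleotide Component whose Sequence has elements; located
    SubComponents flatten to table entries, unlocated ones are omitted with
    a warning.
    """
    if terms.SBO_PROTEIN in component.types or \
            (component.types and terms.SBO_DNA not in component.types
             and terms.SBO_RNA not in component.types):
        raise ConversionError(
            "GenBank export supports nucleotide Components only")
    if not component.sequences:
        raise ConversionError(f"{component.uri} has no Sequence")
    seq_obj = doc.lookup(component.sequences[0])
    if not isinstance(seq_obj, Sequence) or not seq_obj.elements:
        raise ConversionError(
            f"{component.uri}'s Sequence has no elements to export")

    record = SeqRecord(Seq(seq_obj.elements),
                       id=component.display_id or "record",
                       name=(component.display_id or "record")[:16],
                       description=component.description or "")
    record.annotations["molecule_type"] = "DNA"
    for feature in component.features:
        ranges = [loc for loc in feature.locations if isinstance(loc, Range)]
        if not ranges:
            if isinstance(feature, (SubComponent, SequenceFeature)):
                warnings.warn(
                    f"feature {feature.uri} has no Range location; omitted "
                    "from GenBank export", ConversionWarning, stacklevel=2)
            continue
        key = None
        for pred, value in feature.annotations:
            if pred == GENBANK_KEY_PRED:
                key = str(value)
        if key is None:
            roles = set(feature.roles)
            if isinstance(feature, SubComponent) and feature.instance_of:
                definition = doc.lookup(feature.instance_of)
                if isinstance(definition, Component):
                    roles |= definition.roles
            key = next((SO_TO_GENBANK_KEY[r] for r in sorted(roles)
                        if r in SO_TO_GENBANK_KEY), "misc_feature")
        strand = (-1 if feature.orientation == terms.REVERSE_COMPLEMENT
                  else 1)
        parts = [SimpleLocation(r.start - 1, r.end, strand=strand)
                 for r in ranges]
        location = parts[0] if len(parts) == 1 else CompoundLocation(parts)
        gb_feature = SeqFeature(location, type=key)
        if feature.name:
            gb_feature.qualifiers["label"] = [feature.name]
        record.features.append(gb_feature)
    return record


def write_genbank(record: SeqRecord) -> str:
    handle = io.StringIO()
    SeqIO.write([record], handle, "genbank")
    return handle.getvalue()
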
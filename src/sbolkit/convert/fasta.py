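"""FASTA import: one record becomes one Sequence.

The alphabet is inferred from the residues — plain nucleotide letters
(ACGT/U plus N) classify as DNA or RNA, anything clearly proteinaceous as
protein.  Sequences written entirely in nucleotide ambiguity codes are also
valid protein strings, so classification is deliberately conservative: an
ambiguous alphabet without an explicit ``encoding`` override is an error
rather than a guess.
"""
from __future__ import annotations

import io
from typing import Optional, Union

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from .. import terms
from ..errors import ConversionError
from ..model import Sequence

_DNA = set("ACGTN-")
_RNA = set("ACGUN-")
_PROTEIN = set("ACDEFGHIKLMNPQRSTVWY*-")


def _classify(residues: str) -> str:
    letters = set(residues)
    if letters <= _DNA:
        return terms.ENC_IUPAC_DNA
    if letters <= _RNA:
        return terms.ENC_IUPAC_RNA
    if letters <= _PROTEIN:
        return terms.ENC_IUPAC_PROTEIN
    raise ConversionError(
        f"cannot infer alphabet from residues {''.join(sorted(letters))!r}; "
        "pass encoding= explicitly")


def fasta_to_sequence(record: Union[SeqRecord, str, io.IOBase],
                      namespace: str = "http://example.com/fasta",
                      encoding: Optional[str] = None) -> Sequence:
    """Convert one FASTA record into a Sequence (residues upper-cased)."""
    if not isinstance(record, SeqRecord):
        if isinstance(record, str):
            handle = io.StringIO(record) if record.lstrip().startswith(">") \
                else open(record)
        else:
            handle = record
        try:
            record = next(SeqIO.parse(handle, "fasta"))
        except StopIteration:
            raise ConversionError("no FASTA record found in input") from None
        finally:
            if handle is not record:
                handle.close()
    residues = str(record.seq).upper()
    if not residues:
        raise ConversionError(f"FASTA record {record.id!r} is empty")
    if encoding is None:
        encoding = _classify(residues)
    alphabet = terms.ENCODING_ALPHABETS.get(encoding)
    if alphabet is not None:
        bad = set(residues) - alphabet
        if bad:
            raise ConversionError(
                f"residues {''.join(sorted(bad))!r} are illegal under the "
                "requested encoding")
    display_id = "".join(ch if ch.isalnum() or ch == "_" else "_"
                         for ch in (record.id or "sequence"))
    if not display_id or display_id[0].isdigit():
        display_id = "s_" + display_id
    seq = Sequence(namespace, display_id, elements=residues,
                   encoding=encoding)
    if record.description and record.description != record.id:
        seq.description = record.description
    return seq
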
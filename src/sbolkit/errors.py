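"""Exception hierarchy for sbolkit."""


class SbolError(Exception):
    """Base class for all sbolkit errors."""


class IdentityError(SbolError, ValueError):
    """Invalid URI or displayId, or a namespace mismatch/collision."""


class OwnershipError(SbolError, ValueError):
    """Violation of the parent/child ownership contract (duplicate child,
    foreign reference, ownership cycle)."""


class ResolutionError(SbolError, LookupError):
    """A reference could not be resolved, or a reference chain cycles."""


class VocabularyError(SbolError, ValueError):
    """A term falls outside one of the closed vocabularies."""


class SerializationError(SbolError, ValueError):
    """Unknown format or unserializable/unparseable content."""


class ConversionError(SbolError, ValueError):
    """A converter could not map its input (GenBank, FASTA, SBOL2)."""
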
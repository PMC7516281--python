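"""Namespace IRIs and curated ontology terms.

SBOL3 types molecular species with the Systems Biology Ontology (SBO), sequence
roles with the Sequence Ontology (SO), and larger-scale entities such as cells
with the Gene Ontology (GO).  The validator checks term membership against the
small curated subsets below (no network lookups); terms outside every
recognized namespace produce vocabulary findings, not hard errors.
"""

SBOL3 = "http://sbols.org/v3#"
SBOL2 = "http://sbols.org/v2#"
PROV = "http://www.w3.org/ns/prov#"
RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"

#: namespace used by sbolkit itself for bookkeeping annotations (never sbol:)
SBOLKIT_NS = "https://sbolkit.dev/ns#"


def SO(code: str) -> str:
    return f"https://identifiers.org/SO:{code}"


def SBO(code: str) -> str:
    return f"https://identifiers.org/SBO:{code}"


def GO(code: str) -> str:
    return f"https://identifiers.org/GO:{code}"


def CHEBI(code: str) -> str:
    return f"https://identifiers.org/CHEBI:{code}"


# --- component types (SBO molecular species; GO for cells) -------------------
SBO_DNA = SBO("0000251")
SBO_RNA = SBO("0000250")
SBO_PROTEIN = SBO("0000252")
SBO_SIMPLE_CHEMICAL = SBO("0000247")
SBO_NONCOVALENT_COMPLEX = SBO("0000254")
SBO_FUNCTIONAL_ENTITY = SBO("0000241")
GO_CELL = GO("0005623")

# --- compartment roles -------------------------------------------------------
SBO_PHYSICAL_COMPARTMENT = SBO("0000290")
SBO_FUNCTIONAL_COMPARTMENT = SBO("0000289")

# --- interaction types and participant roles ---------------------------------
SBO_INHIBITION = SBO("0000169")
SBO_STIMULATION = SBO("0000170")
SBO_GENETIC_PRODUCTION = SBO("0000589")
SBO_INHIBITOR = SBO("0000020")
SBO_INHIBITED = SBO("0000642")
SBO_STIMULATOR = SBO("0000459")
SBO_STIMULATED = SBO("0000643")
SBO_TEMPLATE = SBO("0000645")
SBO_PRODUCT = SBO("0000011")
SBO_REACTANT = SBO("0000010")

# --- sequence roles (SO) -----------------------------------------------------
SO_PROMOTER = SO("0000167")
SO_RBS = SO("0000139")
SO_CDS = SO("0000316")
SO_TERMINATOR = SO("0000141")
SO_GENE = SO("0000704")
SO_OPERATOR = SO("0000057")
SO_ENGINEERED_REGION = SO("0000804")
SO_SEQUENCE_FEATURE = SO("0000110")
SO_REGION = SO("0000001")
SO_PRIMER_BINDING_SITE = SO("0005850")
SO_ORIGIN_OF_REPLICATION = SO("0000296")
SO_SGRNA = SO("0001998")
SO_NCRNA = SO("0000655")
SO_MISC_FEATURE = SO_SEQUENCE_FEATURE

# --- sequence encodings (IANA/EDAM identifiers used by the standard) ---------
ENC_IUPAC_DNA = "https://identifiers.org/edam:format_1207"
ENC_IUPAC_RNA = "https://identifiers.org/edam:format_1208"
ENC_IUPAC_PROTEIN = "https://identifiers.org/edam:format_1257"

#: legal residue characters per encoding (IUPAC codes, upper case; '-' gap,
#: '.' allowed for alignment-derived content)
ENCODING_ALPHABETS = {
    ENC_IUPAC_DNA: set("ACGTRYSWKMBDHVN-."),
    ENC_IUPAC_RNA: set("ACGURYSWKMBDHVN-."),
    ENC_IUPAC_PROTEIN: set("ACDEFGHIKLMNPQRSTVWYBXZJUO*-."),
}

# --- orientation values ------------------------------------------------------
INLINE = SBOL3 + "inline"
REVERSE_COMPLEMENT = SBOL3 + "reverseComplement"
ORIENTATIONS = frozenset({INLINE, REVERSE_COMPLEMENT})

# --- Activity stage markers --------------------------------------------------
DESIGN = SBOL3 + "design"
BUILD = SBOL3 + "build"
TEST = SBOL3 + "test"
LEARN = SBOL3 + "learn"

# --- combinatorial cardinalities / strategies --------------------------------
CARDINALITY_ONE = SBOL3 + "one"
CARDINALITY_ONE_OR_MORE = SBOL3 + "oneOrMore"
CARDINALITY_ZERO_OR_MORE = SBOL3 + "zeroOrMore"
CARDINALITY_ZERO_OR_ONE = SBOL3 + "zeroOrOne"
CARDINALITIES = frozenset(
    {CARDINALITY_ONE, CARDINALITY_ONE_OR_MORE, CARDINALITY_ZERO_OR_MORE,
     CARDINALITY_ZERO_OR_ONE}
)
STRATEGY_ENUMERATE = SBOL3 + "enumerate"
STRATEGY_SAMPLE = SBOL3 + "sample"

#: namespace prefixes the validator recognizes as ontology homes for
#: Component/Feature type and role terms
RECOGNIZED_TERM_PREFIXES = (
    "https://identifiers.org/SO:",
    "https://identifiers.org/SBO:",
    "https://identifiers.org/GO:",
    "https://identifiers.org/CHEBI:",
    "https://identifiers.org/edam:",
    "http://identifiers.org/so/SO:",
    "http://identifiers.org/sbo/SBO:",
    "http://identifiers.org/go/GO:",
)
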
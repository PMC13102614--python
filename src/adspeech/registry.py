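"""Registry of the 32 linguistic biomarkers.

The registry is the single source of truth for feature codes, display
names, categories and subcategories, and for the canonical column order of
every feature table produced by the package.  Three measurement domains are
covered:

* **Syntactic complexity** — length of production units (MLS, MLC),
  sentence complexity (CS) and coordination (cPC), computed on the
  clause/sentence segmentation of the annotated transcript.
* **Lexical richness** — lexical density (LD), lexical diversity
  (NDW and the TTR family) and lexical sophistication (mean word length in
  characters plus unigram normalized-log-frequency scores against four
  register-specific reference corpora).
* **Information-theoretic** — compression-based Kolmogorov complexity
  (KDbase, a DEFLATE compression ratio) and predictive sequencing
  (bigram-to-fivegram normalized log frequency against the same four
  registers).

Registry order is a format contract: feature CSVs always carry the 32
columns in this order, and deterministic tie-breaks in feature elimination
and importance ranking resolve by registry index.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import RegistryError

#: Reference corpus registers for n-gram frequency lookups.
REGISTERS = ("academic", "fiction", "news", "spoken")

#: Single-letter register suffixes used in NLF feature codes.
REGISTER_SUFFIX = {"academic": "a", "fiction": "f", "news": "n", "spoken": "s"}

SYNTACTIC = "Syntactic Complexity"
LEXICAL = "Lexical Richness"
INFO_THEORETIC = "Information-Theoretic"


@dataclass(frozen=True)
class BiomarkerDef:
    """One registry row: code, human-readable name, category, subcategory."""

    code: str
    name: str
    category: str
    subcategory: str


def _nlf_defs(n: int, category: str, subcategory: str) -> list[BiomarkerDef]:
    return [
        BiomarkerDef(
            code=f"{n}GNLF{REGISTER_SUFFIX[reg]}",
            name=f"{n}-gram normalized log frequency ({reg})",
            category=category,
            subcategory=subcategory,
        )
        for reg in REGISTERS
    ]


BIOMARKERS: tuple[BiomarkerDef, ...] = tuple(
    [
        BiomarkerDef("MLS", "Mean length of sentence", SYNTACTIC, "Length of production unit"),
        BiomarkerDef("MLC", "Mean length of clause", SYNTACTIC, "Length of production unit"),
        BiomarkerDef("CS", "Sentence complexity ratio", SYNTACTIC, "Sentence complexity"),
        BiomarkerDef("cPC", "Coordinate phrases per clause", SYNTACTIC, "Coordination"),
        BiomarkerDef("LD", "Lexical density", LEXICAL, "Lexical density"),
        BiomarkerDef("NDW", "Number of different words", LEXICAL, "Lexical diversity"),
        BiomarkerDef("TTR", "Type-token ratio", LEXICAL, "Lexical diversity"),
        BiomarkerDef("bTTR", "Bilogarithmic TTR", LEXICAL, "Lexical diversity"),
        BiomarkerDef("rTTR", "Root TTR", LEXICAL, "Lexical diversity"),
        BiomarkerDef("cTTR", "Corrected TTR", LEXICAL, "Lexical diversity"),
        BiomarkerDef("MLWc", "Mean length of word (characters)", LEXICAL, "Lexical sophistication"),
        *_nlf_defs(1, LEXICAL, "Lexical sophistication"),
        BiomarkerDef("KDbase", "Kolmogorov Deflate", INFO_THEORETIC, "Kolmogorov complexity"),
        *_nlf_defs(2, INFO_THEORETIC, "Predictive sequencing"),
        *_nlf_defs(3, INFO_THEORETIC, "Predictive sequencing"),
        *_nlf_defs(4, INFO_THEORETIC, "Predictive sequencing"),
        *_nlf_defs(5, INFO_THEORETIC, "Predictive sequencing"),
    ]
)

#: Canonical feature-column order.
CODES: tuple[str, ...] = tuple(b.code for b in BIOMARKERS)

_BY_CODE = {b.code: b for b in BIOMARKERS}
_INDEX = {b.code: i for i, b in enumerate(BIOMARKERS)}

N_BIOMARKERS = len(BIOMARKERS)
assert N_BIOMARKERS == 32


def get(code: str) -> BiomarkerDef:
    """Look up a biomarker definition by code."""
    try:
        return _BY_CODE[code]
    except KeyError:
        raise RegistryError(f"unknown biomarker code: {code!r}") from None


def index(code: str) -> int:
    """Registry index (0-based Table-order position) of a code."""
    get(code)
    return _INDEX[code]


def validate_codes(codes) -> list[str]:
    """Check that every code is registered; return them as a list."""
    return [get(c).code for c in codes]


def category_of(code: str) -> str:
    return get(code).category


def category_blocks() -> dict[str, list[str]]:
    """Codes grouped by measurement category, in registry order."""
    blocks: dict[str, list[str]] = {}
    for b in BIOMARKERS:
        blocks.setdefault(b.category, []).append(b.code)
    return blocks
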
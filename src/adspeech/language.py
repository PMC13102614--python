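"""Surface conventions of the artificial test language.

The synthetic corpus is written in an invented SVO language whose
part of speech is recoverable from the surface form alone: a small closed
class of function words plus four open classes marked by unambiguous
suffixes.  This makes gold annotation exact and lets the reference
annotator run without an external parser.

Open-class words are built from consonant-vowel syllable roots, so no open
word can collide with a closed-class form and every word carries exactly
one POS suffix.
"""

from __future__ import annotations

from .errors import AnnotationError

# Universal POS inventory used throughout the package (closed set).
POS_TAGS = frozenset(
    {"NOUN", "PROPN", "VERB", "AUX", "ADJ", "ADV", "DET", "PRON", "ADP",
     "CCONJ", "SCONJ", "PUNCT", "NUM", "PART", "INTJ", "SYM", "X"}
)

#: POS categories counted as lexical content (auxiliaries are not).
CONTENT_POS = frozenset({"NOUN", "PROPN", "VERB", "ADJ", "ADV"})

# Closed-class function words.  "ko" coordinates phrases, "ab" coordinates
# clauses; keeping the two conjunctions lexically distinct makes the
# grammar unambiguous for the rule-based parser.
CLOSED_CLASS = {
    "da": "DET",
    "ko": "CCONJ",   # phrasal coordinator
    "ab": "CCONJ",   # clausal coordinator
    "wen": "SCONJ",  # subordinator
    "ha": "AUX",
    "er": "PRON",
    "in": "ADP",
}

PHRASAL_COORD = "ko"
CLAUSAL_COORD = "ab"
SUBORDINATOR = "wen"

# Open-class suffixes (mutually exclusive; roots end in a vowel).
SUFFIX_POS = (("on", "NOUN"), ("ir", "VERB"), ("al", "ADJ"), ("um", "ADV"))
POS_SUFFIX = {pos: suf for suf, pos in SUFFIX_POS}

PUNCT_CHARS = ".,!?;:"

_CONSONANTS = "bdfglmnprst"
_VOWELS = "aeiou"
_SYLLABLES = [c + v for c in _CONSONANTS for v in _VOWELS]


def root(i: int) -> str:
    """Deterministic two-syllable root for lexicon index ``i``."""
    n = len(_SYLLABLES)
    if i >= n * n:
        raise ValueError(f"lexicon index {i} out of range")
    return _SYLLABLES[i // n] + _SYLLABLES[i % n]


def make_word(i: int, pos: str) -> str:
    """Open-class surface form: syllabic root plus POS suffix."""
    return root(i) + POS_SUFFIX[pos]


def pos_of(surface: str) -> str:
    """Deterministic POS of a surface form.

    Closed-class lookup first, then suffix matching; raises
    :class:`AnnotationError` for forms outside the language.
    """
    w = surface.lower()
    if all(ch in PUNCT_CHARS for ch in w):
        return "PUNCT"
    if w in CLOSED_CLASS:
        return CLOSED_CLASS[w]
    for suffix, pos in SUFFIX_POS:
        if w.endswith(suffix):
            return pos
    raise AnnotationError(f"word outside the synthetic language: {surface!r}", span=surface)


def tokenize(text: str) -> list[str]:
    """Whitespace tokenization with terminal punctuation split off."""
    out: list[str] = []
    for chunk in text.split():
        while chunk and chunk[0] in PUNCT_CHARS:
            out.append(chunk[0])
            chunk = chunk[1:]
        trailing: list[str] = []
        while chunk and chunk[-1] in PUNCT_CHARS:
            trailing.append(chunk[-1])
            chunk = chunk[:-1]
        if chunk:
            out.append(chunk)
        out.extend(reversed(trailing))
    return out
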
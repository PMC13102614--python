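"""Transcript annotation: tokens, sentences, clauses, POS, coordination.

The measurement layer consumes an :class:`AnnotatedTranscript` — tokens with
POS/lemma/dependency structure plus sentence segmentation — produced by any
object satisfying the :class:`Annotator` contract.  Two annotators are
relevant:

* :class:`SyntheticLanguageAnnotator` (shipped, fully tested): a
  deterministic rule-based parser for the artificial test language defined
  in :mod:`adspeech.language`.  On generated text it reconstructs the
  generator's gold annotation exactly.
* An adapter for a universal-dependencies German parser (e.g. a spaCy
  ``de_core_news_*`` pipeline) for real clinical transcripts.  The adapter
  only has to map the parser's output onto :class:`Token` fields — surface,
  lemma, universal POS, sentence-local head index, dependency relation —
  and is deliberately outside the tested surface of this package.

Clause and coordination counting follow a fixed operationalization:

* A **clause** is a finite-verb-headed unit.  Clause heads are the sentence
  root plus every token bearing a clausal dependency relation
  (``ccomp``/``advcl``/``acl``/``csubj``/``parataxis``) or a ``conj``
  relation whose head is verbal.  A verbless sentence counts as one clause
  so that words-per-clause stays defined for fragmentary speech.
* A **coordinate phrase** is a ``conj`` dependent whose head is *not*
  verbal (nominal/adjectival/adverbial coordination).  Coordinated finite
  verbs are clauses, not coordinate phrases, so the two counts never
  overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Protocol

from . import language as lang
from .errors import AnnotationError, EmptyTranscriptError

#: Dependency relations marking a clausal head (besides the root).
CLAUSAL_DEPRELS = frozenset({"ccomp", "advcl", "acl", "acl:relcl", "csubj", "parataxis"})

_VERBAL = frozenset({"VERB", "AUX"})


@dataclass
class Token:
    """One token with its morphosyntactic annotation.

    ``head`` is a sentence-local index; the root points at itself.
    ``char_len`` counts non-punctuation characters of the surface form.
    """

    surface: str
    lemma: str
    pos: str
    head: int
    deprel: str
    char_len: int = 0

    def __post_init__(self) -> None:
        if self.pos not in lang.POS_TAGS:
            raise AnnotationError(f"POS {self.pos!r} outside the closed inventory",
                                  span=self.surface)
        if self.char_len == 0:
            self.char_len = sum(1 for c in self.surface if c not in lang.PUNCT_CHARS)

    @property
    def is_word(self) -> bool:
        return self.pos != "PUNCT"

    def to_dict(self) -> dict:
        return {"surface": self.surface, "lemma": self.lemma, "pos": self.pos,
                "head": self.head, "deprel": self.deprel, "char_len": self.char_len}

    @classmethod
    def from_dict(cls, d: dict) -> "Token":
        return cls(**d)


@dataclass
class Sentence:
    """An annotated sentence with its clause and coordination counts."""

    tokens: list[Token]
    clause_count: int = 0
    coord_phrase_count: int = 0

    @property
    def word_tokens(self) -> list[Token]:
        return [t for t in self.tokens if t.is_word]

    def to_dict(self) -> dict:
        return {"tokens": [t.to_dict() for t in self.tokens],
                "clause_count": self.clause_count,
                "coord_phrase_count": self.coord_phrase_count}

    @classmethod
    def from_dict(cls, d: dict) -> "Sentence":
        return cls(tokens=[Token.from_dict(t) for t in d["tokens"]],
                   clause_count=d["clause_count"],
                   coord_phrase_count=d["coord_phrase_count"])


@dataclass
class AnnotatedTranscript:
    """Sentence-segmented, dependency-annotated transcript of one speaker."""

    id: str
    sentences: list[Sentence] = field(default_factory=list)

    @property
    def word_tokens(self) -> list[Token]:
        return [t for s in self.sentences for t in s.word_tokens]

    @property
    def n_words(self) -> int:
        return len(self.word_tokens)

    def to_dict(self) -> dict:
        return {"id": self.id, "sentences": [s.to_dict() for s in self.sentences]}

    @classmethod
    def from_dict(cls, d: dict) -> "AnnotatedTranscript":
        return cls(id=d["id"], sentences=[Sentence.from_dict(s) for s in d["sentences"]])


def count_clauses(sentence: Sentence) -> int:
    """Number of clause heads in a sentence (always at least 1)."""
    toks = sentence.tokens
    n = 0
    for i, t in enumerate(toks):
        if t.head == i and t.is_word:  # sentence root
            n += 1
        elif t.deprel in CLAUSAL_DEPRELS:
            n += 1
        elif t.deprel == "conj" and toks[t.head].pos in _VERBAL:
            n += 1
    return max(n, 1)


def count_coordinate_phrases(sentence: Sentence) -> int:
    """Number of non-clausal (phrasal) conjunct dependents."""
    toks = sentence.tokens
    return sum(1 for t in toks
               if t.deprel == "conj" and toks[t.head].pos not in _VERBAL)


def content_word_mask(tokens: Iterable[Token]) -> list[bool]:
    """True where the token is a lexical content word.

    Content categories: NOUN, PROPN, VERB (auxiliaries carry the AUX tag
    and are excluded), ADJ, ADV.
    """
    mask = []
    for t in tokens:
        if t.pos not in lang.POS_TAGS:
            raise AnnotationError(f"unknown POS label {t.pos!r}", span=t.surface)
        mask.append(t.pos in lang.CONTENT_POS)
    return mask


class Annotator(Protocol):
    """Contract for pluggable annotators."""

    def annotate(self, text: str, id: str = "") -> AnnotatedTranscript: ...


def annotate(text: str, annotator: "Annotator | None" = None,
             id: str = "") -> AnnotatedTranscript:
    """Annotate raw transcript text.

    Raises :class:`EmptyTranscriptError` when the text contains no word
    token after whitespace normalization (e.g. punctuation-only input).
    """
    if annotator is None:
        annotator = SyntheticLanguageAnnotator()
    text = " ".join(text.split())
    if not text:
        raise EmptyTranscriptError("transcript text is empty")
    out = annotator.annotate(text, id=id)
    if out.n_words == 0:
        raise EmptyTranscriptError("transcript contains no word tokens")
    return out


class SyntheticLanguageAnnotator:
    """Deterministic parser for the artificial test language.

    Sentences are segmented at terminal punctuation; clause boundaries are
    opened by the subordinator and the clausal coordinator; within a clause
    the single main verb heads everything else.  The grammar is unambiguous
    by construction, so parsing is a linear scan.
    """

    def annotate(self, text: str, id: str = "") -> AnnotatedTranscript:
        tokens = lang.tokenize(" ".join(text.split()))
        if not tokens:
            raise EmptyTranscriptError("transcript text is empty")
        sentences: list[Sentence] = []
        current: list[str] = []
        for tok in tokens:
            current.append(tok)
            if tok in {".", "!", "?"}:
                sent = self._parse_sentence(current)
                if sent is not None:
                    sentences.append(sent)
                current = []
        if current:
            sent = self._parse_sentence(current)
            if sent is not None:
                sentences.append(sent)
        transcript = AnnotatedTranscript(id=id, sentences=sentences)
        return transcript

    # -- sentence-level parsing -------------------------------------------

    def _parse_sentence(self, surfaces: list[str]) -> Sentence | None:
        pos = [lang.pos_of(w) for w in surfaces]
        if all(p == "PUNCT" for p in pos):
            return None
        n = len(surfaces)
        head = [-1] * n
        deprel = [""] * n

        # clause segmentation: a new clause opens at "wen" or "ab"
        starts = [0] + [i for i in range(1, n)
                        if surfaces[i].lower() in (lang.SUBORDINATOR, lang.CLAUSAL_COORD)]
        bounds = list(zip(starts, starts[1:] + [n]))

        clause_verbs: list[int] = []
        for lo, hi in bounds:
            v = next((i for i in range(lo, hi) if pos[i] == "VERB"), None)
            if v is None:
                v = next((i for i in range(lo, hi) if pos[i] == "AUX"), None)
            if v is None:  # verbless clause: first word token heads it
                v = next(i for i in range(lo, hi) if pos[i] != "PUNCT")
            clause_verbs.append(v)
        root = clause_verbs[0]

        for ci, (lo, hi) in enumerate(bounds):
            v = clause_verbs[ci]
            opener = surfaces[lo].lower()
            if ci == 0:
                head[v], deprel[v] = v, "root"
            elif opener == lang.SUBORDINATOR:
                head[v], deprel[v] = clause_verbs[ci - 1], "advcl"
            else:  # clausal coordination attaches to the first conjunct
                head[v], deprel[v] = root, "conj"
            self._attach_clause(surfaces, pos, head, deprel, lo, hi, v, root)

        # punctuation attaches to the sentence root
        for i in range(n):
            if pos[i] == "PUNCT":
                head[i], deprel[i] = root, "punct"

        toks = [Token(surface=s, lemma=s.lower(), pos=p, head=h, deprel=d)
                for s, p, h, d in zip(surfaces, pos, head, deprel)]
        sent = Sentence(tokens=toks)
        sent.clause_count = count_clauses(sent)
        sent.coord_phrase_count = count_coordinate_phrases(sent)
        return sent

    def _attach_clause(self, surfaces, pos, head, deprel, lo, hi, v, root) -> None:
        coord_chain_head: int | None = None  # first conjunct of current chain
        for i in range(lo, hi):
            if i == v or pos[i] == "PUNCT" or deprel[i]:
                continue
            w = surfaces[i].lower()
            p = pos[i]
            if p in ("NOUN", "PROPN", "PRON"):
                prev = self._prev_word(pos, lo, i)
                if prev is not None and surfaces[prev].lower() == lang.PHRASAL_COORD:
                    head[i], deprel[i] = coord_chain_head if coord_chain_head is not None else v, "conj"
                else:
                    coord_chain_head = i
                    prev_adp = self._prev_word(pos, lo, i, skip={"DET", "ADJ"})
                    if prev_adp is not None and pos[prev_adp] == "ADP":
                        head[i], deprel[i] = v, "obl"
                    elif i < v:
                        head[i], deprel[i] = v, "nsubj"
                    else:
                        head[i], deprel[i] = v, "obj"
            elif p == "DET":
                j = self._next_of(pos, i + 1, hi, ("NOUN", "PROPN", "PRON"))
                head[i], deprel[i] = (j, "det") if j is not None else (v, "dep")
            elif p == "ADJ":
                j = self._next_of(pos, i + 1, hi, ("NOUN", "PROPN"))
                head[i], deprel[i] = (j, "amod") if j is not None else (v, "amod")
            elif p == "ADV":
                head[i], deprel[i] = v, "advmod"
            elif p == "AUX":
                head[i], deprel[i] = v, "aux"
            elif p == "ADP":
                j = self._next_of(pos, i + 1, hi, ("NOUN", "PROPN", "PRON"))
                head[i], deprel[i] = (j, "case") if j is not None else (v, "dep")
            elif p == "SCONJ":
                head[i], deprel[i] = v, "mark"
            elif p == "CCONJ":
                if w == lang.CLAUSAL_COORD:
                    head[i], deprel[i] = v, "cc"
                else:
                    j = self._next_of(pos, i + 1, hi, ("NOUN", "PROPN", "PRON", "ADJ", "ADV"))
                    head[i], deprel[i] = (j, "cc") if j is not None else (v, "cc")
            else:
                head[i], deprel[i] = v, "dep"

    @staticmethod
    def _prev_word(pos, lo, i, skip=frozenset()):
        for j in range(i - 1, lo - 1, -1):
            if pos[j] == "PUNCT" or pos[j] in skip:
                continue
            return j
        return None

    @staticmethod
    def _next_of(pos, start, hi, kinds):
        for j in range(start, hi):
            if pos[j] in kinds:
                return j
        return None
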
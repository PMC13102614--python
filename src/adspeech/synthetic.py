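"""Synthetic cohorts for exercising the pipeline end to end.

The clinical transcripts this package was designed for are access
restricted, so every downstream stage is validated on synthetic data with
known ground truth.  Two generators are provided:

* a **transcript generator** producing picture-description-length texts in
  the artificial language of :mod:`adspeech.language`, together with the
  exact gold annotation and the realized values of the structural
  parameters (sentence/clause length, clause complexity, coordination,
  lexical density) — the oracle for the annotation and measurement layers;
* a **feature-level generator** drawing 32-column biomarker tables from a
  multivariate Gaussian with planted standardized group differences — the
  fast oracle for selection, modeling and attribution.

The transcript generator controls each group contrast independently:
clause and sentence length through the sentence templates, lexical density
through content/function padding, vocabulary diversity through the Zipf
lexicon, compressibility through sentence-template reuse, and n-gram
familiarity through the rate at which word slots are filled from the
high-frequency band of the reference lexicon.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import language as lang
from . import registry
from .annotation import AnnotatedTranscript, Sentence, Token
from .biomarkers import ReferenceFrequencyTable
from .errors import EmptyTranscriptError, InvalidConfigError

#: The seven biomarkers used as the default planted effect set: the
#: compressibility, lexical-density, unit-length and higher-order n-gram
#: familiarity markers that consistently separate AD from healthy speech.
DEFAULT_EFFECT_FEATURES = ("MLS", "MLC", "LD", "KDbase", "4GNLFa", "4GNLFn", "4GNLFs")

_GRAM_ORDERS = (1, 2, 3, 4, 5)


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class TranscriptGenParams:
    """Knobs of the transcript generator (one group's speech profile).

    ``mean_clause_len`` is in words/clause, ``clauses_per_sentence`` in
    clauses/sentence, ``coord_rate`` is the expected number of coordinate
    phrases per clause, ``content_ratio`` the target fraction of content
    words, ``repetition_rate`` the probability that a sentence reuses an
    earlier sentence verbatim (drives compressibility), and
    ``ngram_familiarity`` the probability that an open-class slot is filled
    from the high-frequency band of the lexicon (drives reference n-gram
    frequency).
    """

    mean_clause_len: float = 6.0
    clauses_per_sentence: float = 1.5
    coord_rate: float = 0.2
    content_ratio: float = 0.55
    vocab_size: int = 120
    zipf_exponent: float = 1.0
    repetition_rate: float = 0.3
    ngram_familiarity: float = 0.5
    n_sentences: int = 25

    def validate(self) -> None:
        if not self.mean_clause_len > 1:
            raise InvalidConfigError("mean_clause_len must be > 1")
        if not self.clauses_per_sentence >= 1:
            raise InvalidConfigError("clauses_per_sentence must be >= 1")
        if self.coord_rate < 0:
            raise InvalidConfigError("coord_rate must be >= 0")
        if not 0 < self.content_ratio <= 1:
            raise InvalidConfigError("content_ratio must be in (0, 1]")
        if self.vocab_size < 10:
            raise InvalidConfigError("vocab_size must be >= 10")
        if not self.zipf_exponent > 0:
            raise InvalidConfigError("zipf_exponent must be > 0")
        for name in ("repetition_rate", "ngram_familiarity"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InvalidConfigError(f"{name} must be in [0, 1]")
        if self.n_sentences < 1:
            raise EmptyTranscriptError("n_sentences must be >= 1")


def chc_speech_params(**overrides) -> TranscriptGenParams:
    """Speech profile emulating cognitively healthy controls."""
    return replace(TranscriptGenParams(), **overrides)


def ad_speech_params(**overrides) -> TranscriptGenParams:
    """Speech profile emulating AD speech: shorter syntactic units, lower
    lexical content, more repetitive (compressible) output and less
    reliance on high-frequency multiword sequences."""
    base = TranscriptGenParams(
        mean_clause_len=4.5,
        clauses_per_sentence=1.2,
        coord_rate=0.1,
        content_ratio=0.45,
        repetition_rate=0.6,
        ngram_familiarity=0.3,
    )
    return replace(base, **overrides)


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of the feature-level cohort generator.

    Group differences of ``effect_size`` standard deviations (Cohen's d)
    are planted on ``effect_features``; all 32 features share unit variance
    and an equicorrelation ``within_category_correlation`` inside each
    measurement category (block-diagonal across categories).
    """

    n_per_group: int = 22
    effect_features: tuple[str, ...] = ()
    effect_size: float = 0.0
    within_category_correlation: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise InvalidConfigError("n_per_group must be >= 2")
        if not 0 <= self.within_category_correlation < 1:
            raise InvalidConfigError("within_category_correlation must be in [0, 1)")
        registry.validate_codes(self.effect_features)


# ---------------------------------------------------------------------------
# lexicon


@dataclass(frozen=True)
class Lexicon:
    """Deterministic POS-partitioned Zipf lexicon."""

    words: dict  # pos -> list of surface forms, rank order = frequency order
    probs: dict  # pos -> np.ndarray of Zipf probabilities
    zipf_exponent: float

    @classmethod
    def build(cls, vocab_size: int, zipf_exponent: float) -> "Lexicon":
        if vocab_size < 10:
            raise InvalidConfigError("vocab_size must be >= 10")
        shares = {"NOUN": 0.5, "VERB": 0.25, "ADJ": 0.15, "ADV": 0.10}
        sizes = {p: max(2, int(round(s * vocab_size))) for p, s in shares.items()}
        words: dict[str, list[str]] = {}
        probs: dict[str, np.ndarray] = {}
        idx = 0
        for pos_tag in ("NOUN", "VERB", "ADJ", "ADV"):
            k = sizes[pos_tag]
            words[pos_tag] = [lang.make_word(idx + j, pos_tag) for j in range(k)]
            idx += k
            ranks = np.arange(1, k + 1, dtype=float)
            p = ranks ** (-zipf_exponent)
            probs[pos_tag] = p / p.sum()
        return cls(words=words, probs=probs, zipf_exponent=zipf_exponent)

    def draw(self, pos_tag: str, rng: np.random.Generator, familiarity: float) -> str:
        """Draw a surface form; with probability ``familiarity`` restrict to
        the high-frequency band (top decile of ranks) of the class."""
        w, p = self.words[pos_tag], self.probs[pos_tag]
        if familiarity > 0 and rng.random() < familiarity:
            k = max(1, len(w) // 10)
            band = p[:k] / p[:k].sum()
            return w[int(rng.choice(k, p=band))]
        return w[int(rng.choice(len(w), p=p))]


# ---------------------------------------------------------------------------
# toy reference frequency tables


def build_toy_frequency_tables(
    vocab_size: int = 120,
    zipf_exponent: float = 1.0,
    registers: tuple[str, ...] = registry.REGISTERS,
    seed: int = 0,
    stream_len: int = 20000,
) -> dict[tuple[str, int], ReferenceFrequencyTable]:
    """Build toy n-gram frequency tables for each register and order 1..5.

    Each register corpus is text in the same artificial language, produced
    by the transcript grammar over the shared Zipf lexicon (open-class
    slots drawn from the full Zipf distribution); n-gram counts of orders
    1..5 are tallied from the register's word-token stream.  Because the
    reference corpora share the grammar and lexicon of generated
    transcripts, transcript n-grams genuinely collide with reference
    n-grams at every order, and drawing from the high-frequency lexical
    band raises reference frequency at all orders.  Returns a mapping
    ``(register, n) -> ReferenceFrequencyTable`` (20 tables for the four
    standard registers).
    """
    if vocab_size < 10:
        raise InvalidConfigError("vocab_size must be >= 10")
    if not registers:
        raise InvalidConfigError("at least one register is required")
    lex = Lexicon.build(vocab_size, zipf_exponent)
    params = TranscriptGenParams(
        vocab_size=vocab_size, zipf_exponent=zipf_exponent,
        ngram_familiarity=0.0, repetition_rate=0.3,
        n_sentences=max(2, stream_len // 8))
    rng = np.random.default_rng(seed)
    tables: dict[tuple[str, int], ReferenceFrequencyTable] = {}
    for reg in registers:
        stream: list[str] = []
        while len(stream) < stream_len:
            sub_seed = int(rng.integers(2**31 - 1))
            _, gold, _ = generate_transcript(params, seed=sub_seed,
                                             id=f"ref-{reg}", lexicon=lex)
            stream.extend(t.surface.lower() for t in gold.word_tokens)
        stream = stream[:stream_len]
        for n in _GRAM_ORDERS:
            counts: dict[str, int] = {}
            for i in range(len(stream) - n + 1):
                g = " ".join(stream[i:i + n])
                counts[g] = counts.get(g, 0) + 1
            tables[(reg, n)] = ReferenceFrequencyTable(
                register=reg, n=n, counts=counts, total=len(stream) - n + 1
            )
    return tables


# ---------------------------------------------------------------------------
# transcript generation


@dataclass
class _ClausePlan:
    tokens: list[Token] = field(default_factory=list)
    n_words: int = 0
    n_content: int = 0
    n_coord: int = 0


def _plan_clause(
    params: TranscriptGenParams,
    lex: Lexicon,
    rng: np.random.Generator,
    opener: str | None,
) -> _ClausePlan:
    """Build one clause as a token list with gold heads/deprels.

    Head indices are clause-local here (verb at index ``_V``, patched to
    sentence-local offsets by the caller); the clause verb's own head and
    deprel are assigned at sentence assembly.
    """
    fam = params.ngram_familiarity
    # the opener ("wen"/"ab") counts as a clause word: shrink the padding
    # budget so realized words/clause stays centered on mean_clause_len
    opener_words = 1 if opener else 0
    target_len = 3 + int(rng.poisson(max(params.mean_clause_len - 3.0 - opener_words, 0.0)))
    n_coord = int(rng.poisson(params.coord_rate))

    subj = lex.draw("NOUN", rng, fam)
    verb = lex.draw("VERB", rng, fam)

    pre_subj: list[str] = []            # ADJ padding before the subject
    coord: list[str] = [lex.draw("NOUN", rng, fam) for _ in range(n_coord)]
    post_verb: list[tuple[str, str]] = []  # (surface, role) after the verb

    n_words = 3 + 2 * n_coord + opener_words  # opener? da subj verb (ko noun)*
    n_content = 2 + n_coord
    used_aux = False

    # split the padding budget into content vs function words so that the
    # clause's content fraction lands on target: content slots are filled
    # by ADJ/ADV, function slots by a pronoun object, an auxiliary and
    # adposition phrases ("in da N": two function words + one noun)
    n_pad = max(target_len - n_words, 0)
    target_content = int(round(params.content_ratio * (n_words + n_pad)))
    content_pad = min(max(target_content - n_content, 0), n_pad)
    function_pad = n_pad - content_pad
    if function_pad >= 1:
        post_verb.append(("er", "obj"))
        function_pad -= 1
    if function_pad >= 1:
        used_aux = True
        function_pad -= 1
    while function_pad >= 2 and content_pad >= 1:
        post_verb.append((lex.draw("NOUN", rng, fam), "obl"))
        function_pad -= 2
        content_pad -= 1
    content_pad += function_pad  # unplaceable function mass becomes content
    for _ in range(content_pad):
        if rng.random() < 0.5:
            pre_subj.append(lex.draw("ADJ", rng, fam))
        else:
            post_verb.append((lex.draw("ADV", rng, fam), "advmod"))
    n_words += n_pad
    n_content = 2 + n_coord + sum(1 for s, r in post_verb if r in ("obl", "advmod")) \
        + len(pre_subj)

    # assemble clause-local token list with gold structure
    toks: list[Token] = []

    def add(surface, pos, head, deprel):
        toks.append(Token(surface=surface, lemma=surface.lower(), pos=pos,
                          head=head, deprel=deprel))

    V = -1  # placeholder head for tokens attaching to the clause verb
    if opener == lang.SUBORDINATOR:
        add(lang.SUBORDINATOR, "SCONJ", V, "mark")
    elif opener == lang.CLAUSAL_COORD:
        add(lang.CLAUSAL_COORD, "CCONJ", V, "cc")

    subj_idx = len(toks) + 1 + len(pre_subj)
    add("da", "DET", subj_idx, "det")
    for a in pre_subj:
        add(a, "ADJ", subj_idx, "amod")
    add(subj, "NOUN", V, "nsubj")
    for c in coord:
        add(lang.PHRASAL_COORD, "CCONJ", len(toks) + 1, "cc")
        add(c, "NOUN", subj_idx, "conj")
    if used_aux:
        add("ha", "AUX", V, "aux")
    verb_idx = len(toks)
    add(verb, "VERB", verb_idx, "root")  # head/deprel patched by caller
    for surface, role in post_verb:
        if role == "obl":
            noun_idx = len(toks) + 2
            add("in", "ADP", noun_idx, "case")
            add("da", "DET", noun_idx, "det")
            add(surface, "NOUN", V, "obl")
        elif role == "obj":
            add(surface, "PRON", V, "obj")
        else:
            add(surface, "ADV", V, "advmod")

    # patch clause-local verb references
    for i, t in enumerate(toks):
        if t.head == V:
            t.head = verb_idx
    plan = _ClausePlan(tokens=toks, n_words=n_words, n_content=n_content, n_coord=n_coord)
    return plan


def _plan_sentence(params: TranscriptGenParams, lex: Lexicon,
                   rng: np.random.Generator) -> Sentence:
    n_clauses = 1 + int(rng.poisson(params.clauses_per_sentence - 1.0))
    toks: list[Token] = []
    clause_verb_idx: list[int] = []
    n_coord = 0
    for ci in range(n_clauses):
        opener = None
        if ci > 0:
            opener = lang.CLAUSAL_COORD if rng.random() < 0.5 else lang.SUBORDINATOR
        plan = _plan_clause(params, lex, rng, opener)
        off = len(toks)
        v_local = next(i for i, t in enumerate(plan.tokens)
                       if t.pos == "VERB")
        for t in plan.tokens:
            t.head += off
        v = off + v_local
        verb = plan.tokens[v_local]
        if ci == 0:
            verb.head, verb.deprel = v, "root"
        elif opener == lang.SUBORDINATOR:
            verb.head, verb.deprel = clause_verb_idx[-1], "advcl"
        else:
            verb.head, verb.deprel = clause_verb_idx[0], "conj"
        clause_verb_idx.append(v)
        toks.extend(plan.tokens)
        n_coord += plan.n_coord
    root = clause_verb_idx[0]
    toks.append(Token(surface=".", lemma=".", pos="PUNCT", head=root, deprel="punct"))
    sent = Sentence(tokens=toks, clause_count=n_clauses, coord_phrase_count=n_coord)
    return sent


def _render(sentences: list[Sentence]) -> str:
    parts = []
    for s in sentences:
        words = [t.surface for t in s.tokens if t.pos != "PUNCT"]
        parts.append(" ".join(words) + ".")
    return " ".join(parts)


def generate_transcript(
    params: TranscriptGenParams,
    seed: int = 0,
    id: str = "t0",
    lexicon: Lexicon | None = None,
) -> tuple[str, AnnotatedTranscript, dict]:
    """Generate one transcript with gold annotation and realized truth.

    Returns ``(text, gold_annotation, gold_truth)`` where ``gold_truth``
    records the realized per-transcript MLS, MLC, CS, cPC and LD computed
    directly from the generated structure.
    """
    params.validate()
    lex = lexicon or Lexicon.build(params.vocab_size, params.zipf_exponent)
    rng = np.random.default_rng(seed)
    sentences: list[Sentence] = []
    for _ in range(params.n_sentences):
        if sentences and rng.random() < params.repetition_rate:
            src = sentences[int(rng.integers(len(sentences)))]
            sentences.append(Sentence(
                tokens=[Token(**t.to_dict()) for t in src.tokens],
                clause_count=src.clause_count,
                coord_phrase_count=src.coord_phrase_count,
            ))
        else:
            sentences.append(_plan_sentence(params, lex, rng))
    gold = AnnotatedTranscript(id=id, sentences=sentences)
    n_words = gold.n_words
    n_clauses = sum(s.clause_count for s in sentences)
    n_coord = sum(s.coord_phrase_count for s in sentences)
    n_content = sum(1 for t in gold.word_tokens if t.pos in lang.CONTENT_POS)
    gold_truth = {
        "id": id,
        "MLS": n_words / len(sentences),
        "MLC": n_words / n_clauses,
        "CS": n_clauses / len(sentences),
        "cPC": n_coord / n_clauses,
        "LD": n_content / n_words,
    }
    return _render(sentences), gold, gold_truth


def generate_transcript_cohort(
    group_params_ad: TranscriptGenParams,
    group_params_chc: TranscriptGenParams,
    n_per_group: int = 22,
    seed: int = 0,
) -> list[dict]:
    """Generate a labeled two-group corpus of synthetic transcripts.

    Returns one record per participant: ``{id, label, text, gold,
    gold_truth}`` with labels balanced (AD then CHC in id order).  Both
    groups share one lexicon so that group contrasts come only from the
    structural parameters.
    """
    if n_per_group < 2:
        raise InvalidConfigError("n_per_group must be >= 2")
    group_params_ad.validate()
    group_params_chc.validate()
    lex = Lexicon.build(group_params_chc.vocab_size, group_params_chc.zipf_exponent)
    root_rng = np.random.default_rng(seed)
    records = []
    for label, params in (("AD", group_params_ad), ("CHC", group_params_chc)):
        for i in range(n_per_group):
            tid = f"{label.lower()}{i:03d}"
            sub_seed = int(root_rng.integers(2**31 - 1))
            text, gold, truth = generate_transcript(params, seed=sub_seed,
                                                    id=tid, lexicon=lex)
            records.append({"id": tid, "label": label, "text": text,
                            "gold": gold, "gold_truth": truth})
    return records


# ---------------------------------------------------------------------------
# feature-level cohort


def generate_feature_cohort(config: CohortConfig):
    """Draw a 32-biomarker feature table with planted group effects.

    Features are multivariate Gaussian with unit variance and
    equicorrelated blocks per measurement category.  The AD group mean is
    shifted by ``-effect_size`` standard deviations on each effect feature
    (AD values lower, matching the direction of the speech contrasts).
    Returns ``(features, labels)``: a DataFrame indexed by participant id
    with the 32 registry columns, and a Series of labels.
    """
    import pandas as pd

    config.validate()
    rng = np.random.default_rng(config.seed)
    p = registry.N_BIOMARKERS
    rho = config.within_category_correlation
    cov = np.eye(p)
    for codes in registry.category_blocks().values():
        idx = [registry.index(c) for c in codes]
        for i in idx:
            for j in idx:
                if i != j:
                    cov[i, j] = rho
    chol = np.linalg.cholesky(cov)
    n = config.n_per_group
    z = rng.standard_normal(size=(2 * n, p)) @ chol.T
    shift = np.zeros(p)
    for code in config.effect_features:
        shift[registry.index(code)] = -config.effect_size
    z[:n, :] += shift  # AD block
    ids = [f"ad{i:03d}" for i in range(n)] + [f"chc{i:03d}" for i in range(n)]
    labels = pd.Series(["AD"] * n + ["CHC"] * n, index=ids, name="label")
    features = pd.DataFrame(z, index=ids, columns=list(registry.CODES))
    features.index.name = "id"
    return features, labels
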
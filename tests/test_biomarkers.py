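import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adspeech import registry, synthetic
from adspeech.annotation import AnnotatedTranscript, Sentence, Token, annotate
from adspeech.biomarkers import (BiomarkerVector, ReferenceFrequencyTable,
                                 WindowConfig, extract_biomarker_vector,
                                 kolmogorov_deflate, lexical_density,
                                 lexical_diversity, mean_word_length,
                                 ngram_nlf, normalized_stream,
                                 sliding_windows, syntactic_measures)
from adspeech.errors import EmptyInputError, InvalidConfigError

WHOLE = WindowConfig(window_len=100000, stride=1)


def tok(surface, pos="NOUN"):
    return Token(surface=surface, lemma=surface.lower(), pos=pos, head=0,
                 deprel="dep")


# ---------------------------------------------------------------------------
# windowing


@pytest.mark.parametrize("T,W,stride,expected", [
    (120, 50, 10, 8),    # floor((120-50)/10)+1
    (30, 50, 10, 1),     # short-sample fallback: one whole-sample window
    (50, 50, 10, 1),     # exact boundary
    (51, 50, 10, 1),
    (60, 50, 10, 2),
])
def test_window_count(T, W, stride, expected):
    wins = sliding_windows(list(range(T)), WindowConfig(window_len=W, stride=stride))
    assert len(wins) == expected
    if T >= W:
        assert all(len(w) == W for w in wins)


def test_window_config_validation():
    with pytest.raises(InvalidConfigError):
        WindowConfig(window_len=5)
    with pytest.raises(InvalidConfigError):
        WindowConfig(stride=0)
    with pytest.raises(EmptyInputError):
        sliding_windows([], WindowConfig())


# ---------------------------------------------------------------------------
# lexical diversity


def test_diversity_formulas_on_worked_example():
    toks = ["a", "b", "c", "d", "a", "b", "c", "d"]  # 8 tokens, 4 types
    d = lexical_diversity(toks)
    assert d["TTR"] == pytest.approx(0.5)
    assert d["rTTR"] == pytest.approx(4 / math.sqrt(8))
    assert d["cTTR"] == pytest.approx(1.0)
    assert d["bTTR"] == pytest.approx(math.log(4) / math.log(8))
    assert d["NDW"] == 4


def test_diversity_degenerate_vocabularies():
    d = lexical_diversity(["x"] * 10)
    assert (d["TTR"], d["NDW"], d["bTTR"]) == (0.1, 1, 0.0)
    d = lexical_diversity([f"w{i}" for i in range(9)])
    assert d["TTR"] == 1.0
    assert d["rTTR"] == pytest.approx(3.0)


def test_types_are_case_folded():
    assert lexical_diversity(["Hund", "hund"])["NDW"] == 1


@given(st.lists(st.sampled_from("abcdef"), min_size=1, max_size=60))
@settings(max_examples=100, deadline=None)
def test_diversity_invariants(tokens):
    d = lexical_diversity(tokens)
    N, V = len(tokens), len(set(tokens))
    assert 0 < d["TTR"] <= 1
    assert d["NDW"] == V
    assert d["rTTR"] == pytest.approx(d["TTR"] * math.sqrt(N))
    assert d["cTTR"] == pytest.approx(d["rTTR"] / math.sqrt(2))


# ---------------------------------------------------------------------------
# density and word length


def test_lexical_density_from_mask():
    toks = [tok("da", "DET"), tok("hundon", "NOUN"), tok("ha", "AUX"),
            tok("laufir", "VERB"), tok("gutum", "ADV")]
    assert lexical_density(toks) == pytest.approx(0.6)
    assert lexical_density([tok("a", "NOUN")] * 4) == 1.0
    assert lexical_density([tok("a", "DET")] * 4) == 0.0


def test_mean_word_length_excludes_punctuation():
    toks = [tok("der", "DET"), tok("Hund", "NOUN")]
    assert mean_word_length(toks) == pytest.approx(3.5)
    assert mean_word_length([tok("sixchar", "NOUN")]) == 7.0
    with_punct = toks + [Token(surface=".", lemma=".", pos="PUNCT", head=0,
                               deprel="punct", char_len=1)]
    assert mean_word_length(with_punct) == pytest.approx(3.5)


# ---------------------------------------------------------------------------
# syntactic measures


def test_syntactic_ratios_on_worked_example():
    s1 = Sentence(tokens=[tok(f"w{i}") for i in range(10)], clause_count=2,
                  coord_phrase_count=1)
    s2 = Sentence(tokens=[tok(f"w{i}") for i in range(6)], clause_count=1,
                  coord_phrase_count=0)
    m = syntactic_measures(AnnotatedTranscript(id="t", sentences=[s1, s2]))
    assert m["MLS"] == pytest.approx(8.0)
    assert m["CS"] == pytest.approx(1.5)
    assert m["MLC"] == pytest.approx(16 / 3)
    assert m["cPC"] == pytest.approx(1 / 3)


def test_monoclausal_transcript_identities():
    sents = [Sentence(tokens=[tok(f"w{i}") for i in range(5)], clause_count=1,
                      coord_phrase_count=0) for _ in range(4)]
    m = syntactic_measures(AnnotatedTranscript(id="t", sentences=sents))
    assert m["CS"] == 1.0 and m["cPC"] == 0.0
    assert m["MLC"] == m["MLS"]


# ---------------------------------------------------------------------------
# compression


def test_deflate_ratio_of_highly_repetitive_text():
    assert kolmogorov_deflate("ab" * 500) < 0.05


def test_deflate_orders_repetitive_below_random():
    rnd = random.Random(1)
    noise = "".join(rnd.choice("abcdefghij ") for _ in range(1000))
    assert kolmogorov_deflate("ab" * 500) < kolmogorov_deflate(noise)
    assert kolmogorov_deflate(noise) == kolmogorov_deflate(noise)


def test_deflate_empty_and_short_inputs():
    with pytest.raises(EmptyInputError):
        kolmogorov_deflate("")
    with pytest.warns(UserWarning):
        kolmogorov_deflate("short text")


# ---------------------------------------------------------------------------
# n-gram normalized log frequency


def _bigram_table():
    return ReferenceFrequencyTable(register="news", n=2,
                                   counts={"der hund": 9, "hund schläft": 1},
                                   total=10)


def test_nlf_worked_example():
    val = ngram_nlf(["der", "hund", "schläft"], 2, _bigram_table())
    expected = (math.log10(9e5) + math.log10(1e5)) / 2
    assert val == pytest.approx(expected, abs=1e-9)
    assert val == pytest.approx(5.477, abs=1e-3)


def test_nlf_floor_for_unseen_grams():
    t = _bigram_table()
    val = ngram_nlf(["x", "y", "z"], 2, t)
    assert val == pytest.approx(math.log10(t.cpm_floor))


def test_nlf_monotone_in_gram_counts():
    t = _bigram_table()
    low = ngram_nlf(["x", "y"], 2, t)          # unseen bigram
    high = ngram_nlf(["der", "hund"], 2, t)    # count-9 bigram
    assert high > low


def test_nlf_undefined_below_order():
    assert math.isnan(ngram_nlf(["der"], 2, _bigram_table()))
    with pytest.raises(InvalidConfigError):
        ngram_nlf(["a", "b"], 3, _bigram_table())


# ---------------------------------------------------------------------------
# full extraction


def _transcript(params=None, seed=0, **kw):
    p = params or synthetic.TranscriptGenParams(**kw)
    text, gold, truth = synthetic.generate_transcript(p, seed=seed)
    return text, gold, truth


def test_vector_has_exactly_32_registry_codes(freq_tables):
    _, gold, _ = _transcript(n_sentences=20)
    vec = extract_biomarker_vector(gold, freq_tables)
    assert len(vec) == 32
    assert set(vec.values) == set(registry.CODES)


def test_biomarker_vector_rejects_wrong_codes():
    with pytest.raises(InvalidConfigError):
        BiomarkerVector(values={"MLS": 1.0})


def test_missing_table_is_a_named_configuration_error(freq_tables):
    _, gold, _ = _transcript(n_sentences=10)
    broken = dict(freq_tables)
    del broken[("fiction", 3)]
    with pytest.raises(InvalidConfigError, match="fiction"):
        extract_biomarker_vector(gold, broken)


def test_short_transcript_windowed_equals_whole_sample(freq_tables):
    _, gold, _ = _transcript(n_sentences=4, seed=2)
    assert len(gold.word_tokens) < 50
    v50 = extract_biomarker_vector(gold, freq_tables, WindowConfig())
    vall = extract_biomarker_vector(gold, freq_tables, WHOLE)
    for c in registry.CODES:
        assert v50[c] == pytest.approx(vall[c], abs=1e-12)


def test_sentence_permutation_leaves_whole_sample_measures_unchanged(freq_tables):
    _, gold, _ = _transcript(n_sentences=30, seed=4)
    rnd = random.Random(0)
    shuffled = AnnotatedTranscript(
        id=gold.id, sentences=rnd.sample(gold.sentences, len(gold.sentences)))
    a = extract_biomarker_vector(gold, freq_tables, WHOLE)
    b = extract_biomarker_vector(shuffled, freq_tables, WHOLE)
    for c in ("NDW", "TTR", "bTTR", "rTTR", "cTTR", "LD", "MLWc",
              "MLS", "MLC", "CS", "cPC"):
        assert a[c] == pytest.approx(b[c], abs=1e-12), c


def test_self_concatenation_strictly_decreases_ttr_and_kdbase(freq_tables):
    _, gold, _ = _transcript(n_sentences=30, seed=6)
    doubled = AnnotatedTranscript(id=gold.id,
                                  sentences=gold.sentences + gold.sentences)
    a = extract_biomarker_vector(gold, freq_tables, WHOLE)
    b = extract_biomarker_vector(doubled, freq_tables, WHOLE)
    assert b["TTR"] < a["TTR"]
    assert b["KDbase"] < a["KDbase"]


def test_extraction_recovers_generator_truth(freq_tables):
    p = synthetic.TranscriptGenParams(n_sentences=200)
    text, gold, truth = synthetic.generate_transcript(p, seed=1)
    vec = extract_biomarker_vector(annotate(text, id=gold.id), freq_tables)
    for c in ("MLS", "MLC", "CS", "cPC"):
        assert vec[c] == pytest.approx(truth[c], abs=0.1), c
    assert vec["LD"] == pytest.approx(p.content_ratio, abs=0.02)


def test_kdbase_uses_normalized_word_stream():
    _, gold, _ = _transcript(n_sentences=15, seed=3)
    stream = normalized_stream(gold)
    assert "." not in stream
    assert stream == stream.lower()
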
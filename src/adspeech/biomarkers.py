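"""Computation of the 32 linguistic biomarkers.

Lexical measures (diversity, density, word length, n-gram frequency) are
computed under a sliding-window scheme — fixed-length token windows at a
fixed stride, aggregated across windows — which yields length-robust,
context-sensitive estimates instead of a single whole-sample score.
Syntactic measures are per-sentence ratios over the whole transcript, and
the compression measure is computed once on the full normalized token
stream (it is order-sensitive by construction).

Formulas
--------
With ``V`` types and ``N`` tokens in a window: ``TTR = V/N``,
``bTTR = ln V / ln N`` (1 when ``N = 1``), ``rTTR = V/sqrt(N)``,
``cTTR = V/sqrt(2N)``, ``NDW = V``.  Lexical density is the content-word
fraction; MLWc the mean character count per word.  Normalized log
frequency of order-``n`` grams against a register table with total ``T``:
``NLF = mean_i log10(1e6 * c(g_i) / T)`` over the window's ``G = N-n+1``
grams, with unseen grams floored at half a count.  Kolmogorov Deflate is
the raw-DEFLATE-stream length divided by the byte length of the
case-folded, space-joined word stream.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np

from . import registry
from .annotation import AnnotatedTranscript, Token, content_word_mask
from .errors import EmptyInputError, InvalidConfigError

#: Minimum encoded length (bytes) below which the compression ratio is
#: considered unstable and a short-sample warning is emitted.
KD_MIN_BYTES = 64


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window settings for the lexical measures.

    50-token windows at stride 10 with mean aggregation; transcripts
    shorter than one window fall back to a single whole-sample window.
    """

    window_len: int = 50
    stride: int = 10
    aggregate: str = "mean"

    def __post_init__(self) -> None:
        if self.window_len < 10:
            raise InvalidConfigError("window_len must be >= 10")
        if self.stride < 1:
            raise InvalidConfigError("stride must be >= 1")
        if self.aggregate not in ("mean", "median"):
            raise InvalidConfigError("aggregate must be 'mean' or 'median'")

    def combine(self, values) -> float:
        vals = [v for v in values if not (isinstance(v, float) and math.isnan(v))]
        if not vals:
            return float("nan")
        return float(np.mean(vals) if self.aggregate == "mean" else np.median(vals))


@dataclass
class ReferenceFrequencyTable:
    """n-gram counts of one register corpus.

    ``counts`` maps space-joined, case-folded grams to positive counts;
    ``total`` is the number of gram tokens in the underlying corpus (the
    table may be truncated, so ``total`` can exceed the sum of listed
    counts).
    """

    register: str
    n: int
    counts: dict
    total: int

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise InvalidConfigError("frequency table total must be positive")
        if not 1 <= self.n <= 5:
            raise InvalidConfigError("gram order must be in 1..5")

    def cpm(self, gram: str) -> float:
        """Counts per million, floored at half a count for unseen grams."""
        c = self.counts.get(gram, 0.5)
        return 1e6 * c / self.total

    @property
    def cpm_floor(self) -> float:
        return 1e6 * 0.5 / self.total


@dataclass
class BiomarkerVector:
    """The 32 named biomarker values of one transcript."""

    values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in registry.CODES if c not in self.values]
        extra = [c for c in self.values if c not in registry.CODES]
        if missing or extra:
            raise InvalidConfigError(
                f"biomarker vector must carry exactly the 32 registry codes "
                f"(missing={missing}, extra={extra})")

    def __getitem__(self, code: str) -> float:
        return self.values[code]

    def __len__(self) -> int:
        return len(self.values)

    def to_series(self):
        import pandas as pd
        return pd.Series({c: self.values[c] for c in registry.CODES})


# ---------------------------------------------------------------------------
# windowing


def sliding_windows(word_tokens: list, cfg: WindowConfig) -> list[list]:
    """Fixed-length windows at fixed stride over the word-token sequence.

    Yields ``floor((T - W)/stride) + 1`` full windows; a sample shorter
    than one window yields a single whole-sample window.
    """
    if not word_tokens:
        raise EmptyInputError("cannot window an empty token sequence")
    T, W = len(word_tokens), cfg.window_len
    if T < W:
        return [list(word_tokens)]
    return [list(word_tokens[i:i + W]) for i in range(0, T - W + 1, cfg.stride)]


# ---------------------------------------------------------------------------
# window-level measures


def _surfaces(tokens) -> list[str]:
    out = []
    for t in tokens:
        out.append(t.lower() if isinstance(t, str) else t.surface.lower())
    return out


def lexical_diversity(tokens) -> dict:
    """TTR family and NDW of one window (types are case-folded surfaces)."""
    surfs = _surfaces(tokens)
    if not surfs:
        raise EmptyInputError("empty window")
    N = len(surfs)
    V = len(set(surfs))
    bttr = 1.0 if N == 1 else math.log(V) / math.log(N)
    return {
        "TTR": V / N,
        "bTTR": bttr,
        "rTTR": V / math.sqrt(N),
        "cTTR": V / math.sqrt(2 * N),
        "NDW": float(V),
    }


def lexical_density(tokens: list[Token]) -> float:
    """Content-word fraction of one window."""
    toks = [t for t in tokens if t.is_word]
    if not toks:
        raise EmptyInputError("empty window")
    mask = content_word_mask(toks)
    return sum(mask) / len(mask)


def mean_word_length(tokens: list[Token]) -> float:
    """Mean non-punctuation character count per word token."""
    toks = [t for t in tokens if t.is_word]
    if not toks:
        raise EmptyInputError("empty window")
    return float(np.mean([t.char_len for t in toks]))


def ngram_nlf(tokens, n: int, table: ReferenceFrequencyTable) -> float:
    """Normalized log frequency of the window's order-``n`` grams.

    Mean base-10 log of counts-per-million over all ``N - n + 1`` grams;
    returns NaN (undefined, excluded from aggregation) when the window is
    shorter than ``n``.
    """
    if table.n != n:
        raise InvalidConfigError(f"table order {table.n} does not match n={n}")
    surfs = _surfaces(tokens)
    if len(surfs) < n:
        return float("nan")
    logs = [math.log10(table.cpm(" ".join(surfs[i:i + n])))
            for i in range(len(surfs) - n + 1)]
    return float(np.mean(logs))


# ---------------------------------------------------------------------------
# transcript-level measures


def syntactic_measures(transcript: AnnotatedTranscript) -> dict:
    """MLS, MLC, CS and cPC over the transcript's sentence units."""
    if not transcript.sentences:
        raise EmptyInputError("transcript has no sentences")
    n_sent = len(transcript.sentences)
    n_words = transcript.n_words
    n_clauses = sum(s.clause_count for s in transcript.sentences)
    n_coord = sum(s.coord_phrase_count for s in transcript.sentences)
    return {
        "MLS": n_words / n_sent,
        "MLC": n_words / n_clauses,
        "CS": n_clauses / n_sent,
        "cPC": n_coord / n_clauses,
    }


def normalized_stream(transcript: AnnotatedTranscript) -> str:
    """Case-folded, single-space-joined word-token stream.

    The compression measure is computed on this normalization so that
    punctuation and whitespace artifacts of transcription do not affect
    the ratio.
    """
    return " ".join(t.surface.lower() for t in transcript.word_tokens)


def kolmogorov_deflate(text: str, level: int = 9) -> float:
    """DEFLATE compression ratio (compressed bytes / original bytes).

    Uses a raw DEFLATE stream (no container header or checksum) at maximum
    compression.  Lower values indicate more redundant, less
    information-dense text.
    """
    data = text.encode("utf-8")
    if not data:
        raise EmptyInputError("cannot compress empty text")
    if len(data) < KD_MIN_BYTES:
        warnings.warn(
            f"compression ratio computed on a short sample ({len(data)} bytes); "
            "the estimate is dominated by stream overhead", stacklevel=2)
    comp = zlib.compressobj(level=level, method=zlib.DEFLATED, wbits=-15)
    stream = comp.compress(data) + comp.flush()
    return len(stream) / len(data)


# ---------------------------------------------------------------------------
# full extraction


def _require_tables(tables: dict) -> None:
    for reg in registry.REGISTERS:
        for n in range(1, 6):
            if (reg, n) not in tables:
                raise InvalidConfigError(
                    f"missing frequency table for register={reg!r}, n={n}")


def extract_biomarker_vector(
    annotation: AnnotatedTranscript,
    tables: dict,
    window_cfg: WindowConfig | None = None,
) -> BiomarkerVector:
    """Compute all 32 biomarkers of one annotated transcript.

    Windowed: TTR family, NDW, LD, MLWc and the 20 NLF measures.
    Sentence-based: MLS, MLC, CS, cPC.  Whole-transcript: KDbase.
    """
    cfg = window_cfg or WindowConfig()
    _require_tables(tables)
    words = annotation.word_tokens
    if not words:
        raise EmptyInputError(f"transcript {annotation.id!r} has no word tokens")

    windows = sliding_windows(words, cfg)
    values: dict[str, float] = {}

    div_keys = ("TTR", "bTTR", "rTTR", "cTTR", "NDW")
    per_window = [lexical_diversity(w) for w in windows]
    for k in div_keys:
        values[k] = cfg.combine(d[k] for d in per_window)
    values["LD"] = cfg.combine(lexical_density(w) for w in windows)
    values["MLWc"] = cfg.combine(mean_word_length(w) for w in windows)
    for n in range(1, 6):
        for reg in registry.REGISTERS:
            code = f"{n}GNLF{registry.REGISTER_SUFFIX[reg]}"
            values[code] = cfg.combine(
                ngram_nlf(w, n, tables[(reg, n)]) for w in windows)

    values.update(syntactic_measures(annotation))
    values["KDbase"] = kolmogorov_deflate(normalized_stream(annotation))
    return BiomarkerVector(values=values)


def extract_feature_table(
    annotations: list[AnnotatedTranscript],
    labels: list[str],
    tables: dict,
    window_cfg: WindowConfig | None = None,
):
    """Extract a cohort feature table: one row per participant.

    Returns a DataFrame indexed by transcript id with a ``label`` column
    followed by the 32 biomarker columns in registry order.
    """
    import pandas as pd

    if len(annotations) != len(labels):
        raise InvalidConfigError("annotations and labels differ in length")
    rows = {}
    for ann, label in zip(annotations, labels):
        vec = extract_biomarker_vector(ann, tables, window_cfg)
        rows[ann.id] = {"label": label, **{c: vec[c] for c in registry.CODES}}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "id"
    return df
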
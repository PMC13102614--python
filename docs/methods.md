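# Methods

## The measurement model

A transcript is annotated into sentences, tokens (surface, lemma,
universal POS, dependency head and relation) and clause units, then mapped
to 32 real-valued biomarkers.

**Clause operationalization.** No universally agreed definition of
"clause" exists for spontaneous speech, so the package fixes one and
derives every clause-based measure from it: a clause head is the sentence
root plus any token with a clausal dependency relation (`ccomp`, `advcl`,
`acl`, `csubj`, `parataxis`) or a `conj` relation headed by a verb.
Coordinated finite verbs therefore count as separate clauses, while a
`conj` dependent with a non-verbal head counts as a coordinate phrase —
the two counts (CS numerator and cPC numerator) never overlap. A verbless
utterance counts as one clause so that words-per-clause stays defined for
fragmentary picture descriptions. Content words are NOUN, PROPN, VERB,
ADJ, ADV; auxiliaries carry the AUX tag and are excluded. These choices
are encoded once in the annotation layer; all derived biomarkers are
defined relative to them.

**Sliding windows.** Lexical measures (the TTR family, NDW, LD, MLWc and
all 20 NLF scores) are computed per 50-token window at stride 10 and
mean-aggregated; a transcript shorter than one window falls back to a
single whole-sample window, which makes the windowed statistic collapse to
the classical whole-sample one. Window length, stride and the aggregation
statistic are configuration, not constants: 50 tokens matches common
moving-average TTR practice and is long enough for 5-gram scores to be
estimated inside a window. Syntactic ratios are per-sentence quantities
pooled over the transcript, and the compression ratio is computed once on
the whole normalized word stream, because it is order-sensitive by
construction.

**Normalized log frequency.** For order-n grams against a register table
with total T gram tokens: `NLF = (1/G) Σ log10(1e6 · c(gᵢ)/T)` over the
window's `G = N − n + 1` case-folded grams, with unseen grams floored at
half a count (`c = 0.5`). The mean over grams is the length normalization;
base 10 and the half-count floor are package conventions (the floor keeps
NLF finite; any monotone alternative would reorder nothing). Absolute NLF
values are meaningful only relative to the reference tables used.

**Kolmogorov Deflate.** `KDbase = |deflate(s)| / |s|` where `s` is the
case-folded, single-space-joined word-token stream encoded as UTF-8 and
the numerator is a raw DEFLATE stream at maximum compression level (no
container header or checksum). Computing on the normalized stream rather
than raw text removes punctuation and whitespace artifacts of
transcription. Samples under 64 bytes are flagged: at that length the
ratio is dominated by stream overhead.

## Feature selection

Stage one: inside each training split of a stratified 5-fold partition,
features are z-scaled on that split and an L2 logistic scorer
(C = 0.5, balanced class weights — the same settings as the final linear
model, so selection and modeling agree on what "informative" means) is
refit repeatedly, dropping the feature with the smallest |coefficient| one
at a time until m = 10 survive. Ties break deterministically by registry
order (the earlier index survives); a zero-variance feature is dropped
first with a warning. Stage two: selection frequencies are aggregated
across folds and features kept in ≥ 60 % of folds (3 of 5) form the
stable set.

A caveat the test suite quantifies: with a fixed cohort of n = 44, the
training splits of a 5-fold partition share 75 % of their rows, so a noise
feature whose *sample* correlation with the label is large by chance tends
to be selected in most folds. With 25 noise features the expected maximum
chance correlation at n = 44 is ≈ 0.38, and m = 10 forces three
beyond-signal picks per fold; consequently the stable set typically
contains the planted markers *plus* one to four persistent chance
features, and under a pure-noise cohort the stable set is far from empty.
This is inherent to per-fold selection on a small fixed sample (the
analogous Meinshausen–Bühlmann bound gives ≈ q²/((2θ−1)p) ≈ 3 expected
false stables at q = 10, θ = 0.6, p = 32), not an implementation artifact;
the acceptance suite states the idealized exact-recovery property and
documents its failure rather than weakening it. Practitioners wanting
tighter support recovery should lower m toward the expected signal size or
raise the threshold.

## Classification and evaluation

Five families with fixed hyperparameters (logistic regression: C = 0.5,
balanced, 3000 iterations; RBF-SVM: C = 1.0, scale kernel width, sigmoid
probability calibration; random forest: 200 trees, depth 4; gradient
boosting and XGBoost: 200 estimators, learning rate 0.05, depth 3).
Inside each fold, mean imputation and z-scaling are fit on the training
split only. The decision threshold is 0.5 on the calibrated probability —
the natural convention for balanced classes. Zero-denominator conventions:
precision/recall/F1 are 0 when undefined, MCC is 0 when any factor of its
denominator vanishes; these never trigger on balanced cohorts but must be
defined. AUROC is computed as tie-aware pairwise concordance (equivalent
to the trapezoidal curve area; a property test checks this equivalence),
AUPRC as step-interpolated average precision. Confidence intervals
resample the five fold-level metric values with replacement (1000 draws,
percentile interval); with only five values these intervals are coarse,
which is reported as-is.

## Shapley attribution

The explained model is logistic regression refit on the full cohort over
the stable set, explained on the log-odds scale with the training data as
background. Two exact routes: the linear closed form
`φᵢ = βᵢ(xᵢ − μᵢ)`, `base = β·μ + b`, and exhaustive coalition enumeration
of the Shapley formula with an interventional value function
`v(S) = E_bg[f(x_S, X_{\bar S})]`. Enumeration is exact and cheap at the
stable-set sizes this pipeline produces (2⁷ = 128 coalitions at p = 7) and
serves as the model-agnostic oracle for any approximation added later; it
refuses p > 15. Marginal (not conditional) expectations are used because
conditional ones are unidentifiable from 44 rows. Additivity
(`base + Σφ = f(x)`), dummy and symmetry are asserted to 1e-9 or better.

## The synthetic cohorts

**Transcript generator.** Transcripts are written in an artificial SVO
language whose POS is recoverable from the surface form (a closed function
class plus suffix-marked open classes), so gold annotation is exact and no
external parser is needed. Sentence templates encode clause structure
explicitly: each clause is `DET N V` plus padding units, extra clauses
attach by a subordinator or a clausal coordinator, and phrasal
coordination adds `ko N` units. The dials map one-to-one onto biomarker
families: `mean_clause_len` (default 6 words) and `clauses_per_sentence`
(1.5) drive MLS/MLC/CS; `coord_rate` (0.2/clause) drives cPC;
`content_ratio` (0.55) is hit by splitting the padding budget between
content (ADJ/ADV) and function (pronoun, auxiliary, adposition-phrase)
words; `repetition_rate` (0.3) reuses earlier sentences verbatim and
drives compressibility; `ngram_familiarity` (0.5) fills open-class slots
from the top-decile frequency band of the Zipf lexicon (120 lemmas,
exponent 1.0). The AD preset shortens units (4.5 words/clause, 1.2
clauses/sentence), lowers content (0.45) and coordination (0.1), doubles
repetition (0.6) and lowers familiarity (0.3).

Reference frequency tables are built from register corpora generated with
the *same* grammar and lexicon (20 000 word tokens per register), so
transcript n-grams genuinely collide with reference n-grams at all orders
and the familiarity dial raises NLF at every order when isolated. Two
honest limitations: (i) the presets confound NLF — shorter, function-heavy
AD speech *raises* mean NLF because function words are corpus-frequent,
largely cancelling the familiarity contrast at the preset level, which
mirrors a real property of frequency-based lexical measures; (ii) the
artificial language has no morphology, semantics or disfluencies, so
passing tests demonstrate correctness of the measurement and modeling
machinery, not clinical validity on real German speech.

**Feature-level generator.** For selection/modeling/attribution tests a
32-column Gaussian cohort is drawn directly: unit variances,
equicorrelation ρ = 0.2 inside each measurement category (block-diagonal
across categories; chosen as a modest within-domain dependence — real
within-category correlations, e.g. among TTR variants, are far higher, but
near-collinearity would make support-recovery ill-posed), and a group mean
shift of −d (Cohen's d, default planted set: MLS, MLC, LD, KDbase,
4GNLFa/n/s — AD lower, matching the direction of the speech contrasts).
With d = 1.5 on seven correlated markers the Mahalanobis separation is
D ≈ 2.7 (Bayes accuracy ≈ 0.91): the linear and kernel families reach
≈ 0.92–0.94 cross-validated accuracy at n = 44, while gradient boosting's
conservative fixed shrinkage underfits at n_train ≈ 35 and stays near
0.83 — the acceptance suite reports this per family rather than averaging
it away.

## Numerical and degenerate-input conventions

`bTTR = 1` for a single-token window; windows shorter than the gram order
yield an undefined NLF sentinel that aggregation skips rather than
imputes; empty transcripts, punctuation-only input and all-zero confusion
matrices raise typed errors; all randomness flows from named integer
seeds (fold seed, model seed, bootstrap seed) and every pipeline artifact
embeds the configuration hash, so a rerun with the same configuration is
bit-identical.

## Problem sizes

Defaults mirror a deeply phenotyped clinical cohort: 22 participants per
group, 5 folds, 32 candidate features, stable sets around 7–10, 1000
bootstrap draws. Simulation-based tests use 20-seed replications at these
sizes; the toy reference corpora use 20 000 tokens per register, enough to
pin the Zipf rank-ratio within a few percent.
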
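# Methods

This note records the model assumptions, parameter choices and numerical
conventions behind `varterm`, and what the synthetic benchmarks do and do
not demonstrate.

## Pipeline model and assumptions

The extractor assumes that domain terms are noun phrases whose *syntactic*
shape is a good candidate filter but a poor termhood signal, and that
occurrence statistics should therefore be aggregated at the level of
normalised concepts, not surface strings. The stages are strictly
feed-forward: tagging → pattern matching → boundary trimming → bag-of-stems
normalisation → aggregation → similarity expansion → re-aggregation →
C-value scoring.

**Tagging.** The tagger is a pluggable contract
(`text -> sentences of (surface, pos, start, end)`). The default
`RuleTagger` is deterministic: a closed lexicon of function words, suffix
heuristics (-tion/-ness/-ment → NN, -al/-ic/-ous/-ive → JJ, -ed → VBN,
-ly → RB), digit-bearing tokens → CD/NN, and NN for unknown alphabetic
tokens. The noun default is the right bias for term extraction (unseen
domain words are overwhelmingly nominal) but it overcalls nouns in general
prose; a statistical tagger of general English can be substituted through
the contract without touching the rest of the pipeline. Hyphenated words
are kept as single tokens so forms like *postero-lateral* remain one
stemmable unit. Raw text is NFC-normalised before tokenisation; offsets are
0-based half-open into the normalised text.

**Patterns.** Tag classes are NN = {NN, NNS, NNP, NNPS},
JJ = {JJ, JJR, JJS}, plus POS and IN; plural and proper nouns thereby count
as nouns, so forms like *menisci* or *Hoffa* stay inside candidates. Matching is *maximal* per pattern: a span is
reported iff it matches and is not properly contained in another matching
span of the same pattern. Nested sub-phrases are not extracted as
independent candidates (except where another pattern matches them, e.g. a
plain noun pair inside a prepositional candidate); their statistics are
recovered through subset nestedness in the scorer instead. The IN class
optionally takes a preposition whitelist; by default any IN token matches.

**Trimming and normalisation ordering.** Stop words are trimmed from both
ends until a fixpoint; survivors need ≥ 2 tokens and a noun-class final
token. Normalisation removes punctuation/numeric/stop tokens first, then
drops *lowercase* tokens of ≤ 2 characters, and only then lowercases and
stems — this ordering is the only one under which a bare uppercase `D`
(*vitamin D*) survives while the possessive clitic `'s` is removed. A token
is "numeric" if it has digits and no letters, so `B12` is kept. Forms with
fewer than two stems are discarded: with a log-length factor, a single-stem
candidate scores zero and can never rank, so early discarding is equivalent
and cheaper.

**Stemming.** Porter's algorithm, implemented in-package and exposed as a
`str -> str` contract. For hyphenated tokens only the final segment is
suffix-stripped (*postero-lateral* → *postero-later*), keeping hyphenation
a single-edit difference from the fused spelling (*posterolater*).

## Similarity expansion

Two distinct stems are variants when

- both are at least `min_fuzzy_len` = 4 characters and their optimal string
  alignment (OSA) distance — unit-cost insert, delete, substitute, adjacent
  transpose, case change — is within a length-banded bound: 1 edit for
  stems of length 4–5, `max_ed` = 2 for length ≥ 6; or
- phonetic matching is enabled (default), their Metaphone codes agree and
  the distance is within the bound + 1.

The bands protect short stems, where a single edit usually lands on an
unrelated word, while still joining the documented variant pairs
(*haemorrhag*/*hemorrhag* at distance 1, *hypoglycem*/*hyperglycem* at 2,
*postero-later*/*posterolater* at 1). The phonetic relaxation has no length
floor, so phonetically identical short stems may pair; with Metaphone's
lossy vowel handling this is intentional (SMS-style spellings) but is the
main overmerge risk. All values are configuration
(`--max-ed`, `--min-fuzzy-len`, `--phonetic/--no-phonetic`).

The OSA variant counts an adjacent transposition once but does not reuse
transposed substrings; it is symmetric and zero exactly on equal strings,
but the triangle inequality is not guaranteed and is not relied upon. The
case-change operation is moot after lowercasing and exists for direct use
on raw tokens. Metaphone is the classic (1990) rule set; codes are compared
only for equality, so small rule-interpretation differences from other
implementations do not propagate beyond borderline pairs.

Expansion is a single symmetric pass: a form's bag gains every vocabulary
stem similar to one of its own stems, with no transitive closure — closure
could chain *a*→*b*→*c* through unrelated intermediates. Expansion never
changes a form's variant counts or its recorded length. When two
pre-expansion forms converge on the same expanded bag they are merged,
pooling variants and counts; the merged length is the largest member
length, since expansion adds alternative spellings, not words.

## Termhood

`C-value(t) = log|t| · f(t)` when no candidate strictly contains `t`'s bag,
else `log|t| · (f(t) − mean_{s∈S(t)} f(s))`. Conventions:

- `|t|` is the pre-expansion stem count (expansion must not inflate length).
- `f(t)` = direct occurrences of `t` + direct occurrences of every strict
  superset form. This is the convention under which `f(t) ≥ f(s)` for every
  superset `s` (by transitivity of ⊂), which makes scores provably
  non-negative; it also matches the idea that a nested term occurs wherever
  its container does.
- Natural log by default; a `log_base` switch (e.g. 2) rescales scores but
  provably cannot change the ranking.
- Ties break by descending frequency, then lexicographic order of the
  sorted stem key, so rankings are byte-reproducible.

Nestedness is O(n²) pairwise subset testing over expanded bags. Candidate
inventories at the intended scale (hundreds to low thousands of forms) keep
this and the pairwise stem comparisons (quadratic in distinct stems, which
grow sublinearly with corpus size) well inside interactive run times.

## Outputs

The ranked table (TSV and a self-contained HTML rendering) has one row per
normalised form: rank, score at 4 decimals, variants in descending
occurrence order, aggregated frequency. The plain term list flattens the
variant column. Stand-off annotation is dictionary matching over the
corpus's own tokenisation — case-insensitive, token-boundary anchored,
longest match wins at each position, scanning left to right, no overlaps.
The overlap policy is this package's documented choice. A regex-lexicon
export (one case-insensitive alternation per variant group) is available
for downstream matchers.

## Evaluation machinery

Gold standards are the intersection of two annotators' positive token sets;
tokens are identified by `(doc_id, start, end)` so stand-off files and
tagger output are directly comparable, and the token universe includes
every emitted token, punctuation included (a documented choice — published
analyses do not state theirs). Cohen's kappa is `(A_o − A_e)/(1 − A_e)`
from the 2×2 table; a table whose expected agreement is 1 raises an
explicit undefined-kappa error. `kappa_from_agreement` accepts pre-rounded
agreement values so that published three-decimal tables can be reproduced
at their printed precision. Token P/R/F uses undefined-as-zero conventions
for empty denominators. Top-k evaluation counts k *variant groups*, each
contributing all its surface variants to the matching dictionary; recall is
non-decreasing in k by construction. Requests for k beyond the available
forms evaluate everything and set a `truncated` flag.

## Synthetic corpora

The generator emulates the study conditions the pipeline targets: a small
document set (default 10 docs × 10 sentences) with five planted noun-phrase
terms at frequency 6 (4–6 over the variants used in tests), each occurrence
independently mutated at rate 0.1 per variation type — inflection
(plural toggle), derivation (suffix swaps of the -us↔-i / -a↔-al family),
preposition swap (*kidney stone* ↔ *stone of kidney*), hyphenation
insertion/removal, and single-edit misspellings — plus two simulated
annotators whose per-token membership flips independently at rate 0.1.
Planted content tokens are ≥ 6 characters so a single surface edit keeps
stems within the fuzzy bands. Filler sentences come from a closed
pseudo-word vocabulary whose suffixes steer the rule tagger (bare nouns,
-ed verbs, -ly adverbs) and contain at most one noun per clause, so filler
can never produce a multiword candidate. One `random.Random(seed)` drives
all choices in a fixed order (mutations, slot assignment, realisation,
annotator A, annotator B), making output byte-identical per seed.

Mutations verify their own contract before being accepted: a mutated token
must still stem-unify with the original under the default similarity
configuration (hyphen placement, for instance, is searched outward from the
token midpoint until the stems stay within one edit), and a preposition
swap must leave a noun-class final token, otherwise the occurrence is
emitted unmutated and flagged. Semantic variation (synonym substitution) is
not generated: the method does not claim to neutralise it.

What passing synthetic tests shows: the stages compose correctly, variant
groups unify under the stated noise model, rankings are deterministic, and
aggregation measurably protects a term whose spelling is inconsistent. What
it does not show: performance on real clinical or scientific language —
real corpora have richer syntax, tagger errors, semantic variants and
stop-word inventories that this generator deliberately does not model.

## Known limitations

- The rule tagger's noun default over-extracts in verb-heavy prose;
  swapping in a statistical tagger is recommended for real corpora.
- The default stop list is a small configuration artefact, not a curated
  resource; results on real text are sensitive to it.
- Phonetic matching without a length floor can overmerge very short stems.
- Single-pass expansion cannot unify variant chains that need two hops
  (e.g. a misspelling of a hyphenated variant may connect to only one of
  its siblings).
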
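# varterm

Automatic term recognition (ATR) for domain corpora — clinical notes,
abstracts, patient blogs — built to survive the term variation that breaks
exact-matching extractors: inflection (*lateral meniscus* / *lateral
menisci*), derivation (*meniscal* / *meniscus tear*), word-order and
preposition changes (*kidney stone* / *stone in kidney*), hyphenation
(*posterolateral* / *postero-lateral*) and plain misspellings (*mensicus*).

## Method

Recognition runs in two stages:

1. **Linguistic filtering.** Documents are sentence-split, tokenised and
   POS-tagged (Penn Treebank tags). Term candidates are noun phrases matched
   by tag-class patterns — by default
   `(JJ|NN)+ NN`, `(NN|JJ)* NN POS (NN|JJ)* NN` and
   `(NN|JJ)* NN IN (NN|JJ)* NN` — with leading/trailing stop words trimmed.

2. **Termhood scoring over normalised candidates.** Each candidate is
   reduced to a *bag of stems*: punctuation, numbers and stop words are
   removed, lowercase tokens of ≤ 2 characters dropped (the `D` of
   *vitamin D* survives), and the rest Porter-stemmed — so *hypoxia at rest*
   and *resting hypoxia* both become `{hypoxia, rest}`. Bags are then
   expanded with similar stems found in the corpus: stems within a small
   edit distance (insert / delete / substitute / adjacent transpose, with a
   length-banded threshold) or sharing a Metaphone phonetic code. This pulls
   `{asymptomat, hiv, infect}` and `{symptomat, hiv, infect}` onto the same
   expanded bag, and makes *postero-later* / *posterolater* interchangeable.

   Candidates are ranked by a C-value termhood computed over the expanded
   bags, with nestedness decided by **subset** rather than substring:

       C-value(t) = ln|t| · f(t)                                 if S(t) = ∅
       C-value(t) = ln|t| · ( f(t) − (1/|S(t)|) · Σ_{s∈S(t)} f(s) )  otherwise

   where |t| is the pre-expansion stem count, S(t) the set of candidates
   whose stem sets strictly contain t's, and f(t) the occurrence count of t
   plus the occurrences of every member of S(t).

The package also ships the evaluation machinery used for this kind of
extractor — dual-annotator gold standards by token intersection, Cohen's
kappa from 2×2 token contingency tables, token-level precision/recall/F over
the top-k ranked terms — and a seeded synthetic-corpus generator that plants
terms with controlled variation so every stage is testable offline.

## Worked example

Given a two-file corpus of knee-MRI-style sentences
(`report1.txt`: *"The medial collateral ligament was intact . A medial
collateral ligament sprain was noted . The collateral ligament was swollen ."*,
`report2.txt`: *"A sprain of collateral ligament was seen . The lateral
meniscus was torn . The lateral menisci were torn ."*):

```sh
$ varterm extract corpus --out-prefix ranked
5 terms -> ranked.tsv/.html/.txt/.annotations.tsv

$ cat ranked.tsv
rank	score	variants	frequency
1	2.3105	collateral ligament	5
2	1.3863	lateral menisci | lateral meniscus	2
3	1.3863	medial collateral ligament sprain	1
4	1.0986	medial collateral ligament	2
5	1.0986	sprain of collateral ligament	2
```

*collateral ligament* tops the list: it occurs twice on its own and is
nested (as a stem subset) in three longer candidates, so f = 5, penalised by
the mean frequency of its supersets — ln 2 · (5 − 5/3) ≈ 2.3105. The
inflectional variants *lateral meniscus* / *lateral menisci* are grouped
into one entry with their frequencies pooled (ln 2 · 2 ≈ 1.3863); ranks 4
and 5 show the word-order-insensitive treatment of *sprain of collateral
ligament*. The `.txt` file is the variant column flattened (a lexicon for
other tools), and `.annotations.tsv` holds stand-off spans
(doc, start, length, text) of every term occurrence.

Other subcommands: `varterm annotate` (dictionary matching with an existing
term list), `varterm evaluate` (kappa + top-k token P/R/F against two
annotators' stand-off files), `varterm simulate` (synthetic corpus), all
documented under `--help`.

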
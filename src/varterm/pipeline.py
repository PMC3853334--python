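"""End-to-end term recognition pipeline.

Chains the stages: tagging -> pattern matching -> boundary trimming ->
bag-of-stems normalisation -> aggregation -> fuzzy/phonetic expansion ->
re-aggregation -> C-value scoring and ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .candidates import PosPattern, extract_candidates, parse_patterns, trim_boundaries
from .normalise import NormalisedForm, StopList, aggregate_forms, normalise_candidate
from .preprocess import Corpus
from .similarity import SimilarityConfig, StemVocabulary, expand_form
from .termhood import ScoredTerm, TermIndex, build_index, rank_terms

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    terms: list[ScoredTerm]
    index: TermIndex

    def top(self, k: int) -> list[ScoredTerm]:
        return self.terms[:k]


def _merge_expanded(expanded: list[NormalisedForm]) -> dict[str, NormalisedForm]:
    """Aggregate by expanded stem set; variant groups that converge on one
    expanded bag merge, keeping the largest pre-expansion length."""
    merged = aggregate_forms(expanded)
    # aggregate_forms keys by stem set and maxes length; nothing more needed
    return merged


def extract_terms(corpus: Corpus,
                  stoplist: StopList | None = None,
                  patterns: Sequence[PosPattern] | None = None,
                  prepositions: Sequence[str] | None = None,
                  similarity: SimilarityConfig | None = None,
                  expand: bool = True,
                  log_base: float | None = None) -> PipelineResult:
    """Run the full term recognition pipeline over a tagged corpus."""
    stoplist = stoplist or StopList()
    patterns = list(patterns) if patterns is not None else parse_patterns()
    similarity = similarity or SimilarityConfig()

    occurrences = []
    for doc in corpus:
        for cand in extract_candidates(doc, patterns, prepositions):
            trimmed = trim_boundaries(cand, stoplist)
            if trimmed is not None:
                occurrences.append(trimmed)
    logger.info("extracted %d candidate occurrences", len(occurrences))

    forms = []
    for occ in occurrences:
        form = normalise_candidate(occ, stoplist)
        if form is not None:
            forms.append(form)
    aggregated = aggregate_forms(forms)
    logger.info("aggregated into %d normalised forms", len(aggregated))

    if expand:
        vocab = StemVocabulary.from_forms(list(aggregated.values()))
        cache: dict[str, set[str]] = {}
        expanded = [expand_form(f, vocab, similarity, _cache=cache)
                    for f in aggregated.values()]
        final = _merge_expanded(expanded)
    else:
        final = aggregated

    index = build_index(final)
    terms = rank_terms(index, log_base=log_base)
    return PipelineResult(terms=terms, index=index)
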
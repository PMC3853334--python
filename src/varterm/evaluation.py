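"""Token-level evaluation machinery.

Gold standards for term recognition are built by intersecting two
annotators' positive token sets; chance-corrected agreement between the
annotators is Cohen's kappa computed from a 2x2 token contingency table.
System output is scored token-wise — every token covered by an extracted
term is a prediction — giving precision, recall and F-measure that credit
partial phrase overlap instead of demanding exact boundaries.

Token identity is the character span ``(doc_id, start, end)``, so sets from
stand-off annotations and from the tagger's own tokenisation are directly
comparable. The token universe includes every token the tokeniser emits,
punctuation included.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

from .outputs import StandoffAnnotation, annotate_corpus
from .preprocess import Corpus
from .termhood import ScoredTerm

TokenKey = Hashable  # conventionally (doc_id, start, end)


class UndefinedKappaError(ValueError):
    """Raised when expected agreement is 1 (degenerate marginals)."""


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 annotator-agreement table over the token universe.

    ``n11`` counts tokens marked positive by both annotators, ``n12``
    positive by A only, ``n21`` by B only, ``n22`` by neither.
    """

    n11: float
    n12: float
    n21: float
    n22: float

    @classmethod
    def from_token_sets(cls, ann_a: set, ann_b: set,
                        universe: set) -> "ContingencyTable":
        if not (ann_a <= universe and ann_b <= universe):
            raise ValueError("annotator sets must be subsets of the universe")
        both = len(ann_a & ann_b)
        return cls(n11=both, n12=len(ann_a) - both, n21=len(ann_b) - both,
                   n22=len(universe - ann_a - ann_b))

    @property
    def N(self) -> float:
        return self.n11 + self.n12 + self.n21 + self.n22

    def proportions(self) -> tuple[float, float, float, float]:
        n = self.N
        if n <= 0:
            raise ValueError("empty contingency table")
        return self.n11 / n, self.n12 / n, self.n21 / n, self.n22 / n

    @property
    def observed_agreement(self) -> float:
        p11, _, _, p22 = self.proportions()
        return p11 + p22

    @property
    def expected_agreement(self) -> float:
        p11, p12, p21, p22 = self.proportions()
        return (p11 + p12) * (p11 + p21) + (p21 + p22) * (p12 + p22)

    @property
    def positive_fraction(self) -> float:
        """Fraction of tokens both annotators marked terminological."""
        return self.n11 / self.N


def kappa_from_agreement(a_o: float, a_e: float) -> float:
    """Cohen's kappa from observed and expected agreement."""
    if a_e >= 1.0:
        raise UndefinedKappaError("expected agreement is 1; kappa undefined")
    return (a_o - a_e) / (1.0 - a_e)


def cohens_kappa(table: ContingencyTable) -> float:
    return kappa_from_agreement(table.observed_agreement,
                                table.expected_agreement)


def gold_intersection(ann_a: set, ann_b: set) -> set:
    """Gold standard: tokens both annotators marked as term constituents."""
    return set(ann_a) & set(ann_b)


@dataclass(frozen=True)
class EvalResult:
    TP: int
    FP: int
    FN: int

    @property
    def P(self) -> float:
        return self.TP / (self.TP + self.FP) if self.TP + self.FP else 0.0

    @property
    def R(self) -> float:
        return self.TP / (self.TP + self.FN) if self.TP + self.FN else 0.0

    @property
    def F(self) -> float:
        p, r = self.P, self.R
        return 2 * p * r / (p + r) if p + r else 0.0


def token_prf(predicted: set, gold: set) -> EvalResult:
    """Token-level precision/recall/F of a predicted token set."""
    predicted, gold = set(predicted), set(gold)
    tp = len(predicted & gold)
    return EvalResult(TP=tp, FP=len(predicted) - tp, FN=len(gold) - tp)


# --------------------------------------------------------------------------
# corpus-level helpers

def corpus_token_keys(corpus: Corpus) -> set[tuple[str, int, int]]:
    return {(doc.doc_id, t.start, t.end)
            for doc in corpus for t in doc.tokens()}


def tokens_covered(corpus: Corpus,
                   annotations: Iterable[StandoffAnnotation],
                   ) -> set[tuple[str, int, int]]:
    """Token keys lying inside any annotation span of their document."""
    spans: dict[str, list[tuple[int, int]]] = {}
    for ann in annotations:
        spans.setdefault(ann.doc_id, []).append((ann.start, ann.end))
    covered = set()
    for doc in corpus:
        doc_spans = sorted(spans.get(doc.doc_id, ()))
        if not doc_spans:
            continue
        for t in doc.tokens():
            for start, end in doc_spans:
                if start <= t.start and t.end <= end:
                    covered.add((doc.doc_id, t.start, t.end))
                    break
    return covered


@dataclass(frozen=True)
class TopKResult:
    k: int
    result: EvalResult
    truncated: bool = False  # fewer than k forms were available


def evaluate_topk(terms: Sequence[ScoredTerm], corpus: Corpus,
                  gold: set, ks: Sequence[int]) -> list[TopKResult]:
    """Token P/R/F of the top-k variant groups for each k in ``ks``.

    Each of the k best normalised forms contributes all of its surface
    variants to the matching dictionary. Recall is non-decreasing in k.
    """
    out = []
    for k in ks:
        if k <= 0:
            out.append(TopKResult(k=k, result=EvalResult(0, 0, len(gold))))
            continue
        top = terms[:k]
        variants = [v for term in top for v, _ in term.variants]
        predicted = tokens_covered(corpus, annotate_corpus(variants, corpus))
        out.append(TopKResult(k=k, result=token_prf(predicted, gold),
                              truncated=k > len(terms)))
    return out


def topk_report(results: Sequence[TopKResult]) -> str:
    lines = ["k\tTP\tFP\tFN\tP\tR\tF\ttruncated"]
    for r in results:
        e = r.result
        lines.append(f"{r.k}\t{e.TP}\t{e.FP}\t{e.FN}\t{e.P:.4f}\t{e.R:.4f}"
                     f"\t{e.F:.4f}\t{int(r.truncated)}")
    return "\n".join(lines) + "\n"
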
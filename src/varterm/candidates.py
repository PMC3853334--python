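"""Term-candidate extraction: POS-pattern matching and boundary trimming.

Candidates are noun phrases matched by tag-sequence patterns written over
four tag classes — JJ (adjectives: JJ/JJR/JJS), NN (nouns: NN/NNS/NNP/NNPS),
POS (possessive clitic) and IN (prepositions) — with regex quantifiers, e.g.
``(JJ|NN)+ NN``. Matching is per sentence and *maximal*: every match that
cannot be extended on either side is returned, and no returned span for a
pattern is properly contained in another. Leading and trailing stop words
are then trimmed off; what survives must still be at least two tokens ending
in a noun.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

from .preprocess import Document, Token

if TYPE_CHECKING:  # pragma: no cover
    from .normalise import StopList

NN_CLASS = frozenset({"NN", "NNS", "NNP", "NNPS"})
JJ_CLASS = frozenset({"JJ", "JJR", "JJS"})

#: Default patterns: plain noun phrases, possessives, prepositional phrases.
DEFAULT_PATTERNS = (
    "(JJ|NN)+ NN",
    "(NN|JJ)* NN POS (NN|JJ)* NN",
    "(NN|JJ)* NN IN (NN|JJ)* NN",
)

_CLASS_SYMBOLS = {"JJ": "J", "NN": "N", "POS": "P", "IN": "I"}


@dataclass(frozen=True)
class PosPattern:
    """A compiled tag-class sequence pattern."""

    pattern_id: int
    expression: str
    regex: re.Pattern

    @classmethod
    def parse(cls, expression: str, pattern_id: int) -> "PosPattern":
        """Compile a pattern like ``(NN|JJ)* NN IN (NN|JJ)* NN``.

        The expression must require at least two tokens and end in the NN
        class.
        """
        compact = re.sub(r"\s+", "", expression)
        symbolic = compact
        for name, sym in sorted(_CLASS_SYMBOLS.items(), key=lambda kv: -len(kv[0])):
            symbolic = symbolic.replace(name, sym)
        if not re.fullmatch(r"[NJPI()|*+?]+", symbolic):
            raise ValueError(f"unsupported pattern syntax: {expression!r}")
        try:
            regex = re.compile(symbolic)
        except re.error as exc:
            raise ValueError(f"bad pattern {expression!r}: {exc}") from exc
        if not symbolic.rstrip(")*+?").endswith("N"):
            raise ValueError(f"pattern must end in the NN class: {expression!r}")
        if regex.fullmatch("N") or regex.fullmatch(""):
            raise ValueError(f"pattern must require >= 2 tokens: {expression!r}")
        return cls(pattern_id=pattern_id, expression=expression, regex=regex)


def parse_patterns(expressions: Sequence[str] = DEFAULT_PATTERNS) -> list[PosPattern]:
    return [PosPattern.parse(expr, i + 1) for i, expr in enumerate(expressions)]


def load_patterns(path: str | Path) -> list[PosPattern]:
    """One pattern per line; blank lines and ``#`` comments ignored."""
    lines = [ln.strip() for ln in Path(path).read_text(encoding="utf-8").splitlines()]
    exprs = [ln for ln in lines if ln and not ln.startswith("#")]
    if not exprs:
        raise ValueError(f"no patterns in {path}")
    return parse_patterns(exprs)


@dataclass(frozen=True)
class CandidateOccurrence:
    """A pattern-matched (and possibly trimmed) noun-phrase span."""

    doc_id: str
    sent_index: int
    tokens: tuple[Token, ...]
    pattern_id: int

    @property
    def surface(self) -> str:
        return " ".join(t.surface for t in self.tokens)

    @property
    def span(self) -> tuple[int, int]:
        """Character span (start of first token, end of last)."""
        return self.tokens[0].start, self.tokens[-1].end


def _tag_symbol(token: Token, prepositions: frozenset[str] | None) -> str:
    if token.pos in NN_CLASS:
        return "N"
    if token.pos in JJ_CLASS:
        return "J"
    if token.pos == "POS":
        return "P"
    if token.pos == "IN":
        if prepositions is None or token.surface.lower() in prepositions:
            return "I"
    return "O"  # outside every class; can never be part of a match


def _maximal_spans(symbols: str, regex: re.Pattern) -> list[tuple[int, int]]:
    """All maximal (non-extendable, not properly nested) matching spans."""
    n = len(symbols)
    spans: list[tuple[int, int]] = []
    for start in range(n):
        for end in range(n, start + 1, -1):  # longest first, >= 2 symbols
            if regex.fullmatch(symbols, start, end):
                spans.append((start, end))
                break
    return [(s, e) for s, e in spans
            if not any((s2 <= s and e <= e2 and (s2, e2) != (s, e))
                       for s2, e2 in spans)]


def extract_candidates(doc: Document, patterns: Sequence[PosPattern] | None = None,
                       prepositions: Sequence[str] | None = None,
                       ) -> list[CandidateOccurrence]:
    """Match every pattern against every sentence of a tagged document.

    ``prepositions`` optionally restricts which IN-tagged surfaces count as
    the IN class (default: any token tagged IN). Identical spans produced by
    several patterns are deduplicated keeping the lowest pattern id.
    """
    patterns = list(patterns) if patterns is not None else parse_patterns()
    prep = frozenset(p.lower() for p in prepositions) if prepositions else None
    seen: dict[tuple[int, int, int], CandidateOccurrence] = {}
    for sent in doc.sentences:
        symbols = "".join(_tag_symbol(t, prep) for t in sent)
        for pattern in patterns:
            for s, e in _maximal_spans(symbols, pattern.regex):
                key = (sent[0].sent_index, s, e)
                if key not in seen or pattern.pattern_id < seen[key].pattern_id:
                    seen[key] = CandidateOccurrence(
                        doc_id=doc.doc_id, sent_index=sent[0].sent_index,
                        tokens=tuple(sent[s:e]), pattern_id=pattern.pattern_id)
    return sorted(seen.values(),
                  key=lambda c: (c.sent_index, c.tokens[0].tok_index,
                                 -len(c.tokens)))


def trim_boundaries(cand: CandidateOccurrence,
                    stoplist: "StopList") -> CandidateOccurrence | None:
    """Iteratively strip stop-list tokens off both ends.

    Returns ``None`` when fewer than two tokens remain or the final token is
    no longer noun-class.
    """
    tokens = list(cand.tokens)
    while tokens and tokens[0].surface.lower() in stoplist:
        tokens.pop(0)
    while tokens and tokens[-1].surface.lower() in stoplist:
        tokens.pop()
    if len(tokens) < 2 or tokens[-1].pos not in NN_CLASS:
        return None
    if len(tokens) == len(cand.tokens):
        return cand
    return CandidateOccurrence(doc_id=cand.doc_id, sent_index=cand.sent_index,
                               tokens=tuple(tokens), pattern_id=cand.pattern_id)
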
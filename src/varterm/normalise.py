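"""Bag-of-stems normalisation of term candidates.

A candidate occurrence is reduced to an unordered set of stems in three
steps: (a) drop punctuation tokens, numeric tokens and stop words
(prepositions included); (b) drop lowercase tokens of at most two characters
— short *uppercase* tokens such as the ``D`` of ``vitamin D`` carry real
content and survive; (c) lowercase and stem what remains. Word order is
deliberately destroyed: ``hypoxia at rest`` and ``resting hypoxia`` both
normalise to ``{hypoxia, rest}``, which is what lets syntactic variants pool
their frequencies. Forms left with fewer than two stems are discarded — a
single-stem candidate scores log(1) = 0 and could never rank anyway.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

from .candidates import CandidateOccurrence
from .stem import stem_token

Stemmer = Callable[[str], str]

#: Small default stop list: common English closed-class words plus a few
#: frequent clinical modifiers. Treated as configuration, not ground truth.
DEFAULT_STOPWORDS = frozenset("""
a an the this that these those any some no all both each
of in on at by for with from to as into during between under over
and or but nor
is are was were be been being has have had do does did
not only very quite more most other such same own
it its he his she her they their there here
small mild moderate severe slight significant marked normal large
""".split())


class StopList:
    """Case-insensitive stop-word lookup."""

    def __init__(self, entries: Iterable[str] = DEFAULT_STOPWORDS):
        self.entries = frozenset(e.strip().lower() for e in entries
                                 if e.strip() and not e.strip().startswith("#"))
        if not self.entries:
            raise ValueError("stop list is empty")

    def __contains__(self, word: str) -> bool:
        return word.lower() in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_file(cls, path: str | Path) -> "StopList":
        """One lowercase entry per line; ``#`` starts a comment line."""
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        return cls(lines)


@dataclass
class NormalisedForm:
    """A candidate reduced to a bag of stems.

    ``length`` is the number of stems *before* any similarity expansion: it
    is the term-length factor of the score and must not be inflated by
    alternative spellings added later. ``source_variants`` maps each
    (lowercased) surface realisation to its occurrence count.
    """

    stems: frozenset[str]
    source_variants: dict[str, int] = field(default_factory=dict)
    length: int = 0

    def __post_init__(self) -> None:
        if self.length == 0:
            self.length = len(self.stems)

    @property
    def key(self) -> str:
        """Canonical key: the sorted, space-joined stem set."""
        return " ".join(sorted(self.stems))

    @property
    def count(self) -> int:
        return sum(self.source_variants.values())

    def variants_by_count(self) -> list[tuple[str, int]]:
        return sorted(self.source_variants.items(),
                      key=lambda kv: (-kv[1], kv[0]))


def _is_numeric(token: str) -> bool:
    """Digit-bearing with no letters (mixed alphanumerics like B12 are kept)."""
    return any(c.isdigit() for c in token) and not any(c.isalpha() for c in token)


def _is_punctuation(token: str) -> bool:
    return not any(c.isalnum() for c in token)


def normalise_candidate(cand: CandidateOccurrence, stoplist: StopList,
                        stemmer: Stemmer = stem_token) -> NormalisedForm | None:
    """Apply normalisation steps (a)-(c) to a trimmed candidate occurrence.

    Returns ``None`` when fewer than two stems survive.
    """
    surfaces = [t.surface for t in cand.tokens]
    kept = [s for s in surfaces
            if not (_is_punctuation(s) or _is_numeric(s) or s in stoplist)]
    # lowercase tokens of <= 2 characters go; uppercase-bearing ones stay
    kept = [s for s in kept if len(s) > 2 or not s.islower()]
    stems = frozenset(stemmer(s.lower()) for s in kept)
    if len(stems) < 2:
        return None
    variant = " ".join(surfaces).lower()
    return NormalisedForm(stems=stems, source_variants={variant: 1},
                          length=len(stems))


def aggregate_forms(forms: Iterable[NormalisedForm]) -> dict[str, NormalisedForm]:
    """Merge occurrences with identical stem sets, summing variant counts.

    Keyed by the canonical sorted-stem key; the merged ``length`` is the
    largest member length (members of one key share a stem set, so lengths
    agree before expansion).
    """
    merged: dict[str, NormalisedForm] = {}
    for form in forms:
        key = form.key
        if key not in merged:
            merged[key] = NormalisedForm(stems=form.stems,
                                         source_variants=dict(form.source_variants),
                                         length=form.length)
        else:
            tgt = merged[key]
            counts = Counter(tgt.source_variants)
            counts.update(form.source_variants)
            tgt.source_variants = dict(counts)
            tgt.length = max(tgt.length, form.length)
    return merged
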
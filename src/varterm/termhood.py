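"""C-value termhood over expanded normalised forms.

A candidate term t is scored

    C-value(t) = log|t| * f(t)                                  if S(t) = {}
    C-value(t) = log|t| * ( f(t) - (1/|S(t)|) * sum_{s in S(t)} f(s) )

where |t| is the pre-expansion stem count, S(t) is the set of candidates
whose (expanded) stem sets strictly contain t's, and f(t) counts direct
occurrences of t plus direct occurrences of every member of S(t) — a term
occurs wherever a longer candidate containing it occurs. Under that
convention f(t) >= f(s) for every s in S(t), so scores are never negative.
Nestedness by *subset* rather than substring is what neutralises word-order
variation; expanded stem sets extend it across spelling variants.

The log base defaults to the natural logarithm; rankings are invariant to
the base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .normalise import NormalisedForm

__all__ = ["TermIndex", "ScoredTerm", "build_index", "c_value", "rank_terms"]


@dataclass
class TermIndex:
    """Candidate set with nestedness map and aggregated frequencies."""

    forms: dict[str, NormalisedForm] = field(default_factory=dict)
    direct_count: dict[str, int] = field(default_factory=dict)
    nested_map: dict[str, frozenset[str]] = field(default_factory=dict)
    freq: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class ScoredTerm:
    form: NormalisedForm
    length: int
    frequency: int
    nested_count: int
    score: float

    @property
    def variants(self) -> list[tuple[str, int]]:
        return self.form.variants_by_count()


def build_index(forms: dict[str, NormalisedForm]) -> TermIndex:
    """Compute S(t) by pairwise strict-subset test and aggregate f(t)."""
    index = TermIndex(forms=dict(forms))
    index.direct_count = {k: f.count for k, f in forms.items()}
    keys = list(forms)
    for t in keys:
        ts = forms[t].stems
        supersets = frozenset(
            s for s in keys
            if s != t and ts < forms[s].stems)
        index.nested_map[t] = supersets
        index.freq[t] = index.direct_count[t] + sum(
            index.direct_count[s] for s in supersets)
    return index


def c_value(key: str, index: TermIndex, log_base: float | None = None) -> float:
    """Score one indexed candidate; raises ``KeyError`` if absent."""
    if key not in index.forms:
        raise KeyError(f"candidate not in index: {key!r}")
    form = index.forms[key]
    log_len = math.log(form.length)
    if log_base is not None:
        log_len /= math.log(log_base)
    nested = index.nested_map[key]
    f_t = index.freq[key]
    if not nested:
        return log_len * f_t
    penalty = sum(index.freq[s] for s in nested) / len(nested)
    return log_len * (f_t - penalty)


def rank_terms(index: TermIndex, log_base: float | None = None) -> list[ScoredTerm]:
    """Rank all candidates: descending score, then descending frequency,
    then lexicographic sorted-stem key (fully deterministic)."""
    scored = [
        ScoredTerm(form=index.forms[k],
                   length=index.forms[k].length,
                   frequency=index.freq[k],
                   nested_count=len(index.nested_map[k]),
                   score=c_value(k, index, log_base))
        for k in index.forms
    ]
    return sorted(scored, key=lambda t: (-t.score, -t.frequency, t.form.key))
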
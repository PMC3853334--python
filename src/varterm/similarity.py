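"""Token-level approximate matching and normalised-form expansion.

Two stems count as similar when they are within a small edit distance of one
another (optimal string alignment over insertion, deletion, substitution,
adjacent transposition and case change, unit cost each) or when they share a
Metaphone code and are almost within that distance. Each normalised term
candidate is then expanded with every similar stem found in the corpus-wide
stem vocabulary, so orthographic variants such as ``haemorrhag`` /
``hemorrhag`` or ``postero-later`` / ``posterolater`` end up in the same bag
of stems and unify under the subset-based nestedness test.

Edit-distance thresholds are length-banded: very short stems are excluded
from fuzzy matching entirely (an edit on a 3-character stem nearly always
changes the word), mid-length stems allow one edit, long stems allow
``max_ed``. All thresholds are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .normalise import NormalisedForm
from .phonetic import phonetic_code

__all__ = [
    "SimilarityConfig", "StemVocabulary", "edit_distance", "phonetic_code",
    "similar_stems", "expand_form",
]


@dataclass(frozen=True)
class SimilarityConfig:
    """Tunable knobs for fuzzy stem matching.

    max_ed
        Edit-distance ceiling for long stems (length >= ``long_len``).
    min_fuzzy_len
        Stems shorter than this never fuzzy-match lexically.
    long_len
        Length from which ``max_ed`` applies; stems of length
        ``min_fuzzy_len`` .. ``long_len``-1 allow a single edit.
    phonetic_enabled
        Whether Metaphone-code equality may relax the threshold by one.
    case_sensitive
        Compare characters case-sensitively (a case change then costs one
        edit). Stems are lowercased upstream, so this matters only for
        direct use on raw tokens.
    """

    max_ed: int = 2
    min_fuzzy_len: int = 4
    long_len: int = 6
    phonetic_enabled: bool = True
    case_sensitive: bool = False

    def __post_init__(self) -> None:
        if self.max_ed < 0:
            raise ValueError("max_ed must be >= 0")
        if self.min_fuzzy_len < 1:
            raise ValueError("min_fuzzy_len must be >= 1")

    def threshold(self, a: str, b: str) -> int:
        """Effective edit-distance bound for a stem pair (0 = no fuzzy)."""
        short = min(len(a), len(b))
        if short < self.min_fuzzy_len:
            return 0
        if short < self.long_len:
            return min(1, self.max_ed)
        return self.max_ed


def edit_distance(a: str, b: str, config: SimilarityConfig | None = None) -> int:
    """Optimal-string-alignment distance between ``a`` and ``b``.

    Unit-cost single-character insertion, deletion, substitution and
    adjacent transposition; substituting a letter for its other-case self
    costs one (the case-change operation) unless the comparison is
    case-insensitive, in which case case never costs anything. Symmetric;
    0 iff the strings are equal under the configured case sensitivity.
    """
    config = config or SimilarityConfig()
    if not config.case_sensitive:
        a, b = a.lower(), b.lower()
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        return la or lb
    prev2: list[int] = []
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            best = min(prev[j] + 1,        # deletion
                       cur[j - 1] + 1,     # insertion
                       prev[j - 1] + cost)  # substitution / case change
            if (i > 1 and j > 1 and a[i - 1] == b[j - 2]
                    and a[i - 2] == b[j - 1]):
                best = min(best, prev2[j - 2] + 1)  # transposition
            cur[j] = best
        prev2, prev = prev, cur
    return prev[lb]


def similar_stems(a: str, b: str, config: SimilarityConfig | None = None) -> bool:
    """Decide whether two distinct stems should be treated as variants.

    True iff the pair is within its length-banded edit-distance threshold,
    or (with phonetic matching enabled) the Metaphone codes agree and the
    pair is within threshold + 1.
    """
    if a == b:
        return False
    config = config or SimilarityConfig()
    limit = config.threshold(a, b)
    if limit > 0 and edit_distance(a, b, config) <= limit:
        return True
    if config.phonetic_enabled:
        ca = phonetic_code(a)
        if ca and ca == phonetic_code(b):
            return edit_distance(a, b, config) <= config.max_ed + 1
    return False


@dataclass
class StemVocabulary:
    """All distinct stems over the candidate set, with a phonetic index."""

    stems: set[str] = field(default_factory=set)
    phonetic_index: dict[str, set[str]] = field(default_factory=dict)

    @classmethod
    def from_forms(cls, forms: list[NormalisedForm]) -> "StemVocabulary":
        vocab = cls()
        for form in forms:
            for stem in form.stems:
                vocab.add(stem)
        return vocab

    def add(self, stem: str) -> None:
        if stem in self.stems:
            return
        self.stems.add(stem)
        code = phonetic_code(stem)
        if code:
            self.phonetic_index.setdefault(code, set()).add(stem)

    def similar_to(self, stem: str, config: SimilarityConfig) -> set[str]:
        return {v for v in self.stems if similar_stems(stem, v, config)}


def expand_form(form: NormalisedForm, vocab: StemVocabulary,
                config: SimilarityConfig | None = None,
                _cache: dict[str, set[str]] | None = None) -> NormalisedForm:
    """Expand a normalised form with all similar vocabulary stems.

    Single symmetric pass — no transitive closure — so alternative spellings
    join the bag without chaining unrelated stems. Variant counts and the
    pre-expansion length are untouched.
    """
    config = config or SimilarityConfig()
    stems = set(form.stems)
    for stem in form.stems:
        if _cache is not None:
            if stem not in _cache:
                _cache[stem] = vocab.similar_to(stem, config)
            stems |= _cache[stem]
        else:
            stems |= vocab.similar_to(stem, config)
    return NormalisedForm(stems=frozenset(stems),
                          source_variants=dict(form.source_variants),
                          length=form.length)
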
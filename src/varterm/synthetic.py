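"""Seeded synthetic corpora with planted multiword terms.

The generator plants a handful of noun-phrase terms at controlled
frequencies inside carrier sentences, mutates individual occurrences to
emulate the main sources of term variation — inflection, derivation,
preposition swaps (``kidney stone`` ~ ``stone of kidney``), hyphenation and
single-character misspellings — and surrounds them with filler sentences
drawn from a closed pseudo-word vocabulary. Filler nouns occur one per
clause, so filler text can never yield a multiword noun-phrase candidate,
and filler suffixes (-ed verbs, -ly adverbs, bare nouns) are chosen so the
offline rule tagger needs no model. Two simulated annotators mark the
planted tokens, each with an independent per-token flip probability, which
exercises the kappa/gold-standard machinery. One global RNG seeded from
``spec.seed`` drives every stochastic choice in a fixed, documented order:
mutations first (occurrence by occurrence, type by type), then sentence-slot
assignment, then sentence realisation, then annotator A flips, then B flips.

Mutations verify their own contract: a mutated token is only accepted if its
stem still unifies with the original's under the default similarity
configuration; otherwise the occurrence is emitted unmutated and flagged.
Semantic variation (synonym substitution) is deliberately not generated —
the recognition method does not claim to neutralise it.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .candidates import NN_CLASS
from .preprocess import Corpus, RuleTagger, tag_document
from .similarity import SimilarityConfig, edit_distance, similar_stems
from .stem import stem_token

__all__ = ["SyntheticSpec", "GenerationError", "PlantedOccurrence",
           "Registry", "generate_corpus", "mutate_occurrence",
           "write_synthetic"]

MUTATION_TYPES = ("inflection", "derivation", "prep_swap", "hyphenation",
                  "misspelling")

#: Default planted terms (content tokens >= 6 characters so that a single
#: surface edit keeps the stems within the fuzzy-matching thresholds).
DEFAULT_TERMS = (
    (("lateral", "meniscus"), 6),
    (("collateral", "ligament"), 6),
    (("chronic", "bronchitis"), 6),
    (("kidney", "stone"), 6),
    (("posterior", "cruciate", "ligament"), 6),
)

_FILLER_NOUNS = (
    "blorfen", "crandel", "dripnet", "flumert", "gorbelt", "hastrin",
    "jintrop", "krellit", "lombrit", "morfent", "nestrip", "plovern",
    "quibrent", "rastpol", "sorbent", "tramnel", "ulprest", "vintrel",
    "wolbrint", "yestrom", "zorbelt", "brintel", "clovert", "drastin",
    "fropnel", "glimert", "hulprin", "jastrev", "kronvel", "lumpert",
    "mastrel", "norvint", "opstrel", "prelvin", "questor", "rovnelt",
    "stremin", "trovelt", "urbinel", "vastrom",
)
_FILLER_VERBS = ("glorped", "snarked", "brimmed", "clorfed", "drilped",
                 "frosked", "grolted", "plinked", "trosped", "whirled")
_FILLER_ADVERBS = ("softly", "oddly", "briskly", "dimly", "neatly")

_CARRIER_TEMPLATES = ("The {term} was {verb} .",
                      "There was a {term} .",
                      "A {term} was {verb} .")
_FILLER_TEMPLATES = ("The {noun} {verb} {adv} .",
                     "The {noun} {verb} .",
                     "It {verb} the {noun} {adv} .")


class GenerationError(ValueError):
    """Raised for impossible synthetic specifications."""


@dataclass(frozen=True)
class SyntheticSpec:
    n_docs: int = 10
    sentences_per_doc: int = 10
    planted_terms: tuple[tuple[tuple[str, ...], int], ...] = DEFAULT_TERMS
    inflection_rate: float = 0.1
    derivation_rate: float = 0.1
    prep_swap_rate: float = 0.1
    hyphenation_rate: float = 0.1
    misspelling_rate: float = 0.1
    filler_vocab_size: int = 30
    disagreement_rate: float = 0.1
    seed: int = 0

    def rates(self) -> dict[str, float]:
        return {"inflection": self.inflection_rate,
                "derivation": self.derivation_rate,
                "prep_swap": self.prep_swap_rate,
                "hyphenation": self.hyphenation_rate,
                "misspelling": self.misspelling_rate}

    def validate(self) -> None:
        for name, rate in self.rates().items():
            if not 0.0 <= rate <= 1.0:
                raise GenerationError(f"{name} rate out of [0,1]: {rate}")
        if not 0.0 <= self.disagreement_rate <= 1.0:
            raise GenerationError("disagreement rate out of [0,1]")
        if not self.planted_terms:
            raise GenerationError("no planted terms")
        for tokens, freq in self.planted_terms:
            if freq < 1:
                raise GenerationError(f"frequency < 1 for {tokens}")
            if len(tokens) < 2:
                raise GenerationError(f"planted term too short: {tokens}")
        if not 1 <= self.filler_vocab_size <= len(_FILLER_NOUNS):
            raise GenerationError("filler_vocab_size out of range")
        planted_stems = {stem_token(t.lower())
                        for tokens, _ in self.planted_terms for t in tokens}
        filler_stems = {stem_token(n)
                        for n in _FILLER_NOUNS[: self.filler_vocab_size]}
        clash = planted_stems & filler_stems
        if clash:
            raise GenerationError(f"filler vocabulary collides with planted "
                                  f"stems: {sorted(clash)}")
        total = self.n_docs * self.sentences_per_doc
        need = sum(freq for _, freq in self.planted_terms)
        if need > total:
            raise GenerationError(
                f"{need} occurrences do not fit in {total} sentences")


@dataclass(frozen=True)
class PlantedOccurrence:
    term_id: int
    doc_id: str
    start: int
    length: int
    variant_type: str
    surface: str

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class Registry:
    entries: list[PlantedOccurrence] = field(default_factory=list)
    token_keys: set[tuple[str, int, int]] = field(default_factory=set)
    terms: tuple[tuple[tuple[str, ...], int], ...] = ()


# --------------------------------------------------------------------------
# mutations

_DERIVATION_SUFFIXES = (("us", "i"), ("i", "us"), ("al", "a"), ("a", "al"))

_tagger = RuleTagger()
_SIM = SimilarityConfig()


def _stem_compatible(original: str, mutated: str) -> bool:
    a, b = stem_token(original.lower()), stem_token(mutated.lower())
    return a == b or similar_stems(a, b, _SIM)


def mutate_occurrence(tokens: tuple[str, ...], mtype: str,
                      rng: random.Random) -> tuple[tuple[str, ...], bool]:
    """Apply one variation type to a term occurrence.

    Returns ``(tokens, applied)``; inapplicable mutations return the input
    unchanged with ``applied=False``.
    """
    if mtype not in MUTATION_TYPES:
        raise ValueError(f"unknown mutation type: {mtype!r}")
    if mtype == "inflection":
        last = tokens[-1]
        if last.endswith(("us", "is", "ss")):
            return tokens, False
        new = last[:-1] if last.endswith("s") else last + "s"
        if not _stem_compatible(last, new):
            return tokens, False
        return tokens[:-1] + (new,), True

    if mtype == "derivation":
        for i in range(len(tokens) - 1, -1, -1):
            for old, newsuf in _DERIVATION_SUFFIXES:
                if tokens[i].endswith(old):
                    new = tokens[i][: -len(old)] + newsuf
                    if _stem_compatible(tokens[i], new):
                        return tokens[:i] + (new,) + tokens[i + 1:], True
        return tokens, False

    if mtype == "prep_swap":
        if "of" in tokens:
            rest = tuple(t for t in tokens if t != "of")
            return rest[1:] + rest[:1], True  # B of A -> A B
        swapped = tokens[-1:] + ("of",) + tokens[:-1]
        if _tagger.tag_word(swapped[-1]) not in NN_CLASS:
            return tokens, False
        return swapped, True

    if mtype == "hyphenation":
        for i, tok in enumerate(tokens):
            if "-" in tok:
                new = tok.replace("-", "")
                if _stem_compatible(tok, new):
                    return tokens[:i] + (new,) + tokens[i + 1:], True
        for i, tok in enumerate(tokens):
            if len(tok) >= 8 and tok.isalpha():
                mid = len(tok) // 2
                # try split points nearest the middle until the stems unify
                offsets = sorted(range(3, len(tok) - 2),
                                 key=lambda p: abs(p - mid))
                for pos in offsets:
                    new = tok[:pos] + "-" + tok[pos:]
                    if _stem_compatible(tok, new):
                        return tokens[:i] + (new,) + tokens[i + 1:], True
        return tokens, False

    # misspelling: one random edit on a content token, re-drawn until the
    # surface edit distance is exactly 1 and the stems still unify
    eligible = [i for i, t in enumerate(tokens) if len(t) >= 6 and t.isalpha()]
    if not eligible:
        return tokens, False
    i = eligible[rng.randrange(len(eligible))]
    tok = tokens[i]
    for _ in range(20):
        op = rng.choice(("insert", "delete", "substitute", "transpose"))
        pos = rng.randrange(len(tok))
        letter = rng.choice("abcdefghijklmnopqrstuvwxyz")
        if op == "insert":
            new = tok[:pos] + letter + tok[pos:]
        elif op == "delete":
            new = tok[:pos] + tok[pos + 1:]
        elif op == "substitute":
            new = tok[:pos] + letter + tok[pos + 1:]
        else:
            if pos == len(tok) - 1:
                pos -= 1
            new = tok[:pos] + tok[pos + 1] + tok[pos] + tok[pos + 2:]
        if new != tok and edit_distance(tok, new) == 1 \
                and _stem_compatible(tok, new):
            return tokens[:i] + (new,) + tokens[i + 1:], True
    return tokens, False


# --------------------------------------------------------------------------
# corpus generation

def generate_corpus(spec: SyntheticSpec,
                    ) -> tuple[Corpus, set, set, Registry]:
    """Generate a tagged corpus, two annotator token sets and the registry."""
    spec.validate()
    rng = random.Random(spec.seed)
    nouns = _FILLER_NOUNS[: spec.filler_vocab_size]
    rates = spec.rates()

    # 1. plan occurrences and their mutations
    planned: list[tuple[int, tuple[str, ...], str]] = []
    for term_id, (tokens, freq) in enumerate(spec.planted_terms):
        for _ in range(freq):
            variant, vtype = tokens, "none"
            for mtype in MUTATION_TYPES:
                if rng.random() < rates[mtype]:
                    variant, applied = mutate_occurrence(tokens, mtype, rng)
                    if applied:
                        vtype = mtype
                    break
            planned.append((term_id, variant, vtype))

    # 2. assign occurrences to sentence slots
    total = spec.n_docs * spec.sentences_per_doc
    slots = rng.sample(range(total), len(planned))
    slot_map = dict(zip(slots, planned))

    # 3. realise sentences document by document
    registry = Registry(terms=spec.planted_terms)
    raw_docs: list[tuple[str, str]] = []
    pending_spans: list[tuple[str, int, int, int, str, str]] = []
    for d in range(spec.n_docs):
        doc_id = f"doc_{d:03d}.txt"
        parts: list[str] = []
        offset = 0
        for s in range(spec.sentences_per_doc):
            slot = d * spec.sentences_per_doc + s
            if slot in slot_map:
                term_id, variant, vtype = slot_map[slot]
                template = _CARRIER_TEMPLATES[
                    rng.randrange(len(_CARRIER_TEMPLATES))]
                verb = _FILLER_VERBS[rng.randrange(len(_FILLER_VERBS))]
                term_text = " ".join(variant)
                sentence = template.format(term="\x00", verb=verb)
                prefix = sentence.split("\x00")[0]
                sentence = sentence.replace("\x00", term_text)
                start = offset + len(prefix)
                pending_spans.append((doc_id, term_id, start,
                                      len(term_text), vtype, term_text))
            else:
                template = _FILLER_TEMPLATES[
                    rng.randrange(len(_FILLER_TEMPLATES))]
                sentence = template.format(
                    noun=nouns[rng.randrange(len(nouns))],
                    verb=_FILLER_VERBS[rng.randrange(len(_FILLER_VERBS))],
                    adv=_FILLER_ADVERBS[rng.randrange(len(_FILLER_ADVERBS))])
            parts.append(sentence)
            offset += len(sentence) + 1  # sentences joined by single space
        raw_docs.append((doc_id, " ".join(parts)))

    tagger = RuleTagger()
    corpus = Corpus(documents=[tag_document(raw, tagger, doc_id=doc_id)
                               for doc_id, raw in raw_docs])

    for doc_id, term_id, start, length, vtype, surface in pending_spans:
        doc = next(d for d in corpus if d.doc_id == doc_id)
        if doc.raw[start:start + length] != surface:
            raise GenerationError("registry span does not match text")
        registry.entries.append(PlantedOccurrence(
            term_id=term_id, doc_id=doc_id, start=start, length=length,
            variant_type=vtype, surface=surface))
        for t in doc.tokens():
            if start <= t.start and t.end <= start + length:
                registry.token_keys.add((doc_id, t.start, t.end))

    # 4./5. simulated annotators: membership of every token flipped
    # independently at the disagreement rate (A first, then B)
    universe = sorted((doc.doc_id, t.start, t.end)
                      for doc in corpus for t in doc.tokens())
    ann_a, ann_b = set(), set()
    for target in (ann_a, ann_b):
        for key in universe:
            member = key in registry.token_keys
            if rng.random() < spec.disagreement_rate:
                member = not member
            if member:
                target.add(key)
    return corpus, ann_a, ann_b, registry


def write_synthetic(spec: SyntheticSpec, out_dir: str | Path) -> Path:
    """Materialise a synthetic corpus as a standard corpus directory plus
    two annotator stand-off TSVs and a registry TSV."""
    from .outputs import StandoffAnnotation, write_standoff

    out_dir = Path(out_dir)
    corpus_dir = out_dir / "corpus"
    corpus_dir.mkdir(parents=True, exist_ok=True)
    corpus, ann_a, ann_b, registry = generate_corpus(spec)
    raw_by_id = {doc.doc_id: doc.raw for doc in corpus}
    for doc_id, raw in raw_by_id.items():
        (corpus_dir / doc_id).write_text(raw, encoding="utf-8")
    for name, tokens in (("annotator_a.tsv", ann_a), ("annotator_b.tsv", ann_b)):
        annotations = [StandoffAnnotation(doc_id, start, end - start,
                                          raw_by_id[doc_id][start:end])
                       for doc_id, start, end in sorted(tokens)]
        write_standoff(annotations, out_dir / name)
    lines = ["term_id\tdoc_id\tstart\tlength\tvariant_type\tsurface"]
    for e in registry.entries:
        lines.append(f"{e.term_id}\t{e.doc_id}\t{e.start}\t{e.length}\t"
                     f"{e.variant_type}\t{e.surface}")
    (out_dir / "registry.tsv").write_text("\n".join(lines) + "\n",
                                          encoding="utf-8")
    return out_dir
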
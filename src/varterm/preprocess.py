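"""Linguistic pre-processing: corpus loading, sentence splitting, tokenisation
and part-of-speech tagging.

Documents are plain UTF-8 text files, one document per file. Tagging is
delegated to a pluggable backend implementing the :class:`Tagger` contract;
the default is :class:`RuleTagger`, a deterministic closed-lexicon tagger with
suffix heuristics that needs no model download. All tags belong to the Penn
Treebank tag set. Character offsets are 0-based, half-open, into the
NFC-normalised raw text.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol

logger = logging.getLogger(__name__)

#: Penn Treebank tag set (word tags + punctuation tags).
PTB_TAGS = frozenset({
    "CC", "CD", "DT", "EX", "FW", "IN", "JJ", "JJR", "JJS", "LS", "MD",
    "NN", "NNS", "NNP", "NNPS", "PDT", "POS", "PRP", "PRP$", "RB", "RBR",
    "RBS", "RP", "SYM", "TO", "UH", "VB", "VBD", "VBG", "VBN", "VBP",
    "VBZ", "WDT", "WP", "WP$", "WRB",
    ".", ",", ":", "``", "''", "(", ")", "$", "#",
})


@dataclass(frozen=True)
class Token:
    """A single token with its tag and character span in the raw document."""

    surface: str
    pos: str
    start: int
    end: int
    sent_index: int
    tok_index: int


@dataclass
class Document:
    doc_id: str
    raw: str
    sentences: list[list[Token]] = field(default_factory=list)

    def tokens(self) -> Iterable[Token]:
        for sent in self.sentences:
            yield from sent


@dataclass
class Corpus:
    documents: list[Document] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [d.doc_id for d in self.documents]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate doc_ids in corpus")

    def __iter__(self):
        return iter(self.documents)

    def __len__(self) -> int:
        return len(self.documents)


class TaggingError(RuntimeError):
    """Raised when a tagger backend fails on a document."""


class Tagger(Protocol):
    """Tagger contract: text -> sentences of (surface, pos, start, end)."""

    def tag(self, text: str) -> list[list[tuple[str, str, int, int]]]:
        ...


# --------------------------------------------------------------------------
# Tokenisation shared by the rule tagger: words (hyphenated compounds stay
# single tokens), possessive clitics as separate tokens, single punctuation
# marks. Numbers and mixed alphanumerics are single tokens.

_TOKEN_RE = re.compile(r"'[sS]\b|\w+(?:-\w+)*|[^\w\s]")
_SENT_FINAL = {".", "!", "?"}


def _tokenise(text: str) -> list[tuple[str, int, int]]:
    return [(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


class RuleTagger:
    """Deterministic offline tagger: closed lexicon plus suffix heuristics.

    Unknown alphabetic tokens default to NN, which is the right bias for a
    noun-phrase term extractor: unseen domain words are overwhelmingly nouns.
    """

    #: Closed function-word / example lexicon (lowercase lookup).
    LEXICON: dict[str, str] = {
        "the": "DT", "a": "DT", "an": "DT", "this": "DT", "that": "DT",
        "these": "DT", "those": "DT", "any": "DT", "some": "DT", "no": "DT",
        "of": "IN", "in": "IN", "with": "IN", "at": "IN", "on": "IN",
        "for": "IN", "from": "IN", "by": "IN", "to": "TO", "as": "IN",
        "and": "CC", "or": "CC", "but": "CC",
        "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD", "be": "VB",
        "been": "VBN", "has": "VBZ", "have": "VBP", "had": "VBD",
        "shows": "VBZ", "showed": "VBD", "show": "VBP", "seen": "VBN",
        "noted": "VBD", "torn": "VBN", "found": "VBD", "revealed": "VBD",
        "appears": "VBZ", "suggests": "VBZ", "may": "MD", "can": "MD",
        "will": "MD", "not": "RB", "very": "RB", "quite": "RB",
        "there": "EX", "it": "PRP", "he": "PRP", "she": "PRP",
        "his": "PRP$", "her": "PRP$", "its": "PRP$",
        "which": "WDT", "who": "WP",
        # proper names used in worked examples
        "hoffa": "NNP", "baker": "NNP",
    }

    _PUNCT_TAGS = {
        ".": ".", "!": ".", "?": ".", ",": ",", ";": ":", ":": ":",
        "(": "(", ")": ")", "``": "``", "''": "''", '"': "''", "$": "$",
        "#": "#",
    }

    # Suffix heuristics, tried in order (longest effective suffix first).
    _SUFFIX_RULES: list[tuple[str, str]] = [
        ("tion", "NN"), ("sion", "NN"), ("ness", "NN"), ("ment", "NN"),
        ("ity", "NN"), ("ical", "JJ"), ("ous", "JJ"), ("ive", "JJ"),
        ("able", "JJ"), ("ary", "JJ"), ("al", "JJ"), ("ic", "JJ"),
        ("ing", "JJ"), ("ed", "VBN"), ("ly", "RB"),
    ]

    def tag(self, text: str) -> list[list[tuple[str, str, int, int]]]:
        sentences: list[list[tuple[str, str, int, int]]] = []
        current: list[tuple[str, str, int, int]] = []
        for surface, start, end in _tokenise(text):
            current.append((surface, self.tag_word(surface), start, end))
            if surface in _SENT_FINAL:
                sentences.append(current)
                current = []
        if current:
            sentences.append(current)
        return sentences

    def tag_word(self, surface: str) -> str:
        low = surface.lower()
        if low in ("'s", "'S".lower()):
            return "POS"
        if surface in self._PUNCT_TAGS:
            return self._PUNCT_TAGS[surface]
        if low in self.LEXICON:
            return self.LEXICON[low]
        if not any(ch.isalpha() for ch in surface):
            return "CD" if any(ch.isdigit() for ch in surface) else "SYM"
        if any(ch.isdigit() for ch in surface):
            return "NN"  # mixed alphanumerics: B12, i2b2
        for suffix, tag in self._SUFFIX_RULES:
            if low.endswith(suffix) and len(low) > len(suffix) + 2:
                # plural of a heuristic noun: "-tions" etc.
                return tag
        if low.endswith("tions") or low.endswith("ments"):
            return "NNS"
        if low.endswith("s") and not low.endswith("ss") and len(low) > 3:
            return "NNS"
        return "NN"


def tag_document(raw: str, tagger: Tagger | None = None,
                 doc_id: str = "<string>") -> Document:
    """Sentence-split, tokenise and POS-tag ``raw`` into a :class:`Document`.

    The raw text is NFC-normalised first; offsets refer to the normalised
    string stored on the returned document.
    """
    raw = unicodedata.normalize("NFC", raw)
    tagger = tagger or RuleTagger()
    try:
        tagged = tagger.tag(raw)
    except Exception as exc:  # pragma: no cover - backend dependent
        raise TaggingError(f"tagger failed on document {doc_id!r}: {exc}") from exc
    doc = Document(doc_id=doc_id, raw=raw)
    for sent_index, sent in enumerate(tagged):
        tokens = []
        for tok_index, (surface, pos, start, end) in enumerate(sent):
            if raw[start:end] != surface:
                raise TaggingError(
                    f"offset mismatch in {doc_id!r}: {surface!r} vs "
                    f"{raw[start:end]!r} at {start}:{end}")
            if pos not in PTB_TAGS:
                raise TaggingError(f"non-PTB tag {pos!r} for {surface!r}")
            tokens.append(Token(surface, pos, start, end, sent_index, tok_index))
        if tokens:
            doc.sentences.append(tokens)
    # re-number sentences in case empty ones were dropped
    doc.sentences = [
        [Token(t.surface, t.pos, t.start, t.end, i, j)
         for j, t in enumerate(sent)]
        for i, sent in enumerate(doc.sentences)
    ]
    return doc


def load_corpus(path: str | Path, tagger: Tagger | None = None,
                encoding: str = "utf-8") -> Corpus:
    """Load every readable text file under ``path`` as one document each.

    Files are processed in file-name order; undecodable files are skipped
    with a logged per-file error. Raises ``FileNotFoundError`` if the
    directory is missing and ``ValueError`` if it contains no input.
    """
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"no input: {path} is not a directory")
    files = sorted(p for p in path.iterdir() if p.is_file())
    if not files:
        raise ValueError(f"no input: {path} contains no files")
    tagger = tagger or RuleTagger()
    documents = []
    for fp in files:
        try:
            raw = fp.read_text(encoding=encoding)
        except UnicodeDecodeError as exc:
            logger.error("skipping undecodable file %s: %s", fp.name, exc)
            continue
        documents.append(tag_document(raw, tagger, doc_id=fp.name))
    if not documents:
        raise ValueError(f"no input: no readable files in {path}")
    return Corpus(documents=documents)


def corpus_to_tsv(corpus: Corpus) -> str:
    """Serialise the tagged representation to a debugging TSV."""
    lines = ["doc_id\tsent_index\ttok_index\tstart\tend\tsurface\tpos"]
    for doc in corpus:
        for t in doc.tokens():
            lines.append(
                f"{doc.doc_id}\t{t.sent_index}\t{t.tok_index}\t{t.start}\t"
                f"{t.end}\t{t.surface}\t{t.pos}")
    return "\n".join(lines) + "\n"
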
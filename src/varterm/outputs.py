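"""Output artefacts: ranked term table (TSV/HTML), plain term list, and
stand-off corpus annotations via dictionary matching.

The ranked table carries one row per normalised form — rank, score to four
decimals, the surface variants in descending occurrence order, and the
aggregated frequency. The plain list is the variant column flattened, one
variant per line, usable as a lexicon by other applications. Stand-off
annotations are (doc_id, start, length, matched_text) rows produced by
case-insensitive, token-boundary-anchored, longest-match-first dictionary
matching.
"""

from __future__ import annotations

import html as _html
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .preprocess import Corpus, Document
from .termhood import ScoredTerm

VARIANT_SEP = " | "


@dataclass(frozen=True)
class StandoffAnnotation:
    doc_id: str
    start: int
    length: int
    text: str = ""

    @property
    def end(self) -> int:
        return self.start + self.length


# --------------------------------------------------------------------------
# ranked list

def ranked_rows(terms: Sequence[ScoredTerm]) -> list[tuple[int, str, str, int]]:
    rows = []
    for rank, term in enumerate(terms, start=1):
        variants = VARIANT_SEP.join(v for v, _ in term.variants)
        rows.append((rank, f"{term.score:.4f}", variants, term.frequency))
    return rows


def write_ranked_list(terms: Sequence[ScoredTerm], path: str | Path,
                      format: str = "tsv") -> Path:
    """Write the ranked table; ``format`` is ``tsv`` or ``html``."""
    if not terms:
        raise ValueError("ranked list is empty")
    path = Path(path)
    if format == "tsv":
        lines = ["rank\tscore\tvariants\tfrequency"]
        for rank, score, variants, freq in ranked_rows(terms):
            lines.append(f"{rank}\t{score}\t{variants}\t{freq}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif format == "html":
        path.write_text(_render_html(terms), encoding="utf-8")
    else:
        raise ValueError(f"unknown format: {format!r}")
    return path


def read_ranked_list(path: str | Path) -> list[tuple[int, float, list[str], int]]:
    """Reparse a TSV ranked list into (rank, score, variants, frequency)."""
    rows = []
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for line in lines[1:]:
        rank, score, variants, freq = line.split("\t")
        rows.append((int(rank), float(score), variants.split(VARIANT_SEP),
                     int(freq)))
    return rows


def _render_html(terms: Sequence[ScoredTerm]) -> str:
    rows = []
    for rank, score, variants, freq in ranked_rows(terms):
        rows.append(
            "<tr><td>{}</td><td>{}</td><td>{}</td><td>{}</td></tr>".format(
                rank, score, _html.escape(variants), freq))
    return (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        "<title>Ranked terms</title><style>"
        "table{border-collapse:collapse;font-family:sans-serif}"
        "td,th{border:1px solid #999;padding:4px 8px}"
        "th{background:#eee}</style></head><body>"
        "<table><tr><th>Rank</th><th>Termhood</th><th>Term variants</th>"
        "<th>Frequency</th></tr>\n" + "\n".join(rows) +
        "\n</table></body></html>\n")


# --------------------------------------------------------------------------
# plain term list

def term_list(terms: Sequence[ScoredTerm]) -> list[str]:
    """All surface variants in ranked-group order, duplicates removed."""
    seen: dict[str, None] = {}
    for term in terms:
        for variant, _ in term.variants:
            seen.setdefault(variant)
    return list(seen)


def write_term_list(terms: Sequence[ScoredTerm], path: str | Path) -> Path:
    path = Path(path)
    path.write_text("".join(line + "\n" for line in term_list(terms)),
                    encoding="utf-8")
    return path


# --------------------------------------------------------------------------
# dictionary matching / stand-off annotations

def annotate_corpus(terms: Iterable[str], corpus: Corpus) -> list[StandoffAnnotation]:
    """Annotate every term occurrence in the corpus.

    Terms are matched as token sequences (case-insensitive) against each
    document's own tokenisation; scanning is left to right and at each
    position the longest matching term wins, so matches never overlap.
    """
    lexicon: dict[tuple[str, ...], None] = {}
    for term in terms:
        seq = tuple(term.lower().split())
        if seq:
            lexicon.setdefault(seq)
    if not lexicon:
        return []
    max_len = max(len(seq) for seq in lexicon)
    annotations = []
    for doc in corpus:
        annotations.extend(_annotate_document(doc, lexicon, max_len))
    return annotations


def _annotate_document(doc: Document, lexicon: dict[tuple[str, ...], None],
                       max_len: int) -> list[StandoffAnnotation]:
    out = []
    for sent in doc.sentences:
        lowered = [t.surface.lower() for t in sent]
        i = 0
        while i < len(sent):
            for width in range(min(max_len, len(sent) - i), 0, -1):
                if tuple(lowered[i:i + width]) in lexicon:
                    start = sent[i].start
                    end = sent[i + width - 1].end
                    out.append(StandoffAnnotation(
                        doc_id=doc.doc_id, start=start, length=end - start,
                        text=doc.raw[start:end]))
                    i += width
                    break
            else:
                i += 1
    return out


def write_standoff(annotations: Sequence[StandoffAnnotation],
                   path: str | Path) -> Path:
    path = Path(path)
    lines = ["doc_id\tstart\tlength\tmatched_text"]
    for ann in annotations:
        lines.append(f"{ann.doc_id}\t{ann.start}\t{ann.length}\t{ann.text}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_standoff(path: str | Path) -> list[StandoffAnnotation]:
    annotations = []
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for line in lines[1:]:
        parts = line.split("\t")
        doc_id, start, length = parts[0], int(parts[1]), int(parts[2])
        text = parts[3] if len(parts) > 3 else ""
        annotations.append(StandoffAnnotation(doc_id, start, length, text))
    return annotations


def regex_lexicon(terms: Sequence[ScoredTerm]) -> list[str]:
    """Optional extra: one case-insensitive, whitespace-tolerant regular
    expression per normalised form, covering all of its variants."""
    import re as _re
    out = []
    for term in terms:
        alts = sorted({_re.escape(v).replace(r"\ ", r"\s+")
                       for v, _ in term.variants})
        out.append("(?i)\\b(?:" + "|".join(alts) + ")\\b")
    return out
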
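"""Ranked-list, term-list and stand-off annotation outputs plus the CLI."""

import pytest
from click.testing import CliRunner

from varterm.cli import main, read_config
from varterm.outputs import (annotate_corpus, read_ranked_list, read_standoff,
                             term_list, write_ranked_list, write_standoff,
                             write_term_list)
from varterm.pipeline import extract_terms
from varterm.preprocess import Corpus, tag_document

from conftest import TOY_SENTENCES


@pytest.fixture()
def ranked(toy_corpus):
    return extract_terms(toy_corpus).terms


class TestRankedList:
    def test_tsv_rows_and_rank_column(self, ranked, tmp_path):
        path = write_ranked_list(ranked, tmp_path / "t.tsv")
        rows = read_ranked_list(path)
        assert [r[0] for r in rows] == list(range(1, len(ranked) + 1))

    def test_tsv_round_trip(self, ranked, tmp_path):
        path = write_ranked_list(ranked, tmp_path / "t.tsv")
        rows = read_ranked_list(path)
        for row, term in zip(rows, ranked):
            assert row[1] == pytest.approx(term.score, abs=5e-5)
            assert row[2] == [v for v, _ in term.variants]
            assert row[3] == term.frequency

    def test_variants_ordered_by_descending_count(self, tmp_path):
        # two "collateral ligament" + one spelled-out variant via merging
        raw = " ".join(["The collateral ligament was torn ."] * 2
                       + ["The coll-ateral ligament was torn ."])
        corpus = Corpus([tag_document(raw, doc_id="d.txt")])
        terms = extract_terms(corpus).terms
        counts = [c for _, c in terms[0].variants]
        assert counts == sorted(counts, reverse=True)
        assert terms[0].variants[0][0] == "collateral ligament"

    def test_html_contains_all_variants(self, ranked, tmp_path):
        path = write_ranked_list(ranked, tmp_path / "t.html", format="html")
        html = path.read_text()
        for term in ranked:
            for variant, _ in term.variants:
                assert variant in html

    def test_empty_list_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_ranked_list([], tmp_path / "t.tsv")


class TestTermList:
    def test_one_line_per_distinct_variant(self, ranked, tmp_path):
        path = write_term_list(ranked, tmp_path / "terms.txt")
        lines = path.read_text().splitlines()
        n_variants = len({v for t in ranked for v, _ in t.variants})
        assert len(lines) == n_variants

    def test_every_line_is_a_ranked_variant(self, ranked, tmp_path):
        tsv = write_ranked_list(ranked, tmp_path / "t.tsv")
        listed = set(write_term_list(ranked, tmp_path / "l.txt")
                     .read_text().splitlines())
        in_table = {v for _, _, variants, _ in read_ranked_list(tsv)
                    for v in variants}
        assert listed == in_table


class TestAnnotation:
    def _corpus(self, text):
        return Corpus([tag_document(text, doc_id="d.txt")])

    def test_all_occurrences_annotated_with_offsets(self):
        corpus = self._corpus("The lateral meniscus was torn . "
                              "The lateral meniscus was intact .")
        anns = annotate_corpus(["lateral meniscus"], corpus)
        doc = corpus.documents[0]
        assert len(anns) == 2
        for ann in anns:
            assert doc.raw[ann.start:ann.end] == "lateral meniscus"

    def test_longest_match_wins(self):
        corpus = self._corpus("The lateral meniscus was torn .")
        anns = annotate_corpus(["meniscus", "lateral meniscus"], corpus)
        assert [a.text for a in anns] == ["lateral meniscus"]

    def test_matching_is_case_insensitive(self):
        corpus = self._corpus("Lateral Meniscus was torn .")
        anns = annotate_corpus(["lateral meniscus"], corpus)
        assert len(anns) == 1

    def test_token_boundaries_respected(self):
        corpus = self._corpus("The bilateral meniscus was torn .")
        assert annotate_corpus(["lateral meniscus"], corpus) == []

    def test_matches_never_overlap(self):
        corpus = self._corpus("lateral meniscus tear was seen .")
        anns = annotate_corpus(["lateral meniscus", "meniscus tear"], corpus)
        spans = sorted((a.start, a.end) for a in anns)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_every_annotation_matches_a_listed_term(self, toy_corpus):
        terms = term_list(extract_terms(toy_corpus).terms)
        anns = annotate_corpus(terms, toy_corpus)
        assert anns
        lowered = {t for t in terms}
        docs = {d.doc_id: d for d in toy_corpus}
        for ann in anns:
            text = docs[ann.doc_id].raw[ann.start:ann.end].lower()
            assert text in lowered

    def test_standoff_round_trip(self, toy_corpus, tmp_path):
        terms = term_list(extract_terms(toy_corpus).terms)
        anns = annotate_corpus(terms, toy_corpus)
        path = write_standoff(anns, tmp_path / "a.tsv")
        assert read_standoff(path) == anns


class TestCli:
    @pytest.fixture()
    def corpus_dir(self, tmp_path):
        d = tmp_path / "corpus"
        d.mkdir()
        (d / "doc1.txt").write_text(" ".join(TOY_SENTENCES))
        (d / "doc2.txt").write_text("The collateral ligament was torn .")
        return d

    def test_help_lists_subcommands(self):
        result = CliRunner().invoke(main, ["--help"])
        assert result.exit_code == 0
        for sub in ("extract", "annotate", "evaluate", "simulate"):
            assert sub in result.output

    def test_extract_writes_all_outputs(self, corpus_dir, tmp_path):
        prefix = tmp_path / "out"
        result = CliRunner().invoke(
            main, ["extract", str(corpus_dir), "--out-prefix", str(prefix)])
        assert result.exit_code == 0, result.output
        for suffix in (".tsv", ".html", ".txt", ".annotations.tsv"):
            assert (tmp_path / f"out{suffix}").exists()

    def test_missing_input_dir_fails(self, tmp_path):
        result = CliRunner().invoke(main, ["extract", str(tmp_path / "none")])
        assert result.exit_code != 0

    def test_simulate_then_extract_and_evaluate(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "syn"
        r1 = runner.invoke(main, ["simulate", "--out-dir", str(out),
                                  "--seed", "5"])
        assert r1.exit_code == 0, r1.output
        assert (out / "corpus").is_dir()
        assert (out / "registry.tsv").exists()
        r2 = runner.invoke(main, [
            "evaluate", str(out / "corpus"), str(out / "annotator_a.tsv"),
            str(out / "annotator_b.tsv"), "--ks", "5",
            "--out", str(tmp_path / "eval.tsv")])
        assert r2.exit_code == 0, r2.output
        assert "kappa=" in r2.output
        assert (tmp_path / "eval.tsv").read_text().startswith("k\tTP")

    def test_config_file_provides_defaults(self, corpus_dir, tmp_path):
        cfg = tmp_path / "varterm.cfg"
        cfg.write_text("out-prefix = {}\n".format(tmp_path / "cfg_out"))
        result = CliRunner().invoke(
            main, ["extract", str(corpus_dir), "--config", str(cfg)])
        assert result.exit_code == 0, result.output
        assert (tmp_path / "cfg_out.tsv").exists()

    def test_read_config_rejects_bad_lines(self, tmp_path):
        cfg = tmp_path / "bad.cfg"
        cfg.write_text("not a pair\n")
        with pytest.raises(ValueError):
            read_config(cfg)
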
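"""Cleaning, back-matter stripping, reflow, filtering and deduplication."""

import pytest

from litcooc import preprocess as pp


def _raw(lines, doc_id="d1"):
    return pp.RawArticle(doc_id=doc_id, lines=list(lines))


def _char_classes(line):
    """Independent oracle: digit/symbol/lowercase fractions over non-space chars."""
    chars = [c for c in line if not c.isspace()]
    n = len(chars)
    digit = sum(c.isdigit() for c in chars) / n
    symbol = sum(not c.isalnum() or not c.isascii() for c in chars) / n
    lower = sum(c.islower() and c.isascii() for c in chars) / n
    return digit, symbol, lower


class TestCleanLines:
    @pytest.mark.parametrize(
        "line,kept",
        [
            ("p53 binds mdm2 in vivo", False),  # digit fraction 3/18 > 10%
            ("the protein localizes to the nucleus", True),
            ("TABLE 1. 1234 5678 9012", False),  # majority digits
            ("A LINE THAT IS ENTIRELY UPPERCASE TEXT", False),  # lowercase < 50%
            ("some text with one digit 1 in a long enough line", True),
        ],
    )
    def test_line_composition_rules(self, line, kept):
        digit, symbol, lower = _char_classes(line)
        expected = not (digit > 0.10 or symbol > 0.10 or lower < 0.50)
        assert expected == kept  # the oracle agrees with the example labels
        out = pp.clean_lines(_raw([line]))
        assert (line in out.lines) == kept

    def test_non_printable_removed_and_counted(self):
        out = pp.clean_lines(_raw(["hello\x00world this is a line\x07 of text"]))
        assert out.lines == ["helloworld this is a line of text"]
        assert out.provenance[-1]["chars_removed"] == 2

    def test_tabs_become_spaces(self):
        out = pp.clean_lines(_raw(["alpha\tbeta gamma delta words here"]))
        assert out.lines[0] == "alpha beta gamma delta words here"

    def test_empty_input_passes_through(self):
        out = pp.clean_lines(_raw([]))
        assert out.lines == []

    def test_idempotent(self):
        lines = ["the protein localizes", "TABLE 99 100", "a fine lowercase line"]
        once = pp.clean_lines(_raw(lines))
        twice = pp.clean_lines(once)
        assert twice.lines == once.lines


class TestStripBackMatter:
    def test_heading_trigger(self):
        body = [f"plain lowercase body line number {w}" for w in "abcdefgh"]
        lines = body + ["References", "[1] Smith, A. something", "[2] Jones, B. other"]
        out = pp.strip_back_matter(_raw(lines))
        assert out.lines == body
        assert "no_references_found" not in out.flags

    def test_bracketed_run_without_heading(self):
        body = [f"plain lowercase body line number {w}" for w in "abcdefgh"]
        refs = ["[1] Alpha et al", "[2] Beta et al", "[3] Gamma et al"]
        out = pp.strip_back_matter(_raw(body + refs))
        assert out.lines == body

    def test_short_run_is_not_back_matter(self):
        body = [f"plain lowercase body line number {w}" for w in "abcdefgh"]
        out = pp.strip_back_matter(_raw(body + ["[1] lone artifact line"]))
        assert out.lines == body + ["[1] lone artifact line"]
        assert "no_references_found" in out.flags

    def test_no_trigger_flags_document(self):
        out = pp.strip_back_matter(_raw(["just a body line", "and another one"]))
        assert "no_references_found" in out.flags

    def test_heading_only_in_tail_region(self):
        # "literature" early in a long document must not truncate it.
        lines = ["literature review of the field"] + [
            f"body line {i} with ordinary text" for i in range(20)
        ]
        out = pp.strip_back_matter(_raw(lines))
        assert len(out.lines) == 21

    def test_misspelled_headings_match(self):
        body = [f"plain lowercase body line number {w}" for w in "abcdefgh"]
        for heading in ("Refirences", "Literatur", "Referesces", "Acknowledgments"):
            out = pp.strip_back_matter(_raw(body + [heading, "[1] X y", "[2] Z w"]))
            assert out.lines == body, heading

    def test_idempotent_on_truncated_output(self):
        body = [f"plain lowercase body line number {w}" for w in "abcdefgh"]
        lines = body + ["References", "[1] A a", "[2] B b", "[3] C c"]
        once = pp.strip_back_matter(_raw(lines))
        assert pp.strip_back_matter(once).lines == once.lines


class TestReflow:
    def test_mid_sentence_break_joined(self):
        doc = pp.reflow(_raw(["The protein binds", "the receptor."]))
        assert doc.paragraphs == [["The protein binds the receptor."]]

    def test_terminal_then_uppercase_opens_paragraph(self):
        doc = pp.reflow(_raw(["...was significant.", "We conclude that all is well."]))
        assert len(doc.paragraphs) == 2

    def test_lowercase_start_continues_paragraph(self):
        doc = pp.reflow(_raw(["Results were clear.", "however, caveats apply."]))
        assert len(doc.paragraphs) == 1
        assert doc.paragraphs[0] == ["Results were clear.", "however, caveats apply."]

    def test_strict_mode_differs_on_lowercase_start(self):
        lines = ["Results were clear.", "however, caveats apply."]
        default = pp.reflow(_raw(lines), strict_as_printed=False)
        strict = pp.reflow(_raw(lines), strict_as_printed=True)
        assert len(default.paragraphs) == 1
        assert len(strict.paragraphs) == 2

    def test_sentence_split_requires_uppercase_or_digit(self):
        doc = pp.reflow(_raw(["This is v. small test. Next sentence here. 2 more follow."]))
        # "v. small" must not split (lowercase continuation)
        assert doc.paragraphs[0][0] == "This is v. small test."
        assert doc.paragraphs[0][1] == "Next sentence here."
        assert doc.paragraphs[0][2] == "2 more follow."

    def test_no_empty_sentences(self, tiny_generated):
        _, _, _, corpus = tiny_generated
        for doc_id in list(corpus.documents)[:30]:
            doc = pp.reflow(pp.clean_lines(_raw(corpus.documents[doc_id], doc_id)))
            for para in doc.paragraphs:
                assert para and all(s.strip() for s in para)

    def test_text_is_subsequence_of_input(self, tiny_generated):
        _, _, _, corpus = tiny_generated
        for doc_id in list(corpus.documents)[:20]:
            raw = _raw(corpus.documents[doc_id], doc_id)
            doc = pp.reflow(pp.strip_back_matter(pp.clean_lines(raw)))
            out = "".join(doc.text().split())
            src = "".join("".join(corpus.documents[doc_id]).split())
            it = iter(src)
            assert all(c in it for c in out)  # subsequence check


class TestFilterArticle:
    def _doc(self, sentences, doc_id="d1", lines=None):
        return pp.Document(
            doc_id=doc_id, paragraphs=[list(sentences)], source_lines=lines or list(sentences)
        )

    def test_requires_precomputed_cutoff(self):
        with pytest.raises(ValueError):
            pp.filter_article(self._doc(["Some text here."]), None)

    def test_spaced_out_text_discarded_for_word_length(self):
        doc = self._doc(["t h e p r o t e i n w a s f o u n d h e r e"])
        decision = pp.filter_article(doc, word_length_cutoff=3.0)
        assert (decision.verdict, decision.reason) == ("discard", "low_avg_word_length")

    def test_blacklist_keyword_on_heading_line(self):
        doc = self._doc(
            ["The experiment was described in the text here."],
            lines=["The experiment was described in the text here.", "Editorial Board"],
        )
        decision = pp.filter_article(doc, word_length_cutoff=1.0)
        assert (decision.verdict, decision.reason) == ("discard", "blacklist_keyword")

    def test_blacklist_ignored_on_long_lines(self):
        long_line = "as noted in the erratum of the previous paper the values were corrected"
        doc = self._doc([long_line], lines=[long_line])
        decision = pp.filter_article(doc, word_length_cutoff=1.0)
        assert decision.verdict == "keep"

    def test_empty_text_first(self):
        doc = pp.Document(doc_id="d0", paragraphs=[])
        decision = pp.filter_article(doc, word_length_cutoff=1.0)
        assert (decision.verdict, decision.reason) == ("discard", "empty_text")

    def test_non_english_detected_before_word_length(self):
        doc = self._doc(["Zaqxuv qikzov wyxquz xaqzyq zovqik quzwyx zaqxaq qikqik."])
        decision = pp.filter_article(doc, word_length_cutoff=0.0)
        assert (decision.verdict, decision.reason) == ("discard", "non_english")

    def test_ordinary_article_kept(self):
        doc = self._doc(["The results of the analysis were consistent with the model."])
        assert pp.filter_article(doc, word_length_cutoff=2.0).verdict == "keep"

    def test_quantile_is_linear_interpolated(self):
        import numpy as np

        docs = [self._doc([f"{'a' * k} {'b' * k} {'c' * k}"]) for k in range(1, 51)]
        got = pp.word_length_quantile(docs, q=0.02)
        assert got == pytest.approx(np.quantile(np.arange(1.0, 51.0), 0.02))


class TestDeduplicate:
    def _doc(self, doc_id, text):
        return pp.Document(doc_id=doc_id, paragraphs=[[text]])

    def test_concatenation_dropped_when_parts_exist(self):
        a = self._doc("a", "First article body with words.")
        b = self._doc("b", "Second article body other words.")
        c = self._doc("c", a.paragraphs[0][0] + " " + b.paragraphs[0][0])
        kept, removed = pp.deduplicate([a, b, c])
        assert {d.doc_id for d in kept} == {"a", "b"}
        assert [(d.doc_id, why) for d, why, _ in removed] == [("c", "concatenation")]

    def test_exact_duplicates_keep_one(self):
        a = self._doc("a", "Same text here.")
        b = self._doc("b", "Same text here.")
        kept, removed = pp.deduplicate([a, b])
        assert [d.doc_id for d in kept] == ["a"]
        assert removed[0][0].doc_id == "b" and removed[0][2] == "a"

    def test_single_subset_dropped_for_superset(self):
        small = self._doc("s", "Shared body of the article.")
        big = self._doc("b", "Shared body of the article. Plus extra trailing material.")
        kept, removed = pp.deduplicate([small, big])
        assert {d.doc_id for d in kept} == {"b"}
        assert removed[0][0].doc_id == "s" and removed[0][1] == "subset"

    def test_disjoint_docs_all_kept(self):
        docs = [self._doc(f"d{i}", f"Entirely unique body number {i} here.") for i in range(4)]
        kept, removed = pp.deduplicate(docs)
        assert len(kept) == 4 and not removed

    def test_normalisation_is_case_and_whitespace_insensitive(self):
        a = self._doc("a", "Some  Text   Here.")
        b = self._doc("b", "some text here.")
        kept, _ = pp.deduplicate([a, b])
        assert len(kept) == 1
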
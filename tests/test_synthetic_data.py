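"""Generator: dictionaries, corpora, truth logs, gold standards."""

import numpy as np
import pytest

import litcooc.synthetic_data as sd
from litcooc.pipeline import preprocess_corpus
from litcooc.scoring import ScoreParams, count_pairs


class TestConfigValidation:
    def test_granularity_mix_must_sum_to_one(self):
        with pytest.raises(sd.ConfigurationError):
            sd.GeneratorConfig(granularity_mix=(0.5, 0.5, 0.5))

    def test_probabilities_bounded(self):
        with pytest.raises(sd.ConfigurationError):
            sd.GeneratorConfig(background_rate=1.5)

    def test_counts_positive(self):
        with pytest.raises(sd.ConfigurationError):
            sd.GeneratorConfig(n_documents=0)
        with pytest.raises(sd.ConfigurationError):
            sd.GeneratorConfig(n_entities_per_type={"gene": 1, "disease": 5, "compartment": 5})

    def test_empty_year_range(self):
        with pytest.raises(sd.ConfigurationError):
            sd.GeneratorConfig(years=(2010, 2000))


class TestGenDictionary:
    def test_every_entity_has_a_name_and_types_are_complete(self):
        tables = sd.gen_dictionary(sd.GeneratorConfig(seed=3))
        named = {s for s, _ in tables.names}
        assert {s for s, _, _ in tables.entities} <= named
        types = {t for _, t, _ in tables.entities}
        assert {"gene", "disease", "compartment"} <= types

    def test_ontology_rooted(self):
        tables = sd.gen_dictionary(sd.GeneratorConfig(seed=3, ontology_depth=2))
        d = tables.to_dictionary()
        for etype in ("disease", "compartment"):
            root = [s for s, t, i in tables.entities if t == etype and i.endswith("ROOT")][0]
            for leaf in tables.leaf_serials[etype]:
                assert root in d.ancestors(leaf)  # every leaf reaches the root

    def test_zero_ambiguous_fraction_means_disjoint_names(self):
        tables = sd.gen_dictionary(sd.GeneratorConfig(seed=3, ambiguous_fraction=0.0))
        types = {s: t for s, t, _ in tables.entities}
        by_name: dict[str, set[str]] = {}
        for s, n in tables.names:
            by_name.setdefault(n, set()).add(types[s])
        assert all(len(ts) == 1 for ts in by_name.values())

    def test_ambiguous_fraction_counts_shared_names(self):
        cfg = sd.GeneratorConfig(
            seed=3,
            ambiguous_fraction=0.2,
            n_entities_per_type={"gene": 40, "disease": 30, "compartment": 30},
            ontology_depth=0,
        )
        tables = sd.gen_dictionary(cfg)
        base_names = len({n for _, n in tables.names})
        types = {s: t for s, t, _ in tables.entities}
        by_name: dict[str, set[str]] = {}
        for s, n in tables.names:
            by_name.setdefault(n, set()).add(types[s])
        shared = sum(1 for ts in by_name.values() if len(ts) > 1)
        assert shared == round(0.2 * base_names)

    def test_names_disjoint_from_filler(self):
        tables = sd.gen_dictionary(sd.GeneratorConfig(seed=3))
        assert not {n for _, n in tables.names} & set(sd.FILLER_WORDS)


class TestYearSchedule:
    def test_counts_follow_doubling_law(self):
        cfg = sd.GeneratorConfig(
            n_documents=20000, years=(1945, 2016), doubling_time_years=9.7, seed=0
        )
        counts = sd.year_counts_schedule(cfg)
        years = np.array(sorted(counts))
        logc = np.log2([counts[y] for y in years])
        slope = np.polyfit(years, logc, 1)[0]
        assert slope == pytest.approx(1 / 9.7, rel=0.01)

    def test_total_close_to_requested(self):
        cfg = sd.GeneratorConfig(n_documents=3000, years=(1990, 2016))
        total = sum(sd.year_counts_schedule(cfg).values())
        assert abs(total - 3000) <= 30


class TestGenCorpus:
    def test_reproducible_byte_identical(self, tmp_path):
        outs = []
        for sub in ("a", "b"):
            cfg = sd.GeneratorConfig(n_documents=60, years=(2000, 2005), seed=9)
            tables = sd.gen_dictionary(cfg)
            truth = sd.gen_truth(cfg, tables)
            corpus = sd.gen_corpus(cfg, tables, truth)
            d = tmp_path / sub
            corpus.write(str(d))
            tables.write(str(d / "dict"))
            truth.write_jsonl(str(d / "truth.jsonl"))
            outs.append(d)
        files_a = sorted(p.relative_to(outs[0]) for p in outs[0].rglob("*") if p.is_file())
        files_b = sorted(p.relative_to(outs[1]) for p in outs[1].rglob("*") if p.is_file())
        assert files_a == files_b
        for rel in files_a:
            assert (outs[0] / rel).read_bytes() == (outs[1] / rel).read_bytes(), rel

    def test_single_sentence_pair_is_unique_comention(self):
        """background 0, one planted sentence pair -> unique co-mentioned pair."""
        cfg = sd.GeneratorConfig(
            n_documents=40,
            years=(2000, 2002),
            seed=4,
            noise_rates={},
            background_rate=0.0,
            singles_per_doc=0.0,
            n_positive_pairs=1,
            pathway_size=2,
            granularity_mix=(1.0, 0.0, 0.0),
            effect_size_range=(0.5, 0.5),
        )
        tables = sd.gen_dictionary(cfg)
        truth = sd.gen_truth(cfg, tables)
        corpus = sd.gen_corpus(cfg, tables, truth)
        co = set()
        for doc_id, ms in truth.mentions.items():
            by_sent: dict[tuple[int, int], set[int]] = {}
            for p, s, serial in ms:
                by_sent.setdefault((p, s), set()).add(serial)
            for serials in by_sent.values():
                for a in serials:
                    for b in serials:
                        if a < b:
                            co.add((a, b))
        planted = {
            pair for pairs in truth.planted_pairs.values() for pair in pairs
        }
        assert co  # the plants did occur
        assert co <= planted

    def test_reference_lists_logged_and_counted(self):
        cfg = sd.GeneratorConfig(
            n_documents=400,
            years=(2000, 2008),
            seed=6,
            noise_rates={"reference_list": 0.3},
        )
        tables = sd.gen_dictionary(cfg)
        truth = sd.gen_truth(cfg, tables)
        corpus = sd.gen_corpus(cfg, tables, truth)
        ref_docs = [a for a in truth.artifacts if a["artifact"] == "reference_list"]
        n_expected = sum(
            1 for doc_id, lines in corpus.documents.items() if "References" in lines
        )
        assert len(ref_docs) == n_expected
        assert 0.2 * len(corpus.documents) < len(ref_docs) < 0.4 * len(corpus.documents)

    def test_document_structure_matches_truth(self, tiny_generated):
        _, _, truth, corpus = tiny_generated
        kept, _, _ = preprocess_corpus(corpus.documents, corpus.metadata)
        by_id = {d.doc_id: d for d in kept}
        checked = 0
        for doc_id, n_sents in truth.doc_structure.items():
            if doc_id in by_id:
                assert [len(p) for p in by_id[doc_id].paragraphs] == n_sents
                checked += 1
        assert checked > 0.9 * len(truth.doc_structure)

    def test_abstracts_are_single_paragraph(self, tiny_generated):
        from litcooc import preprocess as pp

        _, _, _, corpus = tiny_generated
        for doc_id in list(corpus.abstracts)[:25]:
            raw = pp.RawArticle(doc_id, list(corpus.abstracts[doc_id]))
            doc = pp.reflow(pp.clean_lines(raw))
            assert len(doc.paragraphs) == 1

    def test_planted_granularity_is_respected(self):
        cfg = sd.GeneratorConfig(
            n_documents=60,
            years=(2000, 2002),
            seed=8,
            noise_rates={},
            background_rate=0.0,
            singles_per_doc=0.0,
            effect_size_range=(0.2, 0.2),
            n_positive_pairs=6,
        )
        tables = sd.gen_dictionary(cfg)
        truth = sd.gen_truth(cfg, tables)
        sd.gen_corpus(cfg, tables, truth)
        mentions_at: dict[str, dict[int, list]] = {}
        for doc_id, ms in truth.mentions.items():
            at = mentions_at.setdefault(doc_id, {})
            for p, s, serial in ms:
                at.setdefault(serial, []).append((p, s))
        for plant in truth.per_document_plants:
            at = mentions_at[plant["doc_id"]]
            locs_i, locs_j = at[plant["i"]], at[plant["j"]]
            if plant["granularity"] == "sentence":
                assert any(li == lj for li in locs_i for lj in locs_j)
            elif plant["granularity"] == "paragraph":
                assert any(
                    li[0] == lj[0] and li[1] != lj[1] for li in locs_i for lj in locs_j
                )
            else:
                assert any(li[0] != lj[0] for li in locs_i for lj in locs_j)


class TestGoldStandards:
    def test_pathway_mode_counts(self):
        truth = sd.SyntheticTruth()
        truth.pathways = {"p1": [1, 2, 3], "p2": [4, 5, 6]}
        tables = sd.gen_dictionary(sd.GeneratorConfig(seed=2))
        rows = sd.gen_gold_standard(truth, tables, "pathway")
        assert len(rows) == 6
        from litcooc.benchmark import build_pathway_benchmark

        memberships: dict[str, set[str]] = {}
        for pw, prot in rows:
            memberships.setdefault(pw, set()).add(prot)
        bench = build_pathway_benchmark(memberships)
        assert len(bench.positives) == 6 and len(bench.negatives) == 9

    def test_empty_truth_gives_empty_files(self):
        truth = sd.SyntheticTruth()
        tables = sd.gen_dictionary(sd.GeneratorConfig(seed=2))
        for mode in ("pathway", "shuffle", "compartment"):
            assert sd.gen_gold_standard(truth, tables, mode) == []

    def test_unknown_mode_raises(self):
        with pytest.raises(ValueError):
            sd.gen_gold_standard(sd.SyntheticTruth(), sd.gen_dictionary(sd.GeneratorConfig()), "xx")

    def test_positives_coincide_with_planted_pairs(self, tiny_generated):
        _, tables, truth, _ = tiny_generated
        d = tables.to_dictionary()
        ident = {s: d.identifier(s) for s, _, _ in tables.entities}
        types = {s: t for s, t, _ in tables.entities}
        rows = set(sd.gen_gold_standard(truth, tables, "shuffle"))
        expected = set()
        for a, b in truth.planted_pairs["disease_gene"]:
            dd, gg = (a, b) if types[a] == "disease" else (b, a)
            expected.add((ident[dd], ident[gg]))
        assert rows == expected


class TestGranularityLever:
    def test_document_only_corpus_needs_document_weight(self):
        """100% document-only plants: AUC ~ 0.5 with w_d=0, > 0.8 with w_d=1."""
        from litcooc.benchmark import build_pathway_benchmark, roc
        from litcooc.pipeline import preprocess_corpus, tag_corpus
        from litcooc.scoring import score_pairs

        cfg = sd.GeneratorConfig(
            n_documents=500,
            years=(2000, 2008),
            seed=13,
            noise_rates={},
            background_rate=0.0,
            singles_per_doc=0.0,
            granularity_mix=(0.0, 0.0, 1.0),
            effect_size_range=(0.01, 0.03),
        )
        tables = sd.gen_dictionary(cfg)
        truth = sd.gen_truth(cfg, tables)
        corpus = sd.gen_corpus(cfg, tables, truth)
        dictionary = tables.to_dictionary()
        kept, _, _ = preprocess_corpus(corpus.documents, corpus.metadata)
        mentions = tag_corpus(kept, dictionary)
        memberships = {}
        for pw, prot in sd.gen_gold_standard(truth, tables, "pathway"):
            memberships.setdefault(pw, set()).add(prot)
        bench = build_pathway_benchmark(memberships)
        aucs = {}
        for w_d in (0.0, 1.0):
            params = ScoreParams(w_d=w_d)
            counts = count_pairs(mentions, ("gene", "gene"), params, dictionary)
            aucs[w_d] = roc(score_pairs(counts, params, dictionary), bench, rank_by="s").auc
        assert aucs[0.0] == pytest.approx(0.5, abs=0.05)
        assert aucs[1.0] > 0.8
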
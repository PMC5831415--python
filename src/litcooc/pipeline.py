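"""Stage wiring and the four-corpus comparison driver.

The pipeline runs generate -> preprocess -> tag -> score -> benchmark ->
stats over four matched corpora:

* ``all_fulltext``   - every full-text article surviving filtering;
* ``core_fulltext``  - surviving full texts that possess a separate abstract;
* ``core_abstracts`` - the abstracts of the core full texts;
* ``medline_like``   - the abstracts of all generated articles (a superset,
  standing in for an abstract-only bibliographic database).

Each corpus is scored with the default weights and with the document weight
w_d set to zero, against the three gold standards (pathway protein-protein,
shuffled disease-gene, protein-compartment complement), yielding a summary
table of AUC and TPR@10%FPR per (corpus, benchmark, weight mode).  Every
emitted file is listed in a JSON manifest with a content hash, and the whole
run is deterministic under fixed seeds.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import benchmark as bench_mod
from . import corpus_stats, ner, preprocess, scoring, synthetic_data

__all__ = ["RunConfig", "PipelineError", "run_comparison", "end_to_end_smoke", "load_config"]

CORPUS_LABELS = ("all_fulltext", "core_fulltext", "core_abstracts", "medline_like")
BENCHMARK_LABELS = ("ppi", "disease_gene", "protein_compartment")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class RunConfig:
    """Declarative configuration for a full pipeline run."""

    generator: synthetic_data.GeneratorConfig = field(
        default_factory=synthetic_data.GeneratorConfig
    )
    score_params: scoring.ScoreParams = field(default_factory=scoring.ScoreParams)
    word_length_quantile: float = 0.02
    shuffle_seed: int = 42
    outdir: str = "litcooc_run"

    @classmethod
    def from_mapping(cls, data: Mapping) -> "RunConfig":
        gen = synthetic_data.GeneratorConfig(**data.get("generator", {}))
        sp = scoring.ScoreParams(**data.get("score_params", {}))
        return cls(
            generator=gen,
            score_params=sp,
            word_length_quantile=float(data.get("word_length_quantile", 0.02)),
            shuffle_seed=int(data.get("shuffle_seed", 42)),
            outdir=str(data.get("outdir", "litcooc_run")),
        )


def load_config(path: str) -> RunConfig:
    """Load a RunConfig from a declarative YAML (or key: value) file."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_mapping(data)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def preprocess_corpus(
    raw_docs: Mapping[str, Sequence[str]],
    metadata: pd.DataFrame,
    quantile: float = 0.02,
) -> tuple[list[preprocess.Document], list[preprocess.FilterDecision], list]:
    """Clean, reflow, filter and deduplicate a set of raw articles.

    Returns (kept documents, all filter decisions, dedup removals).
    """
    meta_by_id = metadata.set_index("doc_id").to_dict("index") if not metadata.empty else {}
    cleaned: list[preprocess.Document] = []
    for doc_id in sorted(raw_docs):
        raw = preprocess.RawArticle(
            doc_id=doc_id, lines=list(raw_docs[doc_id]), metadata=dict(meta_by_id.get(doc_id, {}))
        )
        raw = preprocess.clean_lines(raw)
        raw = preprocess.strip_back_matter(raw)
        cleaned.append(preprocess.reflow(raw))
    cutoff = preprocess.word_length_quantile(cleaned, quantile)
    decisions: list[preprocess.FilterDecision] = []
    kept: list[preprocess.Document] = []
    for doc in cleaned:
        decision = preprocess.filter_article(doc, cutoff)
        decisions.append(decision)
        if decision.verdict == "keep":
            kept.append(doc)
    kept, removed = preprocess.deduplicate(kept)
    return kept, decisions, removed


def tag_corpus(
    docs: Sequence[preprocess.Document], dictionary: ner.Dictionary
) -> dict[str, list[ner.Mention]]:
    """Tag, disambiguate and ontology-backtrack every document."""
    out: dict[str, list[ner.Mention]] = {}
    for doc in docs:
        mentions = ner.tag_document(doc, dictionary)
        mentions = ner.resolve_ambiguity(mentions, dictionary)
        mentions = ner.backtrack_ontology(mentions, dictionary)
        out[doc.doc_id] = mentions
    return out


def _benchmarks(
    truth: synthetic_data.SyntheticTruth,
    tables: synthetic_data.DictionaryTables,
    shuffle_seed: int,
) -> dict[str, bench_mod.BenchmarkSet]:
    dictionary = tables.to_dictionary()
    pathway_rows = synthetic_data.gen_gold_standard(truth, tables, "pathway")
    memberships: dict[str, set[str]] = {}
    for pw, prot in pathway_rows:
        memberships.setdefault(pw, set()).add(prot)
    dg_rows = synthetic_data.gen_gold_standard(truth, tables, "shuffle")
    comp_rows = synthetic_data.gen_gold_standard(truth, tables, "compartment")
    annotations: dict[str, set[str]] = {}
    for prot, comp in comp_rows:
        annotations.setdefault(prot, set()).add(comp)
    universe = [dictionary.identifier(s) for s in tables.leaf_serials["compartment"]]
    return {
        "ppi": bench_mod.build_pathway_benchmark(memberships),
        "disease_gene": bench_mod.build_shuffle_benchmark(dg_rows, seed=shuffle_seed),
        "protein_compartment": bench_mod.build_compartment_benchmark(annotations, universe),
    }


def score_and_evaluate(
    mentions_by_doc: Mapping[str, Sequence[ner.Mention]],
    dictionary: ner.Dictionary,
    benchmarks: Mapping[str, bench_mod.BenchmarkSet],
    params: scoring.ScoreParams,
) -> dict[str, bench_mod.RocResult]:
    """Count, score and ROC-evaluate one corpus against every benchmark.

    Ranking uses S (Z is a strictly monotone transform of S, so ROC results
    are identical and degenerate-scale corner cases on tiny corpora are
    avoided).
    """
    out: dict[str, bench_mod.RocResult] = {}
    for label, bench in benchmarks.items():
        type_pair = synthetic_data.ASSOC_TYPE_PAIRS[label]
        counts = scoring.count_pairs(mentions_by_doc, type_pair, params, dictionary)
        scores = scoring.score_pairs(counts, params, dictionary)
        out[label] = bench_mod.roc(scores, bench, rank_by="s")
    return out


def run_comparison(config: RunConfig) -> pd.DataFrame:
    """Run the full four-corpus, three-benchmark, two-weight-mode comparison.

    Returns the summary table with one row per (corpus, benchmark, weight
    mode): AUC, TPR@10%FPR and the pair counts actually used.
    """
    gen = config.generator
    try:
        tables = synthetic_data.gen_dictionary(gen)
        truth = synthetic_data.gen_truth(gen, tables)
        corpus = synthetic_data.gen_corpus(gen, tables, truth)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage=generate: {exc}") from exc
    dictionary = tables.to_dictionary()

    try:
        kept_full, _, _ = preprocess_corpus(
            corpus.documents, corpus.metadata, config.word_length_quantile
        )
        abstract_meta = corpus.metadata[corpus.metadata["has_abstract"]]
        kept_abs, _, _ = preprocess_corpus(
            corpus.abstracts, abstract_meta, config.word_length_quantile
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage=preprocess: {exc}") from exc

    has_abstract = set(corpus.metadata.loc[corpus.metadata["has_abstract"], "doc_id"])
    surviving_full_ids = {d.doc_id for d in kept_full}
    corpora: dict[str, list[preprocess.Document]] = {
        "all_fulltext": kept_full,
        "core_fulltext": [d for d in kept_full if d.doc_id in has_abstract],
        "core_abstracts": [
            d for d in kept_abs if d.doc_id in surviving_full_ids
        ],
        "medline_like": kept_abs,
    }

    try:
        benchmarks = _benchmarks(truth, tables, config.shuffle_seed)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage=benchmark: {exc}") from exc

    params_default = config.score_params
    params_nodoc = scoring.ScoreParams(
        w_d=0.0,
        w_p=params_default.w_p,
        w_s=params_default.w_s,
        alpha=params_default.alpha,
        per_instance=params_default.per_instance,
    )
    rows = []
    for corpus_label in CORPUS_LABELS:
        docs = corpora[corpus_label]
        try:
            mentions = tag_corpus(docs, dictionary)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage=tag corpus={corpus_label}: {exc}") from exc
        for mode_label, params in (("default", params_default), ("no_document_weight", params_nodoc)):
            try:
                results = score_and_evaluate(mentions, dictionary, benchmarks, params)
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(f"stage=score corpus={corpus_label}: {exc}") from exc
            for bench_label in BENCHMARK_LABELS:
                r = results[bench_label]
                rows.append(
                    {
                        "corpus": corpus_label,
                        "benchmark": bench_label,
                        "weight_mode": mode_label,
                        "auc": round(r.auc, 6),
                        "tpr_at_10pct_fpr": round(r.tpr_at_10pct_fpr, 6),
                        "n_pos": r.n_pos,
                        "n_neg": r.n_neg,
                        "n_docs": len(docs),
                    }
                )
    return pd.DataFrame(rows)


def end_to_end_smoke(seed: int = 42, outdir: str | None = None, n_documents: int = 120) -> dict:
    """Flow a tiny corpus through every stage; return (and write) a manifest.

    The manifest lists every emitted artifact with row counts and content
    hashes; identical seeds give identical manifests.  An empty corpus flows
    through with empty outputs and a warning flag rather than an error.
    """
    gen = synthetic_data.GeneratorConfig(
        n_documents=n_documents, years=(2000, 2010), seed=seed, n_positive_pairs=8
    )
    config = RunConfig(generator=gen, outdir=outdir or "litcooc_smoke")
    summary = run_comparison(config)
    manifest: dict = {"seed": seed, "artifacts": []}
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        tables = synthetic_data.gen_dictionary(gen)
        truth = synthetic_data.gen_truth(gen, tables)
        corpus = synthetic_data.gen_corpus(gen, tables, truth)
        paths = corpus.write(outdir)
        dict_paths = tables.write(os.path.join(outdir, "dictionary"))
        truth_path = os.path.join(outdir, "truth.jsonl")
        truth.write_jsonl(truth_path)
        summary_path = os.path.join(outdir, "summary.tsv")
        summary.to_csv(summary_path, sep="\t", index=False)
        for name, p in {
            **dict_paths,
            "metadata": paths["metadata"],
            "truth": truth_path,
            "summary": summary_path,
        }.items():
            with open(p, encoding="utf-8") as fh:
                n_rows = sum(1 for _ in fh)
            manifest["artifacts"].append(
                {"name": name, "path": os.path.relpath(p, outdir), "rows": n_rows, "sha256": _sha256(p)}
            )
        manifest["artifacts"].sort(key=lambda a: a["name"])
        with open(os.path.join(outdir, "manifest.json"), "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["summary_rows"] = len(summary)
    manifest["mean_auc"] = float(summary["auc"].mean()) if len(summary) else None
    return manifest
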
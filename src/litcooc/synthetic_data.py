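"""Synthetic corpora, dictionaries, ontologies and gold standards.

Every downstream stage of the pipeline (cleaning, NER, co-occurrence scoring,
ROC benchmarking, corpus statistics) is exercised against corpora generated
here, so no licensed article collection or curated dictionary is needed.  The
generator emulates the statistical structure the analysis assumes:

* per-year document counts following exponential growth with a configurable
  doubling time;
* multi-paragraph documents whose sentences are filler text drawn from a
  fixed list of common English words, guaranteed disjoint from every
  dictionary name, so the ground truth of planted mentions is exact;
* entity pairs planted as co-mentions at a chosen granularity - within one
  sentence, within one paragraph (different sentences), or document-only
  (different paragraphs) - with per-pair effect sizes (per-document plant
  probabilities);
* abstract counterparts holding a configurable, sentence-biased fraction of
  each document's mentions;
* PDF-artifact noise: reference lists, digit-heavy lines, broken-spacing
  text, non-English bodies written in a disjoint pseudo-word alphabet, and
  duplicated / concatenated files.

Everything planted or injected is logged in a :class:`SyntheticTruth` record
(serialisable as JSON lines) so tests can assert exact recovery.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ner import Dictionary

__all__ = [
    "GeneratorConfig",
    "ConfigurationError",
    "DictionaryTables",
    "SyntheticTruth",
    "SyntheticCorpus",
    "gen_dictionary",
    "gen_truth",
    "gen_corpus",
    "gen_gold_standard",
    "year_counts_schedule",
    "FILLER_WORDS",
]


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


# Filler vocabulary: common English words only (heavy stop-word overlap keeps
# the built-in language detector happy); entity names are pseudo-words built
# from a restricted syllable set and checked disjoint from this list.
FILLER_WORDS: tuple[str, ...] = tuple(
    """the of and to in was for that with are on as by this from at or an be
    it not we which have were but their can all been more one our these they
    had also between than when into during both each may such used results
    show found study data analysis method observed however therefore among
    across where while through well many less could would there about then
    under further over after before same within without given number case
    group level effect model value section sample measure change increase
    decrease present report describe compare approach condition response
    period range total mean standard clear strong weak small large early
    late recent common general specific related possible likely important
    consistent similar different several various initial final single
    overall relative direct indirect main broad narrow simple complex""".split()
)

_NAME_SYLLABLES = (
    "ba", "de", "fi", "go", "lu", "mo", "ny", "pe", "ra", "su",
    "ti", "wa", "bo", "da", "fe", "gi", "lo", "mu", "na", "po",
)
_PSEUDO_SYLLABLES = ("zaq", "xuv", "qik", "zov", "wyx", "quz", "xaq", "zyq")

SCORED_TYPES = ("gene", "disease", "compartment")
ASSOC_TYPE_PAIRS: dict[str, tuple[str, str]] = {
    "ppi": ("gene", "gene"),
    "disease_gene": ("disease", "gene"),
    "protein_compartment": ("gene", "compartment"),
}

_OTHER_CATEGORIES = (
    "Chemistry",
    "Life Sciences",
    "Engineering",
    "Physics",
    "Agriculture Sciences",
    "Earth Sciences",
    "Mathematical Sciences",
)


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic corpus.

    Defaults describe the regime the corpus-comparison analysis assumes: a
    2,000-document corpus growing with a 9.7-year doubling time, planted
    associations with low background co-mention noise, a substantial
    document-only share of plants, and abstracts echoing roughly half of each
    article's mentions with a bias toward sentence-level co-mentions.
    """

    n_documents: int = 2000
    years: tuple[int, int] = (1990, 2016)
    n_entities_per_type: Mapping[str, int] = field(
        default_factory=lambda: {"gene": 30, "disease": 15, "compartment": 10}
    )
    n_positive_pairs: int = 24
    granularity_mix: tuple[float, float, float] = (0.35, 0.25, 0.40)  # sentence/paragraph/document
    background_rate: float = 0.30
    abstract_fraction_of_mentions: float = 0.5
    abstract_presence_rate: float = 0.85
    noise_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "reference_list": 0.25,
            "digit_lines": 0.15,
            "broken_spacing": 0.01,
            "non_english": 0.02,
            "duplicate_concat": 0.01,
            "duplicate_copy": 0.01,
        }
    )
    seed: int = 0
    doubling_time_years: float = 9.7
    ambiguous_fraction: float = 0.0
    ontology_depth: int = 2
    effect_size_range: tuple[float, float] = (0.0008, 0.012)
    singles_per_doc: float = 1.0
    mention_trend: float = 0.0  # relative change of singles rate per year
    pathway_size: int = 3
    paragraphs_range: tuple[int, int] = (3, 6)
    sentences_range: tuple[int, int] = (2, 5)
    health_share: tuple[float, float] = (0.75, 0.25)
    line_width: int = 78

    def __post_init__(self):
        if self.n_documents <= 0:
            raise ConfigurationError("n_documents must be positive")
        if self.years[0] > self.years[1]:
            raise ConfigurationError("empty year range")
        for t, n in self.n_entities_per_type.items():
            if n < 2:
                raise ConfigurationError(f"need >= 2 entities per type, got {n} for {t}")
        mix = self.granularity_mix
        if any(m < 0 for m in mix) or abs(sum(mix) - 1.0) > 1e-9:
            raise ConfigurationError("granularity_mix must be non-negative and sum to 1")
        probs = [
            self.background_rate,
            self.abstract_fraction_of_mentions,
            self.abstract_presence_rate,
            self.ambiguous_fraction,
            *self.noise_rates.values(),
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigurationError("all probabilities must lie in [0, 1]")
        if self.doubling_time_years <= 0:
            raise ConfigurationError("doubling_time_years must be positive")
        lo, hi = self.effect_size_range
        if not (0 < lo <= hi <= 1):
            raise ConfigurationError("effect_size_range must satisfy 0 < lo <= hi <= 1")


# ---------------------------------------------------------------------------
# dictionary generation
# ---------------------------------------------------------------------------


@dataclass
class DictionaryTables:
    """Row-level dictionary content, writable as the four TSV files."""

    entities: list[tuple[int, str, str]]  # serial, type, identifier
    names: list[tuple[int, str]]  # serial, name
    groups: list[tuple[int, int]]  # child, parent
    stopwords: list[tuple[str, str]]  # name, flag
    leaf_serials: dict[str, list[int]] = field(default_factory=dict)

    def to_dictionary(self) -> Dictionary:
        entries = {s: (ident, etype) for s, etype, ident in self.entities}
        names: dict[str, set[int]] = {}
        for s, n in self.names:
            names.setdefault(n, set()).add(s)
        parents: dict[int, set[int]] = {}
        for c, p in self.groups:
            parents.setdefault(c, set()).add(p)
        stop = {n for n, flag in self.stopwords if flag.lower() in ("1", "true", "t", "yes")}
        return Dictionary(entries, names, stop, parents)

    def write(self, outdir: str) -> dict[str, str]:
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "entities": os.path.join(outdir, "entities.tsv"),
            "names": os.path.join(outdir, "names.tsv"),
            "groups": os.path.join(outdir, "groups.tsv"),
            "stopwords": os.path.join(outdir, "stopwords.tsv"),
        }
        with open(paths["entities"], "w", encoding="utf-8") as fh:
            for s, t, i in self.entities:
                fh.write(f"{s}\t{t}\t{i}\n")
        with open(paths["names"], "w", encoding="utf-8") as fh:
            for s, n in self.names:
                fh.write(f"{s}\t{n}\n")
        with open(paths["groups"], "w", encoding="utf-8") as fh:
            for c, p in self.groups:
                fh.write(f"{c}\t{p}\n")
        with open(paths["stopwords"], "w", encoding="utf-8") as fh:
            for n, flag in self.stopwords:
                fh.write(f"{n}\t{flag}\n")
        return paths


def _make_name(rng: np.random.Generator, taken: set[str]) -> str:
    """Pseudo-word entity name, disjoint from filler text and prior names."""
    forbidden = set(FILLER_WORDS)
    while True:
        k = int(rng.integers(3, 5))
        name = "".join(rng.choice(_NAME_SYLLABLES) for _ in range(k))
        if name not in forbidden and name not in taken:
            taken.add(name)
            return name


def gen_dictionary(config: GeneratorConfig) -> DictionaryTables:
    """Generate typed entity tables with names, stop words and ontologies.

    Every entity gets one unique pseudo-word name; a configurable fraction of
    names is additionally attached to an entity of another type, producing
    deliberately cross-type-ambiguous names.  Ontology types (disease,
    compartment) receive a rooted parent tree of the configured depth: the
    configured per-type count is the number of leaves, with internal terms
    added above them.  The leaf serials (the plantable terms) are recorded.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    taken: set[str] = set()
    entities: list[tuple[int, str, str]] = []
    names: list[tuple[int, str]] = []
    groups: list[tuple[int, int]] = []
    leaf_serials: dict[str, list[int]] = {}
    serial = 0

    def add_entity(etype: str, ident: str) -> int:
        nonlocal serial
        serial += 1
        entities.append((serial, etype, ident))
        names.append((serial, _make_name(rng, taken)))
        return serial

    for etype in SCORED_TYPES:
        n_leaves = int(config.n_entities_per_type.get(etype, 0))
        if etype == "gene" or config.ontology_depth < 1:
            leaf_serials[etype] = [
                add_entity(etype, f"{etype.upper()}:{i:04d}") for i in range(1, n_leaves + 1)
            ]
            continue
        # Rooted tree: root -> internal levels -> leaves.
        root = add_entity(etype, f"{etype.upper()}:ROOT")
        previous_level = [root]
        for depth in range(1, config.ontology_depth):
            width = max(2, n_leaves // (2 ** (config.ontology_depth - depth)))
            level = [
                add_entity(etype, f"{etype.upper()}:L{depth}.{i:03d}") for i in range(1, width + 1)
            ]
            for i, node in enumerate(level):
                groups.append((node, previous_level[i % len(previous_level)]))
            previous_level = level
        leaves = [add_entity(etype, f"{etype.upper()}:{i:04d}") for i in range(1, n_leaves + 1)]
        for i, node in enumerate(leaves):
            groups.append((node, previous_level[i % len(previous_level)]))
        leaf_serials[etype] = leaves

    # Cross-type ambiguous names: reuse an existing name for an entity of a
    # different type.
    n_ambiguous = int(round(config.ambiguous_fraction * len(names)))
    if n_ambiguous:
        serial_type = {s: t for s, t, _ in entities}
        pool = list(names)
        idx = rng.permutation(len(pool))
        added = 0
        for k in idx:
            if added >= n_ambiguous:
                break
            src_serial, name = pool[k]
            src_type = serial_type[src_serial]
            other_types = [t for t in SCORED_TYPES if t != src_type and leaf_serials.get(t)]
            if not other_types:
                continue
            tgt_type = other_types[int(rng.integers(len(other_types)))]
            tgt = leaf_serials[tgt_type][int(rng.integers(len(leaf_serials[tgt_type])))]
            if (tgt, name) not in names:
                names.append((tgt, name))
                added += 1

    stopwords = [("assay", "true"), ("control", "true")]
    return DictionaryTables(entities, names, groups, stopwords, leaf_serials)


# ---------------------------------------------------------------------------
# truth construction (planted associations)
# ---------------------------------------------------------------------------


@dataclass
class SyntheticTruth:
    """Complete record of everything planted or injected."""

    planted_pairs: dict[str, dict[tuple[int, int], float]] = field(default_factory=dict)
    pair_granularity: dict[str, dict[tuple[int, int], str]] = field(default_factory=dict)
    pathways: dict[str, list[int]] = field(default_factory=dict)
    per_document_plants: list[dict] = field(default_factory=list)
    mentions: dict[str, list[tuple[int, int, int]]] = field(default_factory=dict)
    abstract_mentions: dict[str, list[int]] = field(default_factory=dict)
    artifacts: list[dict] = field(default_factory=list)
    expected_discards: dict[str, str] = field(default_factory=dict)
    expected_dedup_drops: dict[str, str] = field(default_factory=dict)
    doc_structure: dict[str, list[int]] = field(default_factory=dict)
    year_counts: dict[int, int] = field(default_factory=dict)

    def write_jsonl(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for assoc, pairs in sorted(self.planted_pairs.items()):
                for (i, j), eff in sorted(pairs.items()):
                    fh.write(
                        json.dumps(
                            {
                                "kind": "planted_pair",
                                "assoc": assoc,
                                "i": i,
                                "j": j,
                                "effect": eff,
                                "granularity": self.pair_granularity.get(assoc, {}).get((i, j)),
                            },
                            sort_keys=True,
                        )
                        + "\n"
                    )
            for pw, members in sorted(self.pathways.items()):
                fh.write(
                    json.dumps({"kind": "pathway", "id": pw, "members": members}, sort_keys=True)
                    + "\n"
                )
            for rec in self.per_document_plants:
                fh.write(json.dumps({"kind": "plant", **rec}, sort_keys=True) + "\n")
            for doc_id, ms in sorted(self.mentions.items()):
                fh.write(
                    json.dumps({"kind": "mentions", "doc_id": doc_id, "at": ms}, sort_keys=True)
                    + "\n"
                )
            for rec in self.artifacts:
                fh.write(json.dumps({"kind": "artifact", **rec}, sort_keys=True) + "\n")


def gen_truth(config: GeneratorConfig, tables: DictionaryTables) -> SyntheticTruth:
    """Choose the planted association pairs and their effect sizes.

    Protein-protein positives arise from disjoint synthetic pathways (all
    within-pathway pairs are planted, so the pathway gold standard coincides
    with the planted signal); disease-gene and protein-compartment positives
    are sampled directly.  Effect sizes (per-document plant probabilities)
    are drawn log-uniformly from ``config.effect_size_range``.  Each pair is
    assigned its reporting granularity once, from ``granularity_mix``: a
    sentence-level association is always co-mentioned within a sentence, a
    document-only association is only ever co-mentioned across paragraphs -
    emulating associations that are discussed in context rather than stated
    in a single sentence, the signal the document weight exists to capture.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    truth = SyntheticTruth()

    def granularity() -> str:
        return ("sentence", "paragraph", "document")[
            int(rng.choice(3, p=config.granularity_mix))
        ]
    genes = list(tables.leaf_serials["gene"])
    diseases = list(tables.leaf_serials["disease"])
    compartments = list(tables.leaf_serials["compartment"])

    def effect() -> float:
        lo, hi = config.effect_size_range
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    # Pathways over disjoint gene groups.
    per_pathway = config.pathway_size * (config.pathway_size - 1) // 2
    n_pathways = max(2, math.ceil(config.n_positive_pairs / per_pathway))
    needed = n_pathways * config.pathway_size
    if needed > len(genes):
        raise ConfigurationError(
            f"need {needed} genes for {n_pathways} pathways of size {config.pathway_size}"
        )
    order = [genes[i] for i in rng.permutation(len(genes))]
    ppi: dict[tuple[int, int], float] = {}
    gran_ppi: dict[tuple[int, int], str] = {}
    for p in range(n_pathways):
        members = sorted(order[p * config.pathway_size : (p + 1) * config.pathway_size])
        truth.pathways[f"pw{p + 1:03d}"] = members
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                key = (members[a], members[b])
                ppi[key] = effect()
                gran_ppi[key] = granularity()
    truth.planted_pairs["ppi"] = ppi
    truth.pair_granularity["ppi"] = gran_ppi

    dg: dict[tuple[int, int], float] = {}
    gran_dg: dict[tuple[int, int], str] = {}
    while len(dg) < config.n_positive_pairs:
        d = diseases[int(rng.integers(len(diseases)))]
        g = genes[int(rng.integers(len(genes)))]
        key = (min(d, g), max(d, g))
        if key not in dg:
            dg[key] = effect()
            gran_dg[key] = granularity()
    truth.planted_pairs["disease_gene"] = dg
    truth.pair_granularity["disease_gene"] = gran_dg

    gc: dict[tuple[int, int], float] = {}
    gran_gc: dict[tuple[int, int], str] = {}
    gene_order = [genes[i] for i in rng.permutation(len(genes))]
    for k in range(config.n_positive_pairs):
        g = gene_order[k % len(gene_order)]
        c = compartments[int(rng.integers(len(compartments)))]
        key = (min(g, c), max(g, c))
        if key in gc:
            continue
        gc[key] = effect()
        gran_gc[key] = granularity()
    truth.planted_pairs["protein_compartment"] = gc
    truth.pair_granularity["protein_compartment"] = gran_gc
    return truth


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------


def year_counts_schedule(config: GeneratorConfig) -> dict[int, int]:
    """Per-year document counts: round(c * 2^((year - y0) / doubling_time)).

    The scale c is set so the rounded counts total approximately
    ``config.n_documents``.
    """
    y0, y1 = config.years
    years = list(range(y0, y1 + 1))
    weights = np.array([2.0 ** ((y - y0) / config.doubling_time_years) for y in years])
    c = config.n_documents / weights.sum()
    counts = {y: int(round(c * w)) for y, w in zip(years, weights)}
    return {y: n for y, n in counts.items() if n > 0}


@dataclass
class SyntheticCorpus:
    """Generated raw article files plus metadata."""

    documents: dict[str, list[str]]  # doc_id -> raw body lines
    abstracts: dict[str, list[str]]  # doc_id -> raw abstract lines
    metadata: pd.DataFrame

    def write(self, outdir: str) -> dict[str, str]:
        body_dir = os.path.join(outdir, "fulltext")
        abs_dir = os.path.join(outdir, "abstracts")
        os.makedirs(body_dir, exist_ok=True)
        os.makedirs(abs_dir, exist_ok=True)
        for doc_id in sorted(self.documents):
            with open(os.path.join(body_dir, f"{doc_id}.txt"), "w", encoding="utf-8") as fh:
                fh.write("\n".join(self.documents[doc_id]) + "\n")
        for doc_id in sorted(self.abstracts):
            with open(os.path.join(abs_dir, f"{doc_id}.txt"), "w", encoding="utf-8") as fh:
                fh.write("\n".join(self.abstracts[doc_id]) + "\n")
        meta_path = os.path.join(outdir, "metadata.tsv")
        self.metadata.to_csv(meta_path, sep="\t", index=False)
        return {"fulltext": body_dir, "abstracts": abs_dir, "metadata": meta_path}


def _wrap_paragraph(text: str, width: int) -> list[str]:
    """Hard-wrap paragraph text, PDF-style, without creating line breaks at
    sentence boundaries (so reflow can reconstruct paragraphs exactly)."""
    words = text.split()
    lines: list[list[str]] = []
    cur: list[str] = []
    cur_len = 0
    for w in words:
        add = len(w) + (1 if cur else 0)
        if cur and cur_len + add > width:
            lines.append(cur)
            cur, cur_len = [w], len(w)
        else:
            cur.append(w)
            cur_len += add
    if cur:
        lines.append(cur)
    # A non-final line must not end with terminal punctuation.
    i = 0
    while i < len(lines) - 1:
        if lines[i] and lines[i][-1][-1] in ".!?" and len(lines[i]) > 1:
            lines[i + 1].insert(0, lines[i].pop())
        else:
            i += 1
    # A very short final line (a stray "word.") would trip the 10% symbol
    # filter; fold it into the previous line.
    if len(lines) > 1 and sum(len(w) for w in lines[-1]) < 12:
        lines[-2].extend(lines.pop())
    return [" ".join(ws) for ws in lines]


def _render_sentence(words: Sequence[str]) -> str:
    first = words[0][0].upper() + words[0][1:]
    rest = " ".join(words[1:])
    return (first + " " + rest if rest else first) + "."


class _DocBuilder:
    """Sentence-grid builder for one document.

    Pair plants reserve their sentence slots exclusively, so two different
    planted pairs never share a sentence and the co-mention ground truth is
    exact; singleton mentions use unreserved slots only.
    """

    def __init__(self, rng: np.random.Generator, config: GeneratorConfig):
        self.rng = rng
        self.n_para = int(rng.integers(config.paragraphs_range[0], config.paragraphs_range[1] + 1))
        self.n_sents = [
            int(rng.integers(config.sentences_range[0], config.sentences_range[1] + 1))
            for _ in range(self.n_para)
        ]
        self.words: list[list[list[str]]] = [
            [
                [FILLER_WORDS[i] for i in rng.integers(0, len(FILLER_WORDS), int(rng.integers(5, 10)))]
                for _ in range(ns)
            ]
            for ns in self.n_sents
        ]
        self.placed: dict[tuple[int, int], set[int]] = {}
        self.reserved: set[tuple[int, int]] = set()

    def free_slots(self, paragraph: int | None = None) -> list[tuple[int, int]]:
        slots = [
            (p, s)
            for p in (range(self.n_para) if paragraph is None else [paragraph])
            for s in range(self.n_sents[p])
            if (p, s) not in self.reserved
        ]
        return slots

    def insert(self, p: int, s: int, serial: int, name: str, reserve: bool = False) -> bool:
        key = (p, s)
        placed = self.placed.setdefault(key, set())
        if reserve:
            self.reserved.add(key)
        if serial in placed:
            return False
        pos = int(self.rng.integers(1, len(self.words[p][s]) + 1))
        self.words[p][s].insert(pos, name)
        placed.add(serial)
        return True

    def render_paragraphs(self) -> list[str]:
        return [
            " ".join(_render_sentence(ws) for ws in para)
            for para in self.words
        ]


def _reference_block(rng: np.random.Generator, marker: str, max_refs: int) -> list[str] | None:
    """Heading + bracketed reference lines; None when the body is too short
    for the block to sit inside the back-matter scan's tail region."""
    n = min(int(rng.integers(3, 7)), max_refs)
    if n < 3:
        return None
    lines = ["References"]
    for k in range(1, n + 1):
        body = " ".join(FILLER_WORDS[i] for i in rng.integers(0, len(FILLER_WORDS), 8))
        lines.append(f"[{k}] {body} {marker}")
    return lines


def _digit_line(rng: np.random.Generator) -> str:
    nums = " ".join(str(int(rng.integers(10, 9999))) for _ in range(int(rng.integers(4, 8))))
    return f"table {nums}"


def _break_spacing(lines: list[str]) -> list[str]:
    return [" ".join(" ".join(w) for w in line.split()) for line in lines]


def _pseudo_language_lines(rng: np.random.Generator, width: int) -> list[str]:
    paras = []
    for _ in range(int(rng.integers(2, 4))):
        sents = []
        for _ in range(int(rng.integers(2, 5))):
            ws = [
                "".join(rng.choice(_PSEUDO_SYLLABLES) for _ in range(int(rng.integers(2, 4))))
                for _ in range(int(rng.integers(5, 10)))
            ]
            sents.append(_render_sentence(ws))
        paras.append(" ".join(sents))
    out: list[str] = []
    for p in paras:
        out.extend(_wrap_paragraph(p, width))
    return out


def gen_corpus(
    config: GeneratorConfig, tables: DictionaryTables, truth: SyntheticTruth
) -> SyntheticCorpus:
    """Generate raw article files, abstracts and metadata; fill the truth log.

    Per-year counts follow the exponential schedule; planted pairs co-occur
    at their sampled granularity; abstracts echo a sentence-biased fraction
    of mentions; noise artifacts are injected at the configured rates, each
    logged with its expected downstream consequence.  Deterministic given the
    config (identical config implies byte-identical output files).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    dictionary = tables.to_dictionary()
    name_of: dict[int, str] = {}
    for s, n in tables.names:
        name_of.setdefault(s, n)  # first (unambiguous) name per serial

    schedule = year_counts_schedule(config)
    truth.year_counts = dict(schedule)
    y0, y1 = config.years

    all_planted = [
        (assoc, pair, eff)
        for assoc, pairs in truth.planted_pairs.items()
        for pair, eff in sorted(pairs.items())
    ]
    planted_keys = {
        (assoc, pair) for assoc, pairs in truth.planted_pairs.items() for pair in pairs
    }
    leaf = tables.leaf_serials
    scored_leaves = sorted(set().union(*(leaf[t] for t in SCORED_TYPES)))

    # duplicate artifacts are handled after the main pass (they need the
    # finished documents); all other kinds are mutually exclusive per doc
    noise_kinds = [k for k in sorted(config.noise_rates) if not k.startswith("duplicate")]
    documents: dict[str, list[str]] = {}
    abstracts: dict[str, list[str]] = {}
    meta_rows: list[dict] = []
    clean_doc_ids: list[str] = []

    doc_no = 0
    for year in sorted(schedule):
        for _ in range(schedule[year]):
            doc_no += 1
            doc_id = f"doc{doc_no:05d}"
            # Artifact assignment: at most one per document.
            artifact = None
            u = float(rng.random())
            acc = 0.0
            for kind in noise_kinds:
                acc += config.noise_rates[kind]
                if u < acc:
                    artifact = kind
                    break
            has_abstract = bool(rng.random() < config.abstract_presence_rate)

            builder = _DocBuilder(rng, config)
            doc_mentions: list[tuple[int, int, int]] = []
            abstract_events: list[tuple[str, object]] = []

            if artifact not in ("broken_spacing", "non_english"):
                # planted associations
                for assoc, (i, j), eff in all_planted:
                    if rng.random() >= eff:
                        continue
                    gran = truth.pair_granularity[assoc][(i, j)]
                    if not _place_pair(builder, rng, i, j, gran, name_of, doc_mentions):
                        continue
                    truth.per_document_plants.append(
                        {"doc_id": doc_id, "assoc": assoc, "i": i, "j": j, "granularity": gran}
                    )
                    abstract_events.append(("pair", (i, j, gran)))
                # background co-mention
                if rng.random() < config.background_rate:
                    assoc = sorted(ASSOC_TYPE_PAIRS)[int(rng.integers(len(ASSOC_TYPE_PAIRS)))]
                    ta, tb = ASSOC_TYPE_PAIRS[assoc]
                    for _try in range(20):
                        i = leaf[ta][int(rng.integers(len(leaf[ta])))]
                        j = leaf[tb][int(rng.integers(len(leaf[tb])))]
                        if i == j:
                            continue
                        key = (min(i, j), max(i, j))
                        if (assoc, key) in planted_keys:
                            continue
                        gran = ("sentence", "paragraph", "document")[
                            int(rng.choice(3, p=config.granularity_mix))
                        ]
                        if _place_pair(builder, rng, i, j, gran, name_of, doc_mentions):
                            abstract_events.append(("pair", (i, j, gran)))
                        break
                # singleton mentions
                rate = config.singles_per_doc * (
                    1.0 + config.mention_trend * (year - y0)
                )
                for _ in range(int(rng.poisson(max(0.0, rate)))):
                    s = scored_leaves[int(rng.integers(len(scored_leaves)))]
                    free = builder.free_slots()
                    if not free:
                        continue
                    p, q = free[int(rng.integers(len(free)))]
                    if builder.insert(p, q, s, name_of[s]):
                        doc_mentions.append((p, q, s))
                        abstract_events.append(("single", s))

            # render body
            paragraphs = builder.render_paragraphs()
            lines: list[str] = []
            for ptext in paragraphs:
                lines.extend(_wrap_paragraph(ptext, config.line_width))

            if artifact == "non_english":
                lines = _pseudo_language_lines(rng, config.line_width)
                truth.expected_discards[doc_id] = "non_english"
                truth.artifacts.append({"doc_id": doc_id, "artifact": "non_english"})
            elif artifact == "broken_spacing":
                lines = _break_spacing(lines)
                truth.expected_discards[doc_id] = "low_avg_word_length"
                truth.artifacts.append({"doc_id": doc_id, "artifact": "broken_spacing"})
            else:
                if artifact == "digit_lines":
                    n_inserted = int(rng.integers(2, 6))
                    for _ in range(n_inserted):
                        pos = int(rng.integers(0, len(lines) + 1))
                        lines.insert(pos, _digit_line(rng))
                    truth.artifacts.append(
                        {"doc_id": doc_id, "artifact": "digit_lines", "n_lines": n_inserted}
                    )
                if artifact == "reference_list":
                    marker = "zzrefmarkerzz"
                    block = _reference_block(rng, marker, max_refs=len(lines) - 2)
                    if block is not None:
                        lines = lines + block
                        truth.artifacts.append(
                            {"doc_id": doc_id, "artifact": "reference_list", "marker": marker}
                        )
                truth.doc_structure[doc_id] = list(builder.n_sents)

            documents[doc_id] = lines
            truth.mentions[doc_id] = doc_mentions
            if artifact is None:
                clean_doc_ids.append(doc_id)

            # abstract: one paragraph echoing a biased fraction of mentions
            if has_abstract:
                af = config.abstract_fraction_of_mentions
                abs_sents: list[str] = []
                abs_serials: list[int] = []
                for kind, payload in abstract_events:
                    if kind == "pair":
                        i, j, gran = payload
                        if gran == "sentence":
                            if rng.random() < af:
                                ws = [
                                    FILLER_WORDS[k]
                                    for k in rng.integers(0, len(FILLER_WORDS), 5)
                                ]
                                ws.insert(1, name_of[i])
                                ws.insert(3, name_of[j])
                                abs_sents.append(_render_sentence(ws))
                                abs_serials.extend([i, j])
                        else:
                            for s in (i, j):
                                if rng.random() < af / 2:
                                    ws = [
                                        FILLER_WORDS[k]
                                        for k in rng.integers(0, len(FILLER_WORDS), 5)
                                    ]
                                    ws.insert(1, name_of[s])
                                    abs_sents.append(_render_sentence(ws))
                                    abs_serials.append(s)
                    else:
                        s = payload
                        if rng.random() < af / 2:
                            ws = [FILLER_WORDS[k] for k in rng.integers(0, len(FILLER_WORDS), 5)]
                            ws.insert(1, name_of[s])
                            abs_sents.append(_render_sentence(ws))
                            abs_serials.append(s)
                if not abs_sents:
                    ws = [FILLER_WORDS[k] for k in rng.integers(0, len(FILLER_WORDS), 8)]
                    abs_sents.append(_render_sentence(ws))
                abstracts[doc_id] = _wrap_paragraph(" ".join(abs_sents), config.line_width)
                truth.abstract_mentions[doc_id] = abs_serials

            health_p = config.health_share[0] + (
                (config.health_share[1] - config.health_share[0]) * (year - y0) / max(1, y1 - y0)
            )
            cats = []
            if rng.random() < health_p:
                cats.append("Health Sciences")
            if not cats or rng.random() < 0.2:
                cats.append(_OTHER_CATEGORIES[int(rng.integers(len(_OTHER_CATEGORIES)))])
            meta_rows.append(
                {
                    "doc_id": doc_id,
                    "year": year,
                    "journal": f"journal{int(rng.integers(1, 40)):02d}",
                    "issn": f"{int(rng.integers(1000, 9999))}-{int(rng.integers(1000, 9999))}",
                    "pages": int(builder.n_para + rng.poisson(2)),
                    "categories": ";".join(sorted(set(cats))),
                    "has_abstract": has_abstract,
                    "corpus": "full_text",
                }
            )

    # Duplicate artifacts: exact copies and concatenations of clean documents.
    extras: list[tuple[str, list[str], int]] = []
    meta_by_id = {r["doc_id"]: r for r in meta_rows}
    copy_no = 0
    cat_no = 0
    for doc_id in list(clean_doc_ids):
        for kind, rate in (
            ("duplicate_copy", config.noise_rates.get("duplicate_copy", 0.0)),
            ("duplicate_concat", config.noise_rates.get("duplicate_concat", 0.0)),
        ):
            if rng.random() >= rate:
                continue
            if kind == "duplicate_copy":
                copy_no += 1
                new_id = f"dup{copy_no:05d}"
                extras.append((new_id, list(documents[doc_id]), meta_by_id[doc_id]["year"]))
                survivor = min(doc_id, new_id)
                dropped = max(doc_id, new_id)
                truth.expected_dedup_drops[dropped] = survivor
                truth.artifacts.append(
                    {"doc_id": new_id, "artifact": "duplicate_copy", "of": doc_id}
                )
            else:
                others = [d for d in clean_doc_ids if d != doc_id]
                if not others:
                    continue
                partner = others[int(rng.integers(len(others)))]
                cat_no += 1
                new_id = f"cat{cat_no:05d}"
                extras.append(
                    (
                        new_id,
                        list(documents[doc_id]) + list(documents[partner]),
                        max(meta_by_id[doc_id]["year"], meta_by_id[partner]["year"]),
                    )
                )
                truth.expected_dedup_drops[new_id] = min(doc_id, partner)
                truth.artifacts.append(
                    {
                        "doc_id": new_id,
                        "artifact": "duplicate_concat",
                        "parts": [doc_id, partner],
                    }
                )
    for new_id, lines, year in extras:
        documents[new_id] = lines
        meta_rows.append(
            {
                "doc_id": new_id,
                "year": year,
                "journal": "journal99",
                "issn": "0000-0000",
                "pages": max(1, len(lines) // 12),
                "categories": "Health Sciences",
                "has_abstract": False,
                "corpus": "full_text",
            }
        )

    metadata = pd.DataFrame(meta_rows).sort_values("doc_id").reset_index(drop=True)
    return SyntheticCorpus(documents=documents, abstracts=abstracts, metadata=metadata)


def _place_pair(
    builder: _DocBuilder,
    rng: np.random.Generator,
    i: int,
    j: int,
    granularity: str,
    name_of: Mapping[int, str],
    doc_mentions: list[tuple[int, int, int]],
) -> None:
    """Place the two names of a pair into reserved sentence slots.

    sentence: both names in one sentence; paragraph: same paragraph,
    different sentences; document: different paragraphs.  Returns False
    (placing nothing) when the document has no free slots left for the
    requested granularity.
    """
    free = builder.free_slots()
    if granularity == "sentence":
        if not free:
            return False
        p, s = free[int(rng.integers(len(free)))]
        spots = [(p, s), (p, s)]
    elif granularity == "paragraph":
        by_para: dict[int, list[tuple[int, int]]] = {}
        for p, s in free:
            by_para.setdefault(p, []).append((p, s))
        candidates = sorted(p for p, slots in by_para.items() if len(slots) >= 2)
        if not candidates:
            return False
        p = candidates[int(rng.integers(len(candidates)))]
        picks = rng.choice(len(by_para[p]), size=2, replace=False)
        spots = [by_para[p][int(k)] for k in picks]
    elif granularity == "document":
        paras = sorted({p for p, _ in free})
        if len(paras) < 2:
            return False
        p1, p2 = (paras[int(k)] for k in rng.choice(len(paras), size=2, replace=False))
        slots1 = [t for t in free if t[0] == p1]
        slots2 = [t for t in free if t[0] == p2]
        spots = [
            slots1[int(rng.integers(len(slots1)))],
            slots2[int(rng.integers(len(slots2)))],
        ]
    else:
        raise ValueError(f"unknown granularity {granularity!r}")
    for serial, (p, s) in zip((i, j), spots):
        if builder.insert(p, s, serial, name_of[serial], reserve=True):
            doc_mentions.append((p, s, serial))
    return True


# ---------------------------------------------------------------------------
# gold-standard emission
# ---------------------------------------------------------------------------


def gen_gold_standard(
    truth: SyntheticTruth,
    tables: DictionaryTables,
    mode: str,
    seed: int | None = None,
) -> list[tuple[str, str]]:
    """Emit gold-standard input rows consistent with the planted pairs.

    * ``pathway``: (pathway_id, protein identifier) memberships;
    * ``shuffle``: (disease identifier, gene identifier) known associations;
    * ``compartment``: (protein identifier, compartment identifier)
      annotations.

    An empty truth yields empty rows.  Unknown modes raise ValueError.
    """
    dictionary = tables.to_dictionary()
    ident = dictionary.identifier
    if mode == "pathway":
        return [
            (pw, ident(m)) for pw, members in sorted(truth.pathways.items()) for m in members
        ]
    if mode == "shuffle":
        rows = []
        types = {s: t for s, t, _ in tables.entities}
        for (a, b) in sorted(truth.planted_pairs.get("disease_gene", {})):
            d, g = (a, b) if types[a] == "disease" else (b, a)
            rows.append((ident(d), ident(g)))
        return rows
    if mode == "compartment":
        rows = []
        types = {s: t for s, t, _ in tables.entities}
        for (a, b) in sorted(truth.planted_pairs.get("protein_compartment", {})):
            g, c = (a, b) if types[a] == "gene" else (b, a)
            rows.append((ident(g), ident(c)))
        return rows
    raise ValueError(f"unknown gold-standard mode {mode!r}")
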
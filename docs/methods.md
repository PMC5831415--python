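# Methods

This note documents the models and procedures implemented in `litcooc`, the
assumptions behind them, the tunable parameters, and the design choices made
where several defensible readings existed. Every number quoted here is
computed by the test suite or by `scripts/acceptance.py`; nothing is
asserted that the code does not itself measure.

## Preprocessing of PDF-extracted text

The preprocessing model assumes articles arrive as plain text produced by a
PDF-to-text converter: hard line wraps inside sentences, page/column breaks,
and artifact lines (tables, headers) interleaved with prose.

**Line filters.** Non-printable characters are deleted (tabs become single
spaces). A line is removed when, over its non-whitespace characters, the
digit fraction exceeds 0.10, the symbol fraction (anything outside
`[0-9A-Za-z]`) exceeds 0.10, or the lowercase fraction falls below 0.50. All
three thresholds are strict inequalities and configurable
(`LineFilterConfig`). Whether the denominators should include whitespace is
genuinely ambiguous; we exclude it, which makes the thresholds independent
of indentation and wrap width.

**Back matter.** Acknowledgments and reference lists are assumed to sit at
the end of the article, so triggers are honoured only in the final 50% of
lines — this stops the word "literature" in running text from truncating an
article. Two triggers are recognised: a heading line (trimmed, lowercased,
≤ 40 characters, starting with one of the section keywords, misspellings
included) or a run of ≥ 3 consecutive lines matching `^\[\d+\]\s[A-Za-z]`.
A single bracketed line is treated as an in-text artifact, not a reference
list. The earliest trigger wins; when a run fires directly below a heading
the heading is included in the cut, which keeps truncation idempotent.
Articles without a detectable reference list are flagged, never discarded.

**Reflow.** A line continues the current sentence chunk when the previous
line lacks terminal punctuation (`.!?`); it continues the current paragraph
as a *new* sentence when the previous line ends with terminal punctuation
but the line starts lowercase; otherwise a new paragraph begins. Paragraph
chunks are split into sentences at terminal punctuation followed by
whitespace and an uppercase letter or digit (so "v. small" does not split).
The disjunctive continuation rule is one of two possible readings of the
underlying heuristic; the conjunctive alternative (continuation only when
the previous line lacks punctuation *and* the line does not start
lowercase) is available as `strict_as_printed=True`. We default to the
disjunctive reading because a lowercase-starting line is the clearest
continuation signal a wrapped text can give.

**Article filters**, applied in a fixed order so every discard has exactly
one primary reason: empty text; non-English; mean word length below the
corpus 2% quantile; administrative blacklist keyword. The word-length
statistic treats a word as a maximal non-whitespace run and the quantile is
computed with linear interpolation over the whole corpus in a first pass —
it is a relative filter, so roughly 2% of articles fall below it even in a
clean corpus; its purpose is that *catastrophic* extractions (every
character space-separated, mean word length ≈ 1) fall far below it.
Blacklist keywords are matched case-insensitively, but only on heading-like
lines (≤ 40 characters), so an article merely citing an erratum is not
discarded.

**Language detection** is a pluggable predicate. The built-in default
scores the fraction of multi-character alphabetic tokens found in a small
built-in English stop-word list (threshold 0.15). It abstains (returns
English) when fewer than five such tokens exist: a document consisting
entirely of single-character tokens carries no lexical evidence either way,
and the word-length filter is the correct instrument for that failure mode.

**Deduplication** normalises text (lowercase, collapsed whitespace) and
tests exact containment. Exact duplicates keep one copy (smallest id). A
file that strictly contains two or more other files is a
conference-proceedings concatenation whose parts exist independently: the
parts are kept, the container dropped. A file contained in a single kept
superset is dropped in favour of the superset.

## Named entity recognition

Tagging is dictionary-based: left-to-right, longest match, non-overlapping,
anchored at token boundaries (a match must be flanked by non-alphanumeric
characters or string edges, so "CAT" cannot match inside "sCATter").
Matching is case-insensitive by default with a per-name case-sensitive flag
in the names file. Stop-worded names are suppressed at load time. The
matcher is contracted to equal a brute-force scan of every name at every
position (tested against exactly that oracle); the token-anchored hashed
lookup is an internal acceleration.

A name mapping to serials of more than one entity type — including the
auxiliary dictionary types loaded purely to absorb ambiguity — is discarded
as ambiguous. Names mapping to several serials of the *same* type (e.g.
paralogous genes) are kept and contribute to all their serials.

Ontology-backed types propagate every mention to all ancestor terms at the
same location, with duplicates collapsed, so diamond-shaped parent paths
count an ancestor once. The serial set at a location is therefore closed
under the ancestor relation.

## Co-occurrence scoring

δ in the weighted count is read as a per-document indicator: each
granularity level fires at most once per document per pair. A per-instance
counting mode (number of shared paragraphs/sentences) exists behind the
`per_instance` flag for sensitivity analysis. Defaults: w_d = 1.0,
w_p = 2.0, w_s = 0.2, α = 0.6; a grid-search operation
(`optimize_weights`) can re-calibrate them against the pathway benchmark,
with exact ties broken toward these defaults.

Marginals C_i· and the total C·· are computed within one entity-type pair
(all disease–gene pairs, say), because the normalisation in S is
meaningless across heterogeneous type spaces. Self-pairs and
ancestor–descendant pairs are excluded: backtracking would otherwise
guarantee a spurious association between a term and its own parent.
Abstracts reflow to single-paragraph documents, so the paragraph weight
fires for any same-abstract co-mention — the structural reason abstract
corpora are insensitive to the document weight.

The Z conversion standardises log S over all pairs with S > 0 using the
unbiased (n−1) standard deviation; pairs with S = 0 carry a −∞ sentinel.
The choice of standardisation cannot affect any benchmark result: the
transform is strictly monotone in S, and all evaluation is rank-based
(asserted by a dedicated invariance test).

## Benchmarking

ROC curves sweep thresholds over unique scores in descending order; tied
scores advance as a single step, AUC is the trapezoidal area (equal to the
Mann–Whitney U statistic divided by n_pos·n_neg on tie-free data, tested
against both scikit-learn and scipy), and TPR@10%FPR is linearly
interpolated. Gold-standard pairs never co-mentioned in the corpus are
included with a sentinel score below every real value: excluding them would
silently inflate AUC whenever recall is imperfect. The shuffle benchmark
permutes the gene column with an explicit seed (default 42) and discards
collisions with the positives.

## The synthetic-corpus generator

The generator defines the study conditions under which the pipeline's
claims are exercised. Defaults: 2,000 documents over 1990–2016 with a
9.7-year doubling time; 30 genes, 15 diseases and 10 compartment leaf terms
(diseases and compartments carry a depth-2 rooted parent ontology); 24
positive pairs per association type (protein–protein positives arise from
eight disjoint 3-gene pathways, so the pathway gold standard coincides with
the planted signal); per-pair effect sizes — per-document co-mention
probabilities — drawn log-uniformly from [0.0008, 0.012], giving pairs
between ~2 and ~25 supporting documents; a background rate of 0.30 random
non-planted co-mentions per document; one singleton mention per document on
average.

**Granularity is a per-pair property.** Each planted pair is assigned once,
from the mix (0.35 sentence, 0.25 paragraph, 0.40 document-only), the level
at which it is ever co-mentioned. This emulates the real distinction
between associations stated in a single sentence and associations only
discussed in context across paragraphs, and it is what makes the
document-weight ablation structural: with a per-event assignment every pair
would accumulate sentence-level evidence and the document weight would have
nothing specific to capture.

**Exact truth.** Filler text is drawn from a fixed list of common English
words checked disjoint from every generated entity name, and pair plants
reserve their sentence slots exclusively, so the truth log of mentions and
co-mentions is exact — NER precision and recall are 1.0 on noiseless
corpora by construction, and any co-mention is either a plant, a logged
background event, or a collision between singleton mentions.

**Abstracts** echo a sentence-biased fraction of each document's mentions:
a sentence-level co-mention is copied whole with probability 0.5, while
each side of a paragraph/document-level co-mention (and each singleton) is
echoed independently at half that rate — so non-sentence associations
rarely survive into the abstract with both partners. 85% of articles have
an abstract; the "MEDLINE-like" corpus is all abstracts, "core abstracts"
are those whose full text also survived filtering.

**Noise artifacts** are mutually exclusive per document and each is logged
with its expected downstream consequence: appended reference lists (with a
marker token so truncation can be verified), digit-heavy inserted lines,
broken-spacing bodies (every word space-separated — expected discard:
low mean word length), non-English bodies written in a disjoint
pseudo-word alphabet that no English stop word matches (expected discard:
non-English), byte-identical copies and two-article concatenations
(expected dedup resolution). Reference blocks are skipped for bodies too
short to keep the block inside the back-matter tail region.

What the generator does *not* emulate: realistic scientific prose,
citation-network structure, abbreviation or coreference phenomena,
cross-sentence relations beyond co-occurrence, and entity-name morphology
(plurals, hyphenation). Passing tests therefore certify the pipeline's
mechanics and the direction of its corpus-level comparisons, not NER
accuracy on real biomedical text.

## Numerical choices and degenerate inputs

Growth fitting excludes zero-count years (log undefined) and requires at
least three positive years; a non-positive slope raises a warning and
leaves the doubling time undefined. Doubling times are reported to one
decimal. Page-bin edges are the 25/50/75% quantiles rounded half-up with
right-closed bins; fixed edges (4, 7, 10 — i.e. 1–4/5–7/8–10/11+) can be
imposed via config. The Z transform refuses fewer than two distinct
positive scores (degenerate scale). The comparison driver ranks by S
directly, which is equivalent to ranking by Z and avoids the degenerate
case on tiny corpora. Pipeline problem sizes (2,000-document comparison
corpus, 600-document preprocessing-accounting corpus, ≤ 50-document oracle
corpora) keep every stage exact or well-powered while the whole suite runs
in well under a minute.

## Known limitations

* The disjunctive reflow rule and the token-boundary/case conventions of
  the tagger are defaults for genuinely under-determined choices; both are
  configurable and flagged above rather than attributed.
* `strip_back_matter` is idempotent on realistic documents, but an
  adversarial document with a second heading planted mid-text above a
  trailing reference run can require two passes.
* Benchmark AUCs on synthetic corpora depend on the generator's effect-size
  and noise regime; they demonstrate ordering and ablation structure, not
  absolute performance on real literature.
* Deduplication is O(n²) in the number of kept documents (exact substring
  containment); adequate for the corpus sizes generated here.
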
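# litcooc

Literature co-occurrence mining for systems biology: extract
protein–protein, disease–gene and protein–subcellular-compartment
associations from raw full-text article collections and quantify, against
gold-standard benchmarks, how much is gained by mining full texts instead of
abstracts only.

Most biomedical text mining runs on abstracts because they are easy to get.
Full-text articles, however, usually arrive as PDF-extracted plain text:
hard-wrapped lines, digit-heavy table fragments, reference lists that repeat
entity names from cited titles, broken extractions with a space between
every character, non-English articles, and conference-proceedings files
holding several articles at once. `litcooc` implements the whole chain
needed to work with such corpora, together with a synthetic-corpus generator
that makes every stage testable — and the abstract-versus-full-text
comparison reproducible — without any licensed data.

## The method

**Cleaning and filtering.** Non-printable characters are removed; a line is
dropped when digits or symbols exceed 10% of its characters or lowercase
falls below 50%. Acknowledgments and reference lists are truncated at a
trailing heading (`references`, `bibliography`, … including common
misspellings) or at a run of bracketed references matching
`^\[\d+\]\s[A-Za-z]`. Wrapped lines are reflowed into sentences and
paragraphs; whole articles are discarded when empty, non-English, below the
corpus 2% quantile of mean word length (the signature of broken-spacing
extractions), or carrying administrative keywords (Erratum, Editorial Board,
…). Duplicate and subset files (conference proceedings) resolve to one copy.

**NER.** Dictionary-based tagging: left-to-right longest match at token
boundaries, case-insensitive, with stop-word suppression. A name found in
dictionaries of different entity types is discarded as ambiguous. Mentions of
ontology terms (diseases, compartments) are backtracked through all parents,
so e.g. a *type 1 diabetes mellitus* mention also counts for *diabetes
mellitus* and every further ancestor.

**Scoring.** For each entity pair (i, j), a weighted co-occurrence count
over documents k,

```
C(i,j) = Σ_k  w_d δ_d^k(i,j) + w_p δ_p^k(i,j) + w_s δ_s^k(i,j)
```

where δ indicates co-occurrence within the same document, paragraph, or
sentence, with weights w_d = 1.0, w_p = 2.0, w_s = 0.2. The association
score interpolates between the raw count and an observed/expected ratio
against the marginals,

```
S(i,j) = C_ij^α · (C_ij C·· / (C_i· C·j))^(1−α),   α = 0.6
```

and is standardised to a Z score (monotone, so rank-based evaluation is
unaffected).

**Benchmarking.** Three gold standards: pathway co-membership
(protein–protein), known disease–gene pairs versus a shuffled-column
negative set, and protein–compartment annotations versus their complement.
Ranked scores are swept into ROC curves (TPR = TP/P, FPR = 1 − TN/N),
summarised by AUC and TPR@10%FPR. Gold pairs never co-mentioned enter with a
sentinel score below all real values, so recall losses stay visible.
Re-scoring with w_d = 0 isolates the contribution of document-level
(cross-paragraph) context.

## Worked example

Run the four-corpus comparison on the default synthetic study (2,000
articles, 1990–2016, three planted association types, PDF-artifact noise):

```python
import litcooc as lc
from litcooc.pipeline import RunConfig, run_comparison

cfg = RunConfig(generator=lc.GeneratorConfig(seed=0))
df = run_comparison(cfg)
print(df.pivot_table(index=["benchmark", "corpus"],
                     columns="weight_mode", values="auc").round(3))
```

prints

```
weight_mode                         default  no_document_weight
benchmark           corpus
disease_gene        all_fulltext      0.861               0.752
                    core_abstracts    0.648               0.650
                    core_fulltext     0.838               0.723
                    medline_like      0.648               0.652
ppi                 all_fulltext      0.904               0.713
                    core_abstracts    0.748               0.749
                    core_fulltext     0.910               0.735
                    medline_like      0.748               0.749
protein_compartment all_fulltext      0.947               0.856
                    core_abstracts    0.771               0.771
                    core_fulltext     0.897               0.794
                    medline_like      0.771               0.771
```

Reading the table: full-text corpora (`all_fulltext`, `core_fulltext`)
out-rank the matched abstract corpora (`core_abstracts`, `medline_like`) on
every benchmark — associations reported only in the article body are
invisible to abstract mining. Setting the document weight to zero
(`no_document_weight`) costs the full-text corpora 0.09–0.19 AUC while
leaving abstracts essentially unchanged (abstracts are one paragraph, so the
document level adds nothing there).

The same pipeline is available from the shell:

```
litcooc generate --seed 0 --out corpus/
litcooc preprocess --corpus-dir corpus/ --out cleaned/
litcooc compare --seed 0 --out summary.tsv
litcooc stats --seed 0 --out stats/
```

`litcooc stats` also fits the corpus growth model: yearly publication
counts follow `c · 2^(year/T)`; an ordinary least-squares fit of log₂
counts gives the growth rate and the doubling time T = 1/slope (the default
synthetic corpus uses T = 9.7 years).

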
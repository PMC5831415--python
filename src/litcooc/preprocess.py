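"""Cleaning and filtering of raw PDF-extracted article text.

Raw text dumped out of PDFs is noisy: hard line wraps in the middle of
sentences, page headers full of digits, reference lists that repeat entity
names from cited titles, and occasional documents whose extraction failed
altogether (every character separated by a space, or a language other than
English).  This module turns such raw text into paragraph/sentence-structured
:class:`Document` objects and applies the article-level inclusion filters,
recording every removal so discard tallies can be audited.

The stages run in a fixed order::

    clean_lines -> strip_back_matter -> reflow -> filter_article -> deduplicate

Each stage is idempotent and only ever deletes text (the single spaces
inserted when joining wrapped lines are the one exception).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

__all__ = [
    "RawArticle",
    "Document",
    "FilterDecision",
    "LineFilterConfig",
    "EnglishStopwordDetector",
    "clean_lines",
    "strip_back_matter",
    "reflow",
    "word_length_quantile",
    "mean_word_length",
    "filter_article",
    "deduplicate",
    "BACK_MATTER_KEYWORDS",
    "BLACKLIST_KEYWORDS",
]

# Headings that open acknowledgment / bibliography sections, including the
# misspellings observed in real converted PDFs.
BACK_MATTER_KEYWORDS: tuple[str, ...] = (
    "acknowledgment",
    "bibliography",
    "literature cited",
    "literature",
    "references",
    "refirences",
    "literatur",
    "références",
    "referesces",
)

# Whole-article discard keywords (front-matter/administrative documents).
BLACKLIST_KEYWORDS: tuple[str, ...] = (
    "author index",
    "key word index",
    "erratum",
    "editorial board",
    "corrigendum",
    "announcement",
    "books received",
    "product news",
    "business news",
)

# Typical way of listing references, e.g. "[1] Westergaard, ..."
BRACKETED_REF_RE = re.compile(r"^\[\d+\]\s[A-Za-z]")

# Sentence boundary: terminal punctuation, whitespace, then an uppercase
# letter or a digit.
_SENTENCE_SPLIT_RE = re.compile(r"(?<=[.!?])\s+(?=[A-Z0-9])")


@dataclass
class RawArticle:
    """One article as an ordered list of raw text lines plus metadata."""

    doc_id: str
    lines: list[str]
    metadata: dict = field(default_factory=dict)
    provenance: list[dict] = field(default_factory=list)
    flags: set = field(default_factory=set)

    def copy(self) -> "RawArticle":
        return RawArticle(
            doc_id=self.doc_id,
            lines=list(self.lines),
            metadata=dict(self.metadata),
            provenance=list(self.provenance),
            flags=set(self.flags),
        )


@dataclass
class Document:
    """Cleaned article with reconstructed paragraph/sentence structure."""

    doc_id: str
    paragraphs: list[list[str]]
    metadata: dict = field(default_factory=dict)
    provenance: list[dict] = field(default_factory=list)
    flags: set = field(default_factory=set)
    source_lines: list[str] = field(default_factory=list)

    def sentences(self) -> Iterable[str]:
        for para in self.paragraphs:
            yield from para

    def text(self) -> str:
        return "\n".join(" ".join(para) for para in self.paragraphs)

    def normalized_text(self) -> str:
        return " ".join(self.text().lower().split())


@dataclass(frozen=True)
class FilterDecision:
    doc_id: str
    verdict: str  # "keep" | "discard"
    reason: str | None = None  # first failing rule
    detail: str = ""


@dataclass(frozen=True)
class LineFilterConfig:
    """Thresholds for the per-line character-composition filters.

    Fractions are computed over the non-whitespace characters of the line;
    removal uses strict inequalities.
    """

    max_digit_fraction: float = 0.10
    max_symbol_fraction: float = 0.10
    min_lowercase_fraction: float = 0.50


def _char_fractions(line: str) -> tuple[float, float, float]:
    """(digit, symbol, lowercase) fractions over non-whitespace characters."""
    chars = [c for c in line if not c.isspace()]
    if not chars:
        return 0.0, 0.0, 1.0
    n = len(chars)
    digits = sum(c.isdigit() for c in chars)
    symbols = sum(not ("0" <= c <= "9" or "A" <= c <= "Z" or "a" <= c <= "z") for c in chars)
    lower = sum("a" <= c <= "z" for c in chars)
    return digits / n, symbols / n, lower / n


def clean_lines(raw: RawArticle, config: LineFilterConfig = LineFilterConfig()) -> RawArticle:
    """Remove non-printable characters and digit/symbol/uppercase-heavy lines.

    Non-printable characters are deleted (tabs become single spaces).  A line
    is then dropped when its digit fraction exceeds ``max_digit_fraction``, its
    symbol fraction (anything outside ``[0-9A-Za-z]``) exceeds
    ``max_symbol_fraction``, or its lowercase fraction falls below
    ``min_lowercase_fraction``.  Empty lines are dropped.  Counts are recorded
    in provenance.
    """
    out = raw.copy()
    kept: list[str] = []
    n_chars_removed = 0
    n_lines_removed = 0
    for line in out.lines:
        cleaned = []
        for c in line:
            if c == "\t":
                cleaned.append(" ")
            elif c.isprintable():
                cleaned.append(c)
            else:
                n_chars_removed += 1
        cline = "".join(cleaned)
        if not cline.strip():
            if line:
                n_lines_removed += 1
            continue
        digit_f, symbol_f, lower_f = _char_fractions(cline)
        if (
            digit_f > config.max_digit_fraction
            or symbol_f > config.max_symbol_fraction
            or lower_f < config.min_lowercase_fraction
        ):
            n_lines_removed += 1
            continue
        kept.append(cline)
    out.lines = kept
    out.provenance.append(
        {"rule": "clean_lines", "lines_removed": n_lines_removed, "chars_removed": n_chars_removed}
    )
    return out


def strip_back_matter(
    raw: RawArticle,
    keywords: Sequence[str] = BACK_MATTER_KEYWORDS,
    min_run: int = 3,
    tail_region: float = 0.5,
    max_heading_len: int = 40,
) -> RawArticle:
    """Truncate the article at its acknowledgments / reference list.

    Reference lists are assumed to sit at the end of the article, so triggers
    are only honoured in the final ``tail_region`` fraction of lines.  Two
    triggers are recognised: a short heading line starting with one of the
    section ``keywords`` (lowercased, trimmed, <= ``max_heading_len`` chars),
    or the start of a run of >= ``min_run`` consecutive lines that look like
    bracketed references ("[1] Author ...").  The earliest trigger wins; when
    none fires the article is returned unchanged and flagged
    ``no_references_found``.
    """
    out = raw.copy()
    n = len(out.lines)
    if n == 0:
        out.flags.add("no_references_found")
        return out
    start = n - max(1, int(round(n * tail_region)))
    cut: int | None = None
    run_start: int | None = None
    run_len = 0
    for i in range(start, n):
        stripped = out.lines[i].strip()
        low = stripped.lower()
        if len(stripped) <= max_heading_len and any(low.startswith(k) for k in keywords):
            cut = i
            break
        if BRACKETED_REF_RE.match(stripped):
            if run_start is None:
                run_start, run_len = i, 1
            else:
                run_len += 1
            if run_len >= min_run:
                cut = run_start
                # A section heading immediately above the run belongs to the
                # same back matter (keeps truncation idempotent).
                if cut > 0:
                    above = raw.lines[cut - 1].strip().lower()
                    if len(above) <= max_heading_len and any(
                        above.startswith(k) for k in keywords
                    ):
                        cut -= 1
                break
        else:
            run_start, run_len = None, 0
    if cut is None:
        out.flags.add("no_references_found")
        out.provenance.append({"rule": "strip_back_matter", "lines_removed": 0})
        return out
    removed = n - cut
    out.lines = out.lines[:cut]
    out.provenance.append({"rule": "strip_back_matter", "lines_removed": removed})
    return out


def _starts_lowercase(line: str) -> bool:
    stripped = line.lstrip()
    return bool(stripped) and "a" <= stripped[0] <= "z"


def _ends_terminal(line: str) -> bool:
    stripped = line.rstrip()
    return bool(stripped) and stripped[-1] in ".!?"


def reflow(raw: RawArticle, strict_as_printed: bool = False) -> Document:
    """Merge hard-wrapped lines back into sentences and paragraphs.

    PDF extraction breaks paragraphs at page and column boundaries.  The
    default rule treats a line as a continuation of the previous one when the
    previous line lacks terminal punctuation (``.!?``) OR the current line
    starts with a lowercase letter; otherwise a new paragraph begins.
    ``strict_as_printed`` switches to the alternative conjunctive reading
    (continuation only when the previous line lacks terminal punctuation AND
    the current line does not start lowercase).  Completed paragraphs are
    split into sentences at terminal punctuation followed by whitespace and an
    uppercase letter or digit.
    """
    # A paragraph accumulates as "chunks": a new chunk opens when a
    # lowercase-starting line continues the paragraph after terminal
    # punctuation - the previous sentence ended, so the chunk boundary is a
    # forced sentence break even though a lowercase word follows.
    paragraphs: list[list[str]] = []
    chunks: list[list[str]] = []

    def flush() -> None:
        if not chunks:
            return
        sentences: list[str] = []
        for chunk in chunks:
            text = " ".join(s.strip() for s in chunk)
            sentences.extend(s.strip() for s in _SENTENCE_SPLIT_RE.split(text) if s.strip())
        if sentences:
            paragraphs.append(sentences)
        chunks.clear()

    prev: str | None = None
    for line in raw.lines:
        if prev is None:
            chunks.append([line])
        else:
            if strict_as_printed:
                cont = not _ends_terminal(prev) and not _starts_lowercase(line)
            else:
                cont = not _ends_terminal(prev) or _starts_lowercase(line)
            if cont:
                if _ends_terminal(prev):
                    chunks.append([line])
                else:
                    chunks[-1].append(line)
            else:
                flush()
                chunks.append([line])
        prev = line
    flush()
    return Document(
        doc_id=raw.doc_id,
        paragraphs=paragraphs,
        metadata=dict(raw.metadata),
        provenance=list(raw.provenance) + [{"rule": "reflow", "paragraphs": len(paragraphs)}],
        flags=set(raw.flags),
        source_lines=list(raw.lines),
    )


def mean_word_length(doc: Document) -> float:
    """Mean length of words (maximal non-whitespace runs) in the document."""
    words = doc.text().split()
    if not words:
        return 0.0
    return sum(len(w) for w in words) / len(words)


def word_length_quantile(docs: Iterable[Document], q: float = 0.02) -> float:
    """Corpus quantile of per-article mean word length (linear interpolation).

    First-pass statistic required by :func:`filter_article`; articles that are
    empty after cleaning are excluded (they are discarded for emptiness, not
    word length).
    """
    import numpy as np

    means = [mean_word_length(d) for d in docs]
    means = [m for m in means if m > 0]
    if not means:
        return 0.0
    return float(np.quantile(means, q))


class EnglishStopwordDetector:
    """Built-in language predicate: stop-word overlap scoring.

    Scores a document by the fraction of its multi-character alphabetic tokens
    found in a small built-in English stop-word list.  Documents with fewer
    than ``min_tokens`` such tokens give the detector nothing to decide on and
    are passed through as English (degenerate extractions of single-character
    tokens are handled by the word-length filter instead).
    """

    STOPWORDS = frozenset(
        """the of and to in is was for that with are on as by this from at or
        an be it not we which have has were but their can all been its more
        one our these they had also between than when into during both each
        may such used using use no any other some only most over after before
        under further then out very up down same so if do does did within
        without found show shown study studies results result data method
        methods analysis observed however therefore thus among across where
        while through per due based high low new two three first second well
        many less could would should there here about against because until
        again once being above below own just how what who whom why will
        made make given take number case cases group groups level levels
        effect effects model models value values table figure section""".split()
    )

    def __init__(self, threshold: float = 0.15, min_tokens: int = 5):
        self.threshold = threshold
        self.min_tokens = min_tokens

    def score(self, doc: Document) -> float | None:
        tokens = [
            t for t in re.findall(r"[A-Za-z]{2,}", doc.text().lower())
        ]
        if len(tokens) < self.min_tokens:
            return None
        hits = sum(t in self.STOPWORDS for t in tokens)
        return hits / len(tokens)

    def __call__(self, doc: Document) -> bool:
        s = self.score(doc)
        if s is None:
            return True
        return s >= self.threshold


def filter_article(
    doc: Document,
    word_length_cutoff: float | None,
    lang_detector: Callable[[Document], bool] | None = None,
    blacklist: Sequence[str] = BLACKLIST_KEYWORDS,
    max_heading_len: int = 40,
) -> FilterDecision:
    """Decide keep/discard for one article; first failing rule wins.

    Rule order: empty text; non-English (pluggable predicate); mean word
    length strictly below the corpus cutoff (the 2% quantile from
    :func:`word_length_quantile`); blacklist keyword present on a heading-like
    line (case-insensitive substring on cleaned source lines of length
    <= ``max_heading_len``).
    """
    if word_length_cutoff is None:
        raise ValueError("word-length cutoff must be computed over the corpus first")
    if not any(True for _ in doc.sentences()):
        return FilterDecision(doc.doc_id, "discard", "empty_text", "no text after cleaning")
    detector = lang_detector if lang_detector is not None else EnglishStopwordDetector()
    if not detector(doc):
        return FilterDecision(doc.doc_id, "discard", "non_english", "language predicate rejected")
    mwl = mean_word_length(doc)
    if mwl < word_length_cutoff:
        return FilterDecision(
            doc.doc_id,
            "discard",
            "low_avg_word_length",
            f"mean word length {mwl:.3f} < cutoff {word_length_cutoff:.3f}",
        )
    heading_lines = doc.source_lines if doc.source_lines else list(doc.sentences())
    for line in heading_lines:
        stripped = line.strip()
        if len(stripped) <= max_heading_len:
            low = stripped.lower()
            for kw in blacklist:
                if kw in low:
                    return FilterDecision(doc.doc_id, "discard", "blacklist_keyword", kw)
    return FilterDecision(doc.doc_id, "keep")


def deduplicate(
    docs: Sequence[Document],
) -> tuple[list[Document], list[tuple[Document, str, str]]]:
    """Resolve duplicate and subset articles.

    Conference-proceedings PDFs often hold several articles in one file, and
    some files are byte-identical copies.  Texts are normalised (lowercase,
    collapsed whitespace) and compared by exact containment:

    * byte-identical groups keep one copy (smallest ``doc_id``);
    * a document that strictly contains two or more other documents is a
      concatenation whose parts exist independently - the parts are kept and
      the container dropped;
    * a document strictly contained in a single kept superset is dropped in
      favour of the superset.

    Returns ``(kept, removed)`` where each removed entry is
    ``(document, reason, retained_doc_id)``.
    """
    norm = {d.doc_id: d.normalized_text() for d in docs}
    removed: list[tuple[Document, str, str]] = []
    # Exact duplicates: group by normalised text.
    by_text: dict[str, list[Document]] = {}
    for d in docs:
        by_text.setdefault(norm[d.doc_id], []).append(d)
    reps: list[Document] = []
    for text, group in by_text.items():
        group = sorted(group, key=lambda d: d.doc_id)
        reps.append(group[0])
        for extra in group[1:]:
            removed.append((extra, "duplicate", group[0].doc_id))
    # Strict containment among representatives.
    reps.sort(key=lambda d: (-len(norm[d.doc_id]), d.doc_id))
    contains: dict[str, list[str]] = {d.doc_id: [] for d in reps}
    contained_in: dict[str, list[str]] = {d.doc_id: [] for d in reps}
    for i, big in enumerate(reps):
        big_text = norm[big.doc_id]
        for small in reps[i + 1 :]:
            small_text = norm[small.doc_id]
            if len(small_text) < len(big_text) and small_text and small_text in big_text:
                contains[big.doc_id].append(small.doc_id)
                contained_in[small.doc_id].append(big.doc_id)
    dropped: set[str] = set()
    # Concatenations first: container with >=2 independently present parts.
    for d in reps:
        parts = contains[d.doc_id]
        if len(parts) >= 2:
            dropped.add(d.doc_id)
            removed.append((d, "concatenation", parts[0]))
    # Subsets of a surviving superset.
    for d in reps:
        if d.doc_id in dropped:
            continue
        supersets = [s for s in contained_in[d.doc_id] if s not in dropped]
        if supersets:
            dropped.add(d.doc_id)
            removed.append((d, "subset", sorted(supersets)[0]))
    kept = [d for d in sorted(reps, key=lambda d: d.doc_id) if d.doc_id not in dropped]
    return kept, removed
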
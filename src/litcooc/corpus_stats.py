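"""Temporal and structural corpus descriptives.

Yearly publication counts, exponential-growth fitting (log2-linear regression
with doubling time 1/slope), page-length quartile bins, per-year topical
category shares, and per-year mean entity mentions per article.  All outputs
are plain pandas objects so they can be dumped as TSV behind the plotting
hooks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GrowthFit",
    "yearly_counts",
    "fit_growth",
    "page_bins",
    "category_shares",
    "mention_trends",
    "PAPER_PAGE_BIN_EDGES",
]

# Fixed quartile edges (1-4 / 5-7 / 8-10 / 11+ pages) usable instead of
# corpus-derived quantiles.
PAPER_PAGE_BIN_EDGES: tuple[int, int, int] = (4, 7, 10)


@dataclass(frozen=True)
class GrowthFit:
    """Log2-linear growth fit over a year period."""

    period: tuple[int, int]
    slope: float  # log2 counts per year
    intercept: float
    r_squared: float
    n_years: int

    @property
    def doubling_time_years(self) -> float:
        return 1.0 / self.slope

    @property
    def doubling_time_reported(self) -> float:
        """Doubling time rounded to one decimal (reporting precision)."""
        return round(self.doubling_time_years, 1)


def yearly_counts(
    metadata: pd.DataFrame, condense_pre_1900: bool = False
) -> dict[int | str, int]:
    """Publication count per year; optionally condense pre-1900 into one bin."""
    if metadata.empty:
        return {}
    counts = metadata.groupby("year").size().to_dict()
    if not condense_pre_1900:
        return {int(y): int(c) for y, c in sorted(counts.items())}
    out: dict[int | str, int] = {}
    early = 0
    for y, c in sorted(counts.items()):
        if y <= 1900:
            early += int(c)
        else:
            out[int(y)] = int(c)
    result: dict[int | str, int] = {}
    if early:
        result["<=1900"] = early
    result.update(out)
    return result


def fit_growth(counts: Mapping[int, int], period: tuple[int, int]) -> GrowthFit:
    """OLS of log2(count) on year over the period; zero-count years excluded.

    Warns (and reports an undefined doubling time as +/-inf via 1/slope) when
    the fitted slope is not positive.
    """
    y0, y1 = period
    years = [y for y in sorted(counts) if y0 <= y <= y1 and counts[y] > 0]
    if len(years) < 3:
        raise ValueError("need >= 3 years with positive counts in the period")
    x = np.array(years, dtype=float)
    y = np.log2([counts[yy] for yy in years])
    res = stats.linregress(x, y)
    if res.slope <= 0:
        warnings.warn("non-positive growth slope: doubling time undefined", stacklevel=2)
    return GrowthFit(
        period=period,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_years=len(years),
    )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def page_bins(
    metadata: pd.DataFrame,
    edges: Sequence[int] | None = None,
    quantiles: Sequence[float] = (0.25, 0.50, 0.75),
) -> tuple[pd.Series, tuple[int, int, int], pd.DataFrame]:
    """Assign each article to a page-length quartile bin.

    Edges default to the integer-rounded (half-up) 25/50/75% quantiles of the
    corpus page counts; pass ``edges`` (e.g. :data:`PAPER_PAGE_BIN_EDGES`) to
    impose fixed ones.  Bins are right-closed: pages <= e1, e1 < pages <= e2,
    e2 < pages <= e3, pages > e3.  Articles without a page count are excluded
    and logged via the returned Series index.  Also returns per-year bin
    proportions.
    """
    pages = pd.to_numeric(metadata["pages"], errors="coerce")
    valid = metadata[pages.notna() & (pages >= 1)].copy()
    valid["pages"] = pages[pages.notna() & (pages >= 1)].astype(int)
    if valid.empty:
        raise ValueError("no articles with page counts")
    if edges is None:
        qs = np.quantile(valid["pages"].to_numpy(), quantiles)
        e = tuple(_round_half_up(q) for q in qs)
    else:
        e = tuple(int(v) for v in edges)
    e1, e2, e3 = e
    if not (e1 < e2 < e3):
        warnings.warn(f"degenerate page-bin edges {e}: bins collapse", stacklevel=2)
    labels = [f"1-{e1}", f"{e1 + 1}-{e2}", f"{e2 + 1}-{e3}", f"{e3 + 1}+"]

    def assign(p: int) -> str:
        if p <= e1:
            return labels[0]
        if p <= e2:
            return labels[1]
        if p <= e3:
            return labels[2]
        return labels[3]

    binned = valid["pages"].map(assign)
    binned.index = valid["doc_id"].to_numpy() if "doc_id" in valid else valid.index
    per_year = (
        pd.DataFrame({"year": valid["year"].to_numpy(), "bin": binned.to_numpy()})
        .groupby(["year", "bin"])
        .size()
        .unstack(fill_value=0)
    )
    per_year = per_year.div(per_year.sum(axis=1), axis=0)
    return binned, (e1, e2, e3), per_year


def category_shares(metadata: pd.DataFrame, top_n: int = 6) -> pd.DataFrame:
    """Per-year fraction of articles carrying each top-n category (+ "Other").

    Categories are multi-valued (semicolon-separated or list-valued);
    multi-category articles count once per category, so yearly shares may sum
    above 1.
    """
    rows: list[tuple[int, str]] = []
    for _, rec in metadata.iterrows():
        cats = rec["categories"]
        if isinstance(cats, str):
            cats = [c.strip() for c in cats.split(";") if c.strip()]
        for c in set(cats):
            rows.append((int(rec["year"]), c))
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows, columns=["year", "category"])
    top = df["category"].value_counts().index[:top_n]
    df["category"] = df["category"].where(df["category"].isin(top), "Other")
    per_year = df.groupby(["year", "category"]).size().unstack(fill_value=0)
    denom = metadata.groupby("year").size()
    return per_year.div(denom, axis=0).fillna(0.0)


def mention_trends(
    mentions_per_doc: Mapping[str, Mapping[str, int]], metadata: pd.DataFrame
) -> pd.DataFrame:
    """Per-year mean mentions per article, by entity type.

    ``mentions_per_doc`` maps doc_id -> {entity_type: mention count}.  Years
    without articles are omitted; a type absent from the corpus yields an
    all-zero column.
    """
    year_of = dict(zip(metadata["doc_id"], metadata["year"]))
    types = sorted({t for counts in mentions_per_doc.values() for t in counts})
    rows: dict[int, dict[str, float]] = {}
    n_docs: dict[int, int] = {}
    for _, rec in metadata.iterrows():
        y = int(rec["year"])
        n_docs[y] = n_docs.get(y, 0) + 1
    totals: dict[int, dict[str, int]] = {}
    for doc_id, counts in mentions_per_doc.items():
        if doc_id not in year_of:
            continue
        y = int(year_of[doc_id])
        t = totals.setdefault(y, {})
        for etype, c in counts.items():
            t[etype] = t.get(etype, 0) + c
    for y in sorted(n_docs):
        rows[y] = {etype: totals.get(y, {}).get(etype, 0) / n_docs[y] for etype in types}
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()
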
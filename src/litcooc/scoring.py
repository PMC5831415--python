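"""Weighted co-occurrence counting and association scoring.

For a pair of entities (i, j) the evidence across a corpus of n documents is
summarised by the weighted count

    C(i,j) = sum_k  w_d * delta_d^k(i,j) + w_p * delta_p^k(i,j) + w_s * delta_s^k(i,j)

where delta_d/delta_p/delta_s indicate whether i and j co-occur in document k
within the same document, paragraph, or sentence, and the weights default to
w_d = 1.0, w_p = 2.0, w_s = 0.2.  The association score interpolates (with
exponent alpha = 0.6) between the raw count and an observed/expected ratio
against the marginal counts:

    S(i,j) = C_ij^alpha * (C_ij * C_.. / (C_i. * C_.j))^(1-alpha)

S scores are converted to Z scores - here the standardised log-S over all
pairs with S > 0 - which is the ranking variable used for ROC benchmarking.
Because all downstream evaluation is rank-based, any strictly monotone
standardisation yields identical benchmark results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .ner import Dictionary, Mention

__all__ = [
    "ScoreParams",
    "PairCounts",
    "PairScore",
    "DegenerateScaleError",
    "count_pairs",
    "score_pairs",
    "z_transform",
    "canonical_pair",
]


class DegenerateScaleError(ValueError):
    """All scores identical: the Z standardisation is undefined."""


@dataclass(frozen=True)
class ScoreParams:
    """Co-occurrence weights and the mixing exponent.

    ``per_instance`` switches the paragraph/sentence indicators to instance
    counts (number of shared paragraphs / sentences per document) for
    sensitivity analysis; the default reads delta as a per-document indicator
    that fires at most once per granularity level.
    """

    w_d: float = 1.0
    w_p: float = 2.0
    w_s: float = 0.2
    alpha: float = 0.6
    per_instance: bool = False

    def __post_init__(self):
        if min(self.w_d, self.w_p, self.w_s) < 0:
            raise ValueError("weights must be non-negative")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


def canonical_pair(i: int, j: int) -> tuple[int, int]:
    """Canonical (sorted) storage order for an unordered serial pair."""
    return (i, j) if i <= j else (j, i)


@dataclass
class PairCounts:
    """Weighted counts for one entity-type pair, with marginals.

    Marginals and the grand total are computed within the type pair: C_i. sums
    C_ij over all partners j of i, and C_.. sums C_ij over all canonically
    stored pairs.
    """

    type_pair: tuple[str, str]
    counts: dict[tuple[int, int], float] = field(default_factory=dict)

    def get(self, i: int, j: int) -> float:
        return self.counts.get(canonical_pair(i, j), 0.0)

    def marginals(self) -> dict[int, float]:
        marg: dict[int, float] = {}
        for (i, j), c in self.counts.items():
            marg[i] = marg.get(i, 0.0) + c
            if j != i:
                marg[j] = marg.get(j, 0.0) + c
        return marg

    def total(self) -> float:
        return sum(self.counts.values())


@dataclass(frozen=True)
class PairScore:
    pair: tuple[int, int]
    identifiers: tuple[str, str]
    type_pair: tuple[str, str]
    c: float
    s: float
    z: float = float("nan")


def _locations_by_serial(
    mentions: Sequence[Mention], wanted_types: set[str], dictionary: Dictionary
) -> dict[int, tuple[set[int], set[tuple[int, int]]]]:
    """serial -> (paragraph set, (paragraph, sentence) set) within one doc."""
    locs: dict[int, tuple[set[int], set[tuple[int, int]]]] = {}
    for m in mentions:
        for s in m.serials:
            if dictionary.entity_type(s) not in wanted_types:
                continue
            paras, sents = locs.setdefault(s, (set(), set()))
            paras.add(m.paragraph_index)
            sents.add((m.paragraph_index, m.sentence_index))
    return locs


def count_pairs(
    mentions_by_doc: Mapping[str, Sequence[Mention]],
    type_pair: tuple[str, str],
    params: ScoreParams,
    dictionary: Dictionary,
) -> PairCounts:
    """Accumulate weighted co-occurrence counts for every pair of a type pair.

    Mentions must already carry paragraph/sentence indices and be
    ontology-backtracked.  Identical serials and ancestor-descendant pairs are
    excluded (backtracking would otherwise guarantee spurious
    self-association).  Raises on a mention serial absent from the dictionary.
    """
    t_a, t_b = type_pair
    same_type = t_a == t_b
    wanted = {t_a, t_b}
    out = PairCounts(type_pair=type_pair)
    for doc_id in sorted(mentions_by_doc):
        mentions = mentions_by_doc[doc_id]
        for m in mentions:
            for s in m.serials:
                if s not in dictionary.entries:
                    raise KeyError(f"mention in {doc_id} references unknown serial {s}")
        locs = _locations_by_serial(mentions, wanted, dictionary)
        if same_type:
            serials = sorted(s for s in locs if dictionary.entity_type(s) == t_a)
            candidates = [
                (serials[a], serials[b])
                for a in range(len(serials))
                for b in range(a + 1, len(serials))
            ]
        else:
            left = sorted(s for s in locs if dictionary.entity_type(s) == t_a)
            right = sorted(s for s in locs if dictionary.entity_type(s) == t_b)
            candidates = [(i, j) for i in left for j in right]
        for i, j in candidates:
            if i == j or dictionary.is_ancestor_pair(i, j):
                continue
            paras_i, sents_i = locs[i]
            paras_j, sents_j = locs[j]
            if params.per_instance:
                d_p = len(paras_i & paras_j)
                d_s = len(sents_i & sents_j)
                contrib = params.w_d + params.w_p * d_p + params.w_s * d_s
            else:
                d_p = 1.0 if paras_i & paras_j else 0.0
                d_s = 1.0 if sents_i & sents_j else 0.0
                contrib = params.w_d + params.w_p * d_p + params.w_s * d_s
            if contrib:
                key = canonical_pair(i, j)
                out.counts[key] = out.counts.get(key, 0.0) + contrib
    return out


def score_pairs(counts: PairCounts, params: ScoreParams, dictionary: Dictionary) -> list[PairScore]:
    """Evaluate S(i,j) for every counted pair.

    Pairs with C_ij = 0 are simply absent (S would be 0); callers that need
    them - e.g. benchmark pairs never co-mentioned - assign the sentinel
    minimum rank downstream.
    """
    total = counts.total()
    if total <= 0:
        return []
    marg = counts.marginals()
    scores: list[PairScore] = []
    a = params.alpha
    for (i, j), c in sorted(counts.counts.items()):
        expected_ratio = c * total / (marg[i] * marg[j])
        s = (c ** a) * (expected_ratio ** (1.0 - a))
        scores.append(
            PairScore(
                pair=(i, j),
                identifiers=(dictionary.identifier(i), dictionary.identifier(j)),
                type_pair=counts.type_pair,
                c=c,
                s=s,
            )
        )
    return scores


def z_transform(scores: Sequence[PairScore]) -> list[PairScore]:
    """Standardise log(S) into Z over all pairs of the type pair.

    Z = (log S - mean(log S)) / sd(log S), with the unbiased (n-1) standard
    deviation, computed over pairs with S > 0; pairs with S = 0 receive
    Z = -inf.  Strictly monotone in S, so any rank-based evaluation is
    unaffected by this choice of standardisation.  Raises
    :class:`DegenerateScaleError` when fewer than two distinct positive S
    values exist.
    """
    logs = [math.log(p.s) for p in scores if p.s > 0]
    if len(set(logs)) < 2:
        raise DegenerateScaleError("need >= 2 distinct positive S values for Z conversion")
    n = len(logs)
    mean = sum(logs) / n
    var = sum((x - mean) ** 2 for x in logs) / (n - 1)
    sd = math.sqrt(var)
    out: list[PairScore] = []
    for p in scores:
        if p.s > 0:
            z = (math.log(p.s) - mean) / sd
        else:
            z = float("-inf")
        out.append(PairScore(p.pair, p.identifiers, p.type_pair, p.c, p.s, z))
    return out
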
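"""Gold-standard construction and ROC benchmarking of ranked associations.

Three standard constructions are supported:

* pathway: any two proteins sharing a pathway are positive; two proteins each
  present in some pathway but never the same one are negative.
* shuffle: known disease-gene pairs are positive; negatives are produced by
  permuting the gene column against the disease column and discarding any
  shuffled pair that collides with a positive.
* compartment: annotated (protein, compartment) pairs are positive; for every
  annotated protein, each compartment of the universe it is not annotated to
  is negative.

Ranked scores are swept into an ROC curve by gradually lowering the Z
threshold: TPR = TP / P and FPR = 1 - TN / N at each threshold.  The curve is
summarised by the trapezoidal AUC and by TPR@10%FPR, the true positive rate
at the practically relevant 10% false positive rate.  Benchmark pairs never
co-mentioned in the corpus enter the sweep with a sentinel score below every
real Z, so recall losses stay visible in the curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .scoring import PairScore, ScoreParams, count_pairs, score_pairs

__all__ = [
    "BenchmarkSet",
    "RocResult",
    "BenchmarkError",
    "build_pathway_benchmark",
    "build_shuffle_benchmark",
    "build_compartment_benchmark",
    "roc",
    "optimize_weights",
]

SENTINEL = float("-inf")


class BenchmarkError(ValueError):
    """Benchmark construction impossible (no negatives, single pathway, ...)."""


def _canon(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class BenchmarkSet:
    """Labelled positive/negative identifier pairs (stored canonically)."""

    positives: set[tuple[str, str]]
    negatives: set[tuple[str, str]]
    label: str = ""

    def __post_init__(self):
        self.positives = {_canon(*p) for p in self.positives}
        self.negatives = {_canon(*p) for p in self.negatives}
        overlap = self.positives & self.negatives
        if overlap:
            raise BenchmarkError(f"positives and negatives overlap: {sorted(overlap)[:3]}")


@dataclass
class RocResult:
    curve: list[tuple[float, float]]  # (FPR, TPR), from (0,0) to (1,1)
    auc: float
    tpr_at_10pct_fpr: float
    n_pos: int
    n_neg: int


def build_pathway_benchmark(memberships: Mapping[str, Iterable[str]]) -> BenchmarkSet:
    """Positives share >= 1 pathway; negatives are cross-pathway-only pairs."""
    memberships = {k: set(v) for k, v in memberships.items()}
    if len(memberships) < 2:
        raise BenchmarkError("need >= 2 pathways to define negative examples")
    positives: set[tuple[str, str]] = set()
    for members in memberships.values():
        ms = sorted(members)
        for a in range(len(ms)):
            for b in range(a + 1, len(ms)):
                positives.add(_canon(ms[a], ms[b]))
    universe = sorted(set().union(*memberships.values()))
    negatives: set[tuple[str, str]] = set()
    for a in range(len(universe)):
        for b in range(a + 1, len(universe)):
            pair = _canon(universe[a], universe[b])
            if pair not in positives:
                negatives.add(pair)
    if not negatives:
        raise BenchmarkError("no cross-pathway negative pairs")
    return BenchmarkSet(positives, negatives, label="pathway")


def build_shuffle_benchmark(
    known_pairs: Sequence[tuple[str, str]], seed: int = 42
) -> BenchmarkSet:
    """Known (disease, gene) pairs vs a seeded shuffle of the gene column."""
    if len(known_pairs) < 2:
        raise BenchmarkError("need >= 2 known pairs to shuffle")
    positives = {(d, g) for d, g in known_pairs}
    diseases = [d for d, _ in known_pairs]
    genes = [g for _, g in known_pairs]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(genes))
    negatives = {(diseases[i], genes[perm[i]]) for i in range(len(genes))}
    negatives -= positives
    if not negatives:
        raise BenchmarkError("shuffle produced no non-overlapping negatives; try another seed")
    return BenchmarkSet(set(positives), negatives, label="shuffle")


def build_compartment_benchmark(
    annotations: Mapping[str, Iterable[str]], universe: Iterable[str]
) -> BenchmarkSet:
    """Annotated (protein, compartment) pairs vs the complement over the universe."""
    universe = set(universe)
    if not universe:
        raise BenchmarkError("empty compartment universe")
    annotations = {p: set(cs) for p, cs in annotations.items()}
    for p, cs in annotations.items():
        missing = cs - universe
        if missing:
            raise BenchmarkError(f"annotation outside universe for {p}: {sorted(missing)}")
    positives: set[tuple[str, str]] = set()
    negatives: set[tuple[str, str]] = set()
    for p, cs in annotations.items():
        for c in cs:
            positives.add(_canon(p, c))
        for c in universe - cs:
            negatives.add(_canon(p, c))
    return BenchmarkSet(positives, negatives, label="compartment")


def roc(
    scores: Sequence[PairScore] | Mapping[tuple[str, str], float],
    bench: BenchmarkSet,
    rank_by: str = "z",
) -> RocResult:
    """Threshold sweep of ranked pair scores against a benchmark.

    ``scores`` may be PairScore records (ranked by ``rank_by``, "z" or "s")
    or a ready mapping of canonical identifier pairs to scores.  Benchmark
    pairs without a score enter with the -inf sentinel.  Tied scores are
    processed as a single threshold step; AUC is the trapezoidal area and
    TPR@10%FPR is linearly interpolated at FPR = 0.10.
    """
    if not bench.positives or not bench.negatives:
        raise BenchmarkError("benchmark needs non-empty positives and negatives")
    if isinstance(scores, Mapping):
        score_map = {_canon(*k): v for k, v in scores.items()}
    else:
        score_map = {_canon(*p.identifiers): getattr(p, rank_by) for p in scores}
    labelled: list[tuple[float, int]] = []
    for pair in bench.positives:
        labelled.append((score_map.get(pair, SENTINEL), 1))
    for pair in bench.negatives:
        labelled.append((score_map.get(pair, SENTINEL), 0))
    labelled.sort(key=lambda t: -t[0] if not math.isnan(t[0]) else math.inf)
    n_pos = len(bench.positives)
    n_neg = len(bench.negatives)
    curve: list[tuple[float, float]] = [(0.0, 0.0)]
    tp = fp = 0
    idx = 0
    while idx < len(labelled):
        threshold = labelled[idx][0]
        while idx < len(labelled) and labelled[idx][0] == threshold:
            if labelled[idx][1] == 1:
                tp += 1
            else:
                fp += 1
            idx += 1
        curve.append((fp / n_neg, tp / n_pos))
    if curve[-1] != (1.0, 1.0):
        curve.append((1.0, 1.0))
    xs = np.array([p[0] for p in curve])
    ys = np.array([p[1] for p in curve])
    auc = float(np.trapezoid(ys, xs))
    tpr_at = float(np.interp(0.10, xs, ys))
    return RocResult(curve=curve, auc=auc, tpr_at_10pct_fpr=tpr_at, n_pos=n_pos, n_neg=n_neg)


def optimize_weights(
    mentions_by_doc,
    bench: BenchmarkSet,
    grid: Sequence[ScoreParams],
    dictionary,
    type_pair: tuple[str, str] = ("gene", "gene"),
) -> ScoreParams:
    """Grid search of co-occurrence weights maximising benchmark AUC.

    Ranking uses S directly (Z is a strictly monotone transform of S, so the
    selected grid point is identical).  Exact AUC ties break toward the
    calibrated defaults (w_d=1.0, w_p=2.0, w_s=0.2, alpha=0.6), then toward
    the earliest grid point.
    """
    if not grid:
        raise ValueError("empty parameter grid")
    defaults = ScoreParams()
    best: tuple[float, int, ScoreParams] | None = None
    for order, params in enumerate(grid):
        counts = count_pairs(mentions_by_doc, type_pair, params, dictionary)
        scores = score_pairs(counts, params, dictionary)
        auc = roc(scores, bench, rank_by="s").auc
        is_default = (
            params.w_d == defaults.w_d
            and params.w_p == defaults.w_p
            and params.w_s == defaults.w_s
            and params.alpha == defaults.alpha
        )
        key = (auc, 1 if is_default else 0, -order)
        if best is None or key > (best[0], best[1], -best[2]):
            best = (auc, key[1], order)
            best_params = params
    return best_params
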
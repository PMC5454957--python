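"""Cross-validated evaluation and the guilt-by-association baseline.

The validated seed genes are split into k near-equal folds; each fold is
held out in turn, the method runs with the remaining seeds only, and the
held-out fold is scored by recall, precision and the F1-measure:

    recall    = TP / (TP + FN)
    precision = TP / (TP + FP)
    F1        = 2 * recall * precision / (recall + precision)

where TP are held-out genes the method recovered, FN held-out genes it
missed, and FP predicted genes outside the fold.  Zero denominators yield a
metric of zero.

The baseline is classic guilt by association: predict the union of each
training seed's k highest-weight neighbors, grid-searching k per fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .network_io import SeedSet, WeightedNetwork

#: the k values tried by the baseline grid search (19 values)
DEFAULT_K_GRID: tuple[int, ...] = (*range(1, 11), *range(20, 101, 10))


def f1_score(recall: float, precision: float) -> float:
    """Harmonic mean of recall and precision; 0 when both are 0."""
    denom = recall + precision
    if denom == 0.0:
        return 0.0
    return 2.0 * recall * precision / denom


def round3(x: float) -> float:
    """Half-even rounding to 3 decimals, the reporting precision."""
    return round(x, 3)


@dataclass
class FoldMetrics:
    """Confusion counts and derived metrics for one cross-validation fold."""

    tp: int
    fp: int
    fn: int

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def f1(self) -> float:
        return f1_score(self.recall, self.precision)


@dataclass
class Partition:
    """k disjoint folds covering the seed IDs; deterministic per rng seed."""

    parts: list[list[str]]
    rng_seed: int

    @property
    def k(self) -> int:
        return len(self.parts)

    def training_ids(self, fold: int) -> list[str]:
        out: list[str] = []
        for i, part in enumerate(self.parts):
            if i != fold:
                out.extend(part)
        return out


@dataclass
class CvResult:
    folds: list[FoldMetrics]

    @property
    def mean_recall(self) -> float:
        return float(np.mean([m.recall for m in self.folds]))

    @property
    def mean_precision(self) -> float:
        return float(np.mean([m.precision for m in self.folds]))

    @property
    def mean_f1(self) -> float:
        return float(np.mean([m.f1 for m in self.folds]))


def prf1(predicted: Iterable[str], held_out: Iterable[str]) -> FoldMetrics:
    """Score a predicted gene set against the held-out fold (set semantics)."""
    pred = set(predicted)
    held = set(held_out)
    tp = len(pred & held)
    return FoldMetrics(tp=tp, fp=len(pred - held), fn=len(held - pred))


def kfold_partition(ids: Sequence[str], k: int, rng_seed: int) -> Partition:
    """Randomly split ``ids`` into k folds whose sizes differ by at most one."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the {len(ids)} available IDs")
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    parts = [list(chunk) for chunk in np.array_split(np.array(shuffled, dtype=object), k)]
    return Partition(parts=[[str(x) for x in p] for p in parts], rng_seed=rng_seed)


def cross_validate(
    predictor: Callable[[list[str]], set[str]],
    ids: Sequence[str],
    k_folds: int = 5,
    rng_seed: int = 0,
    partition: Partition | None = None,
) -> CvResult:
    """Hold each fold out in turn and score ``predictor(training_ids)``.

    The predictor sees only the training-fold seeds; held-out IDs influence
    nothing but the scoring.
    """
    part = partition or kfold_partition(ids, k_folds, rng_seed)
    folds = [
        prf1(predictor(part.training_ids(i)), part.parts[i])
        for i in range(part.k)
    ]
    return CvResult(folds=folds)


# ---------------------------------------------------------------------------
# guilt-by-association baseline


def gba_predict(net: WeightedNetwork, seeds: SeedSet, k: int) -> set[str]:
    """Union of each seed's k highest-weight neighbors, minus the seeds.

    A neighbor is "nearer" when its edge weight is higher; ties at the k-th
    rank break by ID ascending for determinism.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seed_ids = set(seeds.ids)
    predicted: set[str] = set()
    for s in seeds.ids:
        ranked = sorted(
            ((net.score(s, v), v) for v in net.neighbors(s)),
            key=lambda t: (-t[0], t[1]),
        )
        predicted.update(v for _, v in ranked[:k])
    return predicted - seed_ids


@dataclass
class GbaFoldResult:
    """Grid-search outcome for one fold: metrics per k and the F1-best k."""

    per_k: dict[int, FoldMetrics]
    best_k: int

    @property
    def best(self) -> FoldMetrics:
        return self.per_k[self.best_k]


def gba_grid_search(
    net: WeightedNetwork,
    ids: Sequence[str],
    k_grid: Sequence[int] = DEFAULT_K_GRID,
    partition: Partition | None = None,
    k_folds: int = 5,
    rng_seed: int = 0,
) -> list[GbaFoldResult]:
    """Per fold, score the baseline for every k and pick the F1-best k.

    Ties on F1 go to the smallest k.  Pass the same ``partition`` used for
    the main method to compare on identical folds.
    """
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    part = partition or kfold_partition(ids, k_folds, rng_seed)
    results: list[GbaFoldResult] = []
    for i in range(part.k):
        training = SeedSet(ids=[g for g in part.training_ids(i) if g in net])
        per_k = {
            k: prf1(gba_predict(net, training, k), part.parts[i]) for k in k_grid
        }
        best_k = min(per_k, key=lambda k: (-per_k[k].f1, k))
        results.append(GbaFoldResult(per_k=per_k, best_k=best_k))
    return results


def write_cv_table(result: CvResult, stream) -> None:
    """Emit a per-fold recall/precision/F1 table with a mean row (3 d.p.)."""
    stream.write("fold\trecall\tprecision\tf1\n")
    for i, m in enumerate(result.folds, start=1):
        stream.write(f"{i}\t{round3(m.recall):.3f}\t{round3(m.precision):.3f}\t{round3(m.f1):.3f}\n")
    stream.write(
        f"mean\t{round3(result.mean_recall):.3f}"
        f"\t{round3(result.mean_precision):.3f}"
        f"\t{round3(result.mean_f1):.3f}\n"
    )


def write_gba_table(results: list[GbaFoldResult], stream) -> None:
    """Emit a per-fold best-k table for the baseline (3 d.p.)."""
    stream.write("fold\tbest_k\trecall\tprecision\tf1\n")
    for i, r in enumerate(results, start=1):
        m = r.best
        stream.write(
            f"{i}\t{r.best_k}\t{round3(m.recall):.3f}"
            f"\t{round3(m.precision):.3f}\t{round3(m.f1):.3f}\n"
        )
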
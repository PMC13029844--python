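"""Rank-based fusion of classifier ensembles.

Each of K base classifiers turns a sample's posterior vector into a Top-T
ranking (the T most probable identities, descending).  Fusion then works
entirely on these ordinal rankings:

* per classifier j and position p, a Top-p accuracy ``Acc[j, p]`` is
  measured on held-out labelled data — the fraction of samples whose true
  class appears within the first p positions;
* classifiers are ranked per position: ``R[j, p] = 1 + #{l : Acc[l, p] >
  Acc[j, p]}``, ties reordered by Top-1 accuracy, persistent ties sharing a
  rank; the rank maps to a quality weight ``w[j, p] = (K + 1 - R[j, p]) / K``;
* **weighted vote by rank order** — every classifier casts one vote, for its
  Top-1 class, with weight ``w[j, 1]``;
* **rank-based additive weighted Top-T vote** — every classifier casts T
  votes; position p carries the coefficient ``lambda * f_p + (1 - lambda) *
  w[j, p]`` with the position weight ``f_p = (T + 1 - p) / T``.  ``lambda``
  balances position information against classifier quality and may exceed 1
  (the quality term then turns negative — implemented literally, as the
  formulation intends, since useful optima sit slightly above 1).

Tied maximal scores are resolved by the Top-1 indication of the most
accurate base classifier; if that indication is itself ambiguous the
ensemble outputs ``None`` (no decision).  Score comparisons treat values
within a 1e-12 relative tolerance as equal so floating-point noise cannot
manufacture spurious winners.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifiers import PosteriorMatrix

__all__ = [
    "TopTRanking",
    "RankWeightTable",
    "EnsembleDecision",
    "LambdaSweep",
    "DEFAULT_LAMBDA_GRID",
    "topT_rankings",
    "topp_accuracy",
    "rank_and_weight",
    "build_weight_table",
    "vote_rank_order",
    "vote_topT_additive",
    "resolve_tie",
    "sweep_lambda",
]

#: relative tolerance below which two fused scores count as tied
SCORE_TIE_RTOL = 1e-12

#: the lambda evaluation grid (0, 5] in steps of 0.1 — 50 points
DEFAULT_LAMBDA_GRID = tuple(np.round(np.arange(1, 51) * 0.1, 10))


@dataclass
class TopTRanking:
    """Per-sample ordered Top-T class lists of one classifier.

    ``classes[m, p-1]`` is the class index this classifier ranked at
    position p for sample m.
    """

    classifier_id: str
    classes: np.ndarray  # (M, T) int
    n_classes: int

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.intp)
        if self.classes.ndim != 2:
            raise ValueError("rankings must be a 2-D (samples x positions) array")
        m, t = self.classes.shape
        if t > self.n_classes:
            raise ValueError("more positions than classes")
        for row in self.classes:
            if len(set(row.tolist())) != t:
                raise ValueError("a class repeats within a Top-T list")

    @property
    def n_samples(self) -> int:
        return self.classes.shape[0]

    @property
    def T(self) -> int:
        return self.classes.shape[1]


def topT_rankings(posteriors: PosteriorMatrix | np.ndarray, T: int,
                  classifier_id: str = "") -> TopTRanking:
    """Sort each posterior row descending and keep the first T positions.

    Exactly equal posteriors are broken by ascending class index (stable
    sort on the negated values), so rankings are deterministic regardless
    of which backend produced the probabilities.
    """
    if isinstance(posteriors, PosteriorMatrix):
        values = posteriors.values
        classifier_id = classifier_id or posteriors.classifier_id
    else:
        values = np.asarray(posteriors, dtype=np.float64)
    c = values.shape[1]
    if not 1 <= T <= c:
        raise ValueError(f"T={T} outside [1, {c}]")
    order = np.argsort(-values, axis=1, kind="stable")[:, :T]
    return TopTRanking(classifier_id=classifier_id, classes=order, n_classes=c)


def topp_accuracy(ranking: TopTRanking, labels: np.ndarray, p: int) -> float:
    """Fraction of samples whose true class sits within the first p positions."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("cannot compute an accuracy on an empty sample set")
    if not 1 <= p <= ranking.T:
        raise ValueError(f"p={p} outside [1, {ranking.T}]")
    if labels.size != ranking.n_samples:
        raise ValueError("labels/rankings length mismatch")
    hits = np.any(ranking.classes[:, :p] == labels[:, None], axis=1)
    return float(np.mean(hits))


@dataclass
class RankWeightTable:
    """The fusion coefficients: position-wise accuracies, classifier ranks,
    quality weights and position weights."""

    acc: np.ndarray     # (K, T)
    rank: np.ndarray    # (K, T) int, competition ranking
    weight: np.ndarray  # (K, T) = (K + 1 - rank) / K
    f: np.ndarray       # (T,)   = (T + 1 - p) / T
    classifier_ids: list[str] = field(default_factory=list)

    @property
    def K(self) -> int:
        return self.acc.shape[0]

    @property
    def T(self) -> int:
        return self.acc.shape[1]

    def drop(self, j: int) -> "RankWeightTable":
        """Table with classifier ``j`` removed; ranks/weights recomputed."""
        keep = [i for i in range(self.K) if i != j]
        ids = [self.classifier_ids[i] for i in keep] if self.classifier_ids else []
        return rank_and_weight(self.acc[keep], classifier_ids=ids)


def rank_and_weight(acc: np.ndarray, classifier_ids: list[str] | None = None) -> RankWeightTable:
    """Ranks and weights from a (K, T) position-wise accuracy matrix.

    A classifier's rank at position p counts the classifiers strictly
    better at p; equal accuracies are reordered by Top-1 accuracy, and
    classifiers still tied after that share a rank.  Both tie clauses
    reduce to competition ranking on the lexicographic key
    ``(Acc[:, p], Acc[:, 1])``.
    """
    acc = np.asarray(acc, dtype=np.float64)
    if acc.ndim != 2 or acc.shape[0] < 1:
        raise ValueError("accuracy matrix must be (K, T) with K >= 1")
    if not np.all(np.isfinite(acc)):
        raise ValueError("non-finite accuracies")
    if np.any(acc < 0) or np.any(acc > 1):
        raise ValueError("accuracies must lie in [0, 1]")
    k, t = acc.shape
    rank = np.empty((k, t), dtype=np.intp)
    for p in range(t):
        for j in range(k):
            better = sum(
                1
                for l in range(k)
                if (acc[l, p], acc[l, 0]) > (acc[j, p], acc[j, 0])
            )
            rank[j, p] = 1 + better
    weight = (k + 1 - rank) / k
    f = (t + 1 - np.arange(1, t + 1)) / t
    return RankWeightTable(
        acc=acc, rank=rank, weight=weight, f=f,
        classifier_ids=list(classifier_ids or []),
    )


def build_weight_table(
    rankings: list[TopTRanking], labels: np.ndarray
) -> RankWeightTable:
    """Measure ``Acc[j, p]`` for every classifier and position on a labelled
    evaluation set (typically the held-out 20% validation split) and derive
    the rank/weight table."""
    t = rankings[0].T
    if any(r.T != t for r in rankings):
        raise ValueError("rankings disagree on T")
    acc = np.array(
        [[topp_accuracy(r, labels, p) for p in range(1, t + 1)] for r in rankings]
    )
    return rank_and_weight(acc, classifier_ids=[r.classifier_id for r in rankings])


@dataclass
class EnsembleDecision:
    """Fused per-sample decisions: class index or None, tie diagnostics and
    the per-class score matrix."""

    predicted: list  # int | None per sample
    tie_flags: np.ndarray
    scores: np.ndarray  # (M, C)
    strategy: str

    @property
    def n_ties(self) -> int:
        return int(np.sum(self.tie_flags))

    def accuracy(self, labels: np.ndarray) -> float:
        """Top-1 accuracy; an undecided (None) output counts as an error."""
        labels = np.asarray(labels)
        hits = sum(
            1 for pred, y in zip(self.predicted, labels) if pred is not None and pred == y
        )
        return hits / len(labels)


def _check_aligned(rankings: list[TopTRanking], table: RankWeightTable) -> tuple[int, int]:
    if len(rankings) != table.K:
        raise ValueError(f"{len(rankings)} rankings for a K={table.K} table")
    m = rankings[0].n_samples
    c = rankings[0].n_classes
    for r in rankings:
        if r.n_samples != m or r.n_classes != c:
            raise ValueError("rankings cover different sample/class sets")
    return m, c


def _accumulate(rankings, coeff: np.ndarray, m: int, c: int) -> np.ndarray:
    """Score matrix Sum_j Sum_p coeff[j, p] * [classifier j put class i at p]."""
    scores = np.zeros((m, c))
    rows = np.arange(m)
    for j, r in enumerate(rankings):
        for p in range(coeff.shape[1]):
            np.add.at(scores, (rows, r.classes[:, p]), coeff[j, p])
    return scores


def resolve_tie(
    tied_classes, rankings: list[TopTRanking], table: RankWeightTable, sample: int
):
    """Break a score tie via the best base classifier's Top-1 indication.

    The classifier(s) with maximal Top-1 accuracy are consulted; if they
    unanimously put one class at their Top-1 position and that class is
    among the tied ones, it wins.  Any ambiguity — several best classifiers
    disagreeing, or an indication outside the tied set — yields ``None``.
    """
    tied = set(int(t) for t in tied_classes)
    if len(tied) < 2:
        raise ValueError("resolve_tie needs at least two tied classes")
    best_acc = table.acc[:, 0].max()
    best = np.flatnonzero(table.acc[:, 0] == best_acc)
    indications = {int(rankings[j].classes[sample, 0]) for j in best}
    if len(indications) == 1:
        (winner,) = indications
        if winner in tied:
            return winner
    return None


def _decide(scores, rankings, table, strategy) -> EnsembleDecision:
    m = scores.shape[0]
    predicted: list = [None] * m
    tie_flags = np.zeros(m, dtype=bool)
    for i in range(m):
        row = scores[i]
        smax = row.max()
        tol = SCORE_TIE_RTOL * max(abs(smax), 1.0)
        tied = np.flatnonzero(row >= smax - tol)
        if tied.size == 1:
            predicted[i] = int(tied[0])
        else:
            tie_flags[i] = True
            predicted[i] = resolve_tie(tied, rankings, table, i)
    return EnsembleDecision(
        predicted=predicted, tie_flags=tie_flags, scores=scores, strategy=strategy
    )


def vote_rank_order(
    rankings: list[TopTRanking], table: RankWeightTable
) -> EnsembleDecision:
    """Weighted vote by rank order: one Top-1 vote per classifier, weighted
    by its position-1 quality weight."""
    m, c = _check_aligned(rankings, table)
    coeff = table.weight[:, :1]
    scores = _accumulate(rankings, coeff, m, c)
    return _decide(scores, rankings, table, "rank_order")


def vote_topT_additive(
    rankings: list[TopTRanking], table: RankWeightTable, lam: float
) -> EnsembleDecision:
    """Rank-based additive weighted Top-T vote with balance parameter
    ``lam`` (>= 0; values above 1 emphasise ranking position and make the
    quality coefficient negative, literally as defined)."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    m, c = _check_aligned(rankings, table)
    coeff = lam * table.f[None, :] + (1.0 - lam) * table.weight
    scores = _accumulate(rankings, coeff, m, c)
    return _decide(scores, rankings, table, "topT_additive")


@dataclass
class LambdaSweep:
    lambdas: np.ndarray
    accuracies: np.ndarray
    tie_counts: np.ndarray
    best_lambda: float
    best_accuracy: float


def sweep_lambda(
    rankings: list[TopTRanking],
    table: RankWeightTable,
    labels: np.ndarray,
    grid=DEFAULT_LAMBDA_GRID,
) -> LambdaSweep:
    """Accuracy of the Top-T additive vote across a lambda grid.

    Undecided outputs count as errors.  The reported optimum is the
    smallest grid value attaining the maximal accuracy.
    """
    grid = np.asarray(grid, dtype=np.float64)
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    accs = np.empty(grid.size)
    ties = np.empty(grid.size, dtype=int)
    for i, lam in enumerate(grid):
        decision = vote_topT_additive(rankings, table, float(lam))
        accs[i] = decision.accuracy(labels)
        ties[i] = decision.n_ties
    best_i = int(np.argmax(accs))  # argmax returns the first (smallest lambda)
    return LambdaSweep(
        lambdas=grid,
        accuracies=accs,
        tie_counts=ties,
        best_lambda=float(grid[best_i]),
        best_accuracy=float(accs[best_i]),
    )
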
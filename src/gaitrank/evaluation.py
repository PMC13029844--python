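"""Evaluation protocols: the three train/test scenarios, ablation and the
body-mass confusion analysis.

Three closed-set identification scenarios probe robustness to an
asymmetric-load covariate:

* **A** (reference): train and test on unloaded gait, 10-fold
  cross-validation at trial level (every subject appears in every training
  fold, so the class set stays closed);
* **B** (realistic): train on unloaded gait only, test on briefcase-loaded
  gait — the deployment situation where enrolment happens unburdened;
* **C**: Scenario B with nine-fold augmentation of the training cycles
  (test cycles are never augmented).

Every scenario fits the K configured base classifiers, measures their
position-wise accuracies on the held-out validation split, fuses test
rankings with both voting strategies, sweeps the lambda balance parameter
for the Top-T additive vote, and reports per-classifier and ensemble
accuracies (mean +/- sd over folds for Scenario A).  Undecided ensemble
outputs count as errors and are reported separately as tie counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .augment import AugmentationSpec, DEFAULT_SPEC, expand_scenario_c
from .classifiers import (
    ClassifierConfig,
    FittedClassifier,
    PosteriorMatrix,
    predict_posteriors,
    train_classifier,
)
from .ensemble import (
    DEFAULT_LAMBDA_GRID,
    LambdaSweep,
    RankWeightTable,
    TopTRanking,
    build_weight_table,
    sweep_lambda,
    topT_rankings,
    vote_rank_order,
    vote_topT_additive,
)
from .grf import GaitDataset

__all__ = [
    "topk_accuracy",
    "FusionResult",
    "ScenarioReport",
    "AblationRow",
    "MassGapReport",
    "run_scenario",
    "fit_and_fuse",
    "ablate_leave_one_out",
    "mass_confusion_analysis",
]


def topk_accuracy(predictions, labels: np.ndarray, k: int = 1) -> float:
    """Top-k accuracy for rankings (any k <= T) or fused decisions (k = 1,
    None counting as wrong)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty evaluation set")
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(predictions, TopTRanking):
        hits = np.any(predictions.classes[:, :k] == labels[:, None], axis=1)
        return float(np.mean(hits))
    if k != 1:
        raise ValueError("fused decisions support only k = 1")
    return predictions.accuracy(labels)


@dataclass
class FusionResult:
    """Everything one train/test pass produces."""

    base_top1: dict[str, float]
    base_top5: dict[str, float]
    rank_order_accuracy: float
    rank_order_ties: int
    topT_accuracy: float
    topT_best_lambda: float
    topT_ties: int
    lambda_curve: LambdaSweep
    table: RankWeightTable
    val_rankings: list[TopTRanking]
    test_rankings: list[TopTRanking]
    test_labels: np.ndarray
    val_labels: np.ndarray
    test_predictions_topT: list
    fitted: list[FittedClassifier]


@dataclass
class AblationRow:
    removed: str | None
    accuracy: float
    delta: float
    ties: int
    best_lambda: float | None = None

    def to_dict(self) -> dict:
        return {
            "removed": self.removed,
            "accuracy": self.accuracy,
            "delta": self.delta,
            "ties": self.ties,
            "best_lambda": self.best_lambda,
        }


@dataclass
class ScenarioReport:
    """Aggregated scenario results; serialises losslessly to JSON."""

    scenario: str
    base_top1: dict[str, list[float]]
    base_top5: dict[str, list[float]]
    rank_order_accuracy: list[float]
    rank_order_ties: int
    topT_accuracy: list[float]
    topT_best_lambda: list[float]
    topT_ties: int
    lambda_grid: list[float]
    lambda_accuracy: list[list[float]]
    ablation: list[dict] = field(default_factory=list)
    mass_gap: dict | None = None
    n_train: int = 0
    n_test: int = 0

    def mean_sd(self, values: list[float]) -> tuple[float, float]:
        arr = np.asarray(values, dtype=float)
        return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ScenarioReport":
        return cls(**json.loads(text))


def _preds_topk(post: PosteriorMatrix, labels, k):
    r = topT_rankings(post, min(k, post.n_classes))
    return topk_accuracy(r, labels, min(k, post.n_classes))


def fit_and_fuse(
    train: GaitDataset,
    test: GaitDataset,
    configs: list[ClassifierConfig],
    T: int = 5,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    augment_seed: int | None = None,
    augment_spec: AugmentationSpec = DEFAULT_SPEC,
    seed: int = 0,
) -> FusionResult:
    """Train the harness on one split and fuse its test rankings.

    All K members share one stratified 80/20 trial-level split, so the
    rank/weight table is measured on a common validation set the fits never
    optimised on.  When ``augment_seed`` is given, the 80% fitting part is
    expanded nine-fold first (validation and test stay untouched).
    """
    from .classifiers import stratified_split

    labels = train.labels()
    test_labels = test.labels()
    t_eff = min(T, len(train.class_ids()))

    split_rng = np.random.default_rng(np.random.SeedSequence((seed, 37)))
    split = stratified_split(labels, configs[0].val_fraction, split_rng)
    fit_dataset = None
    if augment_seed is not None:
        fit_dataset = expand_scenario_c(
            train.subset(split[0]), seed=augment_seed, spec=augment_spec
        )

    val_rankings, test_rankings = [], []
    base_top1, base_top5 = {}, {}
    fitted_all = []
    val_labels = None
    for i, cfg in enumerate(configs):
        cid = f"{cfg.architecture}#{i}"
        fitted = train_classifier(
            cfg, train, classifier_id=cid, fit_dataset=fit_dataset, split=split
        )
        fitted_all.append(fitted)
        if val_labels is None:
            val_labels = labels[fitted.val_indices]
        val_post = predict_posteriors(fitted, train.signals()[fitted.val_indices])
        val_rankings.append(topT_rankings(val_post, t_eff, cid))
        test_post = predict_posteriors(fitted, test)
        test_rankings.append(topT_rankings(test_post, t_eff, cid))
        base_top1[cid] = topk_accuracy(test_rankings[-1], test_labels, 1)
        base_top5[cid] = _preds_topk(test_post, test_labels, 5)

    table = build_weight_table(val_rankings, val_labels)
    ro = vote_rank_order(test_rankings, table)
    sweep = sweep_lambda(test_rankings, table, test_labels, lambda_grid)
    best = vote_topT_additive(test_rankings, table, sweep.best_lambda)
    return FusionResult(
        base_top1=base_top1,
        base_top5=base_top5,
        rank_order_accuracy=ro.accuracy(test_labels),
        rank_order_ties=ro.n_ties,
        topT_accuracy=sweep.best_accuracy,
        topT_best_lambda=sweep.best_lambda,
        topT_ties=best.n_ties,
        lambda_curve=sweep,
        table=table,
        val_rankings=val_rankings,
        test_rankings=test_rankings,
        test_labels=test_labels,
        val_labels=val_labels,
        test_predictions_topT=best.predicted,
        fitted=fitted_all,
    )


def _trial_folds(ds: GaitDataset, n_folds: int, rng: np.random.Generator):
    """Partition trials into folds within each subject, so every subject is
    present in every training fold (closed-set requirement)."""
    folds = [[] for _ in range(n_folds)]
    by_subject: dict[str, list[int]] = {}
    for i, c in enumerate(ds.cycles):
        by_subject.setdefault(c.subject_id, []).append(i)
    for sid in sorted(by_subject):
        idx = rng.permutation(by_subject[sid])
        offset = int(rng.integers(n_folds))
        for pos, i in enumerate(idx):
            folds[(pos + offset) % n_folds].append(int(i))
    return folds


def run_scenario(
    scenario: str,
    unloaded: GaitDataset,
    loaded: GaitDataset,
    configs: list[ClassifierConfig],
    seed: int = 0,
    T: int = 5,
    n_folds: int = 10,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    augment_spec: AugmentationSpec = DEFAULT_SPEC,
    with_ablation: bool = False,
    with_mass_gap: bool = False,
) -> ScenarioReport:
    """Run one evaluation scenario end to end and aggregate the report."""
    scenario = scenario.upper()
    if scenario not in ("A", "B", "C"):
        raise ValueError(f"unknown scenario {scenario!r}")
    if set(unloaded.subjects) != set(loaded.subjects):
        raise ValueError("scenarios require a shared subject roster")

    results: list[FusionResult] = []
    n_train = n_test = 0
    if scenario == "A":
        rng = np.random.default_rng(np.random.SeedSequence((seed, 31)))
        folds = _trial_folds(unloaded, n_folds, rng)
        for f in range(n_folds):
            test_idx = folds[f]
            train_idx = [i for g in range(n_folds) if g != f for i in folds[g]]
            results.append(
                fit_and_fuse(
                    unloaded.subset(train_idx),
                    unloaded.subset(test_idx),
                    configs,
                    T=T,
                    lambda_grid=lambda_grid,
                    seed=seed + f,
                )
            )
            n_train, n_test = len(train_idx), len(test_idx)
    else:
        augment_seed = seed + 101 if scenario == "C" else None
        res = fit_and_fuse(
            unloaded,
            loaded,
            configs,
            T=T,
            lambda_grid=lambda_grid,
            augment_seed=augment_seed,
            augment_spec=augment_spec,
            seed=seed,
        )
        results.append(res)
        n_train, n_test = len(unloaded), len(loaded)
        if scenario == "C":
            n_train = 9 * len(res.fitted[0].train_indices) + len(
                res.fitted[0].val_indices
            )

    report = ScenarioReport(
        scenario=scenario,
        base_top1={
            cid: [r.base_top1[cid] for r in results] for cid in results[0].base_top1
        },
        base_top5={
            cid: [r.base_top5[cid] for r in results] for cid in results[0].base_top5
        },
        rank_order_accuracy=[r.rank_order_accuracy for r in results],
        rank_order_ties=sum(r.rank_order_ties for r in results),
        topT_accuracy=[r.topT_accuracy for r in results],
        topT_best_lambda=[r.topT_best_lambda for r in results],
        topT_ties=sum(r.topT_ties for r in results),
        lambda_grid=[float(v) for v in results[0].lambda_curve.lambdas],
        lambda_accuracy=[[float(a) for a in r.lambda_curve.accuracies] for r in results],
        n_train=n_train,
        n_test=n_test,
    )
    last = results[-1]
    if with_ablation:
        report.ablation = [
            row.to_dict()
            for row in ablate_leave_one_out(
                last.val_rankings,
                last.val_labels,
                last.test_rankings,
                last.test_labels,
                strategy="topT",
                lambda_grid=lambda_grid,
            )
        ]
    if with_mass_gap:
        masses = {
            i: unloaded.subjects[sid].body_mass_kg
            for i, sid in enumerate(unloaded.class_ids())
        }
        report.mass_gap = mass_confusion_analysis(
            last.test_predictions_topT, last.test_labels, masses
        ).to_dict()
    return report


def ablate_leave_one_out(
    val_rankings: list[TopTRanking],
    val_labels: np.ndarray,
    test_rankings: list[TopTRanking],
    test_labels: np.ndarray,
    strategy: str = "topT",
    lambda_grid=DEFAULT_LAMBDA_GRID,
) -> list[AblationRow]:
    """Remove one classifier at a time and re-fuse with K-1.

    Ranks, weights and (for the Top-T strategy) the optimal lambda are
    recomputed for every reduced ensemble.  The first row is the full
    ensemble (delta 0 by definition).
    """
    k = len(val_rankings)
    if k < 2:
        raise ValueError("ablation needs at least two classifiers")
    if strategy not in ("topT", "rank_order"):
        raise ValueError(f"unknown strategy {strategy!r}")

    def evaluate(vr, tr):
        table = build_weight_table(vr, val_labels)
        if strategy == "rank_order":
            d = vote_rank_order(tr, table)
            return d.accuracy(test_labels), d.n_ties, None
        sweep = sweep_lambda(tr, table, test_labels, lambda_grid)
        d = vote_topT_additive(tr, table, sweep.best_lambda)
        return sweep.best_accuracy, d.n_ties, sweep.best_lambda

    full_acc, full_ties, full_lam = evaluate(val_rankings, test_rankings)
    rows = [AblationRow(None, full_acc, 0.0, full_ties, full_lam)]
    for j in range(k):
        vr = [r for i, r in enumerate(val_rankings) if i != j]
        tr = [r for i, r in enumerate(test_rankings) if i != j]
        acc, ties, lam = evaluate(vr, tr)
        rows.append(
            AblationRow(test_rankings[j].classifier_id, acc, acc - full_acc, ties, lam)
        )
    return rows


@dataclass
class MassGapReport:
    """Distribution of body-mass differences between confused identities."""

    gaps_kg: np.ndarray
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    ecdf: dict[float, float | None]
    n_errors: int
    n_samples: int
    median_gap_kg: float | None
    all_pairs_median_kg: float

    def to_dict(self) -> dict:
        return {
            "n_errors": self.n_errors,
            "n_samples": self.n_samples,
            "bin_edges": [float(v) for v in self.bin_edges],
            "bin_counts": [int(v) for v in self.bin_counts],
            "ecdf": {str(k): v for k, v in self.ecdf.items()},
            "median_gap_kg": self.median_gap_kg,
            "all_pairs_median_kg": self.all_pairs_median_kg,
        }


def mass_confusion_analysis(
    predictions,
    labels: np.ndarray,
    masses: dict[int, float],
    bin_width_kg: float = 1.0,
    thresholds=(4.6, 11.0),
) -> MassGapReport:
    """Histogram and ECDF of |mass(true) - mass(predicted)| over errors.

    If identification errors concentrate among similar-mass subjects the
    histogram is right-skewed and the ECDF rises steeply near zero — the
    signature that confusions follow physiology rather than chance.  A
    run with no errors yields an empty histogram and an undefined ECDF.
    """
    labels = np.asarray(labels)
    preds = predictions.predicted if hasattr(predictions, "predicted") else predictions
    gaps = []
    for pred, y in zip(preds, labels):
        if pred is None or pred == y:
            continue
        if int(pred) not in masses or int(y) not in masses:
            raise KeyError(f"class {pred} missing from the mass roster")
        gaps.append(abs(masses[int(y)] - masses[int(pred)]))
    gaps = np.asarray(gaps, dtype=float)

    mass_values = np.array(sorted(masses.values()))
    iu = np.triu_indices(mass_values.size, k=1)
    all_gaps = np.abs(mass_values[:, None] - mass_values[None, :])[iu]

    if gaps.size:
        top = max(np.ceil(gaps.max() / bin_width_kg), 1.0) * bin_width_kg
        edges = np.arange(0.0, top + bin_width_kg / 2, bin_width_kg)
        counts, _ = np.histogram(gaps, bins=edges)
        ecdf = {float(t): float(np.mean(gaps <= t)) for t in thresholds}
        median = float(np.median(gaps))
    else:
        edges = np.array([0.0])
        counts = np.array([], dtype=int)
        ecdf = {float(t): None for t in thresholds}
        median = None
    return MassGapReport(
        gaps_kg=gaps,
        bin_edges=edges,
        bin_counts=counts,
        ecdf=ecdf,
        n_errors=int(gaps.size),
        n_samples=int(labels.size),
        median_gap_kg=median,
        all_pairs_median_kg=float(np.median(all_gaps)),
    )
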
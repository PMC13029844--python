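"""Unit and property tests for the rank-based fusion layer."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gaitrank.ensemble import (
    DEFAULT_LAMBDA_GRID,
    TopTRanking,
    build_weight_table,
    rank_and_weight,
    resolve_tie,
    sweep_lambda,
    topT_rankings,
    topp_accuracy,
    vote_rank_order,
    vote_topT_additive,
)

from .oracles import brute_decide, brute_scores


def ranking(rows, n_classes, cid="clf"):
    return TopTRanking(classifier_id=cid, classes=np.array(rows), n_classes=n_classes)


# ------------------------------------------------------------------
# Top-T extraction
# ------------------------------------------------------------------

@pytest.mark.parametrize(
    "row, T, expected",
    [
        ((0.5, 0.3, 0.2), 2, [0, 1]),
        ((0.4, 0.4, 0.2), 2, [0, 1]),  # exact tie -> lower class id first
        ((0.1, 0.2, 0.7), 3, [2, 1, 0]),
    ],
)
def test_topT_ordering_and_tie_rule(row, T, expected):
    r = topT_rankings(np.array([row]), T)
    assert r.classes[0].tolist() == expected


def test_topT_full_depth_is_permutation(rng):
    p = rng.dirichlet(np.ones(6), size=10)
    r = topT_rankings(p, 6)
    for row in r.classes:
        assert sorted(row.tolist()) == list(range(6))


def test_topT_rejects_bad_depth():
    with pytest.raises(ValueError):
        topT_rankings(np.eye(3), 4)


# ------------------------------------------------------------------
# Top-p accuracy
# ------------------------------------------------------------------

def test_topp_accuracy_hand_count():
    # true class at positions 1, 2, 2, absent
    r = ranking([[0, 1], [1, 0], [2, 3], [1, 2]], 4)
    y = np.array([0, 0, 3, 3])
    assert topp_accuracy(r, y, 1) == 0.25
    assert topp_accuracy(r, y, 2) == 0.75


def test_topp_accuracy_perfect_and_absent():
    r = ranking([[1, 0], [2, 0]], 3)
    assert topp_accuracy(r, np.array([1, 2]), 1) == 1.0
    assert topp_accuracy(r, np.array([1, 2]), 2) == 1.0
    assert topp_accuracy(r, np.array([0, 1]), 2) == 0.5


def test_topp_accuracy_empty_set_errors():
    r = ranking(np.empty((0, 2), dtype=int), 3)
    with pytest.raises(ValueError):
        topp_accuracy(r, np.array([]), 1)


# ------------------------------------------------------------------
# ranks and weights
# ------------------------------------------------------------------

def test_rank_weight_strict_ordering():
    t = rank_and_weight(np.array([[0.9], [0.8], [0.7]]))
    assert t.rank[:, 0].tolist() == [1, 2, 3]
    assert np.allclose(t.weight[:, 0], [1.0, 2 / 3, 1 / 3])


def test_rank_weight_tie_broken_by_top1():
    acc = np.array([[0.8, 0.9], [0.9, 0.9], [0.6, 0.7]])
    t = rank_and_weight(acc)
    assert t.rank[:, 1].tolist() == [2, 1, 3]


def test_rank_weight_persistent_tie_shares_rank():
    acc = np.full((3, 2), 0.75)
    t = rank_and_weight(acc)
    assert np.all(t.rank == 1)
    assert np.all(t.weight == 1.0)


def test_rank_weight_position_weights():
    t = rank_and_weight(np.array([[0.5, 0.6, 0.7, 0.8, 0.9]]))
    assert np.allclose(t.f, [1.0, 0.8, 0.6, 0.4, 0.2])
    assert t.f[0] == 1.0 and t.f[-1] == 1.0 / 5


def test_rank_weight_rejects_invalid():
    with pytest.raises(ValueError):
        rank_and_weight(np.array([[np.nan]]))
    with pytest.raises(ValueError):
        rank_and_weight(np.array([[1.2]]))


@given(
    st.integers(2, 6).flatmap(
        lambda k: st.lists(
            st.lists(st.integers(0, 10).map(lambda v: v / 10), min_size=3, max_size=3),
            min_size=k,
            max_size=k,
        )
    )
)
def test_rank_weight_bounds_property(acc_rows):
    """Weights always stay in [1/K, 1] and ranks in {1..K}."""
    acc = np.array(acc_rows)
    t = rank_and_weight(acc)
    k = acc.shape[0]
    assert np.all((t.rank >= 1) & (t.rank <= k))
    assert np.all(t.weight >= 1 / k - 1e-12)
    assert np.all(t.weight <= 1.0 + 1e-12)


# ------------------------------------------------------------------
# voting strategies
# ------------------------------------------------------------------

def table_with_top1_weights():
    """Acc matrix whose top-1 column yields weights (1, .8, .6, .4, .2)."""
    acc = np.array([[0.9], [0.8], [0.7], [0.6], [0.5]])
    return rank_and_weight(acc)


def test_rank_order_weighted_majority():
    table = table_with_top1_weights()
    rankings = [ranking([[c]], 3) for c in (0, 0, 1, 1, 1)]
    d = vote_rank_order(rankings, table)
    assert d.predicted == [0]
    assert np.isclose(d.scores[0, 0], 1.8) and np.isclose(d.scores[0, 1], 1.2)
    assert d.n_ties == 0


def test_rank_order_unanimous():
    table = table_with_top1_weights()
    rankings = [ranking([[2]], 3) for _ in range(5)]
    d = vote_rank_order(rankings, table)
    assert d.predicted == [2] and d.n_ties == 0


def test_rank_order_forced_tie_goes_to_tie_path():
    table = rank_and_weight(np.array([[0.8], [0.8]]))
    rankings = [ranking([[0]], 2, "a"), ranking([[1]], 2, "b")]
    d = vote_rank_order(rankings, table)
    assert d.tie_flags[0]
    assert d.predicted == [None]  # two equally-best classifiers disagree


def test_topT_reduces_to_rank_order_at_T1_lambda0():
    rng = np.random.default_rng(7)
    for _ in range(50):
        k, c = rng.integers(2, 5), rng.integers(2, 5)
        acc = rng.random((k, 1))
        table = rank_and_weight(acc)
        rankings = [
            ranking(rng.integers(0, c, size=(4, 1)), c, f"c{j}") for j in range(k)
        ]
        a = vote_rank_order(rankings, table)
        b = vote_topT_additive(rankings, table, 0.0)
        assert a.predicted == b.predicted


def test_topT_identical_classifiers_follow_top1():
    acc = np.full((3, 2), 0.9)
    table = rank_and_weight(acc)
    rankings = [ranking([[1, 0], [2, 1]], 3, f"c{j}") for j in range(3)]
    for lam in (0.3, 1.0, 2.5):
        d = vote_topT_additive(rankings, table, lam)
        assert d.predicted == [1, 2]


def test_topT_lambda1_tie_example():
    # lambda = 1 cancels the quality term; f = (1.0, 0.5)
    acc = np.array([[0.9, 0.95], [0.8, 0.9]])
    table = rank_and_weight(acc)
    rankings = [ranking([[0, 1]], 3, "a"), ranking([[1, 0]], 3, "b")]
    d = vote_topT_additive(rankings, table, 1.0)
    assert np.allclose(d.scores[0, [0, 1]], 1.5)
    assert d.tie_flags[0]
    # the best (first) classifier's top-1 is class 0, which is in the tied set
    assert d.predicted == [0]


def test_topT_rejects_negative_lambda():
    table = table_with_top1_weights()
    with pytest.raises(ValueError):
        vote_topT_additive([ranking([[0]], 3) for _ in range(5)], table, -0.1)


# ------------------------------------------------------------------
# tie resolution
# ------------------------------------------------------------------

def test_resolve_tie_best_classifier_indicates_member():
    table = rank_and_weight(np.array([[0.9, 0.9], [0.5, 0.6]]))
    rankings = [ranking([[0, 1]], 3, "best"), ranking([[1, 0]], 3, "worse")]
    assert resolve_tie([0, 1], rankings, table, 0) == 0


def test_resolve_tie_disagreeing_best_classifiers():
    table = rank_and_weight(np.array([[0.9], [0.9]]))
    rankings = [ranking([[0]], 3, "a"), ranking([[1]], 3, "b")]
    assert resolve_tie([0, 1], rankings, table, 0) is None


def test_resolve_tie_indication_outside_tied_set():
    table = rank_and_weight(np.array([[0.9], [0.5]]))
    rankings = [ranking([[2]], 3, "best"), ranking([[0]], 3, "worse")]
    assert resolve_tie([0, 1], rankings, table, 0) is None


# ------------------------------------------------------------------
# exhaustive oracle equivalence (small worlds)
# ------------------------------------------------------------------

@pytest.mark.parametrize("k,c,t", [(1, 2, 1), (2, 3, 2), (3, 3, 2), (2, 4, 3)])
def test_vote_matches_brute_force_exhaustively(k, c, t):
    """Both strategies agree with a literal loop over the indicator
    definition for every ranking combination of a small world."""
    perms = list(itertools.permutations(range(c), t))
    combos = list(itertools.product(perms, repeat=k))
    rng = np.random.default_rng(42)
    acc = rng.uniform(0.3, 1.0, size=(k, t))
    acc.sort(axis=1)  # Acc must be nondecreasing in p
    table = rank_and_weight(acc)
    # stack every combination as one sample per row
    rankings = [
        TopTRanking(
            classifier_id=f"c{j}",
            classes=np.array([combo[j] for combo in combos]),
            n_classes=c,
        )
        for j in range(k)
    ]
    ro = vote_rank_order(rankings, table)
    assert np.allclose(ro.scores, brute_scores(rankings, table.weight, strategy="rank_order"))
    assert ro.predicted == brute_decide(ro.scores, rankings, table.acc[:, 0])
    for lam in (0.0, 0.5, 1.0, 1.3):
        d = vote_topT_additive(rankings, table, lam)
        bs = brute_scores(rankings, table.weight, lam=lam)
        assert np.allclose(d.scores, bs)
        assert d.predicted == brute_decide(bs, rankings, table.acc[:, 0])


def test_reduction_identity_random_instances():
    """T = 1, lambda = 0 Top-T voting coincides with the rank-order vote on
    1000 random instances."""
    rng = np.random.default_rng(99)
    for _ in range(1000):
        k = int(rng.integers(1, 6))
        c = int(rng.integers(2, 6))
        acc = rng.random((k, 1))
        table = rank_and_weight(acc)
        rankings = [
            ranking(rng.integers(0, c, size=(1, 1)), c, f"c{j}") for j in range(k)
        ]
        assert (
            vote_rank_order(rankings, table).predicted
            == vote_topT_additive(rankings, table, 0.0).predicted
        )


# ------------------------------------------------------------------
# structural properties
# ------------------------------------------------------------------

@given(st.integers(0, 2**31 - 1))
def test_label_permutation_equivariance(seed):
    """Permuting class ids permutes decisions identically."""
    rng = np.random.default_rng(seed)
    k, c, t, m = 3, 5, 3, 6
    post = rng.dirichlet(np.ones(c), size=(k, m))
    acc = np.sort(rng.uniform(0.2, 1.0, size=(k, t)), axis=1)
    table = rank_and_weight(acc)
    rankings = [topT_rankings(post[j], t, f"c{j}") for j in range(k)]
    perm = rng.permutation(c)
    rankings_p = [
        TopTRanking(f"c{j}", perm[rankings[j].classes], c) for j in range(k)
    ]
    for decide in (
        vote_rank_order,
        lambda r, tb: vote_topT_additive(r, tb, 1.2),
    ):
        d = decide(rankings, table)
        dp = decide(rankings_p, table)
        expected = [None if v is None else int(perm[v]) for v in d.predicted]
        assert dp.predicted == expected


def test_duplicating_all_classifiers_preserves_decisions(rng):
    k, c, t, m = 3, 4, 2, 8
    post = rng.dirichlet(np.ones(c), size=(k, m))
    acc = np.sort(rng.uniform(0.2, 1.0, size=(k, t)), axis=1)
    rankings = [topT_rankings(post[j], t, f"c{j}") for j in range(k)]
    table = rank_and_weight(acc)
    doubled = rank_and_weight(np.vstack([acc, acc]))
    rankings2 = rankings + [
        TopTRanking(f"d{j}", r.classes.copy(), c) for j, r in enumerate(rankings)
    ]
    for lam in (0.4, 1.3):
        a = vote_topT_additive(rankings, table, lam)
        b = vote_topT_additive(rankings2, doubled, lam)
        assert a.predicted == b.predicted
    assert (
        vote_rank_order(rankings, table).predicted
        == vote_rank_order(rankings2, doubled).predicted
    )


# ------------------------------------------------------------------
# lambda sweep
# ------------------------------------------------------------------

def test_default_lambda_grid_has_50_points():
    assert len(DEFAULT_LAMBDA_GRID) == 50
    assert DEFAULT_LAMBDA_GRID[0] == pytest.approx(0.1)
    assert DEFAULT_LAMBDA_GRID[-1] == pytest.approx(5.0)


def test_sweep_flat_for_single_classifier(rng):
    c = 4
    post = rng.dirichlet(np.ones(c), size=6)
    r = [topT_rankings(post, 3, "only")]
    table = rank_and_weight(np.array([[0.5, 0.7, 0.9]]))
    labels = post.argmax(axis=1)
    sweep = sweep_lambda(r, table, labels)
    assert np.allclose(sweep.accuracies, sweep.accuracies[0])


def test_sweep_finds_deep_rank_optimum():
    """A K=3 instance (found by exhaustive search, frozen here) where
    position-emphasised voting is strictly better: every lambda < 1 scores
    at most 0.5, the optimum 0.75 first appears at lambda = 1.1.  The whole
    curve is re-derived with the brute-force scorer."""
    acc = np.array(
        [
            [0.4124, 0.8764, 0.9536],
            [0.2161, 0.2895, 0.8153],
            [0.3891, 0.4801, 0.8964],
        ]
    )
    rankings = [
        ranking([[1, 0, 3], [1, 3, 0], [1, 0, 2], [0, 2, 3]], 4, "a"),
        ranking([[1, 2, 3], [1, 2, 0], [0, 3, 2], [3, 2, 0]], 4, "b"),
        ranking([[3, 0, 2], [3, 0, 2], [3, 2, 1], [3, 2, 0]], 4, "x"),
    ]
    labels = np.array([1, 1, 3, 2])
    table = rank_and_weight(acc)
    sweep = sweep_lambda(rankings, table, labels)
    assert sweep.best_lambda == pytest.approx(1.1)
    assert sweep.best_accuracy == pytest.approx(0.75)
    assert sweep.accuracies[sweep.lambdas < 1.0].max() <= 0.5
    for lam, acc_pt in zip(sweep.lambdas, sweep.accuracies):
        scores = brute_scores(rankings, table.weight, lam=lam)
        preds = brute_decide(scores, rankings, table.acc[:, 0])
        ref = np.mean([p == y for p, y in zip(preds, labels)])
        assert acc_pt == pytest.approx(ref)


def test_build_weight_table_acc_monotone_in_p(small_study):
    """Measured Acc[j, p] is nondecreasing in p on real posteriors."""
    rng = np.random.default_rng(3)
    c, m, t = 6, 40, 4
    post = rng.dirichlet(np.ones(c) * 0.5, size=(3, m))
    labels = rng.integers(0, c, size=m)
    rankings = [topT_rankings(post[j], t, f"c{j}") for j in range(3)]
    table = build_weight_table(rankings, labels)
    assert np.all(np.diff(table.acc, axis=1) >= -1e-12)
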
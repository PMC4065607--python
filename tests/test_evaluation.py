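"""Ranking metrics, CV protocols, and distance-constrained subsampling."""

import itertools

import numpy as np
import pytest

from megadesign.evaluation import (
    CVSummary,
    UndefinedAUCError,
    auc,
    distance_subsample,
    evaluate_pool,
    learning_curve,
    outer_cv,
    random_scorer_hit_probability,
    top_n,
)
from megadesign.scaffold import build_palindrome


def brute_force_auc(scores, labels):
    """All positive-negative pairs; ties count one half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p, n in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


def test_auc_examples():
    assert auc([3, 2, 1], [1, 1, 0]) == 1.0
    assert auc([1, 2, 3], [1, 0, 0]) == 0.0
    assert auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == 0.75
    with pytest.raises(UndefinedAUCError):
        auc([1, 2], [1, 1])


def test_auc_matches_brute_force_with_ties():
    rng = np.random.default_rng(0)
    for _ in range(300):
        n = rng.integers(4, 25)
        scores = rng.choice([0.1, 0.2, 0.3, 0.5, 0.9], size=n)
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            continue
        assert abs(auc(scores, labels) - brute_force_auc(scores, labels)) < 1e-12


def test_top_n_rules():
    scores = [0.9, 0.8, 0.7, 0.6, 0.5]
    assert top_n(scores, [0, 1, 1, 0, 0], n=10) == (2, True)
    assert top_n(scores, [0, 0, 0, 0, 0], n=3) == (0, False)
    # fewer candidates than N: use all
    assert top_n([1, 2], [1, 1], n=10) == (2, True)
    # deterministic lexicographic tie-break
    assert top_n([1, 1, 1], [0, 1, 0], n=1, keys=["b", "a", "c"]) == (1, True)
    assert top_n([1, 1, 1], [0, 1, 0], n=1, keys=["a", "b", "c"]) == (0, False)
    with pytest.raises(ValueError):
        top_n(scores, [1, 0, 0, 0, 0], n=0)


def test_evaluate_pool_single_class_flags_auc_only():
    ev = evaluate_pool([3, 2, 1], [1, 1, 1], n=2)
    assert np.isnan(ev.auc) and ev.note
    assert ev.top_n == 2 and ev.hit_n


def test_random_scorer_matches_hypergeometric_closed_form():
    rng = np.random.default_rng(1)
    pool, n_pos, n = 80, 4, 10
    labels = np.array([1] * n_pos + [0] * (pool - n_pos))
    hits = [
        top_n(rng.random(pool), labels, n=n)[1] for _ in range(4000)
    ]
    expected = random_scorer_hit_probability(pool, n_pos, n)
    assert np.mean(hits) == pytest.approx(expected, abs=0.025)


def test_cv_summary_aggregates_are_recomputable():
    import pandas as pd

    per_target = pd.DataFrame(
        {
            "replicate": [0, 0, 1, 1],
            "target": list("abcd"),
            "auc": [0.8, 0.6, 1.0, 0.5],
            "top_n": [2, 0, 3, 1],
            "hit_n": [True, False, True, True],
        }
    )
    s = CVSummary(per_target)
    agg = s.aggregates
    assert agg["mean_auc"] == pytest.approx(np.mean([0.7, 0.75]))
    assert agg["mean_top_n"] == pytest.approx(np.mean([1.0, 2.0]))
    assert agg["pct_top_n"] == pytest.approx(np.mean([50.0, 100.0]))
    # %TopN is the mean of hitN; mean TopN dominates the hit rate
    assert agg["mean_top_n"] >= agg["pct_top_n"] / 100.0


def test_outer_cv_split_arithmetic_and_shapes(tiny_world):
    _, dataset = tiny_world
    cheap = {"members": ("lasso",), "max_negatives_per_target": 60}
    summary = outer_cv(
        dataset, replicates=2, feature_group="Mact", seed=3, config=cheap
    )
    # 8 targets at fraction 0.1 -> exactly 1 test target per replicate
    assert (summary.per_target.groupby("replicate").size() == 1).all()
    assert summary.meta["mean_train_targets"] == 7
    agg = summary.aggregates
    assert agg["n_replicates"] == 2
    assert 0 <= agg["mean_auc"] <= 1

    from megadesign.evaluation import _split_targets

    train, test = _split_targets(251, 0.1, np.random.default_rng(0))
    assert len(train) == 226 and len(test) == 25


def test_learning_curve_full_size_reproduces_outer_cv(tiny_world):
    _, dataset = tiny_world
    cheap = {"members": ("lasso",), "max_negatives_per_target": 60}
    cv = outer_cv(dataset, replicates=1, feature_group="Mact", seed=9, config=cheap)
    curve = learning_curve(
        dataset, train_sizes=[3, 7], replicates=1, feature_group="Mact", seed=9,
        config=cheap,
    )
    full = curve[curve["n_targets"] == 7].iloc[0]
    assert full["mean_auc"] == pytest.approx(cv.aggregates["mean_auc"])
    assert full["pct_top_n"] == pytest.approx(cv.aggregates["pct_top_n"])
    small = curve[curve["n_targets"] == 3]
    assert len(small) == 1
    with pytest.raises(ValueError):
        learning_curve(dataset, train_sizes=[0], replicates=1)
    with pytest.raises(ValueError):
        learning_curve(dataset, train_sizes=[100], replicates=1)


def test_distance_subsample_rules():
    t = [build_palindrome("AC" + r5 + "GA" + r11) for r5, r11 in
         [("GTT", "GCTA"), ("GTA", "GCTA"), ("AAA", "TTTT"), ("GTT", "GCTT")]]
    train, test = t[:3], [t[3]]  # t3 is 1 bp from t0, 2 bp from t1
    kept, frac = distance_subsample(train, test, min_dist=1)
    assert kept == train and frac == 1.0  # min_dist 1 keeps all distinct targets
    kept2, _ = distance_subsample(train, test, min_dist=2)
    assert t[0] not in kept2 and t[2] in kept2
    # identical train/test target removed at any min_dist >= 1
    kept3, _ = distance_subsample(train, [t[0]], min_dist=1)
    assert t[0] not in kept3
    # uniform-matched keeps exactly the same count
    uni, frac_u = distance_subsample(train, test, min_dist=2, mode="uniform-matched",
                                     seed=0)
    assert len(uni) == len(kept2) and frac_u == pytest.approx(len(kept2) / 3)
    with pytest.raises(ValueError):
        distance_subsample(train, test, min_dist=0)
    with pytest.raises(ValueError):
        distance_subsample(train, test, min_dist=2, mode="magic")
    with pytest.raises(ValueError, match="smaller min_dist"):
        distance_subsample([t[0]], [t[0]], min_dist=1)
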
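"""Learner behavior: planted-signal recovery, inner CV, ensembling, ranking."""

import numpy as np
import pytest
import scipy.sparse as sp

from megadesign.evaluation import auc
from megadesign.features import FeatureColumn, FeatureMatrix
from megadesign.models import (
    DegenerateLabelsError,
    TrainedScorer,
    coefficient_table,
    fit_ensemble,
    fit_gbm,
    fit_lasso,
    predict_activity,
    train_model,
)
from megadesign.scaffold import ProteinVariant, WT_RESIDUES, build_palindrome


def _binary_matrix(X, prefix="F"):
    cols = [
        FeatureColumn(f"{prefix}{j}", "protein_seq", "p5N3", kind="binary",
                      block=f"B{j}", level="x")
        for j in range(X.shape[1])
    ]
    return FeatureMatrix(cols, sp.csr_matrix(np.asarray(X, dtype=float)))


def test_lasso_recovers_a_planted_column():
    rng = np.random.default_rng(0)
    n = 600
    X = rng.integers(0, 2, size=(n, 12))
    informative = X[:, 0]
    y = (informative + rng.random(n) * 0.4 > 0.8).astype(int)
    scorer = fit_lasso(_binary_matrix(X), y, seed=0)
    coefs = coefficient_table(scorer).set_index("feature")["coef"]
    assert coefs["F0"] > 1.0
    noise = coefs.drop("F0").abs()
    assert (noise < 0.3).all()


def test_lasso_permuted_labels_are_chance_level():
    rng = np.random.default_rng(1)
    X = rng.integers(0, 2, size=(500, 10))
    y = rng.permutation((X[:, 0] > 0).astype(int))
    scorer = fit_lasso(_binary_matrix(X), y, seed=1)
    aucs = [
        a
        for r in scorer.inner_cv["results"]
        for a in r["fold_aucs"]
    ]
    assert np.mean(aucs) == pytest.approx(0.5, abs=0.08)


def test_lasso_row_duplication_leaves_ranking_unchanged():
    rng = np.random.default_rng(2)
    X = rng.integers(0, 2, size=(300, 8))
    y = ((X[:, 0] + X[:, 1] + rng.random(300)) > 1.6).astype(int)
    groups = np.repeat(np.arange(6), 50)
    base = fit_lasso(_binary_matrix(X), y, groups=groups, seed=2)
    doubled = fit_lasso(
        _binary_matrix(np.vstack([X, X])),
        np.concatenate([y, y]),
        groups=np.concatenate([groups, groups]),
        seed=2,
    )
    # per-observation penalty: the duplicated fit selects the same penalty
    # and produces the same scores, hence the same ranking
    assert base.inner_cv["chosen"] == doubled.inner_cv["chosen"]
    s1 = base.model.predict_proba(np.asarray(X, dtype=float))[:, 1]
    s2 = doubled.model.predict_proba(np.asarray(X, dtype=float))[:, 1]
    np.testing.assert_allclose(s1, s2, atol=1e-6)


def _categorical_matrix(frame):
    cols = [
        FeatureColumn(name, "protein_seq", "p5N3", kind="categorical",
                      levels=tuple(sorted(frame[name].unique())))
        for name in frame.columns
    ]
    return FeatureMatrix(cols, frame)


def test_gbm_learns_xor_where_linear_model_cannot():
    import pandas as pd

    rng = np.random.default_rng(3)
    n = 800
    a = rng.integers(0, 2, size=n)
    b = rng.integers(0, 2, size=n)
    y = ((a ^ b) == 1).astype(int)
    frame = pd.DataFrame({"P44": np.where(a, "R", "Q"), "P77": np.where(b, "R", "I")})
    gbm = fit_gbm(_categorical_matrix(frame), y, depth_grid=(2,), seed=3)
    codes = np.stack(
        [
            pd.Categorical(frame[c], categories=sorted(frame[c].unique())).codes
            for c in frame.columns
        ],
        axis=1,
    ).astype(float)
    gbm_auc = auc(gbm.model.predict_proba(codes)[:, 1], y)
    X = np.stack([a, b], axis=1)
    lin = fit_lasso(_binary_matrix(X), y, seed=3)
    lin_auc = auc(lin.model.predict_proba(X.astype(float))[:, 1], y)
    assert gbm_auc > 0.95
    assert lin_auc == pytest.approx(0.5, abs=0.08)


def test_gbm_auc_degrades_with_label_noise():
    import pandas as pd

    rng = np.random.default_rng(4)
    n = 600
    a = rng.integers(0, 4, size=n)
    frame = pd.DataFrame({"P44": np.array(list("QRKN"))[a]})
    clean = (a >= 2).astype(int)
    mean_inner = []
    for noise in (0.0, 0.2, 0.45):
        flip = rng.random(n) < noise
        y = np.where(flip, 1 - clean, clean)
        scorer = fit_gbm(_categorical_matrix(frame), y, depth_grid=(2,), seed=4)
        aucs = [a_ for r in scorer.inner_cv["results"] for a_ in r["fold_aucs"]]
        mean_inner.append(np.mean(aucs))
    assert mean_inner[0] > mean_inner[1] > mean_inner[2]


def test_degenerate_labels_raise():
    X = np.ones((20, 3))
    with pytest.raises(DegenerateLabelsError):
        fit_lasso(_binary_matrix(X), np.ones(20), seed=0)


def test_seeded_training_is_deterministic(tiny_world):
    model, ds = tiny_world
    records = ds.records_for(range(4))
    kw = dict(feature_group="SM-5_11", seed=7,
              config={"max_negatives_per_target": 80})
    s1 = train_model(records, ds.lib5, ds.lib11, **kw)
    s2 = train_model(records, ds.lib5, ds.lib11, **kw)
    pool = ds.records[5]
    np.testing.assert_array_equal(
        s1.score_records(pool, ds.lib5, ds.lib11),
        s2.score_records(pool, ds.lib5, ds.lib11),
    )


def _constant_scorer(scores_by_key):
    scorer = TrainedScorer(kind="lasso", feature_group="Mact", columns=[])

    class _Model:
        pass

    def score_records(records, lib5, lib11):
        out = []
        for r in records:
            v = r[0] if isinstance(r, tuple) else r.variant
            out.append(scores_by_key[v.key])
        return np.array(out, dtype=float)

    scorer.score_records = score_records
    return scorer


def test_ensemble_rank_mean_properties(tiny_world):
    model, ds = tiny_world
    recs = ds.records[0][:20]
    keys = [r.variant.key for r in recs]
    rng = np.random.default_rng(8)
    raw = dict(zip(keys, rng.random(len(keys))))
    m1 = _constant_scorer(raw)
    m1.fingerprint = "fp"
    # a monotone transform of a member's raw scores changes nothing
    m2 = _constant_scorer({k: np.exp(5 * v) for k, v in raw.items()})
    m2.fingerprint = "fp"
    ens = fit_ensemble([m1, m2])
    s_single = m1.score_records(recs, ds.lib5, ds.lib11)
    s_ens = ens.score_records(recs, ds.lib5, ds.lib11)
    assert list(np.argsort(-s_single)) == list(np.argsort(-s_ens))
    # a perfect member plus a chance member still ranks positives first
    labels = np.array([r.label for r in recs], dtype=float)
    good = _constant_scorer(dict(zip(keys, labels + 0.001 * rng.random(len(keys)))))
    noise = _constant_scorer(dict(zip(keys, rng.random(len(keys)))))
    good.fingerprint = noise.fingerprint = "fp"
    if labels.any() and not labels.all():
        mixed = fit_ensemble([good, noise])
        assert auc(mixed.score_records(recs, ds.lib5, ds.lib11), labels) > 0.5
    # single member passes through; mismatched fingerprints are rejected
    assert fit_ensemble([m1]) is m1
    m3 = _constant_scorer(raw)
    m3.fingerprint = "other"
    with pytest.raises(ValueError, match="fingerprint"):
        fit_ensemble([m1, m3])
    with pytest.raises(ValueError):
        fit_ensemble([])
    with pytest.raises(ValueError):
        fit_ensemble([m1, m2], rule="median")


def test_predict_activity_contract(tiny_world):
    model, ds = tiny_world
    records = ds.records_for(range(4))
    scorer = train_model(records, ds.lib5, ds.lib11, feature_group="Mact", seed=0,
                        config={"max_negatives_per_target": 60})
    pool = ds.pools[5]
    candidates = pool.candidates[:15]
    ranked = predict_activity(scorer, pool.target, candidates, ds.lib5, ds.lib11)
    assert len(ranked) == 15  # conservation
    assert ranked["score"].iloc[0] == ranked["score"].max()
    assert list(ranked["rank"]) == list(range(1, 16))
    # permutation invariance of scores
    perm = candidates[::-1]
    ranked2 = predict_activity(scorer, pool.target, perm, ds.lib5, ds.lib11)
    merged = ranked.set_index("variant")["score"] - ranked2.set_index("variant")["score"]
    assert np.allclose(merged.to_numpy(), 0)
    # an unencodable candidate yields an error row, not a silent drop
    ranked3 = predict_activity(
        scorer, pool.target, candidates[:3] + ["bogus"], ds.lib5, ds.lib11
    )
    assert len(ranked3) == 4
    assert ranked3["error"].notna().sum() == 1
    assert ranked3[ranked3["error"].notna()]["rank"].iloc[0] == 4
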
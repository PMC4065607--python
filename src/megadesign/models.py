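"""Learners and the ensemble scorer.

The scoring model is an ensemble of two complementary learners, each with
its natural representation of the screening data:

* an L1-penalized (LASSO) logistic model on the binary interaction
  encoding (Bin2), whose sparse coefficients are directly interpretable as
  per-mutation and per-interaction effects;
* a gradient-boosted decision-tree classifier (GBM) on the categorical
  encoding.

Hyperparameters are chosen by an inner cross-validation loop split at the
target level (so no candidate pool ever straddles an inner train/validation
boundary), maximizing AUC.  The ensemble combines members by averaging
their per-pool fractional ranks, which makes the combination invariant to
any monotone transform of a member's raw scores.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupKFold, StratifiedKFold

from .combinatorial import ModuleLibrary, ScreeningRecord
from .evaluation import auc
from .features import (
    FeatureColumn,
    FeatureMatrix,
    INTERACTION_GROUPS,
    add_interactions,
    encode_bin1,
    encode_binary_like,
    encode_categorical,
    encode_categorical_like,
    select_group,
)
from .scaffold import ProteinVariant, Target

__all__ = [
    "DegenerateLabelsError",
    "TrainedScorer",
    "DEFAULT_TRAIN_CONFIG",
    "fit_lasso",
    "fit_gbm",
    "fit_ensemble",
    "train_model",
    "predict_activity",
    "coefficient_table",
    "importance_table",
]


class DegenerateLabelsError(ValueError):
    """Raised when training labels contain a single class."""


#: Default training configuration.  ``max_negatives_per_target`` subsamples
#: the assumed-negative bulk of each pool before fitting (all positives are
#: always kept); prediction and evaluation still rank full pools.
DEFAULT_TRAIN_CONFIG: dict = {
    "members": ("lasso", "gbm"),
    "ensemble_rule": "rank_mean",
    "lambda_grid": (2e-3, 2e-4, 2e-5),
    "gbm_learning_rate": 0.1,
    "gbm_max_iter": 120,
    "inner_folds": 2,
    "min_support": 200,
    "support_rule": "parent",
    "max_negatives_per_target": 300,
}


@dataclass
class TrainedScorer:
    """A fitted scorer: a base learner or an ensemble of them.

    Predicts a real activity score for any encodable (target, variant)
    pair; higher means more likely active.
    """

    kind: str  # lasso | gbm | ensemble
    feature_group: str
    columns: list[FeatureColumn]
    model: object | None = None
    members: list["TrainedScorer"] | None = None
    inner_cv: dict = field(default_factory=dict)
    fingerprint: str = ""
    config: dict = field(default_factory=dict)
    real_impute: dict = field(default_factory=dict)

    def score_records(
        self,
        records: Sequence,
        lib5: ModuleLibrary,
        lib11: ModuleLibrary,
    ) -> np.ndarray:
        """Raw scores for a batch of records or (variant, target) pairs.

        For an ensemble the batch is treated as one candidate pool: member
        scores are rank-normalized to [0,1] within the batch and averaged.
        """
        if self.kind == "ensemble":
            parts = [m.score_records(records, lib5, lib11) for m in self.members]
            if self.config.get("rule", "rank_mean") == "score_mean":
                return np.mean(parts, axis=0)
            return np.mean([_fractional_rank(p) for p in parts], axis=0)
        if self.kind == "lasso":
            fm = encode_binary_like(self.columns, records, lib5, lib11)
            X = _impute_reals(fm, self.real_impute)
            return self.model.predict_proba(X)[:, 1]
        if self.kind == "gbm":
            df = encode_categorical_like(self.columns, records, lib5, lib11)
            return self.model.predict_proba(df.to_numpy(dtype=float))[:, 1]
        raise ValueError(f"unknown scorer kind {self.kind!r}")


def _fractional_rank(scores: np.ndarray) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if n <= 1:
        return np.full(n, 0.5)
    return (rankdata(scores, method="average") - 1.0) / (n - 1.0)


def _impute_reals(fm: FeatureMatrix, means: dict, learn: bool = False):
    """Replace NaNs in real-valued columns by stored (or learned) means."""
    X = sp.csc_matrix(fm.values).astype(float)
    for j, c in enumerate(fm.columns):
        if c.kind != "real":
            continue
        col = X.data[X.indptr[j] : X.indptr[j + 1]]
        if learn:
            finite = col[np.isfinite(col)]
            means[c.name] = float(finite.mean()) if finite.size else 0.5
        col[~np.isfinite(col)] = means.get(c.name, 0.5)
        X.data[X.indptr[j] : X.indptr[j + 1]] = col
    return X.tocsr()


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise DegenerateLabelsError(
            "training labels contain a single class; cannot fit a scorer"
        )
    return labels


def _inner_splits(labels, groups, n_folds, seed):
    """Target-level inner CV splits (grouped); stratified fallback when
    there are fewer groups than folds."""
    idx = np.arange(len(labels))
    if groups is not None and len(np.unique(groups)) >= n_folds:
        return list(GroupKFold(n_splits=n_folds).split(idx, labels, groups))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(idx, labels))


def _select_by_inner_auc(candidates, fit_score, labels, groups, n_folds, seed):
    """Grid search by mean inner-CV AUC; ties keep the earliest grid entry."""
    splits = _inner_splits(labels, groups, n_folds, seed)
    results = []
    for params in candidates:
        fold_aucs = []
        for train_idx, val_idx in splits:
            if len(np.unique(labels[train_idx])) < 2:
                continue
            if len(np.unique(labels[val_idx])) < 2:
                continue
            scores = fit_score(params, train_idx, val_idx)
            fold_aucs.append(auc(scores, labels[val_idx]))
        mean_auc = float(np.mean(fold_aucs)) if fold_aucs else 0.5
        results.append({"params": params, "fold_aucs": fold_aucs, "mean_auc": mean_auc})
    best = max(results, key=lambda r: r["mean_auc"])
    return best["params"], results


def fit_lasso(
    bin_matrix: FeatureMatrix,
    labels,
    groups=None,
    lambda_grid: Sequence[float] = DEFAULT_TRAIN_CONFIG["lambda_grid"],
    inner_folds: int = DEFAULT_TRAIN_CONFIG["inner_folds"],
    seed: int = 0,
    feature_group: str = "SeqMact",
) -> TrainedScorer:
    """L1-penalized logistic scorer on a binary (Bin1/Bin2) matrix.

    ``lambda_grid`` is the per-observation L1 penalty (the objective is
    mean log-loss plus lambda times the L1 norm, so the fit is invariant to
    duplicating the data); the penalty is chosen by target-grouped inner-CV
    AUC and the model refit on all rows.
    """
    labels = _check_labels(labels)
    real_impute: dict = {}
    X = _impute_reals(bin_matrix, real_impute, learn=True)

    def make(lam: float, n: int) -> LogisticRegression:
        return LogisticRegression(
            l1_ratio=1.0, C=1.0 / (lam * n), solver="liblinear", max_iter=2000,
            random_state=0,
        )

    def fit_score(lam, train_idx, val_idx):
        est = make(lam, len(train_idx)).fit(X[train_idx], labels[train_idx])
        return est.predict_proba(X[val_idx])[:, 1]

    best_lam, results = _select_by_inner_auc(
        list(lambda_grid), fit_score, labels, groups, inner_folds, seed
    )
    model = make(best_lam, X.shape[0]).fit(X, labels)
    return TrainedScorer(
        kind="lasso",
        feature_group=feature_group,
        columns=list(bin_matrix.columns),
        model=model,
        inner_cv={
            "grid": list(lambda_grid),
            "chosen": {"lambda": best_lam},
            "results": results,
        },
        fingerprint="",
        real_impute=real_impute,
    )


def fit_gbm(
    cat_matrix: FeatureMatrix,
    labels,
    groups=None,
    depth_grid: Sequence[int] = (2, 3),
    learning_rate: float = DEFAULT_TRAIN_CONFIG["gbm_learning_rate"],
    max_iter: int = DEFAULT_TRAIN_CONFIG["gbm_max_iter"],
    inner_folds: int = DEFAULT_TRAIN_CONFIG["inner_folds"],
    seed: int = 0,
    feature_group: str = "SeqMact",
) -> TrainedScorer:
    """Boosted-tree classifier (binomial loss) on the categorical matrix.

    Tree depth is chosen by target-grouped inner-CV AUC.  A depth of 1
    restricts the trees to main effects, which is how interaction-free
    feature groups are fitted.
    """
    labels = _check_labels(labels)
    columns = list(cat_matrix.columns)
    if isinstance(cat_matrix.values, pd.DataFrame):
        df = encode_categorical_like_frame(cat_matrix)
    else:  # already numeric
        df = pd.DataFrame(
            np.asarray(cat_matrix.values.todense()), columns=[c.name for c in columns]
        )
    X = df.to_numpy(dtype=float)
    cat_mask = np.array([c.kind == "categorical" for c in columns])

    def make(depth: int) -> HistGradientBoostingClassifier:
        return HistGradientBoostingClassifier(
            max_depth=depth,
            learning_rate=learning_rate,
            max_iter=max_iter,
            categorical_features=cat_mask if cat_mask.any() else None,
            early_stopping=False,
            random_state=seed,
        )

    def fit_score(depth, train_idx, val_idx):
        est = make(depth).fit(X[train_idx], labels[train_idx])
        return est.predict_proba(X[val_idx])[:, 1]

    best_depth, results = _select_by_inner_auc(
        list(depth_grid), fit_score, labels, groups, inner_folds, seed
    )
    model = make(best_depth).fit(X, labels)
    return TrainedScorer(
        kind="gbm",
        feature_group=feature_group,
        columns=columns,
        model=model,
        inner_cv={
            "grid": list(depth_grid),
            "chosen": {"max_depth": best_depth},
            "results": results,
        },
    )


def encode_categorical_like_frame(cat_matrix: FeatureMatrix) -> pd.DataFrame:
    """Ordinal-code a categorical FeatureMatrix against its own levels."""
    df = cat_matrix.values
    out = {}
    for c in cat_matrix.columns:
        if c.kind == "real":
            out[c.name] = df[c.name].to_numpy(dtype=float)
        else:
            codes = pd.Categorical(df[c.name], categories=list(c.levels)).codes.astype(
                float
            )
            codes[codes < 0] = np.nan
            out[c.name] = codes
    return pd.DataFrame(out)


def fit_ensemble(
    members: Sequence[TrainedScorer], rule: str = "rank_mean"
) -> TrainedScorer:
    """Combine fitted members into one scorer.

    ``rank_mean`` (default) averages per-pool fractional ranks;
    ``score_mean`` averages raw scores.  A single member passes through
    unchanged.  Members must share a training-data fingerprint.
    """
    members = list(members)
    if not members:
        raise ValueError("ensemble needs at least one member")
    prints = {m.fingerprint for m in members}
    if len(prints) > 1:
        raise ValueError(
            "ensemble members were trained on different record sets "
            f"(fingerprints {sorted(prints)})"
        )
    if rule not in ("rank_mean", "score_mean"):
        raise ValueError(f"unknown ensemble rule {rule!r}")
    if len(members) == 1:
        return members[0]
    return TrainedScorer(
        kind="ensemble",
        feature_group=members[0].feature_group,
        columns=[],
        members=members,
        fingerprint=members[0].fingerprint,
        config={"rule": rule},
    )


def _fingerprint(records: Sequence[ScreeningRecord]) -> str:
    h = hashlib.md5()
    for key in sorted(r.variant.key + r.target.full_seq for r in records):
        h.update(key.encode())
    return h.hexdigest()


def _subsample_negatives(
    records: Sequence[ScreeningRecord], max_per_target: int | None, seed: int
) -> list[ScreeningRecord]:
    if max_per_target is None:
        return list(records)
    rng = np.random.default_rng(seed)
    by_target: dict[str, list[ScreeningRecord]] = {}
    for r in records:
        by_target.setdefault(r.target.full_seq, []).append(r)
    kept: list[ScreeningRecord] = []
    for key in sorted(by_target):
        recs = by_target[key]
        pos = [r for r in recs if r.label]
        neg = [r for r in recs if not r.label]
        if len(neg) > max_per_target:
            idx = rng.choice(len(neg), size=max_per_target, replace=False)
            neg = [neg[i] for i in sorted(idx)]
        kept.extend(pos)
        kept.extend(neg)
    return kept


def train_model(
    records: Sequence[ScreeningRecord],
    lib5: ModuleLibrary,
    lib11: ModuleLibrary,
    feature_group: str = "SeqMact",
    seed: int = 0,
    config: dict | None = None,
) -> TrainedScorer:
    """Fit the LASSO+GBM ensemble for one feature group.

    Builds the group's Bin2 matrix for the LASSO member and its categorical
    matrix for the GBM member, runs each member's inner-CV hyperparameter
    selection, and combines them by per-pool rank averaging.  Interaction
    products are only constructed for groups whose hypothesis class includes
    them; for the others the GBM depth grid is restricted to stumps so the
    trees cannot smuggle interactions back in.
    """
    cfg = dict(DEFAULT_TRAIN_CONFIG)
    if config:
        cfg.update(config)
    records = _subsample_negatives(records, cfg["max_negatives_per_target"], seed)
    labels = np.array([r.label for r in records], dtype=int)
    groups = np.array([r.target.full_seq for r in records])
    fingerprint = _fingerprint(records)
    with_interactions = feature_group in INTERACTION_GROUPS

    members: list[TrainedScorer] = []
    for member in cfg["members"]:
        if member == "lasso":
            bin1 = encode_bin1(records, lib5, lib11)
            mat = (
                add_interactions(bin1, cfg["min_support"], cfg["support_rule"])
                if with_interactions
                else bin1
            )
            mat = select_group(mat, feature_group)
            scorer = fit_lasso(
                mat,
                labels,
                groups=groups,
                lambda_grid=cfg["lambda_grid"],
                inner_folds=cfg["inner_folds"],
                seed=seed,
                feature_group=feature_group,
            )
        elif member == "gbm":
            cat = select_group(encode_categorical(records, lib5, lib11), feature_group)
            depth_grid = (2, 3) if with_interactions else (1,)
            scorer = fit_gbm(
                cat,
                labels,
                groups=groups,
                depth_grid=depth_grid,
                learning_rate=cfg["gbm_learning_rate"],
                max_iter=cfg["gbm_max_iter"],
                inner_folds=cfg["inner_folds"],
                seed=seed,
                feature_group=feature_group,
            )
        else:
            raise ValueError(f"unknown ensemble member {member!r}")
        scorer.fingerprint = fingerprint
        members.append(scorer)
    return fit_ensemble(members, cfg["ensemble_rule"])


def predict_activity(
    scorer: TrainedScorer,
    target: Target,
    candidates: Sequence[ProteinVariant],
    lib5: ModuleLibrary,
    lib11: ModuleLibrary,
) -> pd.DataFrame:
    """Score and rank candidate variants for one target.

    Returns a frame sorted by descending score with a deterministic
    lexicographic tie-break on the variant residue string.  A candidate that
    cannot be encoded yields an error row (NaN score, ranked last) rather
    than being silently dropped.
    """
    ok_idx, err_rows = [], []
    for i, v in enumerate(candidates):
        if isinstance(v, ProteinVariant):
            ok_idx.append(i)
        else:
            err_rows.append((i, f"not a ProteinVariant: {type(v).__name__}"))
    pairs = [(candidates[i], target) for i in ok_idx]
    scores = (
        scorer.score_records(pairs, lib5, lib11) if pairs else np.empty(0)
    )
    rows = [
        {
            "variant": candidates[i].key,
            "score": float(s),
            "error": None,
        }
        for i, s in zip(ok_idx, scores)
    ]
    rows += [
        {"variant": f"<candidate {i}>", "score": float("nan"), "error": msg}
        for i, msg in err_rows
    ]
    df = pd.DataFrame(rows, columns=["variant", "score", "error"])
    df["_ok"] = df["error"].isna()
    df = (
        df.sort_values(["_ok", "score", "variant"], ascending=[False, False, True])
        .drop(columns="_ok")
        .reset_index(drop=True)
    )
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def coefficient_table(scorer: TrainedScorer) -> pd.DataFrame:
    """Named LASSO coefficients (nonzero first, by magnitude)."""
    if scorer.kind != "lasso":
        raise ValueError("coefficient_table applies to lasso scorers")
    coefs = np.asarray(scorer.model.coef_).ravel()
    df = pd.DataFrame({"feature": [c.name for c in scorer.columns], "coef": coefs})
    return df.reindex(df["coef"].abs().sort_values(ascending=False).index).reset_index(
        drop=True
    )


def importance_table(scorer: TrainedScorer, records, lib5, lib11, seed: int = 0):
    """Permutation importances of the GBM's categorical features."""
    from sklearn.inspection import permutation_importance

    if scorer.kind != "gbm":
        raise ValueError("importance_table applies to gbm scorers")
    df = encode_categorical_like(scorer.columns, records, lib5, lib11)
    y = np.array([r.label for r in records], dtype=int)
    res = permutation_importance(
        scorer.model, df.to_numpy(dtype=float), y, n_repeats=5, random_state=seed
    )
    out = pd.DataFrame(
        {
            "feature": [c.name for c in scorer.columns],
            "importance": res.importances_mean,
        }
    )
    return out.sort_values("importance", ascending=False).reset_index(drop=True)
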
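"""Per-target ranking metrics and the cross-validation protocols.

Screening data are grouped by DNA target: each target carries its own pool
of candidate proteins, and a scorer is judged by how well it ranks each
pool.  Metrics are therefore computed per target and averaged:

* ``AUC`` — probability that a random active candidate outranks a random
  inactive one (Mann-Whitney formulation, ties counted 1/2);
* ``TopN`` — number of actives among the N top-ranked candidates;
* ``hitN``/``%TopN`` — whether at least one active is in the top N, and the
  percentage of targets for which that holds.

Cross-validation splits at the *target* level: a held-out target's entire
pool leaves the training set, and inner hyperparameter loops only ever see
training targets.  Learning curves subsample training targets against a
fixed per-replicate test split, and distance subsampling additionally
removes training targets within a Hamming radius of any test target, to
probe generalization to genuinely novel sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from scipy.special import comb

from .combinatorial import ScreeningDataset
from .scaffold import Target, target_distance

__all__ = [
    "UndefinedAUCError",
    "TargetEvaluation",
    "CVSummary",
    "auc",
    "top_n",
    "evaluate_pool",
    "outer_cv",
    "learning_curve",
    "distance_subsample",
    "random_scorer_hit_probability",
]


class UndefinedAUCError(ValueError):
    """Raised when AUC is requested for a single-class candidate pool."""


def auc(scores, labels) -> float:
    """Area under the ROC curve, Mann-Whitney form; ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError(
            f"AUC undefined: {n_pos} positives, {n_neg} negatives"
        )
    ranks = rankdata(scores, method="average")
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def top_n(scores, labels, n: int = 10, keys: Sequence[str] | None = None):
    """Actives among the top-n scored candidates.

    Ties are broken deterministically: by the candidate key (lexicographic)
    when ``keys`` is given, else by input position.  Pools smaller than n
    use all candidates.  Returns ``(count, hit)`` with ``hit = count >= 1``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if keys is None:
        keys = [str(i).zfill(12) for i in range(len(scores))]
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], keys[i]))
    top = order[: min(n, len(order))]
    count = int(labels[top].sum())
    return count, count >= 1


def random_scorer_hit_probability(pool_size: int, n_positives: int, n: int = 10) -> float:
    """Probability a uniformly random ranking puts >=1 of ``n_positives``
    actives in the top n of a ``pool_size`` pool (hypergeometric closed form)."""
    n = min(n, pool_size)
    return float(1.0 - comb(pool_size - n_positives, n) / comb(pool_size, n))


@dataclass(frozen=True)
class TargetEvaluation:
    """Ranking metrics for one target's candidate pool."""

    target: str
    auc: float  # NaN when the pool is single-class
    top_n: int
    hit_n: bool
    n_candidates: int
    n_positives: int
    note: str = ""


@dataclass
class CVSummary:
    """Per-replicate, per-target evaluations with recomputable aggregates."""

    per_target: pd.DataFrame
    n_top: int = 10
    meta: dict = field(default_factory=dict)

    @property
    def replicate_means(self) -> pd.DataFrame:
        g = self.per_target.groupby("replicate")
        return pd.DataFrame(
            {
                "mean_auc": g["auc"].mean(),
                "mean_top_n": g["top_n"].mean(),
                "pct_top_n": g["hit_n"].mean() * 100.0,
            }
        )

    @property
    def aggregates(self) -> dict:
        reps = self.replicate_means
        out = {"n_replicates": int(len(reps)), "n_top": self.n_top}
        for col in ("mean_auc", "mean_top_n", "pct_top_n"):
            vals = reps[col].to_numpy(dtype=float)
            out[col] = float(np.nanmean(vals))
            out[f"se_{col}"] = (
                float(np.nanstd(vals, ddof=1) / np.sqrt(len(vals)))
                if len(vals) > 1
                else float("nan")
            )
        return out


def evaluate_pool(
    scores, labels, keys=None, n: int = 10, target: str = ""
) -> TargetEvaluation:
    """Metrics for one scored pool; AUC is NaN (with a note) when the pool
    has a single class, but TopN is always defined."""
    labels = np.asarray(labels, dtype=bool)
    count, hit = top_n(scores, labels, n=n, keys=keys)
    note = ""
    try:
        a = auc(scores, labels)
    except UndefinedAUCError as exc:
        a, note = float("nan"), str(exc)
    return TargetEvaluation(
        target, a, count, hit, int(len(labels)), int(labels.sum()), note
    )


def _split_targets(n_targets: int, test_fraction: float, rng) -> tuple[list, list]:
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0,1)")
    n_test = max(1, round(test_fraction * n_targets))
    if n_test >= n_targets:
        raise ValueError("test split leaves no training targets")
    perm = rng.permutation(n_targets)
    return sorted(perm[n_test:].tolist()), sorted(perm[:n_test].tolist())


def _replicate_seed(seed: int, replicate: int) -> int:
    # fixed offsets so any replicate is reproducible in isolation
    return (seed * 1000 + replicate) % (2**31)


def _evaluate_on_targets(scorer, dataset, target_indices, n_top, lib5, lib11):
    rows = []
    for i in target_indices:
        recs = dataset.records[i]
        scores = scorer.score_records(recs, lib5, lib11)
        labels = [r.label for r in recs]
        keys = [r.variant.key for r in recs]
        ev = evaluate_pool(
            scores, labels, keys=keys, n=n_top, target=dataset.pools[i].target.full_seq
        )
        rows.append(ev)
    return rows


def outer_cv(
    dataset: ScreeningDataset,
    test_fraction: float = 0.1,
    replicates: int = 30,
    feature_group: str = "SeqMact",
    seed: int = 0,
    n_top: int = 10,
    config: dict | None = None,
) -> CVSummary:
    """Target-level outer cross-validation.

    Each replicate draws an independent random split of targets; the model
    is trained on the training targets' pools only, then every held-out
    target's full pool is ranked and scored.  Aggregates are means over
    replicate means with their standard errors.
    """
    from .models import train_model  # local import to avoid a cycle

    n = len(dataset.pools)
    all_rows = []
    for rep in range(replicates):
        rs = _replicate_seed(seed, rep)
        rng = np.random.default_rng(rs)
        train_idx, test_idx = _split_targets(n, test_fraction, rng)
        scorer = train_model(
            dataset.records_for(train_idx),
            dataset.lib5,
            dataset.lib11,
            feature_group=feature_group,
            seed=rs,
            config=config,
        )
        for ev in _evaluate_on_targets(
            scorer, dataset, test_idx, n_top, dataset.lib5, dataset.lib11
        ):
            all_rows.append({"replicate": rep, **ev.__dict__})
    per_target = pd.DataFrame(all_rows)
    return CVSummary(
        per_target,
        n_top=n_top,
        meta={
            "feature_group": feature_group,
            "test_fraction": test_fraction,
            "seed": seed,
            "n_targets": n,
            "mean_train_targets": n - max(1, round(test_fraction * n)),
        },
    )


def learning_curve(
    dataset: ScreeningDataset,
    train_sizes: Sequence[int],
    replicates: int = 10,
    feature_group: str = "SeqMact",
    seed: int = 0,
    test_fraction: float = 0.1,
    n_top: int = 10,
    config: dict | None = None,
) -> pd.DataFrame:
    """Performance as a function of the number of training targets.

    Each replicate fixes one test split (the same split and seeds as
    :func:`outer_cv` for that replicate), then for every requested size
    fits on a random subsample of the training targets and evaluates on the
    fixed test targets.  Using the full training size therefore reproduces
    the outer-CV result for the same seed.
    """
    from .models import train_model

    n = len(dataset.pools)
    for size in train_sizes:
        if size < 1:
            raise ValueError("train sizes must be >= 1")
    rows = []
    for rep in range(replicates):
        rs = _replicate_seed(seed, rep)
        rng = np.random.default_rng(rs)
        train_idx, test_idx = _split_targets(n, test_fraction, rng)
        for size in train_sizes:
            if size > len(train_idx):
                raise ValueError(
                    f"train size {size} exceeds available training targets "
                    f"({len(train_idx)})"
                )
            if size == len(train_idx):
                sub = list(train_idx)
            else:
                sub_rng = np.random.default_rng(_replicate_seed(rs, size))
                sub = sorted(
                    sub_rng.choice(len(train_idx), size=size, replace=False).tolist()
                )
                sub = [train_idx[i] for i in sub]
            scorer = train_model(
                dataset.records_for(sub),
                dataset.lib5,
                dataset.lib11,
                feature_group=feature_group,
                seed=rs,
                config=config,
            )
            evs = _evaluate_on_targets(
                scorer, dataset, test_idx, n_top, dataset.lib5, dataset.lib11
            )
            rows.append(
                {
                    "n_targets": size,
                    "replicate": rep,
                    "mean_auc": float(np.nanmean([e.auc for e in evs])),
                    "mean_top_n": float(np.mean([e.top_n for e in evs])),
                    "pct_top_n": float(np.mean([e.hit_n for e in evs])) * 100.0,
                }
            )
    return pd.DataFrame(rows)


def distance_subsample(
    train_targets: Sequence[Target],
    test_targets: Sequence[Target],
    min_dist: int,
    mode: str = "distance",
    seed: int = 0,
    scope: Sequence[str] = ("r11N4", "r5N3"),
):
    """Filter training targets by Hamming distance to the test set.

    ``distance`` mode keeps training targets at distance >= ``min_dist``
    from *every* test target (min_dist 1 only removes exact duplicates);
    ``uniform-matched`` mode instead randomly keeps the same number of
    targets, as the size-matched control.  Returns the retained targets and
    the retained fraction.
    """
    if min_dist < 1:
        raise ValueError("min_dist must be >= 1")
    if mode not in ("distance", "uniform-matched"):
        raise ValueError(f"unknown mode {mode!r}")
    keep_mask = [
        all(target_distance(t, s, scope) >= min_dist for s in test_targets)
        for t in train_targets
    ]
    n_keep = sum(keep_mask)
    if n_keep == 0:
        raise ValueError(
            f"no training targets at distance >= {min_dist} from the test set; "
            "use a smaller min_dist"
        )
    if mode == "distance":
        kept = [t for t, k in zip(train_targets, keep_mask) if k]
    else:
        rng = np.random.default_rng(seed)
        idx = sorted(rng.choice(len(train_targets), size=n_keep, replace=False).tolist())
        kept = [train_targets[i] for i in idx]
    return kept, n_keep / len(train_targets)
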
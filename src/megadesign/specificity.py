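"""Specificity profiles and the activity/specificity trade-off ranking.

A designed nuclease should not only cut its intended site; it should cut
little else.  Given a mutant's activities over an enumerated target space
(by default the 64 possible 5N3 region targets), its specificity on target
t is its activity on t divided by its total activity over the space — a
profile that sums to one.  Candidates are then ranked by the trade-off
score

    R_alpha = alpha * A + (1 - alpha) * S,

where A is predicted activity (min-max rescaled across the candidate pool
so alpha mixes two quantities on a common [0,1] scale) and S is predicted
specificity on the target of interest.  alpha = 1 ranks purely by activity,
alpha = 0 purely by specificity.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "specificity_profile",
    "tradeoff_rank",
    "count_specific_actives",
    "predict_specificity_matrix",
    "alpha_sweep",
]


def specificity_profile(activities) -> pd.DataFrame:
    """Row-normalize a mutant x target activity matrix into specificities.

    Rows with zero total activity have undefined specificity and come back
    as all-NaN (flagged, so they are excluded from specificity rankings
    rather than silently treated as uniform).
    """
    df = (
        activities.copy()
        if isinstance(activities, pd.DataFrame)
        else pd.DataFrame(np.asarray(activities, dtype=float))
    )
    values = df.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("activities must be nonnegative")
    totals = values.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = values / totals[:, None]
    s[totals == 0] = np.nan
    return pd.DataFrame(s, index=df.index, columns=df.columns)


def _minmax(a: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(a)), float(np.max(a))
    if hi == lo:
        return np.full_like(a, 0.5, dtype=float)
    return (a - lo) / (hi - lo)


def tradeoff_rank(
    activity,
    spec,
    alpha: float,
    keys: Sequence[str] | None = None,
    rescale_activity: bool = True,
) -> pd.DataFrame:
    """Rank candidates by R_alpha = alpha*A + (1-alpha)*S.

    ``activity`` and ``spec`` must be aligned per-candidate vectors;
    activity is min-max rescaled across the pool before mixing unless
    ``rescale_activity`` is False.  Ties break lexicographically on keys.
    """
    a = np.asarray(activity, dtype=float)
    s = np.asarray(spec, dtype=float)
    if a.shape != s.shape:
        raise ValueError(f"misaligned inputs: {a.shape} vs {s.shape}")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0,1]")
    if keys is None:
        keys = [str(i).zfill(12) for i in range(len(a))]
    elif len(keys) != len(a):
        raise ValueError("keys misaligned with scores")
    a_scaled = _minmax(a) if rescale_activity else a
    r = alpha * a_scaled + (1.0 - alpha) * s
    df = pd.DataFrame(
        {"key": list(keys), "activity": a, "specificity": s, "r_alpha": r}
    )
    df = df.sort_values(["r_alpha", "key"], ascending=[False, True]).reset_index(
        drop=True
    )
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def count_specific_actives(
    ranked: pd.DataFrame,
    true_active: dict,
    true_specificity: dict,
    specificity_threshold: float,
    n: int = 10,
) -> int:
    """Among the top-n ranked candidates, count those that are truly active
    and at least as specific as the threshold (e.g. wild-type I-CreI's
    specificity on its own site within the same target space)."""
    top = ranked.head(n)["key"]
    return int(
        sum(
            bool(true_active.get(k, False))
            and float(true_specificity.get(k, 0.0)) >= specificity_threshold
            for k in top
        )
    )


def predict_specificity_matrix(scorer, mutants, targets, lib5, lib11) -> pd.DataFrame:
    """Predicted activity of every mutant on every target of a space.

    Fast scoring over an enumerated target space is what makes in silico
    specificity profiling practical; the result feeds
    :func:`specificity_profile`.
    """
    cols = {}
    for t in targets:
        pairs = [(m, t) for m in mutants]
        cols[t.full_seq] = scorer.score_records(pairs, lib5, lib11)
    return pd.DataFrame(cols, index=[m.key for m in mutants])


def alpha_sweep(
    activity,
    spec,
    true_active: dict,
    true_specificity: dict,
    specificity_threshold: float,
    alphas: Sequence[float],
    keys: Sequence[str],
    n: int = 10,
) -> pd.DataFrame:
    """Count specific actives in the top n as a function of alpha."""
    rows = []
    for alpha in alphas:
        ranked = tradeoff_rank(activity, spec, alpha, keys=keys)
        rows.append(
            {
                "alpha": float(alpha),
                "top_n_specific_actives": count_specific_actives(
                    ranked, true_active, true_specificity, specificity_threshold, n=n
                ),
            }
        )
    return pd.DataFrame(rows)
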
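"""Multi-class ReliefF feature weighting and ranking.

The multi-class extension of Relief due to Kononenko: for each instance R,
find its k nearest hits (same class) and, for every other class c, its k
nearest misses from c.  Each feature's weight is decreased by the mean
feature difference to the hits and increased by the prior-weighted mean
difference to the misses:

    W[f] += -sum_hits diff(f, R, H) / (n k)
            + sum_{c != class(R)} P(c)/(1 - P(class(R))) sum_miss diff(f, R, M_c) / (n k)

with diff(f, a, b) = |a_f - b_f| / range_f and Manhattan distance on the
range-normalized features for the neighbour search.  Informative features
gain weight; features independent of the class have expected weight zero;
constant features get exactly zero (their diff is defined as 0).

All 30 pipeline features are continuous, so no nominal-feature branch is
implemented.  With ``n_samples='all'`` the procedure is fully deterministic;
neighbour and weight ties are broken by original row/column order.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FeatureRanking", "relieff_rank", "top_n"]


@dataclass
class FeatureRanking:
    """ReliefF weights plus feature names ordered by descending weight."""

    weights: pd.Series  # indexed by feature name, in original column order
    order: list[str]

    def __post_init__(self) -> None:
        if sorted(self.order) != sorted(self.weights.index):
            raise ValueError("order must be a permutation of the feature names")

    def to_frame(self) -> pd.DataFrame:
        """Table of (rank, feature, weight), best first."""
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.order) + 1),
                "feature": self.order,
                "weight": [self.weights[f] for f in self.order],
            }
        )


def relieff_rank(
    matrix: pd.DataFrame,
    labels,
    k_neighbors: int = 10,
    n_samples: int | str = "all",
    seed: int = 0,
) -> FeatureRanking:
    """Rank features by ReliefF weight.

    Parameters
    ----------
    matrix
        Numeric feature matrix, one row per instance; must be free of NaN.
    labels
        Class tag per row (any hashable values, at least two classes).
    k_neighbors
        Hits/misses per class considered for each instance; capped at the
        available class size.
    n_samples
        ``'all'`` (default) updates on every instance deterministically;
        an integer subsamples instances without replacement using ``seed``.
    seed
        Only consulted when subsampling.

    Returns
    -------
    FeatureRanking
        Weights per feature and the descending-weight order (ties broken by
        original column position).
    """
    x = matrix.to_numpy(dtype=float)
    names = list(matrix.columns)
    y = np.asarray(labels)
    n, n_feat = x.shape
    if y.shape[0] != n:
        raise ValueError("labels length must match matrix rows")
    if np.isnan(x).any():
        raise ValueError("feature matrix contains NaN; filter incomplete rows first")
    classes, y_idx = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("ReliefF needs at least two classes")
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")

    rng_range = x.max(axis=0) - x.min(axis=0)
    informative = rng_range > 0
    # normalized copy: constant features contribute 0 to distance and diff
    xn = np.zeros_like(x)
    xn[:, informative] = (x[:, informative] - x[:, informative].min(axis=0)) / rng_range[
        informative
    ]

    priors = np.bincount(y_idx, minlength=classes.size) / n

    if n_samples == "all" or (isinstance(n_samples, int) and n_samples >= n):
        sample_idx = np.arange(n)
    else:
        rng = np.random.default_rng(seed)
        sample_idx = np.sort(rng.choice(n, size=int(n_samples), replace=False))

    m = sample_idx.size
    w = np.zeros(n_feat)
    class_rows = [np.flatnonzero(y_idx == c) for c in range(classes.size)]

    for i in sample_idx:
        dists = np.abs(xn - xn[i]).sum(axis=1)  # Manhattan on normalized features
        ci = y_idx[i]
        for c, rows in enumerate(class_rows):
            cand = rows[rows != i] if c == ci else rows
            if cand.size == 0:
                continue
            k = min(k_neighbors, cand.size)
            # stable sort → ties broken by original row order
            nearest = cand[np.argsort(dists[cand], kind="stable")[:k]]
            diffs = np.abs(xn[nearest] - xn[i]).sum(axis=0) / k
            if c == ci:
                w -= diffs / m
            else:
                w += (priors[c] / (1.0 - priors[ci])) * diffs / m

    weights = pd.Series(w, index=names)
    # descending weight, ties broken by original column order (stable sort)
    order_idx = np.argsort(-w, kind="stable")
    order = [names[j] for j in order_idx]
    return FeatureRanking(weights=weights, order=order)


def top_n(ranking: FeatureRanking, n: int) -> list[str]:
    """First n feature names of the ranking order."""
    if not 1 <= n <= len(ranking.order):
        raise ValueError(f"n must be in [1, {len(ranking.order)}], got {n}")
    return ranking.order[:n]
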
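"""ReliefF feature relevance scoring and selection.

Multiclass ReliefF (Kononenko's formulation): for each sampled instance the
k nearest hits (same class) and k nearest misses per other class are found
under the Manhattan distance on range-normalized features, and each
feature's weight is decreased by the mean hit difference and increased by
the prior-weighted mean miss differences:

    W[f] <- W[f] - sum_hits diff(f, x, h) / (m k)
                 + sum_{C != cls(x)} P(C)/(1 - P(cls(x)))
                   * sum_miss diff(f, x, miss_C) / (m k)

with diff range-normalized to [0, 1], so |W| <= 1.  With two equally
frequent classes and k = 1 this reduces to classic Relief.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = ["ReliefFWeights", "relieff_weights", "relief_weights", "rank_and_select", "ReliefFSelector"]


@dataclass
class ReliefFWeights:
    """Per-feature relevance scores with their descending-weight ranking."""

    feature_names: tuple[str, ...]
    weights: np.ndarray
    k_neighbors: int
    n_sampled: int
    seed: int | None

    @property
    def ranking(self) -> list[str]:
        """Feature names by descending weight; ties break lexicographically."""
        order = sorted(
            range(len(self.feature_names)),
            key=lambda i: (-self.weights[i], self.feature_names[i]),
        )
        return [self.feature_names[i] for i in order]

    def rank_of(self, feature: str) -> int:
        """1-based rank of a feature."""
        return self.ranking.index(feature) + 1

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.feature_names, map(float, self.weights)))


def _core_weights(X: np.ndarray, y: np.ndarray, k: int, sampled: np.ndarray) -> np.ndarray:
    n, f = X.shape
    rng_range = X.max(axis=0) - X.min(axis=0)
    zero = rng_range <= 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} constant feature(s): their diffs are defined as 0",
            stacklevel=3,
        )
    safe = np.where(zero, 1.0, rng_range)
    Xn = (X - X.min(axis=0)) / safe
    Xn[:, zero] = 0.0

    classes, counts = np.unique(y, return_counts=True)
    priors = counts / n
    D = cdist(Xn, Xn, metric="cityblock")
    np.fill_diagonal(D, np.inf)

    m = len(sampled)
    W = np.zeros(f)
    class_idx = {c: np.flatnonzero(y == c) for c in classes}
    for i in sampled:
        ci = y[i]
        same = class_idx[ci]
        same = same[same != i]
        k_hit = min(k, len(same))
        if k_hit < k:
            warnings.warn(
                f"class {ci!r} smaller than k+1; using k={k_hit} hits", stacklevel=3
            )
        if k_hit:
            hits = same[np.argsort(D[i, same], kind="stable")[:k_hit]]
            W -= np.abs(Xn[hits] - Xn[i]).sum(axis=0) / (m * k_hit)
        p_ci = priors[classes == ci][0]
        for c, p_c in zip(classes, priors):
            if c == ci:
                continue
            others = class_idx[c]
            k_miss = min(k, len(others))
            if k_miss == 0:
                continue
            miss = others[np.argsort(D[i, others], kind="stable")[:k_miss]]
            W += (p_c / (1.0 - p_ci)) * np.abs(Xn[miss] - Xn[i]).sum(axis=0) / (
                m * k_miss
            )
    return W


def relieff_weights(
    X,
    y,
    feature_names=None,
    k: int = 10,
    n_sampled: int | None = None,
    seed: int | None = 0,
) -> ReliefFWeights:
    """Multiclass ReliefF weights.

    ``n_sampled=None`` scores every instance deterministically (no
    randomness); otherwise ``n_sampled`` instances are drawn without
    replacement using ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(y) != len(X):
        raise ValueError("X must be (n, f) with matching labels")
    if len(np.unique(y)) < 2:
        raise ValueError("ReliefF needs at least two classes")
    if feature_names is None:
        feature_names = tuple(f"f{i}" for i in range(X.shape[1]))
    n = len(X)
    if n_sampled is None or n_sampled >= n:
        sampled = np.arange(n)
    else:
        rng = np.random.default_rng(seed)
        sampled = np.sort(rng.choice(n, size=n_sampled, replace=False))
    W = _core_weights(X, y, k, sampled)
    return ReliefFWeights(
        feature_names=tuple(feature_names),
        weights=W,
        k_neighbors=k,
        n_sampled=len(sampled),
        seed=seed,
    )


def relief_weights(X, y, feature_names=None, seed: int | None = 0) -> ReliefFWeights:
    """Classic two-class Relief (single nearest hit and miss).

    Implemented as the k = 1 reduction of multiclass ReliefF; exact
    equivalence holds when the two classes are equally frequent.
    """
    if len(np.unique(np.asarray(y))) != 2:
        raise ValueError("classic Relief is defined for exactly two classes")
    return relieff_weights(X, y, feature_names, k=1, n_sampled=None, seed=seed)


def rank_and_select(weights: ReliefFWeights, n_keep: int) -> list[str]:
    """Top ``n_keep`` features by descending weight (lexicographic ties)."""
    n = len(weights.feature_names)
    if not 1 <= n_keep <= n:
        raise ValueError(f"n_keep must lie in [1, {n}], got {n_keep}")
    return weights.ranking[:n_keep]


class ReliefFSelector(SelectorMixin, BaseEstimator):
    """scikit-learn transformer selecting the top ReliefF-ranked features.

    Parameters
    ----------
    n_features_to_select : number of features kept by :meth:`transform`.
    k : neighbors per class.
    n_sampled : instances scored per fit (None = all, deterministic).
    random_state : seed for instance subsampling.
    """

    def __init__(self, n_features_to_select=4, k=10, n_sampled=None, random_state=0):
        self.n_features_to_select = n_features_to_select
        self.k = k
        self.n_sampled = n_sampled
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        names = getattr(self, "feature_names_in_", None)
        names = tuple(names) if names is not None else None
        res = relieff_weights(
            X, y, names, k=self.k, n_sampled=self.n_sampled, seed=self.random_state
        )
        self.relieff_ = res
        self.weights_ = res.weights
        self.ranking_ = np.array(
            [res.feature_names.index(f) for f in res.ranking], dtype=int
        )
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        mask = np.zeros(len(self.weights_), dtype=bool)
        mask[self.ranking_[: self.n_features_to_select]] = True
        return mask
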
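"""Maximum-relevance / minimum-redundancy (mRMR) feature ranking.

The criterion scores a feature subset S against the class variable c by

    Phi(S) = D(S) - R(S)
    D(S)   = (1/|S|)  sum_{i in S} I(x_i; c)            (relevance)
    R(S)   = (1/|S|^2) sum_{i,r in S} I(x_i; x_r)       (redundancy)

where the redundancy double sum runs over all ordered pairs *including*
self-pairs, so the redundancy of a singleton equals the feature's entropy.
A full ranking is produced by the first-order incremental search: the first
feature maximizes relevance, and step n picks the remaining feature
maximizing

    I(x_r; c) - (1/(n-1)) sum_{x_i in S_{n-1}} I(x_r; x_i).

Ties are broken toward the lowest original feature index, which makes
rankings deterministic and independent of column shuffles up to that rule.

`MRMRSelector` exposes the ranking as a scikit-learn feature selector.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .mutual_info import (
    DiscretizedVariable,
    as_nominal,
    discretize,
    entropy,
    mutual_information,
)

__all__ = [
    "FeatureRanking",
    "PairwiseMICache",
    "relevance_D",
    "redundancy_R",
    "phi_score",
    "incremental_rank",
    "exhaustive_best_subset",
    "discretize_features",
    "MRMRSelector",
]


@dataclass(frozen=True)
class FeatureRanking:
    """Total order over features produced by the incremental mRMR search.

    ``order`` holds 0-based feature indices, best first.  ``step_scores[0]``
    is the winner's pure relevance I(x; c); subsequent entries are the
    relevance-minus-mean-redundancy objective at each step.
    """

    order: tuple[int, ...]
    step_scores: tuple[float, ...]
    relevance_per_feature: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(set(self.order)) != len(self.order):
            raise ValueError("order must be a permutation (no repeats)")
        if len(self.step_scores) != len(self.order):
            raise ValueError("one score per ranked feature")

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(f"F{i + 1}" for i in self.order)

    def to_dict(self) -> dict:
        return {
            "order": [f"F{i + 1}" for i in self.order],
            "order_indices": list(self.order),
            "step_scores": list(self.step_scores),
            "relevance_per_feature": list(self.relevance_per_feature),
        }


class PairwiseMICache:
    """Memoized MI evaluator; counts distinct evaluations for cost audits."""

    def __init__(self, variables: Sequence[DiscretizedVariable], log_base: float | None = None):
        self.variables = list(variables)
        self.log_base = log_base
        self._pair: dict[tuple[int, int], float] = {}
        self.n_pair_evaluations = 0

    def pair_mi(self, i: int, r: int) -> float:
        key = (i, r) if i <= r else (r, i)
        if key not in self._pair:
            self._pair[key] = mutual_information(
                self.variables[key[0]], self.variables[key[1]], log_base=self.log_base
            )
            self.n_pair_evaluations += 1
        return self._pair[key]

    def class_mi(self, i: int, cls: DiscretizedVariable) -> float:
        return mutual_information(self.variables[i], cls, log_base=self.log_base)


def _check_subset(subset) -> list[int]:
    subset = sorted(set(int(i) for i in subset))
    if not subset:
        raise ValueError("subset must be nonempty")
    return subset


def relevance_D(
    subset,
    cls: DiscretizedVariable,
    data: Sequence[DiscretizedVariable],
    log_base: float | None = None,
) -> float:
    """Mean mutual information between subset members and the class."""
    subset = _check_subset(subset)
    return float(
        np.mean([mutual_information(data[i], cls, log_base=log_base) for i in subset])
    )


def redundancy_R(
    subset, data: Sequence[DiscretizedVariable], log_base: float | None = None
) -> float:
    """Mean pairwise MI over all ordered pairs of the subset, self-pairs in.

    For a singleton this is I(x; x) = H(x).
    """
    subset = _check_subset(subset)
    total = 0.0
    for i in subset:
        for r in subset:
            total += mutual_information(data[i], data[r], log_base=log_base)
    return total / len(subset) ** 2


def phi_score(
    subset,
    cls: DiscretizedVariable,
    data: Sequence[DiscretizedVariable],
    log_base: float | None = None,
) -> float:
    """Phi = D - R, the mRMR subset objective."""
    return relevance_D(subset, cls, data, log_base=log_base) - redundancy_R(
        subset, data, log_base=log_base
    )


def incremental_rank(
    data: Sequence[DiscretizedVariable],
    cls: DiscretizedVariable,
    m: int | str = "all",
    log_base: float | None = None,
) -> FeatureRanking:
    """Rank features by the first-order incremental mRMR search.

    Returns the top ``m`` features (``"all"`` for a total order).  Pairwise
    MI values are cached so a full ranking evaluates each at most once.
    """
    n_features = len(data)
    if n_features == 0:
        raise ValueError("no features to rank")
    m = n_features if m == "all" else int(m)
    if not 1 <= m <= n_features:
        raise ValueError(f"m must be in [1, {n_features}]")

    cache = PairwiseMICache(data, log_base=log_base)
    relevance = np.array([cache.class_mi(i, cls) for i in range(n_features)])

    order: list[int] = []
    scores: list[float] = []
    remaining = list(range(n_features))
    while len(order) < m:
        if not order:
            objective = {r: relevance[r] for r in remaining}
        else:
            objective = {
                r: relevance[r]
                - np.mean([cache.pair_mi(r, i) for i in order])
                for r in remaining
            }
        # argmax with lowest-index tie-break: max on (score, -index)
        best = max(remaining, key=lambda r: (objective[r], -r))
        order.append(best)
        scores.append(float(objective[best]))
        remaining.remove(best)

    return FeatureRanking(
        order=tuple(order),
        step_scores=tuple(scores),
        relevance_per_feature=tuple(float(v) for v in relevance),
    )


def exhaustive_best_subset(
    data: Sequence[DiscretizedVariable],
    cls: DiscretizedVariable,
    k: int,
    log_base: float | None = None,
    max_features: int = 12,
    max_k: int = 4,
) -> tuple[int, ...]:
    """Brute-force argmax of Phi over all size-k subsets (small instances).

    Serves as the independent oracle for the incremental search; refuses
    combinatorially large instances.
    """
    n = len(data)
    if n > max_features or (k > max_k and k != n):
        raise ValueError(
            f"instance too large for exhaustive search (N={n}, k={k}); "
            f"limits are N<={max_features}, k<={max_k}"
        )
    if not 1 <= k <= n:
        raise ValueError("k must be in [1, N]")
    best_subset = None
    best_phi = -np.inf
    for subset in combinations(range(n), k):
        phi = phi_score(subset, cls, data, log_base=log_base)
        if phi > best_phi + 1e-15:
            best_phi, best_subset = phi, subset
    assert best_subset is not None and comb(n, k) >= 1
    return best_subset


def discretize_features(
    X: np.ndarray,
    discretizer: str = "mean_std",
    n_bins: int = 3,
    nominal_columns: Sequence[int] = (),
) -> list[DiscretizedVariable]:
    """Column-wise discretization of a feature matrix.

    Columns listed in ``nominal_columns`` are taken as category codes;
    the rest are binned with the chosen strategy.
    """
    X = np.asarray(X, dtype=float)
    nominal = set(int(c) for c in nominal_columns)
    out = []
    for j in range(X.shape[1]):
        col = X[:, j]
        if j in nominal:
            out.append(as_nominal(col))
        else:
            out.append(discretize(col, n_bins=n_bins, strategy=discretizer))
    return out


class MRMRSelector(SelectorMixin, BaseEstimator):
    """mRMR feature selector with the scikit-learn transformer API.

    Parameters
    ----------
    k : int or "all", default="all"
        Number of top-ranked features to keep in ``transform``.
    discretizer : {"mean_std", "equal_width"}, default="mean_std"
        Binning strategy for continuous columns.
    n_bins : int, default=3
        Bin count for ``equal_width`` (ignored by ``mean_std``).
    log_base : float or None, default=None
        MI log base; None means natural log.  Rankings are invariant to it.
    nominal_columns : sequence of int, default=()
        Columns to treat as categorical codes rather than binning.

    Attributes
    ----------
    ranking_ : FeatureRanking
        Full mRMR order with per-step objective scores.
    order_ : ndarray of int
        Feature indices, best first.
    """

    def __init__(
        self,
        k: int | str = "all",
        discretizer: str = "mean_std",
        n_bins: int = 3,
        log_base: float | None = None,
        nominal_columns: Sequence[int] = (),
    ):
        self.k = k
        self.discretizer = discretizer
        self.n_bins = n_bins
        self.log_base = log_base
        self.nominal_columns = nominal_columns

    def fit(self, X, y):
        X, y = validate_data(self, X, y, dtype=float)
        variables = discretize_features(
            X,
            discretizer=self.discretizer,
            n_bins=self.n_bins,
            nominal_columns=self.nominal_columns,
        )
        cls = as_nominal(y)
        self.ranking_ = incremental_rank(variables, cls, m="all", log_base=self.log_base)
        self.order_ = np.asarray(self.ranking_.order, dtype=int)
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        k = self.n_features_in_ if self.k == "all" else int(self.k)
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.order_[:k]] = True
        return mask

    def _more_tags(self):
        return {"requires_y": True}
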
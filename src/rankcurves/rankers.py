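"""Baseline feature-ranking methods as scikit-learn style estimators.

Four rankers are provided, spanning the univariate/contextual divide:

* :class:`InfoGainRanker` — mutual information of each feature with the
  target (myopic: blind to pure interactions such as XOR pairs);
* :class:`ReliefFRanker` — nearest hit/miss weight accumulation, which
  credits features engaged in interactions;
* :class:`RandomForestRanker` — impurity-decrease (or permutation)
  importance from a randomized forest;
* :class:`SVMRFERanker` — recursive elimination of the feature with the
  smallest squared weight of a linear soft-margin SVM.

Each estimator follows the ``fit(X, y)`` protocol and exposes ``scores_``
(higher = more relevant) or, for RFE, ``ranking_`` (1 = best).  The
module-level functions are thin wrappers that consume a
:class:`~rankcurves.dataset.LabeledDataset` and return the ranking-domain
objects used by the rest of the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import mutual_info_score
from sklearn.svm import SVC
from sklearn.utils.validation import check_X_y

from .dataset import LabeledDataset
from .rankings import FeatureRanking, RelevanceScores, ranking_from_scores

__all__ = [
    "InfoGainRanker",
    "ReliefFRanker",
    "RandomForestRanker",
    "SVMRFERanker",
    "RankerSpec",
    "make_ranker",
    "info_gain",
    "relieff",
    "random_forest_importance",
    "svm_rfe",
    "rank_dataset",
]


def _as_discrete_mask(X: np.ndarray, feature_types) -> np.ndarray:
    if feature_types is None:
        # treat integer-valued columns as discrete
        return np.array([np.allclose(col, np.round(col)) for col in X.T])
    return np.array([t == "discrete" for t in feature_types])


class InfoGainRanker(BaseEstimator):
    """Information gain (empirical mutual information, in bits) per feature.

    Numeric features are discretized into equal-frequency bins first.  A
    constant target yields all-zero scores with a warning.

    Parameters
    ----------
    n_bins : int
        Equal-frequency bins used to discretize numeric features.
    feature_types : list of {"discrete", "numeric"}, optional
        Per-column typing; inferred from integrality when omitted.
    """

    def __init__(self, n_bins: int = 10, feature_types=None):
        self.n_bins = n_bins
        self.feature_types = feature_types

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        if len(np.unique(y)) < 2:
            warnings.warn("constant target: all information-gain scores are 0")
            self.scores_ = np.zeros(X.shape[1])
            return self
        discrete = _as_discrete_mask(X, self.feature_types)
        scores = np.empty(X.shape[1])
        for j, col in enumerate(X.T):
            if discrete[j]:
                codes = col
            else:
                codes = pd.qcut(col, self.n_bins, labels=False, duplicates="drop")
            scores[j] = mutual_info_score(codes, y) / np.log(2)
        self.scores_ = scores
        return self


class ReliefFRanker(BaseEstimator):
    """ReliefF relevance weights.

    Every instance serves as an anchor (``sample_fraction = 1``); for each
    anchor the ``n_neighbors`` nearest hits and nearest misses per opposing
    class are found (Manhattan distance on normalized per-feature
    differences) and the per-feature weight is decreased by hit differences
    and increased by class-prior-weighted miss differences.  Features that
    only matter through interactions still accumulate positive weight,
    because the neighborhoods are formed in the full feature space.

    Feature differences use the overlap (0/1 mismatch) metric for discrete
    features and range-normalized absolute difference for numeric ones.
    """

    def __init__(
        self,
        n_neighbors: int = 10,
        sample_fraction: float = 1.0,
        feature_types=None,
        random_state: int | None = None,
    ):
        self.n_neighbors = n_neighbors
        self.sample_fraction = sample_fraction
        self.feature_types = feature_types
        self.random_state = random_state

    def _diff(self, A: np.ndarray, B: np.ndarray, discrete: np.ndarray) -> np.ndarray:
        """Per-feature normalized differences between rows of A and B."""
        d = np.abs(A - B)
        if discrete.any():
            d[..., discrete] = (d[..., discrete] != 0).astype(float)
        return d

    def fit(self, X, y):
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be at least 1")
        X, y = check_X_y(X, y, dtype=float)
        n, n_feat = X.shape
        discrete = _as_discrete_mask(X, self.feature_types)
        # range-normalize numeric columns so all differences live in [0, 1]
        Z = X.copy()
        for j in np.where(~discrete)[0]:
            rng_j = np.ptp(Z[:, j])
            if rng_j > 0:
                Z[:, j] = Z[:, j] / rng_j
        classes, y_codes = np.unique(y, return_inverse=True)
        priors = np.bincount(y_codes) / n
        by_class = [np.where(y_codes == c)[0] for c in range(len(classes))]
        k = self.n_neighbors
        for idx in by_class:
            if len(idx) < k + 1:
                raise ValueError(
                    "each class needs at least n_neighbors + 1 instances"
                )
        rng = np.random.default_rng(self.random_state)
        if self.sample_fraction >= 1.0:
            anchors = np.arange(n)
        else:
            m = max(1, int(round(self.sample_fraction * n)))
            anchors = rng.choice(n, size=m, replace=False)
        m = len(anchors)
        W = np.zeros(n_feat)
        chunk = max(1, 2_000_000 // (n * max(n_feat, 1)) * 10) or 1
        chunk = min(max(chunk, 8), m)
        for start in range(0, m, chunk):
            batch = anchors[start : start + chunk]
            # distances of each anchor in the batch to every instance
            D = self._diff(Z[batch][:, None, :], Z[None, :, :], discrete).sum(axis=2)
            for bi, i in enumerate(batch):
                ci = y_codes[i]
                for c, idx in enumerate(by_class):
                    cand = idx[idx != i]
                    near = cand[np.argsort(D[bi, cand], kind="stable")[:k]]
                    contrib = self._diff(Z[near], Z[i], discrete).sum(axis=0)
                    if c == ci:
                        W -= contrib / (m * k)
                    else:
                        W += (priors[c] / (1 - priors[ci])) * contrib / (m * k)
        self.scores_ = W
        return self


class RandomForestRanker(BaseEstimator):
    """Feature importance from a randomized forest.

    ``n_trees`` trees, each split drawing ``ceil(log2(n_features))``
    candidate features.  ``importance="impurity"`` uses mean impurity
    decrease; ``"permutation"`` uses permutation importance on the training
    data.
    """

    def __init__(
        self,
        n_trees: int = 100,
        importance: str = "impurity",
        random_state: int | None = None,
    ):
        self.n_trees = n_trees
        self.importance = importance
        self.random_state = random_state

    def fit(self, X, y):
        if self.n_trees < 1:
            raise ValueError("n_trees must be at least 1")
        if self.importance not in ("impurity", "permutation"):
            raise ValueError(f"unknown importance {self.importance!r}")
        X, y = check_X_y(X, y, dtype=float)
        max_features = max(1, int(np.ceil(np.log2(X.shape[1]))))
        forest = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=max_features,
            random_state=self.random_state,
        ).fit(X, y)
        if self.importance == "impurity":
            self.scores_ = forest.feature_importances_
        else:
            result = permutation_importance(
                forest, X, y, n_repeats=5, random_state=self.random_state
            )
            self.scores_ = result.importances_mean
        self.forest_ = forest
        return self


class SVMRFERanker(BaseEstimator):
    """Recursive feature elimination with a linear soft-margin SVM.

    The SVM is refit on the surviving features and the feature with the
    smallest squared weight is dropped, receiving the worst remaining rank.
    Above ``chunk_threshold`` surviving features, the worst
    ``chunk_fraction`` are dropped per round (a pure-speed measure for
    high-dimensional data); below it, elimination is one at a time.
    """

    def __init__(
        self,
        C: float = 0.1,
        tol: float = 1e-12,
        chunk_threshold: int = 500,
        chunk_fraction: float = 0.1,
    ):
        self.C = C
        self.tol = tol
        self.chunk_threshold = chunk_threshold
        self.chunk_fraction = chunk_fraction

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        n_feat = X.shape[1]
        surviving = list(range(n_feat))
        ranking = np.empty(n_feat, dtype=int)
        next_worst = n_feat  # worst rank still unassigned
        while surviving:
            if len(surviving) == 1:
                ranking[surviving[0]] = next_worst
                break
            try:
                svm = SVC(kernel="linear", C=self.C, tol=self.tol).fit(
                    X[:, surviving], y
                )
            except Exception as exc:  # pragma: no cover - degenerate data
                raise RuntimeError(
                    f"linear SVM failed with {len(surviving)} features remaining"
                ) from exc
            w2 = np.asarray(svm.coef_**2).sum(axis=0)
            n_drop = (
                max(1, int(self.chunk_fraction * len(surviving)))
                if len(surviving) > self.chunk_threshold
                else 1
            )
            drop = np.argsort(w2, kind="stable")[:n_drop]
            # worst weights get the worst remaining ranks
            for d in sorted(drop, key=lambda d: w2[d]):
                ranking[surviving[d]] = next_worst
                next_worst -= 1
            surviving = [f for j, f in enumerate(surviving) if j not in set(drop)]
        self.ranking_ = ranking
        self.scores_ = (n_feat + 1 - ranking).astype(float)  # rank 1 -> top score
        return self


@dataclass(frozen=True)
class RankerSpec:
    """A ranking method and its hyperparameters."""

    method: str  # info_gain | relieff | random_forest | svm_rfe
    hyperparameters: dict = field(default_factory=dict)

    _METHODS = ("info_gain", "relieff", "random_forest", "svm_rfe")

    def __post_init__(self) -> None:
        if self.method not in self._METHODS:
            raise ValueError(
                f"unknown ranker {self.method!r}; expected one of {self._METHODS}"
            )


def make_ranker(spec: RankerSpec, seed: int | None = None, feature_types=None):
    """Instantiate the estimator described by ``spec``."""
    params = dict(spec.hyperparameters)
    if spec.method == "info_gain":
        return InfoGainRanker(feature_types=feature_types, **params)
    if spec.method == "relieff":
        return ReliefFRanker(
            feature_types=feature_types, random_state=seed, **params
        )
    if spec.method == "random_forest":
        return RandomForestRanker(random_state=seed, **params)
    return SVMRFERanker(**params)


def _scores(data: LabeledDataset, est) -> RelevanceScores:
    est.fit(data.X.astype(float), data.y)
    return RelevanceScores(
        features=tuple(data.feature_names), values=est.scores_
    )


def info_gain(data: LabeledDataset, n_bins: int = 10) -> RelevanceScores:
    """Empirical information gain (bits) of every feature."""
    return _scores(
        data, InfoGainRanker(n_bins=n_bins, feature_types=data.feature_types)
    )


def relieff(
    data: LabeledDataset,
    n_neighbors: int = 10,
    sample_fraction: float = 1.0,
    seed: int | None = None,
) -> RelevanceScores:
    """ReliefF relevance weights for every feature."""
    return _scores(
        data,
        ReliefFRanker(
            n_neighbors=n_neighbors,
            sample_fraction=sample_fraction,
            feature_types=data.feature_types,
            random_state=seed,
        ),
    )


def random_forest_importance(
    data: LabeledDataset,
    n_trees: int = 100,
    importance: str = "impurity",
    seed: int | None = None,
) -> RelevanceScores:
    """Random-forest importance for every feature."""
    return _scores(
        data,
        RandomForestRanker(
            n_trees=n_trees, importance=importance, random_state=seed
        ),
    )


def svm_rfe(
    data: LabeledDataset, c: float = 0.1, epsilon: float = 1e-12
) -> FeatureRanking:
    """Full SVM-RFE ranking of the dataset's features."""
    est = SVMRFERanker(C=c, tol=epsilon).fit(data.X.astype(float), data.y)
    order = np.argsort(est.ranking_, kind="stable")
    return FeatureRanking(features=tuple(data.feature_names), order=order)


def rank_dataset(
    data: LabeledDataset,
    spec: RankerSpec | str,
    seed: int | None = None,
    tie_policy: str = "lexicographic",
) -> FeatureRanking:
    """Run a configured ranker on a dataset and return its feature ranking."""
    if isinstance(spec, str):
        spec = RankerSpec(spec)
    if spec.method == "svm_rfe":
        params = spec.hyperparameters
        return svm_rfe(
            data,
            c=params.get("c", 0.1),
            epsilon=params.get("epsilon", 1e-12),
        )
    est = make_ranker(spec, seed=seed, feature_types=data.feature_types)
    scores = _scores(data, est)
    return ranking_from_scores(scores, tie_policy=tie_policy, seed=seed)
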
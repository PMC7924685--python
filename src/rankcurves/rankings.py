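"""Feature rankings: representation, construction and noise perturbation.

A ranking is a total order over features, position 1 being the most
relevant.  Rankings are usually derived from per-feature relevance scores;
tied scores are broken by a configurable policy, and fractional (average)
ranks are kept alongside the integer order for rank-correlation work.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "RelevanceScores",
    "FeatureRanking",
    "ranking_from_scores",
    "random_ranking",
    "perturb_relevances",
]


@dataclass(frozen=True)
class RelevanceScores:
    """One finite, non-negative-or-real relevance value per feature."""

    features: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or len(self.values) != len(self.features):
            raise ValueError("one score per feature is required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("relevance scores must be finite")

    def __len__(self) -> int:
        return len(self.features)

    def __getitem__(self, feature: str) -> float:
        return float(self.values[self.features.index(feature)])

    def fractional_ranks(self) -> np.ndarray:
        """Average ranks (1 = highest score), ties sharing their mean rank."""
        return rankdata(-self.values, method="average")


@dataclass(frozen=True)
class FeatureRanking:
    """A permutation of the feature set; ``order[0]`` is the top feature.

    ``ranks`` maps the feature at column position j to its 1-based rank and
    is the exact inverse of ``order``.  ``fractional_ranks``, when present,
    carries the average-rank treatment of ties in the scores the ranking
    came from; they always sum to n(n+1)/2.
    """

    features: tuple[str, ...]
    order: np.ndarray  # feature positions, best first
    fractional_ranks: np.ndarray | None = None

    def __post_init__(self) -> None:
        order = np.asarray(self.order, dtype=int)
        object.__setattr__(self, "order", order)
        n = len(self.features)
        if sorted(order.tolist()) != list(range(n)):
            raise ValueError("order must be a permutation of the feature positions")
        if self.fractional_ranks is not None:
            fr = np.asarray(self.fractional_ranks, dtype=float)
            object.__setattr__(self, "fractional_ranks", fr)
            if len(fr) != n or not np.isclose(fr.sum(), n * (n + 1) / 2):
                raise ValueError("fractional ranks must sum to n(n+1)/2")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def ranks(self) -> np.ndarray:
        """Integer rank (1..n) per feature position."""
        r = np.empty(len(self.order), dtype=int)
        r[self.order] = np.arange(1, len(self.order) + 1)
        return r

    @property
    def ordered_features(self) -> list[str]:
        return [self.features[i] for i in self.order]

    def top(self, i: int) -> list[str]:
        """The ``i`` best-ranked features, best first."""
        return self.ordered_features[:i]

    def bottom(self, i: int) -> list[str]:
        """The ``i`` worst-ranked features, worst first."""
        return self.ordered_features[::-1][:i]


def ranking_from_scores(
    scores: RelevanceScores,
    tie_policy: str = "lexicographic",
    seed: int | None = None,
) -> FeatureRanking:
    """Sort features by descending relevance.

    Ties are broken lexicographically by feature name (reproducible) or
    uniformly at random (seeded).  Fractional average ranks of the scores
    are preserved on the result.
    """
    values = scores.values
    n = len(values)
    if tie_policy == "lexicographic":
        tiebreak = np.argsort(np.argsort(scores.features))
    elif tie_policy == "random":
        rng = np.random.default_rng(seed)
        tiebreak = rng.permutation(n)
    else:
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    # primary key: descending score; secondary: the tie-break order
    order = np.lexsort((tiebreak, -values))
    return FeatureRanking(
        features=scores.features,
        order=order,
        fractional_ranks=scores.fractional_ranks(),
    )


def random_ranking(n: int, seed: int | None = None, features: tuple[str, ...] | None = None) -> FeatureRanking:
    """A ranking drawn uniformly from the n! permutations."""
    if n < 1:
        raise ValueError("a ranking needs at least one feature")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    if features is None:
        features = tuple(f"F{i + 1}" for i in range(n))
    if len(features) != n:
        raise ValueError("feature list length must equal n")
    return FeatureRanking(features=features, order=order)


def perturb_relevances(
    scores: RelevanceScores,
    theta: float,
    seed: int | None = None,
) -> RelevanceScores:
    """Replace the scores of a proportion ``theta`` of the features by noise.

    Exactly ``round(theta * n)`` distinct features, chosen uniformly without
    replacement, receive independent Uniform(0, 1) scores; the rest keep
    their input values.  ``theta = 0`` returns the scores unchanged and
    ``theta = 1`` redraws every feature, which induces a uniformly random
    ranking.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must lie in [0, 1]")
    n = len(scores)
    k = int(round(theta * n))
    rng = np.random.default_rng(seed)
    values = scores.values.copy()
    idx = rng.choice(n, size=k, replace=False)
    values[idx] = rng.uniform(size=k)
    return RelevanceScores(features=scores.features, values=values)
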
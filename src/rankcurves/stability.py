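"""Stability of feature-ranking algorithms across resampled training sets.

A ranker is run once per cross-validation training fold; the resulting
rankings are compared pairwise with the top-``i`` (partial) Canberra
distance and averaged.  Dividing by the expected distance between two
uniformly random rankings gives a scale-free curve: 0 means the top-``i``
lists are identical in every fold, values near 1 mean they are no more
alike than random rankings.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .curves import CVSpec, _fold_indices
from .dataset import LabeledDataset
from .rankdist import expected_canberra, partial_canberra
from .rankers import RankerSpec, rank_dataset
from .rankings import FeatureRanking, random_ranking

__all__ = [
    "StabilityCurve",
    "resample_rankings",
    "stability_index",
    "stability_curve",
]

_NORMALIZERS = ("exact_expectation", "eq3_verbatim", "monte_carlo")


@dataclass
class StabilityCurve:
    """Normalized top-``i`` instability values; lower is more stable."""

    sizes: np.ndarray
    values: np.ndarray
    raw: np.ndarray
    normalizer_values: np.ndarray
    m: int
    normalizer: str = "exact_expectation"

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("stability values must be non-negative")

    def __len__(self) -> int:
        return len(self.sizes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "i": self.sizes,
                "st_raw": self.raw,
                "normalizer_value": self.normalizer_values,
                "st_normalized": self.values,
                "m": self.m,
            }
        )


def resample_rankings(
    data: LabeledDataset,
    ranker: RankerSpec | str,
    cv: CVSpec,
    seed: int | None = None,
) -> list[FeatureRanking]:
    """One ranking per training fold: repeats x folds rankings in total.

    Each ranking is computed on that fold's training portion only, so the
    collection reflects how the ranker responds to sampling variation.
    """
    if isinstance(ranker, str):
        ranker = RankerSpec(ranker)
    base = seed if seed is not None else cv.seed
    rankings = []
    for r, f, tr, _ in _fold_indices(data.y, cv):
        train = LabeledDataset(
            X=data.X[tr],
            y=data.y[tr],
            feature_names=data.feature_names,
            feature_types=data.feature_types,
        )
        fold_seed = (base * 1_000_003 + r * 1_009 + f) % (2**31)
        rankings.append(rank_dataset(train, ranker, seed=fold_seed))
    return rankings


def stability_index(rankings: list[FeatureRanking], i: int) -> float:
    """Mean pairwise top-``i`` Canberra distance among the rankings."""
    if len(rankings) < 2:
        raise ValueError("at least two rankings are required")
    ranks = [r.ranks for r in rankings]
    total = 0.0
    n_pairs = 0
    for a, b in combinations(ranks, 2):
        total += partial_canberra(a, b, i)
        n_pairs += 1
    return total / n_pairs


def _normalizer_value(
    normalizer: str, n: int, i: int, rng: np.random.Generator, mc_pairs: int
) -> float:
    if normalizer == "exact_expectation":
        return expected_canberra(n, i, method="exact")
    if normalizer == "eq3_verbatim":
        return expected_canberra(n, i, method="approx")
    vals = [
        partial_canberra(
            random_ranking(n, seed=rng.integers(2**31)).ranks,
            random_ranking(n, seed=rng.integers(2**31)).ranks,
            i,
        )
        for _ in range(mc_pairs)
    ]
    return float(np.mean(vals))


def stability_curve(
    rankings: list[FeatureRanking],
    sizes=None,
    normalizer: str = "exact_expectation",
    seed: int | None = None,
    mc_pairs: int = 1_000,
) -> StabilityCurve:
    """The normalized top-``i`` stability curve of a set of rankings.

    The default normalizer is the exact expectation of the partial
    Canberra distance under uniformly random rankings; ``eq3_verbatim``
    evaluates the closed-form approximation instead, and ``monte_carlo``
    estimates the expectation from ``mc_pairs`` random ranking pairs.
    """
    if normalizer not in _NORMALIZERS:
        raise ValueError(
            f"unknown normalizer {normalizer!r}; expected one of {_NORMALIZERS}"
        )
    n = len(rankings[0]) if rankings else 0
    if len(rankings) < 2:
        raise ValueError("at least two rankings are required")
    if sizes is None:
        sizes = list(range(1, n + 1))
    sizes = sorted(set(int(s) for s in sizes))
    if sizes[0] < 1 or sizes[-1] > n:
        raise ValueError("sizes must lie in 1..n")
    rng = np.random.default_rng(seed)
    raw = np.array([stability_index(rankings, i) for i in sizes])
    norms = np.array(
        [_normalizer_value(normalizer, n, i, rng, mc_pairs) for i in sizes]
    )
    return StabilityCurve(
        sizes=np.array(sizes),
        values=raw / norms,
        raw=raw,
        normalizer_values=norms,
        m=len(rankings),
        normalizer=normalizer,
    )
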
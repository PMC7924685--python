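"""Synthetic benchmark generator with known ground-truth feature relevances.

Datasets are binary-classification problems built from *interaction groups*.
A group either contains a single feature that agrees with the target with
probability ``p`` (an individually correlated feature), or a pair of
features whose XOR agrees with the target with probability ``p`` — the
canonical interaction that defeats univariate (myopic) relevance measures,
because each member of the pair is marginally independent of the target.

Groups with ``p = 0.5`` carry no information and model pure noise.  Feature
redundancy is modelled by *copies*: each copy of a group is an independent
realization conditioned on the same target, which yields correlated but
non-identical columns.

The ground truth relevance of a group is the population mutual information
between the group and the target.  With a uniform binary target this has
the closed form ``I = 1 - H_b(p)`` bits, where ``H_b`` is the binary
entropy; it is split evenly among the members of the group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import LabeledDataset
from .rankings import RelevanceScores

__all__ = [
    "InteractionGroup",
    "SyntheticSpec",
    "standard_spec",
    "generate",
    "ground_truth_relevance",
    "binary_entropy",
    "STANDARD_NAMES",
]

STANDARD_NAMES = ("single", "pair", "combined")

#: agreement probabilities of the relevant groups in the standard datasets
_STANDARD_PS = (0.8, 0.7, 0.6)
_STANDARD_COPIES = 3
_STANDARD_TOTAL_FEATURES = 100
_STANDARD_INSTANCES = 1_000


def binary_entropy(p: float) -> float:
    """Entropy of a Bernoulli(p) variable, in bits."""
    if p in (0.0, 1.0):
        return 0.0
    return float(-(p * np.log2(p) + (1 - p) * np.log2(1 - p)))


@dataclass(frozen=True)
class InteractionGroup:
    """One interaction subset: a lone feature or an XOR pair.

    ``p`` is the probability that the group's value (the feature itself, or
    the XOR of the pair) agrees with the target.
    """

    relation: str  # "single" | "xor"
    p: float

    def __post_init__(self) -> None:
        if self.relation not in ("single", "xor"):
            raise ValueError(f"unknown relation {self.relation!r}")
        if not 0.5 <= self.p <= 1.0:
            raise ValueError("p must lie in [0.5, 1]")

    @property
    def arity(self) -> int:
        return 1 if self.relation == "single" else 2

    @property
    def relevance(self) -> float:
        """Population mutual information I(group; target) in bits."""
        return 1.0 - binary_entropy(self.p)


@dataclass(frozen=True)
class SyntheticSpec:
    """Declarative description of a synthetic dataset.

    ``groups`` lists (interaction group, number of copies); each copy is an
    independent realization of the group.  ``n_irrelevant`` fair-coin
    features are appended.
    """

    groups: tuple[tuple[InteractionGroup, int], ...]
    n_irrelevant: int
    n_instances: int

    def __post_init__(self) -> None:
        if self.n_instances < 1:
            raise ValueError("n_instances must be positive")
        if self.n_irrelevant < 0:
            raise ValueError("n_irrelevant must be non-negative")
        for _, copies in self.groups:
            if copies < 1:
                raise ValueError("copies must be positive")

    @property
    def n_relevant(self) -> int:
        return sum(g.arity * c for g, c in self.groups if g.p > 0.5)

    @property
    def n_features(self) -> int:
        return sum(g.arity * c for g, c in self.groups) + self.n_irrelevant

    @property
    def max_group_relevance(self) -> float:
        """Largest mutual information of any interaction group, in bits."""
        if not self.groups:
            return 0.0
        return max(g.relevance for g, _ in self.groups)

    def feature_names(self) -> list[str]:
        names = []
        for gi, (group, copies) in enumerate(self.groups):
            for c in range(copies):
                if group.relation == "single":
                    names.append(f"g{gi + 1}c{c + 1}")
                else:
                    names.append(f"g{gi + 1}c{c + 1}a")
                    names.append(f"g{gi + 1}c{c + 1}b")
        names.extend(f"noise{j + 1}" for j in range(self.n_irrelevant))
        return names


def standard_spec(name: str) -> SyntheticSpec:
    """One of the three standard 100-feature, 1,000-instance benchmarks.

    * ``single``   — 9 individually correlated features (3 copies at each of
      p = 0.8, 0.7, 0.6) plus 91 noise features.
    * ``pair``     — 9 XOR pairs (18 features; 3 copies at each p) plus 82
      noise features.
    * ``combined`` — the union of both relevant blocks plus 73 noise
      features (27 relevant features in total).
    """
    if name not in STANDARD_NAMES:
        raise ValueError(
            f"unknown standard dataset {name!r}; expected one of {STANDARD_NAMES}"
        )
    groups: list[tuple[InteractionGroup, int]] = []
    if name in ("single", "combined"):
        groups += [
            (InteractionGroup("single", p), _STANDARD_COPIES) for p in _STANDARD_PS
        ]
    if name in ("pair", "combined"):
        groups += [
            (InteractionGroup("xor", p), _STANDARD_COPIES) for p in _STANDARD_PS
        ]
    n_rel = sum(g.arity * c for g, c in groups)
    return SyntheticSpec(
        groups=tuple(groups),
        n_irrelevant=_STANDARD_TOTAL_FEATURES - n_rel,
        n_instances=_STANDARD_INSTANCES,
    )


def _realize_single(rng: np.random.Generator, y: np.ndarray, p: float) -> np.ndarray:
    """A column that agrees with y with probability p."""
    agree = rng.random(len(y)) < p
    return np.where(agree, y, 1 - y)


def _realize_xor(
    rng: np.random.Generator, y: np.ndarray, p: float
) -> tuple[np.ndarray, np.ndarray]:
    """A feature pair whose XOR agrees with y with probability p.

    Given the agreement outcome, the admissible (a, b) assignments (two per
    parity) are chosen uniformly, which keeps each member marginally
    independent of the target.
    """
    n = len(y)
    agree = rng.random(n) < p
    parity = np.where(agree, y, 1 - y)
    a = rng.integers(0, 2, size=n)
    b = parity ^ a
    return a, b


def generate(spec: SyntheticSpec, seed: int | None = None) -> LabeledDataset:
    """Draw a dataset from ``spec``.

    The target is a fair coin per instance; every group copy is realized
    independently conditional on the target; irrelevant features are
    independent fair coins.  Identical (spec, seed) pairs give identical
    datasets.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_instances
    y = rng.integers(0, 2, size=n)
    columns: list[np.ndarray] = []
    for group, copies in spec.groups:
        for _ in range(copies):
            if group.relation == "single":
                columns.append(_realize_single(rng, y, group.p))
            else:
                a, b = _realize_xor(rng, y, group.p)
                columns.extend([a, b])
    for _ in range(spec.n_irrelevant):
        columns.append(rng.integers(0, 2, size=n))
    X = np.column_stack(columns) if columns else np.empty((n, 0), dtype=int)
    return LabeledDataset(
        X=X,
        y=y,
        feature_names=spec.feature_names(),
        feature_types=["discrete"] * spec.n_features,
    )


def ground_truth_relevance(spec: SyntheticSpec) -> RelevanceScores:
    """Population relevance of every feature, in bits.

    Each group contributes ``1 - H_b(p)`` bits, split evenly among its
    members; irrelevant (p = 0.5) features score exactly 0.
    """
    values: list[float] = []
    for group, copies in spec.groups:
        per_feature = group.relevance / group.arity
        values.extend([per_feature] * (group.arity * copies))
    values.extend([0.0] * spec.n_irrelevant)
    return RelevanceScores(
        features=tuple(spec.feature_names()), values=np.array(values)
    )
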
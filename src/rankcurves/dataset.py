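"""Tabular classification dataset container.

A :class:`LabeledDataset` is a thin, validated wrapper around a feature
matrix, a categorical target and feature metadata.  It is the common
currency passed between the synthetic-data generator, the rankers and the
curve builders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LabeledDataset"]

#: feature type tags
DISCRETE = "discrete"
NUMERIC = "numeric"


@dataclass
class LabeledDataset:
    """A feature matrix with a categorical target.

    Parameters
    ----------
    X : ndarray of shape (n_instances, n_features)
        Feature values.  Binary {0, 1} for synthetic data; discrete codes or
        real values for external data.
    y : ndarray of shape (n_instances,)
        Categorical target, one label per instance.
    feature_names : list of str
        Unique identifier per column of ``X``.
    feature_types : list of str, optional
        Per-feature tag, ``"discrete"`` or ``"numeric"``.  Defaults to all
        discrete (the synthetic case).
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    feature_types: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-d matrix")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but y has {self.y.shape[0]} entries"
            )
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"X has {self.X.shape[1]} columns but {len(self.feature_names)} "
                "feature names were given"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if self.feature_types is None:
            self.feature_types = [DISCRETE] * self.n_features
        if len(self.feature_types) != self.n_features:
            raise ValueError("one feature type per feature is required")
        bad = set(self.feature_types) - {DISCRETE, NUMERIC}
        if bad:
            raise ValueError(f"unknown feature types: {sorted(bad)}")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_instances(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.y)

    def column_index(self, name: str) -> int:
        try:
            return self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"unknown feature {name!r}") from None

    def subset(self, features: list[str]) -> "LabeledDataset":
        """Dataset restricted to ``features`` (order preserved)."""
        idx = [self.column_index(f) for f in features]
        return LabeledDataset(
            X=self.X[:, idx],
            y=self.y,
            feature_names=[self.feature_names[i] for i in idx],
            feature_types=[self.feature_types[i] for i in idx],
        )

    # -- pandas interop ----------------------------------------------------
    def to_frame(self, target_name: str = "target") -> pd.DataFrame:
        if target_name in self.feature_names:
            raise ValueError(f"target name {target_name!r} collides with a feature")
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df[target_name] = self.y
        return df

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        target: str = "target",
        feature_types: list[str] | None = None,
    ) -> "LabeledDataset":
        if target not in df.columns:
            raise ValueError(f"target column {target!r} not found")
        y = df[target].to_numpy()
        feats = [c for c in df.columns if c != target]
        X = df[feats].to_numpy()
        if feature_types is None:
            feature_types = [
                NUMERIC if pd.api.types.is_float_dtype(df[c]) else DISCRETE
                for c in feats
            ]
        return cls(X=X, y=y, feature_names=list(feats), feature_types=feature_types)
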
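"""Forward and reverse feature-addition error curves.

Given a feature ranking, the FFA curve reports the cross-validated
performance of models trained on the nested subsets of *top*-ranked
features S^1 ⊂ S^2 ⊂ … and the RFA curve the performance on nested subsets
of *bottom*-ranked features.  Together they show where the relevant
features sit in the ranking: a good ranking has an FFA curve that rises
quickly and an RFA curve that stays at chance level until the relevant
features are finally included.

The *expected* curve — the point-wise average over uniformly random
rankings — is the no-information baseline; FFA and RFA coincide there
because a random top-i set and a random bottom-i set have the same
distribution.

Cross-validation folds are a deterministic function of the CV seed and the
repeat index only, so every model in a chain (and across chains) sees the
same train/test partitions: differences between curve points reflect
feature subsets, never fold noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler, OneHotEncoder
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .dataset import LabeledDataset
from .rankings import FeatureRanking, random_ranking

__all__ = [
    "LearnerSpec",
    "CVSpec",
    "ErrorCurve",
    "delta_schedule",
    "schedule_sizes",
    "subset_chain",
    "estimate_error",
    "build_curve",
    "expected_curve",
]

_LEARNERS = ("naive_bayes", "decision_tree", "random_forest", "svm_poly2", "knn")


@dataclass(frozen=True)
class LearnerSpec:
    """The learning method used to score feature subsets.

    Defaults follow the package's standard settings: the quadratic-kernel
    SVM uses cost 0.1 and tolerance 1e-12; kNN uses k = 10; the random
    forest uses 100 trees with ceil(log2 n) feature sampling per split.
    """

    method: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in _LEARNERS:
            raise ValueError(
                f"unknown learner {self.method!r}; expected one of {_LEARNERS}"
            )


@dataclass(frozen=True)
class CVSpec:
    """Repeated (stratified) k-fold cross-validation settings."""

    repeats: int = 10
    folds: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be at least 2")
        if self.repeats < 1:
            raise ValueError("repeats must be at least 1")


@dataclass
class ErrorCurve:
    """A sequence of (subset size, performance) points.

    ``values`` are stored as the configured metric (accuracy by default;
    ``error_rate`` is its complement).  ``std_errors`` carry fold-to-fold
    (or, for expected curves, ranking-to-ranking) standard errors.
    """

    curve_type: str  # FFA | RFA | expected
    sizes: np.ndarray
    values: np.ndarray
    std_errors: np.ndarray
    metric: str = "accuracy"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        self.std_errors = np.asarray(self.std_errors, dtype=float)
        if not (len(self.sizes) == len(self.values) == len(self.std_errors)):
            raise ValueError("sizes, values and std_errors must align")
        if np.any(np.diff(self.sizes) <= 0):
            raise ValueError("subset sizes must be strictly increasing")

    def __len__(self) -> int:
        return len(self.sizes)

    def as_metric(self, metric: str) -> np.ndarray:
        if metric == self.metric:
            return self.values
        if {metric, self.metric} == {"accuracy", "error_rate"}:
            return 1.0 - self.values
        raise ValueError(f"cannot convert {self.metric} to {metric}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "curve_type": self.curve_type,
                "i": self.sizes,
                "performance": self.values,
                "std_error": self.std_errors,
                "metric": self.metric,
            }
        )


# ---------------------------------------------------------------------------
# subset schedules and chains


def delta_schedule(i: int, n: int) -> int:
    """Step size δ(i) for thinning long curves.

    One feature at a time up to 50, five at a time up to 500, then n // 20.
    """
    if not 1 <= i <= n:
        raise ValueError(f"i must lie in 1..{n}")
    if i <= 50:
        return 1
    if i <= 500:
        return 5
    return n // 20


def schedule_sizes(n: int, schedule="auto") -> list[int]:
    """The subset sizes a curve visits, always ending exactly at n.

    ``schedule`` may be ``"full"`` (every size), ``"delta"`` (the thinned
    step schedule), ``"auto"`` (full up to 100 features, thinned beyond), a
    callable ``delta(i, n)``, or an explicit iterable of sizes.
    """
    if n < 1:
        raise ValueError("need at least one feature")
    if schedule == "auto":
        schedule = "full" if n <= 100 else "delta"
    if schedule == "full":
        return list(range(1, n + 1))
    if schedule == "delta":
        schedule = delta_schedule
    if callable(schedule):
        sizes = [1]
        while sizes[-1] < n:
            step = int(schedule(sizes[-1], n))
            if step < 1:
                raise ValueError("schedule steps must be positive")
            sizes.append(min(sizes[-1] + step, n))
        return sizes
    sizes = sorted(set(int(s) for s in schedule) | {n})
    if sizes[0] < 1 or sizes[-1] > n:
        raise ValueError("explicit sizes must lie in 1..n")
    return sizes


def subset_chain(
    ranking: FeatureRanking, curve_type: str, schedule="full"
) -> list[list[str]]:
    """The nested feature subsets a curve evaluates.

    FFA grows from the top of the ranking, RFA from the bottom; for every
    emitted size i the FFA set of size n - i and the RFA set of size i
    partition the feature set.
    """
    if curve_type not in ("FFA", "RFA"):
        raise ValueError("curve_type must be 'FFA' or 'RFA'")
    n = len(ranking)
    ordered = (
        ranking.ordered_features if curve_type == "FFA" else ranking.bottom(n)
    )
    return [ordered[:i] for i in schedule_sizes(n, schedule)]


# ---------------------------------------------------------------------------
# error estimation


def _make_estimator(spec: LearnerSpec, n_features: int, seed: int):
    hp = spec.hyperparameters
    if spec.method == "naive_bayes":
        return GaussianNB()
    if spec.method == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if spec.method == "random_forest":
        return RandomForestClassifier(
            n_estimators=hp.get("n_trees", 100),
            max_features=max(1, int(np.ceil(np.log2(max(n_features, 2))))),
            random_state=seed,
        )
    if spec.method == "svm_poly2":
        # max_iter caps the solver on degenerate (duplicate-row) subsets
        # where SMO at a tiny tolerance can cycle; accuracy is unaffected
        return SVC(
            kernel="poly",
            degree=2,
            coef0=1,
            C=hp.get("c", 0.1),
            tol=hp.get("epsilon", 1e-12),
            max_iter=hp.get("max_iter", 100_000),
        )
    return KNeighborsClassifier(n_neighbors=hp.get("k", 10))


def _preprocessor(sub: LabeledDataset):
    """Per-fold preprocessing for heterogeneous data; None for binary data.

    Numeric features are min-max scaled (and median-imputed when missing);
    non-binary discrete features are one-hot encoded (mode-imputed when
    missing).  All-binary data passes through untouched.
    """
    X = np.asarray(sub.X, dtype=float)
    has_nan = bool(np.isnan(X).any())
    binary = not has_nan and np.isin(X, (0.0, 1.0)).all()
    if binary:
        return None
    num_idx = [i for i, t in enumerate(sub.feature_types) if t == "numeric"]
    disc_idx = [i for i, t in enumerate(sub.feature_types) if t == "discrete"]
    num_steps = [("scale", MinMaxScaler())]
    disc_steps = [("onehot", OneHotEncoder(handle_unknown="ignore"))]
    if has_nan:
        num_steps.insert(0, ("impute", SimpleImputer(strategy="median")))
        disc_steps.insert(0, ("impute", SimpleImputer(strategy="most_frequent")))
    return ColumnTransformer(
        [
            ("numeric", Pipeline(num_steps), num_idx),
            ("discrete", Pipeline(disc_steps), disc_idx),
        ]
    )


def _fold_indices(y: np.ndarray, cv: CVSpec):
    """Train/test partitions, a pure function of (cv.seed, repeat index)."""
    folds = []
    for r in range(cv.repeats):
        state = (cv.seed * 1_000_003 + r) % (2**31)
        splitter = (
            StratifiedKFold(cv.folds, shuffle=True, random_state=state)
            if cv.stratified
            else KFold(cv.folds, shuffle=True, random_state=state)
        )
        for f, (tr, te) in enumerate(splitter.split(np.zeros(len(y)), y)):
            folds.append((r, f, tr, te))
    return folds


def _fold_scores(
    data: LabeledDataset, subset: list[str], learner: LearnerSpec, cv: CVSpec, folds
) -> np.ndarray:
    if len(subset) == 0:
        raise ValueError("cannot estimate the error of an empty feature subset")
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    # canonicalize column order: a subset is a set, and its error estimate
    # must not depend on the order the chain happened to add features in
    # (tree learners are column-order sensitive)
    col = {name: j for j, name in enumerate(data.feature_names)}
    sub = data.subset(sorted(subset, key=col.__getitem__))
    X = np.asarray(sub.X, dtype=float)
    y = sub.y
    prep = _preprocessor(sub)
    scores = np.empty(len(folds))
    warnings.filterwarnings("ignore", category=ConvergenceWarning)
    for k, (r, f, tr, te) in enumerate(folds):
        seed = (cv.seed * 1_000_003 + r * 1_009 + f) % (2**31)
        est = _make_estimator(learner, len(subset), seed)
        if prep is not None:
            from sklearn.base import clone

            est = Pipeline([("prep", clone(prep)), ("model", est)])
        try:
            est.fit(X[tr], y[tr])
        except Exception as exc:
            raise RuntimeError(
                f"learner {learner.method!r} failed on a subset of size "
                f"{len(subset)}"
            ) from exc
        scores[k] = np.mean(est.predict(X[te]) == y[te])
    return scores


def estimate_error(
    data: LabeledDataset,
    subset: list[str],
    learner: LearnerSpec,
    cv: CVSpec,
) -> tuple[float, float]:
    """Cross-validated accuracy of a learner restricted to ``subset``.

    Returns the mean fold accuracy and its standard error.  Folds depend
    only on (cv.seed, repeat index), so calls with different subsets are
    evaluated on identical partitions.
    """
    folds = _fold_indices(data.y, cv)
    scores = _fold_scores(data, subset, learner, cv, folds)
    se = float(scores.std(ddof=1) / np.sqrt(len(scores))) if len(scores) > 1 else 0.0
    return float(scores.mean()), se


def build_curve(
    data: LabeledDataset,
    ranking: FeatureRanking,
    curve_type: str,
    learner: LearnerSpec,
    cv: CVSpec,
    schedule="auto",
    metric: str = "accuracy",
) -> ErrorCurve:
    """The FFA or RFA curve of a ranking."""
    if set(ranking.features) != set(data.feature_names):
        raise ValueError("ranking features must match the dataset's features")
    chain = subset_chain(ranking, curve_type, schedule)
    sizes = [len(s) for s in chain]
    folds = _fold_indices(data.y, cv)
    values, ses = [], []
    for subset in chain:
        scores = _fold_scores(data, subset, learner, cv, folds)
        values.append(scores.mean())
        ses.append(scores.std(ddof=1) / np.sqrt(len(scores)) if len(scores) > 1 else 0.0)
    values = np.array(values)
    if metric == "error_rate":
        values = 1.0 - values
    elif metric != "accuracy":
        raise ValueError(f"unknown metric {metric!r}")
    return ErrorCurve(
        curve_type=curve_type,
        sizes=np.array(sizes),
        values=values,
        std_errors=np.array(ses),
        metric=metric,
        provenance={
            "learner": learner.method,
            "cv_seed": cv.seed,
            "repeats": cv.repeats,
            "folds": cv.folds,
        },
    )


def expected_curve(
    data: LabeledDataset,
    curve_type: str,
    learner: LearnerSpec,
    cv: CVSpec,
    schedule="auto",
    m: int = 100,
    seed: int | None = None,
    metric: str = "accuracy",
) -> ErrorCurve:
    """Point-wise mean curve of ``m`` uniformly random rankings.

    The standard errors are Monte-Carlo errors across rankings; at i = n
    every ranking uses the full feature set, so the error there is 0.
    """
    if m < 1:
        raise ValueError("m must be positive")
    rng = np.random.default_rng(seed)
    stack = []
    sizes = None
    for _ in range(m):
        rnk = random_ranking(
            data.n_features,
            seed=rng.integers(2**31),
            features=tuple(data.feature_names),
        )
        curve = build_curve(
            data, rnk, curve_type, learner, cv, schedule, metric=metric
        )
        stack.append(curve.values)
        sizes = curve.sizes
    stack = np.vstack(stack)
    ses = (
        stack.std(axis=0, ddof=1) / np.sqrt(m) if m > 1 else np.zeros(stack.shape[1])
    )
    return ErrorCurve(
        curve_type="expected",
        sizes=sizes,
        values=stack.mean(axis=0),
        std_errors=ses,
        metric=metric,
        provenance={
            "learner": learner.method,
            "cv_seed": cv.seed,
            "repeats": cv.repeats,
            "folds": cv.folds,
            "m": m,
            "base_curve": curve_type,
        },
    )
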
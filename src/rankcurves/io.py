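"""Reading and writing datasets, rankings, curves and plots.

Datasets travel as CSV (header row, feature columns, target column) or
ARFF; rankings as tab-separated files with score, rank and fractional
rank columns; curves and stability/distance results as CSV.  ``?`` and
empty cells are treated as missing in CSV input.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import arff as scipy_arff
from scipy.stats import rankdata

from .curves import ErrorCurve
from .dataset import LabeledDataset
from .rankings import FeatureRanking, RelevanceScores
from .stability import StabilityCurve

__all__ = [
    "read_dataset",
    "write_dataset_csv",
    "write_dataset_arff",
    "write_ranking",
    "read_ranking",
    "write_curve",
    "read_curve",
    "write_stability",
    "plot_curves",
    "plot_stability",
]


def read_dataset(
    path: str | Path,
    fmt: str | None = None,
    target: str = "target",
    feature_types: list[str] | None = None,
) -> LabeledDataset:
    """Load a classification dataset from CSV or ARFF.

    ARFF attribute declarations decide discrete vs numeric typing; for CSV
    a numeric-parse heuristic is used (override with ``feature_types``).
    The target column is always treated as categorical.
    """
    path = Path(path)
    if fmt is None:
        fmt = "arff" if path.suffix.lower() == ".arff" else "csv"
    if fmt == "arff":
        data, meta = scipy_arff.loadarff(str(path))
        df = pd.DataFrame(data)
        for col in df.columns:
            if df[col].dtype == object:
                df[col] = df[col].str.decode("utf-8")
                df[col] = df[col].replace("?", np.nan)
        if target not in df.columns:
            raise ValueError(f"target column {target!r} not found in {path}")
        if feature_types is None:
            feature_types = [
                "numeric" if meta[c][0] == "numeric" else "discrete"
                for c in df.columns
                if c != target
            ]
    elif fmt == "csv":
        df = pd.read_csv(path, na_values=["?"])
        if target not in df.columns:
            raise ValueError(f"target column {target!r} not found in {path}")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if df[target].isna().any():
        raise ValueError("missing values in the target column")
    if df[target].nunique() < 2:
        raise ValueError("the target column is constant")
    ds = LabeledDataset.from_frame(df, target=target, feature_types=feature_types)
    return ds


def write_dataset_csv(
    data: LabeledDataset, path: str | Path, target_name: str = "target"
) -> None:
    data.to_frame(target_name).to_csv(path, index=False)


def write_dataset_arff(
    data: LabeledDataset,
    path: str | Path,
    relation: str = "dataset",
    target_name: str = "target",
) -> None:
    """Minimal ARFF writer: nominal attributes for discrete features."""
    lines = [f"@relation {relation}", ""]
    df = data.to_frame(target_name)
    for name, ftype in zip(data.feature_names, data.feature_types):
        if ftype == "numeric":
            lines.append(f"@attribute {name} numeric")
        else:
            values = ",".join(str(v) for v in sorted(set(df[name])))
            lines.append(f"@attribute {name} {{{values}}}")
    classes = ",".join(str(v) for v in sorted(set(df[target_name])))
    lines.append(f"@attribute {target_name} {{{classes}}}")
    lines.append("")
    lines.append("@data")
    for _, row in df.iterrows():
        lines.append(",".join(str(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_ranking(
    path: str | Path,
    ranking: FeatureRanking,
    scores: RelevanceScores | None = None,
) -> None:
    """Tab-separated ranking file: feature, score, rank, fractional rank."""
    ranks = ranking.ranks
    frac = (
        ranking.fractional_ranks
        if ranking.fractional_ranks is not None
        else ranks.astype(float)
    )
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["feature", "score", "rank", "fractional_rank"])
        for j, name in enumerate(ranking.features):
            score = "" if scores is None else repr(float(scores.values[j]))
            writer.writerow([name, score, int(ranks[j]), float(frac[j])])


def read_ranking(path: str | Path) -> FeatureRanking:
    """Read a ranking file; a score column takes precedence over ranks."""
    df = pd.read_csv(path, sep="\t")
    if "feature" not in df.columns:
        raise ValueError("ranking file needs a 'feature' column")
    features = tuple(str(f) for f in df["feature"])
    if "score" in df.columns and df["score"].notna().all():
        scores = df["score"].to_numpy(dtype=float)
        order = np.lexsort((np.arange(len(scores)), -scores))
        frac = rankdata(-scores, method="average")
        return FeatureRanking(features=features, order=order, fractional_ranks=frac)
    if "rank" in df.columns:
        order = np.argsort(df["rank"].to_numpy(), kind="stable")
        return FeatureRanking(features=features, order=order)
    raise ValueError("ranking file needs a 'score' or 'rank' column")


def write_curve(path: str | Path, curve: ErrorCurve, ranking_id: str = "") -> None:
    df = curve.to_frame()
    df["ranking_id"] = ranking_id
    for key in ("learner", "cv_seed"):
        df[key] = curve.provenance.get(key, "")
    df.to_csv(path, index=False)


def read_curve(path: str | Path) -> ErrorCurve:
    df = pd.read_csv(path)
    return ErrorCurve(
        curve_type=str(df["curve_type"].iloc[0]),
        sizes=df["i"].to_numpy(),
        values=df["performance"].to_numpy(),
        std_errors=df["std_error"].to_numpy(),
        metric=str(df["metric"].iloc[0]),
    )


def write_stability(path: str | Path, curve: StabilityCurve) -> None:
    curve.to_frame().to_csv(path, index=False)


def _agg_backend():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_curves(
    curves: dict[str, ErrorCurve], path: str | Path, title: str = ""
) -> None:
    """Overlay FFA/RFA/expected curves, one line per labelled curve."""
    plt = _agg_backend()
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for label, curve in curves.items():
        ax.errorbar(
            curve.sizes,
            curve.values,
            yerr=curve.std_errors,
            label=label,
            linewidth=1.2,
            elinewidth=0.5,
            capsize=0,
        )
    ax.set_xlabel("number of features")
    ax.set_ylabel(next(iter(curves.values())).metric if curves else "accuracy")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_stability(
    curves: dict[str, StabilityCurve], path: str | Path, title: str = ""
) -> None:
    plt = _agg_backend()
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for label, curve in curves.items():
        ax.plot(curve.sizes, curve.values, label=label, linewidth=1.2)
    ax.set_xlabel("top-i list size")
    ax.set_ylabel("normalized instability")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
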
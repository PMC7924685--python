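"""End-to-end comparison workflow.

``compare`` ties the modules together: it obtains a dataset (from disk or
from a synthetic specification), runs the configured rankers, builds their
FFA/RFA curves and stability curves plus the random-ranking baseline, and
writes everything — CSV files, plots and a JSON manifest capturing every
seed and setting — into an output directory.  Rerunning with the same
configuration reproduces the outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .curves import CVSpec, LearnerSpec, build_curve, expected_curve
from .dataset import LabeledDataset
from .io import (
    plot_curves,
    plot_stability,
    read_dataset,
    write_curve,
    write_dataset_csv,
    write_ranking,
    write_stability,
)
from .rankers import RankerSpec, rank_dataset
from .stability import resample_rankings, stability_curve
from .syndata import SyntheticSpec, generate, standard_spec

log = logging.getLogger("rankcurves")

__all__ = ["RunConfig", "compare", "load_config"]


@dataclass
class RunConfig:
    """Everything a ``compare`` run needs, with seeds for every stochastic step."""

    dataset: str | SyntheticSpec  # path to CSV/ARFF or a synthetic spec / name
    target: str = "target"
    rankers: tuple[str, ...] = ("info_gain", "relieff", "random_forest", "svm_rfe")
    learner: LearnerSpec = field(default_factory=lambda: LearnerSpec("svm_poly2"))
    cv: CVSpec = field(default_factory=CVSpec)
    schedule: str = "auto"
    data_seed: int = 0
    ranker_seed: int = 0
    expected_m: int = 100
    expected_seed: int = 0
    stability_normalizer: str = "exact_expectation"
    out_dir: str = "rankcurves_out"
    plots: bool = True


def load_config(path: str | Path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file mirroring the CLI flags."""
    raw = yaml.safe_load(Path(path).read_text())
    dataset = raw.get("dataset")
    if isinstance(dataset, dict):
        from .syndata import InteractionGroup

        groups = tuple(
            (InteractionGroup(g["relation"], float(g["p"])), int(g["copies"]))
            for g in dataset.get("groups", [])
        )
        dataset = SyntheticSpec(
            groups=groups,
            n_irrelevant=int(dataset.get("n_irrelevant", 0)),
            n_instances=int(dataset.get("n_instances", 1000)),
        )
    cfg = RunConfig(dataset=dataset)
    if "target" in raw:
        cfg.target = raw["target"]
    if "rankers" in raw:
        cfg.rankers = tuple(raw["rankers"])
    if "learner" in raw:
        lrn = raw["learner"]
        if isinstance(lrn, str):
            cfg.learner = LearnerSpec(lrn)
        else:
            cfg.learner = LearnerSpec(lrn["method"], lrn.get("hyperparameters", {}))
    if "cv" in raw:
        cfg.cv = CVSpec(**raw["cv"])
    for key in (
        "schedule",
        "data_seed",
        "ranker_seed",
        "expected_m",
        "expected_seed",
        "stability_normalizer",
        "out_dir",
        "plots",
    ):
        if key in raw:
            setattr(cfg, key, raw[key])
    return cfg


def _load(config: RunConfig) -> LabeledDataset:
    ds = config.dataset
    if isinstance(ds, SyntheticSpec):
        return generate(ds, seed=config.data_seed)
    if isinstance(ds, str) and ds in ("single", "pair", "combined"):
        return generate(standard_spec(ds), seed=config.data_seed)
    return read_dataset(ds, target=config.target)


def compare(config: RunConfig) -> dict:
    """Run the full ranker comparison and write the report bundle.

    Returns the manifest dictionary (also written as ``manifest.json``).
    Failures in one stage are logged and do not discard the outputs of the
    stages already completed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = _load(config)
    if isinstance(config.dataset, (SyntheticSpec, str)) and not Path(
        str(config.dataset)
    ).exists():
        write_dataset_csv(data, out / "dataset.csv")
    manifest: dict = {
        "dataset": str(config.dataset),
        "n_instances": data.n_instances,
        "n_features": data.n_features,
        "learner": config.learner.method,
        "cv": {
            "repeats": config.cv.repeats,
            "folds": config.cv.folds,
            "seed": config.cv.seed,
        },
        "schedule": str(config.schedule),
        "seeds": {
            "data": config.data_seed,
            "ranker": config.ranker_seed,
            "expected": config.expected_seed,
        },
        "outputs": [],
        "errors": [],
    }

    def _record(path: Path) -> None:
        manifest["outputs"].append(path.name)

    curves_by_ranker: dict[str, dict] = {}
    stab_by_ranker: dict[str, object] = {}
    for method in config.rankers:
        try:
            t0 = time.time()
            ranking = rank_dataset(data, method, seed=config.ranker_seed)
            path = out / f"ranking_{method}.tsv"
            write_ranking(path, ranking)
            _record(path)
            log.info("ranked with %s in %.1fs", method, time.time() - t0)
            curves_by_ranker[method] = {}
            for ctype in ("FFA", "RFA"):
                curve = build_curve(
                    data, ranking, ctype, config.learner, config.cv, config.schedule
                )
                path = out / f"{ctype.lower()}_{method}.csv"
                write_curve(path, curve, ranking_id=method)
                _record(path)
                curves_by_ranker[method][ctype] = curve
            stab_rankings = resample_rankings(
                data, method, config.cv, seed=config.ranker_seed
            )
            stab = stability_curve(
                stab_rankings,
                normalizer=config.stability_normalizer,
                seed=config.ranker_seed,
            )
            path = out / f"stability_{method}.csv"
            write_stability(path, stab)
            _record(path)
            stab_by_ranker[method] = stab
        except Exception as exc:  # keep partial outputs
            log.error("stage %r failed: %s", method, exc)
            manifest["errors"].append({"stage": method, "error": str(exc)})
    try:
        exp = expected_curve(
            data,
            "FFA",
            config.learner,
            config.cv,
            config.schedule,
            m=config.expected_m,
            seed=config.expected_seed,
        )
        path = out / "expected.csv"
        write_curve(path, exp, ranking_id="random")
        _record(path)
    except Exception as exc:
        log.error("stage 'expected' failed: %s", exc)
        manifest["errors"].append({"stage": "expected", "error": str(exc)})
        exp = None
    if config.plots:
        for ctype in ("FFA", "RFA"):
            overlay = {
                m: c[ctype] for m, c in curves_by_ranker.items() if ctype in c
            }
            if exp is not None:
                overlay["random"] = exp
            if overlay:
                path = out / f"{ctype.lower()}_curves.png"
                plot_curves(overlay, path, title=f"{ctype} curves")
                _record(path)
        if stab_by_ranker:
            path = out / "stability_curves.png"
            plot_stability(stab_by_ranker, path, title="ranking stability")
            _record(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
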
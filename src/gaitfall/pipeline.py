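"""End-to-end orchestration: synthetic cohort -> per-speed models -> reports.

A single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence(global_seed).spawn``, so each stage is
independently reproducible.  The pipeline writes the labelled cohort CSV,
one model report per walking speed, and a manifest (versions, seeds, file
hashes); re-running the same config reproduces identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

import gaitfall
from gaitfall import classification, evaluation, synthetic
from gaitfall.errors import ParameterError


@dataclass(frozen=True)
class PipelineConfig:
    n_participants: int = 746
    seed: int = 0
    speeds: tuple[str, ...] = synthetic.SPEEDS
    train_fraction: float = 0.7
    cv_folds: int = 10
    grid_search: bool = False
    out_dir: Path = Path("gaitfall_out")

    def __post_init__(self) -> None:
        unknown = set(self.speeds) - set(synthetic.SPEEDS)
        if unknown:
            raise ParameterError(f"unknown speeds: {sorted(unknown)}")


def stage_seeds(global_seed: int, n: int = 8) -> list[int]:
    """Deterministic per-stage seeds derived from one global seed."""
    return [int(s.generate_state(1)[0]) for s in
            np.random.SeedSequence(global_seed).spawn(n)]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_speed_model(cohort: pd.DataFrame, speed: str, seed: int,
                    train_fraction: float = 0.7, cv_folds: int = 10,
                    grid_search: bool = False) -> dict:
    """Train and evaluate one speed's model on a labelled cohort table.

    Returns the model, the holdout report, and the CV summary.
    """
    features = classification.feature_columns(speed)
    train, test = classification.split_train_test(
        cohort, train_fraction=train_fraction, seed=seed)
    if grid_search:
        candidates = [replace(c, cv_folds=cv_folds, seed=seed)
                      for c in classification.default_config_grid(seed)]
        cv = classification.cross_validate(train, candidates, features)
        config = cv["selected"]
    else:
        config = classification.ModelConfig(cv_folds=cv_folds, seed=seed)
        cv = classification.cross_validate(train, config, features)
        config = cv["selected"]
    model = classification.train_model(train, config, features)
    report = evaluation.full_report(model, test)
    report["speed"] = speed
    report["cv_mean_auc"] = cv["selected_mean_auc"]
    return {"model": model, "report": report, "cv": cv,
            "train": train, "test": test}


def holdout_benchmark(speeds: tuple[str, ...] = synthetic.SPEEDS,
                      n_seeds: int = 20, base_seed: int = 0,
                      n_participants: int = 746) -> pd.DataFrame:
    """Mean holdout AUC/accuracy per speed over repeated cohort draws.

    Each repetition draws a fresh default cohort (exact 290/456-style
    stratification scaled to ``n_participants``), makes a stratified 70/30
    split, trains the default-configuration model, and evaluates on the
    holdout at threshold 0.5.  Returns one row per (seed, speed).
    """
    seeds = stage_seeds(base_seed, n=n_seeds)
    rows = []
    for rep, seed in enumerate(seeds):
        spec = synthetic.default_cohort_spec(n_participants=n_participants,
                                             seed=seed)
        cohort = synthetic.simulate_cohort(spec)
        for speed in speeds:
            cols = classification.feature_columns(speed)
            train, test = classification.split_train_test(cohort, 0.7,
                                                          seed=seed)
            config = classification.ModelConfig(seed=seed)
            model = classification.train_model(train, config, cols)
            report = evaluation.full_report(model, test)
            rows.append({"rep": rep, "seed": seed, "speed": speed,
                         "auc": report["metrics"]["auc"],
                         "accuracy": report["metrics"]["accuracy"],
                         "sensitivity": report["metrics"]["sensitivity"],
                         "specificity": report["metrics"]["specificity"],
                         "n_test": report["n_test"]})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full protocol and write artifacts under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)

    spec = synthetic.default_cohort_spec(n_participants=config.n_participants,
                                         seed=seeds[0])
    cohort = synthetic.simulate_cohort(spec)
    cohort_path = out / "cohort.csv"
    cohort.to_csv(cohort_path, index=False)

    reports = {}
    for i, speed in enumerate(config.speeds):
        try:
            result = run_speed_model(cohort, speed, seed=seeds[1 + i],
                                     train_fraction=config.train_fraction,
                                     cv_folds=config.cv_folds,
                                     grid_search=config.grid_search)
        except Exception as exc:  # surface the failing stage
            raise RuntimeError(f"stage train/evaluate[{speed}] failed: {exc}") from exc
        path = out / f"report_{speed}.json"
        path.write_text(evaluation.report_to_json(result["report"]))
        reports[speed] = result["report"]

    manifest = {
        "package_version": gaitfall.__version__,
        "python": platform.python_version(),
        "global_seed": config.seed,
        "stage_seeds": seeds[: 1 + len(config.speeds)],
        "n_participants": config.n_participants,
        "artifacts": {p.name: _sha256(p)
                      for p in sorted(set(out.glob("*.csv"))
                                      | set(out.glob("report_*.json")))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return {"cohort": cohort, "reports": reports, "manifest": manifest}
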
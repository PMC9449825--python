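"""End-to-end experiment orchestration.

An experiment is described by a single validated config (YAML/JSON on
disk): a simulation block (or a path to an existing session
directory), window settings, one or more model specs, an evaluation
block, and an optional search block.  Running it produces a
reproducible report bundle: per-model cross-validation summaries,
confusion matrices, optional importance grids and grid-search tables,
plus a provenance record (seed, config hash, library versions).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .classifiers import ModelSpec
from .evaluation import cross_validate, cv_grouped_permutation_importance, group_importance
from .featurizer import FeatureMatrix, extract
from .optimizer import SearchSpace, SensorConfig, run_grid, select_best, task_labels
from .segmenter import segment_dataset
from .sensordata import CHANNELS, LOCATIONS, Dataset, read_session, write_session
from .simkit import NoiseModel, simulate_dataset

__all__ = ["ExperimentConfig", "run_experiment", "load_config"]

log = logging.getLogger(__name__)


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulationBlock(_Block):
    n_participants: int = 19
    seed: int = 0
    locations: list[str] = Field(default_factory=lambda: list(LOCATIONS))
    noise: dict[str, float] = Field(default_factory=dict)
    data_dir: str | None = None  # read an existing dataset instead
    save_dataset: bool = False


class WindowBlock(_Block):
    width_s: float = 5.0
    overlap: float = 0.0


class ModelBlock(_Block):
    family: str
    hyperparameters: dict[str, Any] = Field(default_factory=dict)
    seed: int = 0


class SensorBlock(_Block):
    locations: list[str] = Field(default_factory=lambda: list(LOCATIONS))
    channels: list[str] = Field(default_factory=lambda: list(CHANNELS))


class EvaluationBlock(_Block):
    k: int = 6
    seed: int = 0
    tasks: list[str] = Field(default_factory=lambda: ["exercise", "posture"])
    sensor: SensorBlock = Field(default_factory=SensorBlock)
    importance: bool = False
    importance_repeats: int = 5
    importance_folds: int = 2


class SearchBlock(_Block):
    widths_s: list[float] = Field(default_factory=lambda: [0.5, 1.0, 2.0, 3.0, 5.0])
    overlaps: list[float] = Field(default_factory=lambda: [0.0, 0.2, 0.4, 0.6])
    tasks: list[str] = Field(default_factory=lambda: ["exercise", "posture"])
    location_sets: list[list[str]] = Field(default_factory=list)
    channel_sets: list[list[str]] = Field(default_factory=list)
    max_locations: int | None = None
    garment_preset: str | None = None


class ExperimentConfig(_Block):
    simulation: SimulationBlock = Field(default_factory=SimulationBlock)
    window: WindowBlock = Field(default_factory=WindowBlock)
    models: list[ModelBlock] = Field(default_factory=lambda: [ModelBlock(family="random_forest")])
    evaluation: EvaluationBlock = Field(default_factory=EvaluationBlock)
    search: SearchBlock | None = None
    output_dir: str = "imurehab_run"


def load_config(path: str | Path) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return ExperimentConfig.model_validate(raw or {})


def _provenance(config: ExperimentConfig) -> dict:
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    import sklearn, scipy, xgboost  # noqa: PLC0415

    return {
        "imurehab_version": __version__,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": config.simulation.seed,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "sklearn": sklearn.__version__,
            "xgboost": xgboost.__version__,
        },
    }


def _get_dataset(config: ExperimentConfig) -> Dataset:
    sim = config.simulation
    if sim.data_dir:
        return read_session(sim.data_dir)
    noise = NoiseModel(**sim.noise) if sim.noise else NoiseModel()
    return simulate_dataset(
        n_participants=sim.n_participants, noise=noise, seed=sim.seed,
        locations=tuple(sim.locations),
    )


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the configured experiment and write the report bundle.

    Returns the report dict (also written as ``report.json``).
    Identical config and seed produce an identical bundle.
    """
    t0 = time.time()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log.info("stage=simulate seed=%d", config.simulation.seed)
    dataset = _get_dataset(config)
    if config.simulation.save_dataset and not config.simulation.data_dir:
        write_session(dataset, out_dir / "dataset")

    ev = config.evaluation
    sensor = SensorConfig(tuple(ev.sensor.locations), tuple(ev.sensor.channels))
    width_samples = int(round(config.window.width_s * 25.0))
    log.info("stage=segment width_s=%s overlap=%s", config.window.width_s, config.window.overlap)
    segments = segment_dataset(
        dataset, include=sensor.pairs(),
        width_samples=width_samples, overlap_fraction=config.window.overlap,
    )
    features = extract(segments)

    report: dict[str, Any] = {
        "provenance": _provenance(config),
        "n_recordings": len(dataset),
        "n_segments": segments.n_segments,
        "n_channels": segments.n_channels,
        "n_features": features.n_features,
        "results": [],
    }

    for block in config.models:
        spec = ModelSpec(block.family, block.hyperparameters, block.seed)
        for task in ev.tasks:
            mask, labels = task_labels(features.labels, task)
            if spec.family == "cnn":
                data = segments.subset(mask)
                cv = cross_validate(spec, data, labels=labels,
                                    groups=segments.groups[mask], k=ev.k, seed=ev.seed)
            else:
                sub = features.select_rows(mask)
                data = FeatureMatrix(sub.matrix, sub.feature_meta, labels, sub.groups)
                cv = cross_validate(spec, data, k=ev.k, seed=ev.seed)
            tag = f"{block.family}_{task}"
            cv.confusion.to_csv(out_dir / f"confusion_{tag}.csv")
            entry = {"model": block.family, "task": task, **cv.summary()}
            report["results"].append(entry)
            log.info("stage=evaluate model=%s task=%s f1=%.3f sd=%.3f",
                     block.family, task, cv.mean, cv.sd)

            if ev.importance and spec.family in ("decision_tree", "random_forest", "xgboost"):
                table = cv_grouped_permutation_importance(
                    spec, data, k=ev.k, seed=ev.seed,
                    n_repeats=ev.importance_repeats,
                    n_folds_used=ev.importance_folds,
                )
                grid = group_importance(table)
                grid.to_csv(out_dir / f"importance_permutation_{tag}.csv")

    if config.search is not None:
        sb = config.search
        loc_sets = [tuple(s) for s in sb.location_sets] or [tuple(ev.sensor.locations)]
        ch_sets = [tuple(s) for s in sb.channel_sets] or [tuple(ev.sensor.channels)]
        space = SearchSpace(
            widths_s=sb.widths_s, overlaps=sb.overlaps,
            model_specs=[ModelSpec(m.family, m.hyperparameters, m.seed)
                         for m in config.models if m.family != "cnn"],
            sensor_configs=[SensorConfig(l, c) for l in loc_sets for c in ch_sets],
            tasks=sb.tasks,
        )
        log.info("stage=gridsearch trials=%d", len(space.widths_s) * len(space.overlaps))
        grid_result = run_grid(dataset, space, k=ev.k, seed=ev.seed)
        rows = [
            {
                "width_s": t.config.width_s, "overlap": t.config.overlap,
                "model": t.config.spec.family, "task": t.config.task,
                "locations": "+".join(t.config.sensor_config.locations),
                "channels": "+".join(t.config.sensor_config.channels),
                "mean_f1": t.mean, "sd_f1": t.sd,
            }
            for t in grid_result.trials
        ]
        pd.DataFrame(rows).to_csv(out_dir / "gridsearch.csv", index=False)
        constraints = {}
        if sb.max_locations is not None:
            constraints["max_locations"] = sb.max_locations
        if sb.garment_preset is not None:
            constraints["garment_preset"] = sb.garment_preset
        best_cfg, best_trial = select_best(grid_result.trials, constraints)
        report["selection"] = {
            "locations": list(best_cfg.locations),
            "channels": list(best_cfg.channels),
            "mean_f1": best_trial.mean,
            "sd_f1": best_trial.sd,
            "failures": grid_result.failures,
        }

    report["runtime_s"] = round(time.time() - t0, 2)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
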
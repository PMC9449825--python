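"""Grid search over preprocessing, models and sensor subsets.

A trial is one cell of the search space: (window width, window
overlap, model spec, sensor configuration, task).  Each trial
re-segments and re-featurizes the dataset for its window settings and
runs participant-grouped cross-validation.  Featurization over the
union of requested sensors is cached per (width, overlap, task) and
individual sensor configurations are taken as column subsets, so
widening the sensor axis of the search is cheap.

Sensor-subset selection ranks trials by mean F1, breaking ties toward
lower fold variance, then fewer devices, then fewer channels — the
"practicality" ordering a deployable garment design prefers.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .classifiers import ModelSpec
from .evaluation import CvResult, cross_validate
from .featurizer import FeatureMatrix, extract
from .segmenter import SegmentSet, segment_dataset
from .sensordata import CHANNELS, LOCATIONS, Dataset
from .simkit import ActivityClass, ConfigurationError, default_protocol

__all__ = [
    "SensorConfig",
    "SearchSpace",
    "TrialConfig",
    "TrialResult",
    "GridSearchResult",
    "task_labels",
    "enumerate_trials",
    "run_grid",
    "select_best",
    "final_evaluate",
    "LOWER_BODY_TRIO",
    "default_location_presets",
    "default_channel_presets",
]

log = logging.getLogger(__name__)

LOWER_BODY_TRIO: tuple[str, ...] = ("lower_back", "left_thigh", "right_ankle")

_GARMENT_PRESETS: dict[str, tuple[str, ...]] = {
    "pants": LOWER_BODY_TRIO,
    "pants_watch": LOWER_BODY_TRIO + ("wrist",),
}


@dataclass(frozen=True)
class SensorConfig:
    """A deployable subset of device locations and sensor channels."""

    locations: tuple[str, ...]
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.locations or not self.channels:
            raise ConfigurationError("sensor config must be nonempty")
        bad = set(self.locations) - set(LOCATIONS)
        if bad:
            raise ConfigurationError(f"unknown locations {sorted(bad)}")
        bad = set(self.channels) - set(CHANNELS)
        if bad:
            raise ConfigurationError(f"unknown channels {sorted(bad)}")
        # canonical ordering makes configs comparable and hashable
        object.__setattr__(
            self, "locations", tuple(l for l in LOCATIONS if l in set(self.locations))
        )
        object.__setattr__(
            self, "channels", tuple(c for c in CHANNELS if c in set(self.channels))
        )

    def pairs(self) -> list[tuple[str, str]]:
        return [(l, c) for l in self.locations for c in self.channels]

    def key(self) -> str:
        return "+".join(self.locations) + "|" + "+".join(self.channels)


def default_location_presets() -> list[tuple[str, ...]]:
    """Candidate device subsets: every single device, the lower-body
    pairs, the lower-body trio, the trio plus a watch, and the full
    montage."""
    singles = [(l,) for l in LOCATIONS]
    pairs = [
        ("lower_back", "left_thigh"),
        ("lower_back", "right_ankle"),
        ("left_thigh", "right_ankle"),
    ]
    return singles + pairs + [LOWER_BODY_TRIO, LOWER_BODY_TRIO + ("wrist",), LOCATIONS]


def default_channel_presets() -> list[tuple[str, ...]]:
    return [
        ("accelerometer",),
        ("gyroscope",),
        ("accelerometer", "gyroscope"),
        ("accelerometer", "gyroscope", "magnetometer"),
        ("accelerometer", "gyroscope", "magnetometer", "quaternion"),
        CHANNELS,
    ]


@dataclass
class SearchSpace:
    """Enumerable axes of the grid search."""

    widths_s: Sequence[float] = (0.5, 1.0, 2.0, 3.0, 5.0)
    overlaps: Sequence[float] = (0.0, 0.2, 0.4, 0.6)
    model_specs: Sequence[ModelSpec] = (
        ModelSpec("random_forest"),
        ModelSpec("xgboost"),
    )
    sensor_configs: Sequence[SensorConfig] = (
        SensorConfig(LOCATIONS, ("accelerometer", "gyroscope", "magnetometer")),
    )
    tasks: Sequence[str] = ("exercise", "posture")


@dataclass(frozen=True)
class TrialConfig:
    width_s: float
    overlap: float
    spec: ModelSpec
    sensor_config: SensorConfig
    task: str

    def key(self) -> str:
        return json.dumps(
            {
                "width_s": self.width_s,
                "overlap": self.overlap,
                "spec": self.spec.to_dict(),
                "config": self.sensor_config.key(),
                "task": self.task,
            },
            sort_keys=True,
        )


@dataclass
class TrialResult:
    config: TrialConfig
    cv: CvResult

    @property
    def mean(self) -> float:
        return self.cv.mean

    @property
    def sd(self) -> float:
        return self.cv.sd


@dataclass
class GridSearchResult:
    trials: list[TrialResult]
    failures: list[dict] = field(default_factory=list)
    n_fitted: int = 0


def enumerate_trials(space: SearchSpace) -> list[TrialConfig]:
    """Deterministic enumeration; cell count is the product of axis sizes."""
    for name in ("widths_s", "overlaps", "model_specs", "sensor_configs", "tasks"):
        if not list(getattr(space, name)):
            raise ConfigurationError(f"search-space axis {name!r} is empty")
    configs: list[SensorConfig] = []
    for cfg in space.sensor_configs:
        if cfg in configs:
            log.warning("duplicate sensor config %s dropped from search space", cfg.key())
            continue
        configs.append(cfg)
    return [
        TrialConfig(w, o, m, c, t)
        for w, o, m, c, t in itertools.product(
            space.widths_s, space.overlaps, space.model_specs, configs, space.tasks
        )
    ]


def task_labels(
    labels: np.ndarray,
    task: str,
    protocol: Sequence[ActivityClass] | None = None,
    posture_binary: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """(selection mask, mapped labels) for a classification task.

    ``exercise`` keeps dynamic/static exercises plus ADL; ``posture``
    keeps the sitting postures, by default merged to binary poor
    vs not-poor (the slouched class — largest lumbar flexion offset —
    against the rest); ``all`` keeps every class unchanged.
    """
    protocol = list(protocol) if protocol is not None else default_protocol()
    kinds = {a.name: a.kind for a in protocol}
    labels = np.asarray(labels)
    unknown = set(labels) - set(kinds)
    if unknown:
        raise ConfigurationError(f"labels not in protocol: {sorted(unknown)}")
    if task == "all":
        return np.ones(len(labels), dtype=bool), labels.copy()
    if task == "exercise":
        mask = np.array([kinds[l] != "posture" for l in labels])
        return mask, labels[mask]
    if task == "posture":
        postures = [a for a in protocol if a.kind == "posture"]
        mask = np.array([kinds[l] == "posture" for l in labels])
        mapped = labels[mask].copy()
        if posture_binary and len(postures) > 1:
            poor = max(postures, key=lambda a: a.lumbar_pitch_rad).name
            mapped = np.where(mapped == poor, "posture_poor", "posture_good")
        return mask, mapped
    raise ConfigurationError(f"unknown task {task!r}")


class _FeaturizationCache:
    """Features over the union sensor set, keyed by window settings."""

    def __init__(self, dataset: Dataset, union: SensorConfig, grid_hz: float):
        self.dataset = dataset
        self.union = union
        self.grid_hz = grid_hz
        self._segments: dict[tuple, SegmentSet] = {}
        self._features: dict[tuple, FeatureMatrix] = {}

    def segments(self, width_samples: int, overlap: float) -> SegmentSet:
        key = (width_samples, overlap)
        if key not in self._segments:
            self._segments[key] = segment_dataset(
                self.dataset, include=self.union.pairs(), grid_hz=self.grid_hz,
                width_samples=width_samples, overlap_fraction=overlap,
            )
        return self._segments[key]

    def features(self, width_samples: int, overlap: float) -> FeatureMatrix:
        key = (width_samples, overlap)
        if key not in self._features:
            self._features[key] = extract(self.segments(*key))
        return self._features[key]


def _column_mask(meta, config: SensorConfig) -> np.ndarray:
    pairs = set(config.pairs())
    return np.array(
        [(l, c) in pairs for l, c in zip(meta["location"], meta["channel"])]
    )


def run_grid(
    dataset: Dataset,
    space: SearchSpace,
    k: int = 6,
    seed: int = 0,
    grid_hz: float = 25.0,
    protocol: Sequence[ActivityClass] | None = None,
    cache: dict[str, TrialResult] | None = None,
) -> GridSearchResult:
    """Run every trial of the search space with grouped k-fold CV.

    Per-trial failures are recorded, not fatal.  ``cache`` maps trial
    keys to results; warm entries are returned without refitting.
    """
    trials = enumerate_trials(space)
    union_locations = {l for c in space.sensor_configs for l in c.locations}
    union_channels = {ch for c in space.sensor_configs for ch in c.channels}
    # restrict the shared featurization to streams the dataset has, so
    # one unsatisfiable config fails alone instead of poisoning the run
    first = dataset.recordings[0]
    available = {
        (l, c)
        for l in union_locations
        for c in union_channels
        if first.has_stream(l, c)
    }
    feat_cache = _FeaturizationCache(
        dataset,
        SensorConfig(
            tuple(sorted({l for l, _ in available})) or ("lower_back",),
            tuple(sorted({c for _, c in available})) or ("accelerometer",),
        ),
        grid_hz,
    )
    out = GridSearchResult(trials=[])
    cache = cache if cache is not None else {}
    for trial in trials:
        key = trial.key()
        if key in cache:
            out.trials.append(cache[key])
            continue
        try:
            missing = [p for p in trial.sensor_config.pairs() if p not in available]
            if missing:
                raise ConfigurationError(
                    "dataset lacks streams: "
                    + ", ".join(f"{l}/{c}" for l, c in missing)
                )
            width_samples = int(round(trial.width_s * grid_hz))
            if trial.spec.family == "cnn":
                segs = feat_cache.segments(width_samples, trial.overlap)
                mask, labels = task_labels(segs.labels, trial.task, protocol)
                col = _column_mask(segs.channel_meta, trial.sensor_config)
                data: SegmentSet | FeatureMatrix = SegmentSet(
                    tensor=segs.tensor[mask][:, :, col],
                    labels=labels, groups=segs.groups[mask],
                    width_samples=segs.width_samples,
                    overlap_fraction=segs.overlap_fraction,
                    channel_meta=segs.channel_meta.loc[col].reset_index(drop=True),
                )
            else:
                feats = feat_cache.features(width_samples, trial.overlap)
                mask, labels = task_labels(feats.labels, trial.task, protocol)
                col = _column_mask(feats.feature_meta, trial.sensor_config)
                data = feats.select_rows(mask).select_columns(col)
                data = FeatureMatrix(data.matrix, data.feature_meta, labels, data.groups)
            cv = cross_validate(trial.spec, data, labels=labels, k=k, seed=seed)
            result = TrialResult(config=trial, cv=cv)
            cache[key] = result
            out.trials.append(result)
            out.n_fitted += 1
            log.info(
                "trial %s: F1 %.3f (SD %.3f)", key, result.mean, result.sd
            )
        except Exception as exc:  # per-trial failures are reported, not fatal
            log.warning("trial failed: %s (%s)", key, exc)
            out.failures.append({"trial": key, "error": str(exc)})
    return out


def select_best(
    results: Iterable[TrialResult],
    constraints: Mapping | None = None,
) -> tuple[SensorConfig, TrialResult]:
    """Pick the winning sensor configuration under deployment constraints.

    Constraints: ``max_locations`` (device budget), ``allowed_locations``
    (whitelist), ``garment_preset`` ("pants" or "pants_watch").
    Ranking: highest mean F1, then lowest fold SD, then fewer devices,
    then fewer channels, then lexicographic key — fully deterministic.
    """
    constraints = dict(constraints or {})
    allowed = constraints.get("allowed_locations")
    preset = constraints.get("garment_preset")
    if preset is not None:
        if preset not in _GARMENT_PRESETS:
            raise ConfigurationError(
                f"unknown garment preset {preset!r}; valid: {sorted(_GARMENT_PRESETS)}"
            )
        preset_set = set(_GARMENT_PRESETS[preset])
        allowed = preset_set if allowed is None else set(allowed) & preset_set
    max_locations = constraints.get("max_locations")

    pool = []
    for r in results:
        cfg = r.config.sensor_config
        if max_locations is not None and len(cfg.locations) > max_locations:
            continue
        if allowed is not None and not set(cfg.locations) <= set(allowed):
            continue
        pool.append(r)
    if not pool:
        raise ConfigurationError("no trial satisfies the selection constraints")
    winner = min(
        pool,
        key=lambda r: (
            -r.mean, r.sd, len(r.config.sensor_config.locations),
            len(r.config.sensor_config.channels), r.config.key(),
        ),
    )
    return winner.config.sensor_config, winner


def final_evaluate(
    dataset: Dataset,
    config: SensorConfig,
    spec: ModelSpec,
    k: int = 10,
    seed: int = 0,
    width_s: float = 5.0,
    overlap: float = 0.0,
    task: str = "exercise",
    grid_hz: float = 25.0,
    protocol: Sequence[ActivityClass] | None = None,
) -> CvResult:
    """Re-train the chosen configuration under k-fold grouped CV."""
    width_samples = int(round(width_s * grid_hz))
    segs = segment_dataset(
        dataset, include=config.pairs(), grid_hz=grid_hz,
        width_samples=width_samples, overlap_fraction=overlap,
    )
    mask, labels = task_labels(segs.labels, task, protocol)
    if spec.family == "cnn":
        data: SegmentSet | FeatureMatrix = segs.subset(mask)
    else:
        feats = extract(segs)
        data = feats.select_rows(mask)
    return cross_validate(spec, data, labels=labels, groups=segs.groups[mask], k=k, seed=seed)
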
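"""Search-space enumeration, trial caching, and selection ranking."""

import numpy as np
import pytest

from imurehab.classifiers import ModelSpec
from imurehab.evaluation import CvResult
from imurehab.optimizer import (
    SearchSpace,
    SensorConfig,
    TrialConfig,
    TrialResult,
    enumerate_trials,
    final_evaluate,
    run_grid,
    select_best,
    task_labels,
)
from imurehab.simkit import ConfigurationError, default_protocol, simulate_dataset
from conftest import tiny_protocol


def _space(**kw):
    defaults = dict(
        widths_s=[1.0, 2.0],
        overlaps=[0.0, 0.5],
        model_specs=[ModelSpec("decision_tree"), ModelSpec("gaussian_nb")],
        sensor_configs=[SensorConfig(("lower_back",), ("accelerometer",))],
        tasks=["exercise"],
    )
    defaults.update(kw)
    return SearchSpace(**defaults)


class TestEnumerate:
    def test_cell_count_is_axis_product(self):
        assert len(enumerate_trials(_space())) == 2 * 2 * 2 * 1 * 1

    def test_duplicate_sensor_configs_deduplicated(self, caplog):
        cfg = SensorConfig(("lower_back",), ("accelerometer",))
        space = _space(sensor_configs=[cfg, SensorConfig(("lower_back",),
                                                         ("accelerometer",))])
        with caplog.at_level("WARNING"):
            trials = enumerate_trials(space)
        assert len(trials) == 8
        assert any("duplicate" in r.message for r in caplog.records)

    def test_ordering_is_stable(self):
        assert [t.key() for t in enumerate_trials(_space())] == [
            t.key() for t in enumerate_trials(_space())
        ]

    def test_empty_axis_rejected(self):
        with pytest.raises(ConfigurationError):
            enumerate_trials(_space(widths_s=[]))


class TestSensorConfig:
    def test_canonical_ordering(self):
        a = SensorConfig(("right_ankle", "lower_back"), ("gyroscope", "accelerometer"))
        assert a.locations == ("lower_back", "right_ankle")
        assert a.channels == ("accelerometer", "gyroscope")

    def test_unknown_location_rejected(self):
        with pytest.raises(ConfigurationError):
            SensorConfig(("hip",), ("accelerometer",))

    def test_empty_rejected(self):
        with pytest.raises(ConfigurationError):
            SensorConfig((), ("accelerometer",))


class TestTaskLabels:
    def test_exercise_task_has_8_classes(self):
        proto = default_protocol()
        labels = np.array([a.name for a in proto])
        mask, mapped = task_labels(labels, "exercise")
        assert mask.sum() == 8
        assert len(set(mapped)) == 8

    def test_posture_task_merges_to_binary(self):
        proto = default_protocol()
        labels = np.array([a.name for a in proto])
        mask, mapped = task_labels(labels, "posture")
        assert mask.sum() == 3
        assert set(mapped) == {"posture_poor", "posture_good"}
        assert list(mapped).count("posture_good") == 2

    def test_three_class_posture_available(self):
        labels = np.array([a.name for a in default_protocol()])
        _, mapped = task_labels(labels, "posture", posture_binary=False)
        assert len(set(mapped)) == 3

    def test_unknown_label_rejected(self):
        with pytest.raises(ConfigurationError):
            task_labels(np.array(["jumping"]), "exercise")


def _fake_trial(mean, sd, locations, channels=("accelerometer",), width=5.0):
    cfg = TrialConfig(width, 0.0, ModelSpec("decision_tree"),
                      SensorConfig(locations, channels), "exercise")
    scores = [mean - sd, mean + sd] if sd else [mean, mean]
    import pandas as pd
    return TrialResult(cfg, CvResult(fold_scores=scores,
                                     confusion=pd.DataFrame()))


class TestSelectBest:
    def test_fewer_locations_breaks_exact_ties(self):
        trio = _fake_trial(0.9, 0.0, ("lower_back", "left_thigh", "right_ankle"))
        full = _fake_trial(0.9, 0.0, ("lower_back", "left_thigh", "right_ankle",
                                      "wrist", "upper_back", "right_ear",
                                      "left_shoulder", "right_shoulder"))
        cfg, trial = select_best([full, trio])
        assert len(cfg.locations) == 3

    def test_higher_mean_wins_before_anything_else(self):
        low = _fake_trial(0.8, 0.0, ("lower_back",))
        high = _fake_trial(0.9, 0.2, ("lower_back", "left_thigh"))
        cfg, _ = select_best([low, high])
        assert cfg.locations == ("lower_back", "left_thigh")

    def test_lower_spread_breaks_mean_ties(self):
        noisy = _fake_trial(0.9, 0.1, ("lower_back",))
        steady = _fake_trial(0.9, 0.0, ("left_thigh",))
        cfg, _ = select_best([noisy, steady])
        assert cfg.locations == ("left_thigh",)

    def test_garment_preset_filters_locations(self):
        inside = _fake_trial(0.7, 0.0, ("lower_back", "left_thigh"))
        outside = _fake_trial(0.95, 0.0, ("wrist", "upper_back"))
        cfg, _ = select_best([inside, outside], {"garment_preset": "pants"})
        assert set(cfg.locations) <= {"lower_back", "left_thigh", "right_ankle"}

    def test_single_trial_returned_unchanged(self):
        only = _fake_trial(0.5, 0.0, ("wrist",))
        cfg, trial = select_best([only])
        assert trial is only

    def test_all_filtered_out_rejected(self):
        only = _fake_trial(0.5, 0.0, ("wrist", "upper_back", "right_ear",
                                      "lower_back"))
        with pytest.raises(ConfigurationError):
            select_best([only], {"max_locations": 2})


@pytest.fixture(scope="module")
def grid_setup():
    ds = simulate_dataset(4, protocol=tiny_protocol(), seed=0,
                          locations=("lower_back", "left_thigh"))
    space = SearchSpace(
        widths_s=[2.0], overlaps=[0.0],
        model_specs=[ModelSpec("decision_tree", seed=0)],
        sensor_configs=[
            SensorConfig(("lower_back",), ("accelerometer", "gyroscope")),
            SensorConfig(("left_thigh",), ("accelerometer",)),
        ],
        tasks=["exercise"],
    )
    return ds, space


class TestRunGrid:
    def test_trials_complete_with_sane_scores(self, grid_setup):
        ds, space = grid_setup
        result = run_grid(ds, space, k=4, seed=0, protocol=tiny_protocol())
        assert len(result.trials) == 2
        assert not result.failures
        assert all(0.0 <= t.mean <= 1.0 for t in result.trials)

    def test_warm_cache_returns_identical_results_without_refits(self, grid_setup):
        ds, space = grid_setup
        cache = {}
        first = run_grid(ds, space, k=4, seed=0, protocol=tiny_protocol(), cache=cache)
        second = run_grid(ds, space, k=4, seed=0, protocol=tiny_protocol(), cache=cache)
        assert second.n_fitted == 0
        assert [t.cv.fold_scores for t in second.trials] == [
            t.cv.fold_scores for t in first.trials
        ]

    def test_failed_trials_recorded_not_fatal(self, grid_setup):
        ds, _ = grid_setup
        space = SearchSpace(
            widths_s=[2.0], overlaps=[0.0],
            model_specs=[ModelSpec("decision_tree", seed=0)],
            # wrist was never simulated -> alignment failure for this trial
            sensor_configs=[SensorConfig(("wrist",), ("accelerometer",)),
                            SensorConfig(("lower_back",), ("accelerometer",))],
            tasks=["exercise"],
        )
        result = run_grid(ds, space, k=4, seed=0, protocol=tiny_protocol())
        assert len(result.failures) == 1
        assert len(result.trials) == 1


class TestFinalEvaluate:
    def test_ten_fold_grouped_evaluation(self):
        ds = simulate_dataset(11, protocol=tiny_protocol(), seed=1,
                              locations=("lower_back",))
        cv = final_evaluate(
            ds, SensorConfig(("lower_back",), ("accelerometer", "gyroscope")),
            ModelSpec("decision_tree", seed=0), k=10, seed=0,
            width_s=2.0, task="exercise", protocol=tiny_protocol(),
        )
        assert len(cv.fold_scores) == 10
        assert cv.fold_assignment is not None
        assert max(cv.fold_assignment.fold_sizes()) <= 2
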
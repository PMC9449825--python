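"""Shared fixtures.

The expensive fixtures (the 19-participant default dataset and its
feature matrices) are session-scoped so the recovery-style tests share
one simulation.  Small unit tests build their own tiny protocols.
"""

from __future__ import annotations

import numpy as np
import pytest

from imurehab import FeatureMatrix, extract, segment_dataset, simulate_dataset
from imurehab.optimizer import LOWER_BODY_TRIO, SensorConfig, task_labels
from imurehab.simkit import ActivityClass


TRIO_CONFIG = SensorConfig(
    LOWER_BODY_TRIO, ("accelerometer", "gyroscope", "magnetometer")
)


def tiny_protocol() -> list[ActivityClass]:
    """Two quick dynamic classes plus one posture, short durations."""
    return [
        ActivityClass("flex", "dynamic_exercise", "sagittal", 16.0, n_reps=4,
                      amplitude_rad=np.deg2rad(40.0)),
        ActivityClass("twist", "dynamic_exercise", "transverse", 16.0, n_reps=4,
                      amplitude_rad=np.deg2rad(35.0), signed_excursion=False),
        ActivityClass("sit", "posture", "none", 16.0, base_pose="sitting"),
    ]


@pytest.fixture(scope="session")
def dataset19():
    """The default study-scale dataset: 19 participants, 11 classes."""
    return simulate_dataset(19, seed=0)


@pytest.fixture(scope="session")
def trio_features(dataset19):
    """Engineered features for the lower-body trio, 5 s windows."""
    segs = segment_dataset(dataset19, include=TRIO_CONFIG.pairs(), width_samples=125)
    return extract(segs)


@pytest.fixture(scope="session")
def full_features(dataset19):
    """Engineered features over the full 8-device, 5-channel montage."""
    segs = segment_dataset(dataset19, width_samples=125)
    return extract(segs)


def task_subset(features: FeatureMatrix, task: str) -> FeatureMatrix:
    """Row-filter a feature matrix to one classification task."""
    mask, labels = task_labels(features.labels, task)
    sub = features.select_rows(mask)
    return FeatureMatrix(sub.matrix, sub.feature_meta, labels, sub.groups)


@pytest.fixture(scope="session")
def small_dataset():
    """3 participants on the tiny 3-class protocol (fast unit tests)."""
    return simulate_dataset(
        3, protocol=tiny_protocol(), seed=7,
        locations=("lower_back", "left_thigh"),
    )
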
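"""Sliding-window segmentation of aligned recordings.

Windows are fixed-width, labeled with the recording's activity and
participant, and never span recording boundaries.  The step between
window starts is ``max(1, round(width * (1 - overlap)))`` samples
(round half away from zero), so overlap is expressed as a fraction of
the window width; an overlap given in samples (as in CNN-style
segmenters) converts as ``samples / width``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .sensordata import AlignedRecording, Dataset, align_recording

__all__ = ["SegmentSet", "segment_recording", "segment_dataset", "window_step"]

log = logging.getLogger(__name__)


@dataclass
class SegmentSet:
    """Fixed-width aligned multichannel windows with labels and groups."""

    tensor: np.ndarray  # (n_segments, width_samples, n_channels)
    labels: np.ndarray  # (n_segments,) activity-class names
    groups: np.ndarray  # (n_segments,) participant IDs
    width_samples: int
    overlap_fraction: float
    channel_meta: pd.DataFrame  # per-channel (location, channel, axis)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.groups = np.asarray(self.groups)
        if not (len(self.labels) == len(self.groups) == self.tensor.shape[0]):
            raise ValueError("labels/groups length must equal segment count")

    @property
    def n_segments(self) -> int:
        return int(self.tensor.shape[0])

    @property
    def n_channels(self) -> int:
        return int(self.tensor.shape[2])

    def subset(self, mask: np.ndarray) -> "SegmentSet":
        return SegmentSet(
            tensor=self.tensor[mask],
            labels=self.labels[mask],
            groups=self.groups[mask],
            width_samples=self.width_samples,
            overlap_fraction=self.overlap_fraction,
            channel_meta=self.channel_meta,
        )


def window_step(width_samples: int, overlap_fraction: float) -> int:
    """Window start step: round half away from zero, floored at 1."""
    raw = width_samples * (1.0 - overlap_fraction)
    return max(1, int(np.floor(raw + 0.5)))


def segment_recording(
    aligned: AlignedRecording,
    width_samples: int,
    overlap_fraction: float = 0.0,
) -> np.ndarray:
    """Extract windows of shape (n_windows, width, channels).

    Window starts are 0, step, 2*step, ...; trailing partial windows
    are dropped.  Inputs shorter than one window yield zero windows
    (with a logged warning).
    """
    if width_samples < 2:
        raise ValueError("width_samples must be >= 2")
    if not (0.0 <= overlap_fraction < 1.0):
        raise ValueError("overlap_fraction must be in [0, 1)")
    n = aligned.n_samples
    if n < width_samples:
        log.warning(
            "recording %s/%s too short for one window (%d < %d samples)",
            aligned.participant_id, aligned.label, n, width_samples,
        )
        return np.empty((0, width_samples, aligned.n_columns))
    step = window_step(width_samples, overlap_fraction)
    n_windows = (n - width_samples) // step + 1
    starts = np.arange(n_windows) * step
    return np.stack([aligned.matrix[s : s + width_samples] for s in starts])


def segment_dataset(
    dataset: Dataset,
    include: Iterable[tuple[str, str]] | None = None,
    grid_hz: float = 25.0,
    width_samples: int = 125,
    overlap_fraction: float = 0.0,
) -> SegmentSet:
    """Align, window and concatenate every recording of a dataset.

    Ordering is deterministic: dataset order, then window start.
    """
    if not dataset.recordings:
        raise ValueError("dataset is empty")
    include = list(include) if include is not None else None
    tensors: list[np.ndarray] = []
    labels: list[str] = []
    groups: list[str] = []
    meta: pd.DataFrame | None = None
    for rec in dataset.recordings:
        aligned = align_recording(rec, grid_hz=grid_hz, include=include)
        if meta is None:
            meta = aligned.channel_meta
        windows = segment_recording(aligned, width_samples, overlap_fraction)
        if windows.shape[0] == 0:
            continue
        tensors.append(windows)
        labels.extend([rec.label] * windows.shape[0])
        groups.extend([rec.participant_id] * windows.shape[0])
    if not tensors:
        raise ValueError("no recording was long enough for a single window")
    assert meta is not None
    return SegmentSet(
        tensor=np.concatenate(tensors, axis=0),
        labels=np.array(labels),
        groups=np.array(groups),
        width_samples=width_samples,
        overlap_fraction=overlap_fraction,
        channel_meta=meta,
    )
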
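"""Domain containers and I/O for multi-device IMU session data.

A recording is one labeled activity bout by one participant, holding the
streams from every worn device.  Streams are heterogeneous in rate
(accelerometer/gyroscope/magnetometer at 25 Hz, fused quaternions at
50 Hz, barometric pressure at 13 Hz); :func:`align_recording` resamples
them onto one grid and stacks them column-wise in a fixed, documented
order so that downstream feature columns are stable across runs.

On-disk layout (one directory per recording):

    <participant>__<label>__<index>/
        manifest.json            participant_id, label, duration, stream list
        lower_back__accelerometer.csv   header "t,x,y,z", SI units

A dataset directory simply contains one such session directory per
recording.  Values round-trip exactly (written with repr precision).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "LOCATIONS",
    "CHANNELS",
    "CHANNEL_AXES",
    "CHANNEL_RATES",
    "SensorStream",
    "Recording",
    "Dataset",
    "AlignedRecording",
    "FormatError",
    "ValidationError",
    "resample_stream",
    "align_recording",
    "read_session",
    "write_session",
]

# Device placement order fixed for column ordering (head-to-toe reading
# order of the 8-IMU montage).
LOCATIONS: tuple[str, ...] = (
    "wrist",
    "left_shoulder",
    "right_shoulder",
    "upper_back",
    "lower_back",
    "left_thigh",
    "right_ankle",
    "right_ear",
)

CHANNELS: tuple[str, ...] = (
    "accelerometer",
    "gyroscope",
    "magnetometer",
    "quaternion",
    "pressure",
)

CHANNEL_AXES: dict[str, tuple[str, ...]] = {
    "accelerometer": ("x", "y", "z"),
    "gyroscope": ("x", "y", "z"),
    "magnetometer": ("x", "y", "z"),
    "quaternion": ("w", "x", "y", "z"),
    "pressure": ("p",),
}

# Native sampling rates in Hz.
CHANNEL_RATES: dict[str, float] = {
    "accelerometer": 25.0,
    "gyroscope": 25.0,
    "magnetometer": 25.0,
    "quaternion": 50.0,
    "pressure": 13.0,
}


class FormatError(Exception):
    """On-disk session layout violation (missing manifest, missing file)."""


class ValidationError(Exception):
    """In-memory data contract violation (axis counts, norms, NaNs)."""


@dataclass
class SensorStream:
    """One channel group of one device: timestamps plus sample vectors."""

    location: str
    channel: str
    rate_hz: float
    timestamps: np.ndarray  # (n,) seconds from session start
    values: np.ndarray  # (n, n_axes)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != self.timestamps.shape[0]:
            raise ValidationError(
                f"{self.location}/{self.channel}: {self.values.shape[0]} rows "
                f"for {self.timestamps.shape[0]} timestamps"
            )
        if self.location not in LOCATIONS:
            raise ValidationError(f"unknown location {self.location!r}")
        if self.channel not in CHANNELS:
            raise ValidationError(f"unknown channel {self.channel!r}")
        expected = len(CHANNEL_AXES[self.channel])
        if self.values.shape[1] != expected:
            raise ValidationError(
                f"{self.location}/{self.channel}: expected {expected} axes, "
                f"got {self.values.shape[1]}"
            )
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValidationError(
                f"{self.location}/{self.channel}: timestamps not strictly increasing"
            )

    @property
    def axes(self) -> tuple[str, ...]:
        return CHANNEL_AXES[self.channel]

    @property
    def n_samples(self) -> int:
        return int(self.timestamps.shape[0])


@dataclass
class Recording:
    """One labeled activity bout by one participant."""

    participant_id: str
    label: str
    streams: list[SensorStream] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.streams:
            raise ValidationError("recording must contain at least one stream")

    @property
    def duration_s(self) -> float:
        return max(float(s.timestamps[-1]) for s in self.streams if s.n_samples)

    def stream(self, location: str, channel: str) -> SensorStream:
        for s in self.streams:
            if s.location == location and s.channel == channel:
                return s
        raise KeyError((location, channel))

    def has_stream(self, location: str, channel: str) -> bool:
        return any(s.location == location and s.channel == channel for s in self.streams)


@dataclass
class Dataset:
    """A collection of recordings, possibly spanning many participants."""

    recordings: list[Recording] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.recordings)

    @property
    def participants(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.recordings:
            seen.setdefault(r.participant_id, None)
        return list(seen)

    @property
    def labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.recordings:
            seen.setdefault(r.label, None)
        return list(seen)


@dataclass
class AlignedRecording:
    """All requested streams of one recording on a single time grid."""

    grid_hz: float
    matrix: np.ndarray  # (n_samples, n_columns)
    channel_meta: pd.DataFrame  # columns: location, channel, axis
    participant_id: str = ""
    label: str = ""

    @property
    def n_samples(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def n_columns(self) -> int:
        return int(self.matrix.shape[1])


def resample_stream(
    stream: SensorStream, target_hz: float, method: str = "interp"
) -> SensorStream:
    """Resample onto a uniform grid starting at the first sample.

    The grid steps by ``1/target_hz`` and ends at or before the last
    timestamp.  ``method="interp"`` (default) is plain linear
    interpolation; ``method="decimate"`` low-pass filters before
    downsampling (anti-aliasing sensitivity checks) and requires a
    uniform input whose rate is an integer multiple of the target.
    Quaternion streams are renormalized to unit norm afterwards.
    """
    if target_hz <= 0:
        raise ValueError(f"target_hz must be positive, got {target_hz}")
    if stream.n_samples < 2:
        raise ValidationError("resampling requires at least 2 samples")
    t0 = stream.timestamps[0]
    span = stream.timestamps[-1] - t0
    n_out = int(np.floor(span * target_hz + 1e-9)) + 1
    grid = t0 + np.arange(n_out) / target_hz
    if method == "decimate":
        from scipy.signal import decimate

        ratio = stream.rate_hz / target_hz
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError(
                f"decimation needs an integer rate ratio, got {ratio:g}"
            )
        q = int(round(ratio))
        filtered = (
            stream.values
            if q == 1
            else decimate(stream.values, q, axis=0, zero_phase=True)
        )
        out = filtered[:n_out]
        grid = grid[: out.shape[0]]
    elif method != "interp":
        raise ValueError(f"unknown resampling method {method!r}")
    else:
        out = np.empty((n_out, stream.values.shape[1]))
        for j in range(stream.values.shape[1]):
            out[:, j] = np.interp(grid, stream.timestamps, stream.values[:, j])
    if stream.channel == "quaternion":
        norms = np.linalg.norm(out, axis=1, keepdims=True)
        out = out / norms
    return SensorStream(
        location=stream.location,
        channel=stream.channel,
        rate_hz=float(target_hz),
        timestamps=grid,
        values=out,
    )


def _ordered_pairs(include: Iterable[tuple[str, str]]) -> list[tuple[str, str]]:
    pairs = set(include)
    return [
        (loc, ch)
        for loc in LOCATIONS
        for ch in CHANNELS
        if (loc, ch) in pairs
    ]


def align_recording(
    rec: Recording,
    grid_hz: float = 25.0,
    include: Iterable[tuple[str, str]] | None = None,
) -> AlignedRecording:
    """Resample the requested streams to ``grid_hz`` and stack columns.

    Columns are ordered by device placement (head-to-toe montage order),
    then channel (accelerometer, gyroscope, magnetometer, quaternion,
    pressure), then axis.  Streams are truncated to the shortest common
    span; the grid never extrapolates beyond any included stream.
    """
    if include is None:
        pairs = [(s.location, s.channel) for s in rec.streams]
    else:
        pairs = list(include)
    missing = [(loc, ch) for loc, ch in pairs if not rec.has_stream(loc, ch)]
    if missing:
        raise ValidationError(
            "recording is missing requested streams: "
            + ", ".join(f"{loc}/{ch}" for loc, ch in sorted(missing))
        )
    ordered = _ordered_pairs(pairs)
    streams = [rec.stream(loc, ch) for loc, ch in ordered]
    t_start = max(s.timestamps[0] for s in streams)
    t_end = min(s.timestamps[-1] for s in streams)
    if t_end <= t_start:
        raise ValidationError("included streams share no common time span")
    n_out = int(np.floor((t_end - t_start) * grid_hz + 1e-9)) + 1
    grid = t_start + np.arange(n_out) / grid_hz

    cols: list[np.ndarray] = []
    meta_rows: list[tuple[str, str, str]] = []
    for s in streams:
        block = np.empty((n_out, s.values.shape[1]))
        for j in range(s.values.shape[1]):
            block[:, j] = np.interp(grid, s.timestamps, s.values[:, j])
        if s.channel == "quaternion":
            block = block / np.linalg.norm(block, axis=1, keepdims=True)
        cols.append(block)
        meta_rows.extend((s.location, s.channel, ax) for ax in s.axes)
    matrix = np.hstack(cols)
    meta = pd.DataFrame(meta_rows, columns=["location", "channel", "axis"])
    return AlignedRecording(
        grid_hz=float(grid_hz),
        matrix=matrix,
        channel_meta=meta,
        participant_id=rec.participant_id,
        label=rec.label,
    )


# ---------------------------------------------------------------------------
# On-disk format


def _session_dirname(rec: Recording, index: int) -> str:
    safe = re.sub(r"[^A-Za-z0-9_-]", "-", rec.label)
    return f"{rec.participant_id}__{safe}__{index:03d}"


def _write_recording(rec: Recording, session_dir: Path) -> None:
    session_dir.mkdir(parents=True, exist_ok=True)
    stream_entries = []
    for s in rec.streams:
        fname = f"{s.location}__{s.channel}.csv"
        header = "t," + ",".join(s.axes)
        data = np.column_stack([s.timestamps, s.values])
        with open(session_dir / fname, "w") as fh:
            fh.write(header + "\n")
            for row in data:
                fh.write(",".join(repr(float(v)) for v in row) + "\n")
        stream_entries.append(
            {
                "file": fname,
                "location": s.location,
                "channel": s.channel,
                "rate_hz": s.rate_hz,
            }
        )
    manifest = {
        "participant_id": rec.participant_id,
        "label": rec.label,
        "duration_s": rec.duration_s,
        "streams": stream_entries,
    }
    with open(session_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def _read_recording(session_dir: Path) -> Recording:
    manifest_path = session_dir / "manifest.json"
    if not manifest_path.exists():
        raise FormatError(f"missing manifest: {manifest_path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    streams = []
    for entry in manifest["streams"]:
        fpath = session_dir / entry["file"]
        if not fpath.exists():
            raise FormatError(f"manifest references missing stream file: {fpath}")
        table = pd.read_csv(fpath, float_precision="round_trip")
        expected_axes = CHANNEL_AXES[entry["channel"]]
        if tuple(table.columns[1:]) != expected_axes:
            raise ValidationError(
                f"{fpath}: expected axes {expected_axes}, got {tuple(table.columns[1:])}"
            )
        streams.append(
            SensorStream(
                location=entry["location"],
                channel=entry["channel"],
                rate_hz=float(entry["rate_hz"]),
                timestamps=table.iloc[:, 0].to_numpy(),
                values=table.iloc[:, 1:].to_numpy(),
            )
        )
    return Recording(
        participant_id=manifest["participant_id"],
        label=manifest["label"],
        streams=streams,
    )


def write_session(dataset: Dataset, out_dir: str | Path) -> None:
    """Write a dataset as one session directory per recording."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, rec in enumerate(dataset.recordings):
        _write_recording(rec, out / _session_dirname(rec, i))
    with open(out / "dataset.json", "w") as fh:
        json.dump(
            {
                "n_recordings": len(dataset.recordings),
                "metadata": dataset.metadata,
                "sessions": [
                    _session_dirname(r, i) for i, r in enumerate(dataset.recordings)
                ],
            },
            fh,
            indent=2,
        )


def read_session(in_dir: str | Path) -> Dataset:
    """Read a dataset directory (or a single session directory)."""
    root = Path(in_dir)
    if not root.exists():
        raise FormatError(f"no such directory: {root}")
    if (root / "manifest.json").exists():
        return Dataset(recordings=[_read_recording(root)])
    index_path = root / "dataset.json"
    if index_path.exists():
        with open(index_path) as fh:
            index = json.load(fh)
        dirs = [root / name for name in index["sessions"]]
        metadata = index.get("metadata", {})
    else:
        dirs = sorted(p for p in root.iterdir() if (p / "manifest.json").exists())
        metadata = {}
        if not dirs:
            raise FormatError(f"{root} contains no session manifests")
    return Dataset(recordings=[_read_recording(d) for d in dirs], metadata=metadata)
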
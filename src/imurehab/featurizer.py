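"""Engineered statistical and time-domain segment features.

Each channel of each segment is reduced to 23 scalar features
(configurable by name).  Definitions follow common time-series feature
engineering practice; choices that the names leave open are pinned
down here:

* standard deviation / variance / skewness / kurtosis use population
  (biased) estimators; kurtosis is excess-adjusted (0 for a normal);
  skewness and kurtosis of a zero-variance window are defined as 0;
* coefficient of variation is std / |mean|, defined as 0 when the mean
  is numerically zero;
* zero and mean crossings count strict sign changes only (values
  exactly at the threshold do not count);
* the line slope is the least-squares slope against the sample index;
* spectral features use the one-sided magnitude spectrum of the
  de-meaned window; the dominant-frequency index is the argmax bin
  (>= 1) of that spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmenter import SegmentSet
from .sensordata import ValidationError

__all__ = [
    "FEATURE_NAMES",
    "feature_vector",
    "compute_features",
    "extract",
    "FeatureMatrix",
    "Standardizer",
    "fit_standardizer",
]

FEATURE_NAMES: tuple[str, ...] = (
    "mean",
    "median",
    "minimum",
    "maximum",
    "standard_deviation",
    "variance",
    "skewness",
    "kurtosis",
    "absolute_energy",
    "absolute_sum",
    "root_mean_square",
    "coefficient_of_variation",
    "mean_absolute_deviation",
    "interquartile_range",
    "range",
    "mean_first_differences",
    "mean_absolute_first_differences",
    "waveform_length",
    "zero_crossing_count",
    "mean_crossing_count",
    "line_slope",
    "mean_spectral_energy",
    "dominant_frequency_index",
)

_EPS = 1e-12


def compute_features(windows: np.ndarray) -> np.ndarray:
    """Vectorized features along the last axis: (..., n) -> (..., 23)."""
    x = np.asarray(windows, dtype=float)
    if x.shape[-1] < 2:
        raise ValidationError("feature windows need length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValidationError("feature input contains NaN or Inf")
    n = x.shape[-1]

    mean = x.mean(axis=-1)
    centered = x - mean[..., None]
    var = np.mean(centered**2, axis=-1)
    std = np.sqrt(var)
    nonconst = std > _EPS

    with np.errstate(divide="ignore", invalid="ignore"):
        z3 = np.mean(centered**3, axis=-1) / std**3
        z4 = np.mean(centered**4, axis=-1) / var**2 - 3.0
    skew = np.where(nonconst, z3, 0.0)
    kurt = np.where(nonconst, z4, 0.0)

    abs_energy = np.sum(x**2, axis=-1)
    abs_sum = np.sum(np.abs(x), axis=-1)
    rms = np.sqrt(abs_energy / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(np.abs(mean) > _EPS, std / np.abs(mean), 0.0)
    mad = np.mean(np.abs(centered), axis=-1)
    q75, q25 = np.percentile(x, [75, 25], axis=-1)
    iqr = q75 - q25
    rng = x.max(axis=-1) - x.min(axis=-1)

    diffs = np.diff(x, axis=-1)
    mean_diff = diffs.mean(axis=-1)
    mean_abs_diff = np.abs(diffs).mean(axis=-1)
    waveform_length = np.abs(diffs).sum(axis=-1)

    sign = np.sign(x)
    zero_cross = np.sum(sign[..., :-1] * sign[..., 1:] < 0, axis=-1).astype(float)
    sign_c = np.sign(centered)
    mean_cross = np.sum(sign_c[..., :-1] * sign_c[..., 1:] < 0, axis=-1).astype(float)

    idx = np.arange(n) - (n - 1) / 2.0
    slope = (centered * idx).sum(axis=-1) / np.sum(idx**2)

    spectrum = np.abs(np.fft.rfft(centered, axis=-1))
    power = spectrum**2
    mean_spec_energy = power.mean(axis=-1)
    dom_freq = np.argmax(spectrum[..., 1:], axis=-1).astype(float) + 1.0

    return np.stack(
        [
            mean, np.median(x, axis=-1), x.min(axis=-1), x.max(axis=-1),
            std, var, skew, kurt, abs_energy, abs_sum, rms, cv, mad, iqr,
            rng, mean_diff, mean_abs_diff, waveform_length, zero_cross,
            mean_cross, slope, mean_spec_energy, dom_freq,
        ],
        axis=-1,
    )


def feature_vector(signal: np.ndarray) -> dict[str, float]:
    """The 23 named features of a single 1-D window."""
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValidationError("feature_vector expects a 1-D window")
    values = compute_features(signal)
    return dict(zip(FEATURE_NAMES, (float(v) for v in values)))


@dataclass
class FeatureMatrix:
    """Segments x engineered features with per-column provenance."""

    matrix: np.ndarray  # (n_segments, n_features)
    feature_meta: pd.DataFrame  # location, channel, axis, feature_name
    labels: np.ndarray
    groups: np.ndarray

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.feature_meta):
            raise ValidationError(
                f"feature_meta has {len(self.feature_meta)} rows for "
                f"{self.matrix.shape[1]} columns"
            )

    @property
    def n_segments(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def n_features(self) -> int:
        return int(self.matrix.shape[1])

    def select_columns(self, mask: np.ndarray) -> "FeatureMatrix":
        """Column subset (e.g. restricting to a sensor configuration)."""
        mask = np.asarray(mask)
        return FeatureMatrix(
            matrix=self.matrix[:, mask],
            feature_meta=self.feature_meta.loc[mask].reset_index(drop=True),
            labels=self.labels,
            groups=self.groups,
        )

    def select_rows(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            matrix=self.matrix[mask],
            feature_meta=self.feature_meta,
            labels=self.labels[mask],
            groups=self.groups[mask],
        )


def extract(segments: SegmentSet, features: tuple[str, ...] | None = None) -> FeatureMatrix:
    """Featurize every channel of every segment.

    Columns are ordered channel-major (channel_meta order), feature
    name minor, so the count is ``n_channels * len(features)``.
    ``features`` selects a named subset of the default 23.
    """
    if segments.n_segments == 0:
        raise ValidationError("cannot featurize an empty SegmentSet")
    names = tuple(features) if features is not None else FEATURE_NAMES
    unknown = set(names) - set(FEATURE_NAMES)
    if unknown:
        raise ValidationError(f"unknown feature names: {sorted(unknown)}")
    keep = np.array([FEATURE_NAMES.index(n) for n in names])
    # (segments, width, channels) -> (segments, channels, width)
    per_channel = np.moveaxis(segments.tensor, 1, 2)
    feats = compute_features(per_channel)[..., keep]
    matrix = feats.reshape(segments.n_segments, -1)
    meta = segments.channel_meta.loc[
        segments.channel_meta.index.repeat(len(names))
    ].reset_index(drop=True)
    meta["feature_name"] = list(names) * segments.n_channels
    return FeatureMatrix(
        matrix=matrix,
        feature_meta=meta,
        labels=segments.labels.copy(),
        groups=segments.groups.copy(),
    )


@dataclass
class Standardizer:
    """Column-wise z-scoring with statistics learned on a training split.

    Constant training columns (sd below the 1e-12 floor) map to zero.
    """

    mean: np.ndarray
    std: np.ndarray  # raw population SD; values <= the floor mark constants

    def transform(self, features: FeatureMatrix | np.ndarray) -> FeatureMatrix | np.ndarray:
        matrix = features.matrix if isinstance(features, FeatureMatrix) else np.asarray(features)
        if matrix.shape[1] != self.mean.shape[0]:
            raise ValidationError(
                f"standardizer fitted on {self.mean.shape[0]} columns, "
                f"got {matrix.shape[1]}"
            )
        constant = self.std <= _EPS
        scale = np.where(constant, 1.0, self.std)
        out = (matrix - self.mean) / scale
        out[:, constant] = 0.0
        if isinstance(features, FeatureMatrix):
            return FeatureMatrix(out, features.feature_meta, features.labels, features.groups)
        return out


def fit_standardizer(train: FeatureMatrix | np.ndarray) -> Standardizer:
    """Learn per-column mean/SD from training rows only."""
    matrix = train.matrix if isinstance(train, FeatureMatrix) else np.asarray(train)
    return Standardizer(mean=matrix.mean(axis=0), std=matrix.std(axis=0))
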
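"""Signal conditioning and windowed segmentation.

Pipeline order: pressure offset removal -> cleaning (interpolate short
gaps, split at long ones, trim missing edges) -> exponential moving
average smoothing -> sliding-window segmentation into labeled per-subframe
median tensors -> train-statistics z-normalization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import lfilter

from skigears.io_formats import GEARS, LabelTrack, Recording

logger = logging.getLogger(__name__)

PRESSURE_SENSORS = ("BT", "1m", "5m", "H")


def _is_pressure(channel: str) -> bool:
    return channel.split("_", 1)[1] in PRESSURE_SENSORS


@dataclass(frozen=True)
class SensorGeometry:
    """Circular piezoresistive sensor geometry (diameter in mm)."""

    diameter_mm: float = 9.53

    @property
    def area_cm2(self) -> float:
        radius_cm = self.diameter_mm / 2.0 / 10.0
        return math.pi * radius_cm**2


def force_to_pressure(force_kg: float, geom: SensorGeometry = SensorGeometry()) -> float:
    """Convert a sensor force reading (kg) to pressure (kg/cm^2)."""
    if force_kg < 0:
        raise ValueError("force must be non-negative")
    return force_kg / geom.area_cm2


@dataclass
class PreprocessParams:
    """Knobs for the conditioning chain and segmentation."""

    baseline_percentile: float = 5.0
    max_gap_ms: float = 200.0
    max_missing_frac: float = 0.5
    ema_alpha: float = 0.3
    window_ms: int = 5000
    stride_ms: int = 50
    subframe_ms: int = 50


@dataclass
class WindowSet:
    """Segmented, labeled feature tensor: windows x steps x channels."""

    tensor: np.ndarray
    labels: np.ndarray
    groups: np.ndarray
    channel_names: list[str]
    window_ms: int = 5000
    stride_ms: int = 50
    subframe_ms: int = 50

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=object)
        self.groups = np.asarray(self.groups, dtype=object)
        if self.tensor.ndim != 3:
            raise ValueError("tensor must be windows x steps x channels")
        n, steps, c = self.tensor.shape
        if self.window_ms % self.subframe_ms != 0:
            raise ValueError("window_ms must be divisible by subframe_ms")
        if n and steps != self.window_ms // self.subframe_ms:
            raise ValueError(
                f"steps ({steps}) != window_ms/subframe_ms "
                f"({self.window_ms // self.subframe_ms})"
            )
        if c != len(self.channel_names):
            raise ValueError("channel_names length must match tensor channels")
        if len(self.labels) != n or len(self.groups) != n:
            raise ValueError("labels/groups must have one entry per window")
        for lab in self.labels:
            if lab not in GEARS:
                raise ValueError(f"unknown window label: {lab!r}")

    def __len__(self) -> int:
        return self.tensor.shape[0]

    @property
    def steps(self) -> int:
        return self.window_ms // self.subframe_ms

    def select_channels(self, names: Sequence[str]) -> "WindowSet":
        """Restrict to a channel subset (in the given order)."""
        idx = [self.channel_names.index(n) for n in names]
        return WindowSet(
            tensor=self.tensor[:, :, idx],
            labels=self.labels.copy(),
            groups=self.groups.copy(),
            channel_names=list(names),
            window_ms=self.window_ms,
            stride_ms=self.stride_ms,
            subframe_ms=self.subframe_ms,
        )

    def subset(self, mask: np.ndarray) -> "WindowSet":
        return WindowSet(
            tensor=self.tensor[mask],
            labels=self.labels[mask],
            groups=self.groups[mask],
            channel_names=list(self.channel_names),
            window_ms=self.window_ms,
            stride_ms=self.stride_ms,
            subframe_ms=self.subframe_ms,
        )

    @staticmethod
    def concatenate(sets: Iterable["WindowSet"]) -> "WindowSet":
        sets = list(sets)
        if not sets:
            raise ValueError("nothing to concatenate")
        sets = [s for s in sets if len(s) > 0] or sets[:1]
        first = sets[0]
        for s in sets[1:]:
            if s.channel_names != first.channel_names:
                raise ValueError("channel sets differ")
        return WindowSet(
            tensor=np.concatenate([s.tensor for s in sets], axis=0),
            labels=np.concatenate([s.labels for s in sets]),
            groups=np.concatenate([s.groups for s in sets]),
            channel_names=list(first.channel_names),
            window_ms=first.window_ms,
            stride_ms=first.stride_ms,
            subframe_ms=first.subframe_ms,
        )


@dataclass
class NormalizationStats:
    """Per-channel mean/std computed on training windows only."""

    mean: np.ndarray
    std: np.ndarray
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.std = np.asarray(self.std, dtype=np.float64)
        if (self.std <= 0).any():
            raise ValueError("std must be positive for every channel")


# ---------------------------------------------------------------------------
# conditioning


def remove_offset(rec: Recording, baseline_percentile: float = 5.0) -> Recording:
    """Subtract each pressure channel's estimated resting baseline.

    The baseline is the given percentile of the channel over the whole run
    (a proxy for the non-contact phase); results are clipped at zero.
    Non-pressure channels pass through untouched.
    """
    out = rec.samples.copy()
    for j, name in enumerate(rec.channels):
        if not _is_pressure(name):
            continue
        col = out[:, j]
        finite = col[~np.isnan(col)]
        if finite.size == 0:
            raise ValueError(f"channel {name} is entirely missing")
        baseline = np.percentile(finite, baseline_percentile)
        out[:, j] = np.clip(col - baseline, 0.0, None)
    return rec.with_samples(out)


def ema_smooth(series: np.ndarray, alpha: float) -> np.ndarray:
    """Exponential moving average: y0 = x0, y_t = a*x_t + (1-a)*y_{t-1}."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("series must be non-empty")
    # IIR form: y[t] - (1-a) y[t-1] = a x[t]; seed the state so y[0] = x[0]
    zi = np.array([(1.0 - alpha) * x[0]])
    y, _ = lfilter([alpha], [1.0, alpha - 1.0], x, zi=zi)
    return y


def smooth_recording(rec: Recording, alpha: float) -> Recording:
    out = np.empty_like(rec.samples)
    for j in range(rec.samples.shape[1]):
        out[:, j] = ema_smooth(rec.samples[:, j], alpha)
    return rec.with_samples(out)


def clean(
    rec: Recording,
    max_gap_ms: float = 200.0,
    max_missing_frac: float = 0.5,
) -> list[Recording]:
    """Repair missing cells; split the run where gaps are too long.

    Missing runs of at most ``max_gap_ms`` per channel are linearly
    interpolated; leading/trailing missing samples are trimmed; any row
    still missing after interpolation splits the recording there.  A run
    with more than ``max_missing_frac`` missing in any channel is rejected.
    """
    x = rec.samples
    n = x.shape[0]
    if n == 0:
        return []
    missing = np.isnan(x)
    frac = missing.mean(axis=0)
    worst = int(np.argmax(frac))
    if frac[worst] > max_missing_frac:
        raise ValueError(
            f"channel {rec.channels[worst]} is {frac[worst]:.0%} missing "
            f"(limit {max_missing_frac:.0%})"
        )

    max_gap_ticks = int(round(max_gap_ms * rec.rate_hz / 1000.0))
    out = x.copy()
    for j in range(x.shape[1]):
        col = out[:, j]
        nan = np.isnan(col)
        if not nan.any():
            continue
        idx = np.flatnonzero(nan)
        # group consecutive missing indices into gaps
        splits = np.flatnonzero(np.diff(idx) > 1)
        for gap in np.split(idx, splits + 1):
            lo, hi = gap[0], gap[-1]
            if lo == 0 or hi == n - 1 or len(gap) > max_gap_ticks:
                continue  # edge or too long: handled below
            x0, x1 = col[lo - 1], col[hi + 1]
            col[gap] = np.interp(gap, [lo - 1, hi + 1], [x0, x1])

    # rows still containing a missing cell split the run
    bad_row = np.isnan(out).any(axis=1)
    segments: list[Recording] = []
    start = None
    for i in range(n + 1):
        if i < n and not bad_row[i]:
            if start is None:
                start = i
        elif start is not None:
            piece = rec.with_samples(out[start:i])
            piece.run_id = f"{rec.run_id}.{len(segments)}" if bad_row.any() else rec.run_id
            segments.append(piece)
            start = None
    return segments


# ---------------------------------------------------------------------------
# segmentation


def window_count(duration_ms: float, window_ms: int, stride_ms: int) -> int:
    """Number of sliding windows before label filtering: floor((T-W)/S)+1."""
    if duration_ms < window_ms:
        return 0
    return int((duration_ms - window_ms) // stride_ms) + 1


def segment(
    rec: Recording,
    track: LabelTrack,
    window_ms: int = 5000,
    stride_ms: int = 50,
    subframe_ms: int = 50,
) -> WindowSet:
    """Slide fixed windows over a cleaned recording and take subframe medians.

    Windows advance by ``stride_ms``; a window is kept only when it lies
    fully inside a single label interval (boundary-straddling windows and
    unlabeled gaps are dropped).  Each kept window becomes a block of
    per-subframe medians: (window_ms/subframe_ms) steps x channels.
    """
    if window_ms % subframe_ms != 0:
        raise ValueError("window_ms must be divisible by subframe_ms")
    sub_ticks = subframe_ms * rec.rate_hz / 1000.0
    if abs(sub_ticks - round(sub_ticks)) > 1e-9 or round(sub_ticks) < 1:
        raise ValueError("subframe_ms must span a whole number of ticks")
    sub_ticks = int(round(sub_ticks))
    steps = window_ms // subframe_ms
    stride_ticks = stride_ms * rec.rate_hz / 1000.0
    if abs(stride_ticks - round(stride_ticks)) > 1e-9 or round(stride_ticks) < 1:
        raise ValueError("stride_ms must span a whole number of ticks")
    stride_ticks = int(round(stride_ticks))

    n = rec.n_samples
    window_ticks = steps * sub_ticks
    n_windows = window_count(n, window_ticks, stride_ticks)

    tensors, labels = [], []
    if n_windows > 0 and stride_ticks % sub_ticks == 0:
        # fast path: windows align to the subframe grid, so precompute all
        # subframe medians once and slice
        n_blocks = n // sub_ticks
        blocks = rec.samples[: n_blocks * sub_ticks].reshape(
            n_blocks, sub_ticks, len(rec.channels))
        block_medians = np.median(blocks, axis=1)
        block_stride = stride_ticks // sub_ticks
        for w in range(n_windows):
            b0 = w * block_stride
            start_ms = w * stride_ticks * 1000.0 / rec.rate_hz
            gear = track.gear_at(start_ms, start_ms + window_ms)
            if gear is None:
                continue
            tensors.append(block_medians[b0:b0 + steps])
            labels.append(gear)
    else:
        for w in range(n_windows):
            i0 = w * stride_ticks
            start_ms = i0 * 1000.0 / rec.rate_hz
            gear = track.gear_at(start_ms, start_ms + window_ms)
            if gear is None:
                continue
            block = rec.samples[i0:i0 + window_ticks].reshape(
                steps, sub_ticks, len(rec.channels))
            tensors.append(np.median(block, axis=1))
            labels.append(gear)

    if tensors:
        tensor = np.stack(tensors)
    else:
        tensor = np.empty((0, steps, len(rec.channels)), dtype=np.float32)
    return WindowSet(
        tensor=tensor,
        labels=np.array(labels, dtype=object),
        groups=np.array([rec.participant_id] * len(labels), dtype=object),
        channel_names=list(rec.channels),
        window_ms=window_ms,
        stride_ms=stride_ms,
        subframe_ms=subframe_ms,
    )


def preprocess_recording(
    rec: Recording,
    track: LabelTrack,
    params: PreprocessParams = PreprocessParams(),
) -> WindowSet:
    """Full conditioning chain for one raw recording."""
    rec = remove_offset(rec, params.baseline_percentile)
    pieces = clean(rec, params.max_gap_ms, params.max_missing_frac)
    sets = []
    for piece in pieces:
        piece = smooth_recording(piece, params.ema_alpha)
        sets.append(segment(piece, track, params.window_ms,
                            params.stride_ms, params.subframe_ms))
    if not sets:
        steps = params.window_ms // params.subframe_ms
        return WindowSet(
            tensor=np.empty((0, steps, len(rec.channels)), dtype=np.float32),
            labels=np.array([], dtype=object),
            groups=np.array([], dtype=object),
            channel_names=list(rec.channels),
            window_ms=params.window_ms,
            stride_ms=params.stride_ms,
            subframe_ms=params.subframe_ms,
        )
    return WindowSet.concatenate(sets)


# ---------------------------------------------------------------------------
# normalization


def fit_norm(train: WindowSet) -> NormalizationStats:
    """Per-channel mean/std over all training windows and steps.

    Zero-variance channels get std 1 with a warning so they normalize to a
    constant zero rather than dividing by zero.
    """
    if len(train) == 0:
        raise ValueError("cannot fit normalization on an empty WindowSet")
    flat = train.tensor.reshape(-1, train.tensor.shape[2]).astype(np.float64)
    mean = flat.mean(axis=0)
    std = flat.std(axis=0)
    zero = std <= 0
    if zero.any():
        names = [train.channel_names[i] for i in np.flatnonzero(zero)]
        logger.warning("zero-variance channels %s: std set to 1", names)
        std = np.where(zero, 1.0, std)
    return NormalizationStats(mean=mean, std=std, channel_names=list(train.channel_names))


def apply_norm(ws: WindowSet, stats: NormalizationStats) -> WindowSet:
    """z-score a WindowSet with (training) statistics."""
    if list(ws.channel_names) != list(stats.channel_names):
        raise ValueError("channel set differs from normalization stats")
    tensor = (ws.tensor.astype(np.float64) - stats.mean) / stats.std
    return WindowSet(
        tensor=tensor,
        labels=ws.labels.copy(),
        groups=ws.groups.copy(),
        channel_names=list(ws.channel_names),
        window_ms=ws.window_ms,
        stride_ms=ws.stride_ms,
        subframe_ms=ws.subframe_ms,
    )
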
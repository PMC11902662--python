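"""Reading and writing of datalogger-style recordings, label tracks, and
evaluation reports.

File dialects
-------------
*Recordings* are plain CSV with a header row.  The first column is
``time_ms`` (integer milliseconds, strictly increasing at the sampling
rate); the remaining columns are channels drawn from the canonical 26-name
set (per foot ``R_``/``L_``: four pressure sensors ``BT``, ``1m``, ``5m``,
``H`` in kg/cm^2, then accelerometer ``Ax..Az`` in g, gyroscope ``Gx..Gz``
in dps, magnetometer ``Mx..Mz`` in gauss).  Missing values are empty cells
and surface as NaN.  Metadata (participant, run, rate) is stored in leading
``#``-comment lines so a recording file is self-describing.

*Label tracks* are CSV rows of ``start_ms,end_ms,gear`` with gear one of
G2R, G3, G2L; intervals must be disjoint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

#: Gear classes in canonical (table row) order.
GEARS: tuple[str, ...] = ("G2R", "G3", "G2L")

_SENSORS_PER_FOOT: tuple[str, ...] = (
    "BT", "1m", "5m", "H",
    "Ax", "Ay", "Az",
    "Gx", "Gy", "Gz",
    "Mx", "My", "Mz",
)

#: Canonical channel order: right foot block then left foot block.
CHANNELS: tuple[str, ...] = tuple(
    f"{foot}_{s}" for foot in ("R", "L") for s in _SENSORS_PER_FOOT
)

_CHANNEL_INDEX = {name: i for i, name in enumerate(CHANNELS)}


class FormatError(ValueError):
    """Raised when a file violates the recording/label dialect."""


def canonical_sort(names: Iterable[str]) -> list[str]:
    """Sort channel names into canonical order; unknown names raise."""
    names = list(names)
    for n in names:
        if n not in _CHANNEL_INDEX:
            raise FormatError(f"unknown channel name: {n!r}")
    return sorted(names, key=_CHANNEL_INDEX.__getitem__)


@dataclass
class Recording:
    """A per-foot multichannel time series at a fixed sampling rate.

    ``samples`` is a float array of shape (n_ticks, n_channels); NaN marks a
    missing cell awaiting the cleaning stage.
    """

    participant_id: str
    run_id: str
    channels: list[str]
    samples: np.ndarray
    rate_hz: float = 100.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (time x channels) array")
        if self.samples.shape[1] != len(self.channels):
            raise ValueError(
                f"{len(self.channels)} channel names but "
                f"{self.samples.shape[1]} sample columns"
            )
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")
        if len(set(self.channels)) != len(self.channels):
            raise FormatError("duplicate channel names")
        for name in self.channels:
            if name not in _CHANNEL_INDEX:
                raise FormatError(f"unknown channel name: {name!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_ms(self) -> float:
        return self.n_samples * 1000.0 / self.rate_hz

    @property
    def time_ms(self) -> np.ndarray:
        step = 1000.0 / self.rate_hz
        return np.round(np.arange(self.n_samples) * step).astype(int)

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as a 1-D view."""
        return self.samples[:, self.channels.index(name)]

    def with_samples(self, samples: np.ndarray) -> "Recording":
        return Recording(
            participant_id=self.participant_id,
            run_id=self.run_id,
            channels=list(self.channels),
            samples=samples,
            rate_hz=self.rate_hz,
        )


@dataclass
class LabelTrack:
    """Non-overlapping, sorted gear intervals ``(start_ms, end_ms, gear)``."""

    intervals: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ivs = [(int(s), int(e), str(g)) for s, e, g in self.intervals]
        for s, e, g in ivs:
            if s >= e:
                raise ValueError(f"interval start {s} must precede end {e}")
            if g not in GEARS:
                raise ValueError(f"unknown gear token: {g!r}")
        ivs.sort(key=lambda iv: iv[0])
        for (s0, e0, _), (s1, _, _) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise ValueError(
                    f"overlapping intervals: [{s0}, {e0}) and starting {s1}"
                )
        self.intervals = ivs

    def __len__(self) -> int:
        return len(self.intervals)

    def gear_at(self, start_ms: float, end_ms: float) -> str | None:
        """Gear of the interval fully containing [start_ms, end_ms], else None."""
        for s, e, g in self.intervals:
            if s <= start_ms and end_ms <= e:
                return g
        return None


@dataclass
class EvalReport:
    """Confusion matrix plus per-class metrics, WAA, and a learning curve.

    ``confusion`` rows are true gears, columns predicted, in GEARS order.
    ``history`` entries are ``(epoch, elapsed_s, waa)``.
    """

    confusion: np.ndarray
    per_class: dict[str, dict[str, float]]
    waa: float
    history: list[tuple[int, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=float)
        if self.confusion.shape != (len(GEARS), len(GEARS)):
            raise ValueError("confusion must be 3x3 in gear order")
        if (self.confusion < 0).any():
            raise ValueError("confusion entries must be non-negative")
        if not (0.0 <= self.waa <= 1.0):
            raise ValueError("waa must lie in [0, 1]")
        row_sums = self.confusion.sum(axis=1)
        for i, gear in enumerate(GEARS):
            support = self.per_class[gear]["support"]
            if abs(support - row_sums[i]) > 1e-6:
                raise ValueError(
                    f"support for {gear} ({support}) != confusion row sum "
                    f"({row_sums[i]})"
                )

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "class_order": list(GEARS),
            "per_class": self.per_class,
            "waa": self.waa,
            "history": [list(h) for h in self.history],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvalReport":
        return cls(
            confusion=np.asarray(d["confusion"], dtype=float),
            per_class={g: dict(m) for g, m in d["per_class"].items()},
            waa=float(d["waa"]),
            history=[tuple(h) for h in d.get("history", [])],
        )

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load_json(cls, path: str | Path) -> "EvalReport":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# recording CSV


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a Recording to CSV (values kept to >=6 significant digits)."""
    path = Path(path)
    lines = [
        f"# participant_id: {rec.participant_id}",
        f"# run_id: {rec.run_id}",
        f"# rate_hz: {rec.rate_hz:g}",
        "time_ms," + ",".join(rec.channels),
    ]
    times = rec.time_ms
    for i in range(rec.n_samples):
        cells = [str(times[i])]
        for v in rec.samples[i]:
            cells.append("" if np.isnan(v) else format(v, ".8g"))
        lines.append(",".join(cells))
    path.write_text("\n".join(lines) + "\n")


def read_recording(path: str | Path) -> Recording:
    """Read a Recording CSV written by :func:`write_recording`.

    Blank cells become NaN missing markers.  Unknown channel names and
    missing or non-monotone time columns are format errors.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[list[str]] = []
    with path.open() as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, val = body.split(":", 1)
                    meta[key.strip()] = val.strip()
                continue
            if header is None:
                header = [c.strip() for c in line.split(",")]
            else:
                rows.append(line.split(","))
    if header is None:
        raise FormatError(f"{path}: no header row")
    if not header or header[0] != "time_ms":
        raise FormatError(f"{path}: first column must be time_ms")
    channels = header[1:]
    if not channels:
        raise FormatError(f"{path}: no channel columns")
    for name in channels:
        if name not in _CHANNEL_INDEX:
            raise FormatError(f"{path}: unknown channel name {name!r}")
    if len(set(channels)) != len(channels):
        raise FormatError(f"{path}: duplicate channel names")

    n = len(rows)
    samples = np.full((n, len(channels)), np.nan)
    times = np.empty(n)
    for i, cells in enumerate(rows):
        if len(cells) != len(header):
            raise FormatError(f"{path}: row {i} has {len(cells)} cells, "
                              f"expected {len(header)}")
        t = cells[0].strip()
        if not t:
            raise FormatError(f"{path}: row {i} missing time_ms")
        times[i] = float(t)
        for j, cell in enumerate(cells[1:]):
            cell = cell.strip()
            if cell:
                samples[i, j] = float(cell)
    if n > 1 and not (np.diff(times) > 0).all():
        raise FormatError(f"{path}: time_ms column is not strictly increasing")

    return Recording(
        participant_id=meta.get("participant_id", path.stem),
        run_id=meta.get("run_id", "0"),
        channels=channels,
        samples=samples,
        rate_hz=float(meta.get("rate_hz", 100.0)),
    )


# ---------------------------------------------------------------------------
# label CSV


def write_labels(track: LabelTrack, path: str | Path) -> None:
    lines = ["start_ms,end_ms,gear"]
    lines += [f"{s},{e},{g}" for s, e, g in track.intervals]
    Path(path).write_text("\n".join(lines) + "\n")


def read_labels(path: str | Path) -> LabelTrack:
    path = Path(path)
    lines = [l for l in path.read_text().splitlines() if l.strip()]
    if not lines or lines[0].replace(" ", "") != "start_ms,end_ms,gear":
        raise FormatError(f"{path}: expected header 'start_ms,end_ms,gear'")
    intervals = []
    for i, line in enumerate(lines[1:]):
        cells = [c.strip() for c in line.split(",")]
        if len(cells) != 3:
            raise FormatError(f"{path}: row {i} must have 3 cells")
        try:
            start, end = int(cells[0]), int(cells[1])
        except ValueError as exc:
            raise FormatError(f"{path}: row {i}: {exc}") from exc
        intervals.append((start, end, cells[2]))
    return LabelTrack(intervals=intervals)
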
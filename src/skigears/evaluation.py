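"""Metrics, participant-grouped cross-validation, and the sensor ablation grid.

WAA (weighted average accuracy) is the support-weighted mean of per-class
recall, which is identically the confusion-matrix trace over the total
count; the same support weighting applied to precision or F1 gives the
weighted summary rows of a classification report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from skigears.io_formats import GEARS, EvalReport
from skigears.preprocessing import WindowSet, apply_norm, fit_norm
from skigears.sensor_configs import (
    INERTIAL_SUBSETS,
    PRESSURE_SUBSETS,
    SensorConfig,
    channels_for,
    enumerate_configs,
)
from skigears.gear_model import GearModel, ModelSpec, TrainSpec, build_model, predict, train

logger = logging.getLogger(__name__)

NOT_REACHED = None  # sentinel returned by time_to_threshold


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding as used for table display."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def confusion(y_true: Sequence[str], y_pred: Sequence[str],
              classes: Sequence[str] = GEARS) -> np.ndarray:
    """Count matrix, rows true / columns predicted, in ``classes`` order."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    index = {c: i for i, c in enumerate(classes)}
    out = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValueError(f"unknown label in pair ({t!r}, {p!r})")
        out[index[t], index[p]] += 1
    return out


def class_report(conf: np.ndarray, classes: Sequence[str] = GEARS
                 ) -> dict[str, dict[str, float]]:
    """Per-class precision/recall/F1/support from a confusion matrix.

    Division by zero (a class never predicted, or with no support) yields
    0 with a logged warning.
    """
    conf = np.asarray(conf, dtype=float)
    if conf.ndim != 2 or conf.shape[0] != conf.shape[1]:
        raise ValueError("confusion matrix must be square")
    if conf.shape[0] != len(classes):
        raise ValueError("class list must match confusion dimensions")
    report = {}
    for i, cls in enumerate(classes):
        col = conf[:, i].sum()
        row = conf[i, :].sum()
        tp = conf[i, i]
        if col == 0 or row == 0:
            logger.warning("zero division computing metrics for class %s", cls)
        precision = tp / col if col > 0 else 0.0
        recall = tp / row if row > 0 else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall > 0 else 0.0)
        report[cls] = {
            "precision": float(precision),
            "recall": float(recall),
            "f1": float(f1),
            "support": float(row),
        }
    return report


def weighted_average(values: Sequence[float], supports: Sequence[float]) -> float:
    """Support-weighted mean: sum(v_c * s_c) / sum(s_c)."""
    values = np.asarray(values, dtype=float)
    supports = np.asarray(supports, dtype=float)
    if values.shape != supports.shape:
        raise ValueError("values and supports must have equal length")
    total = supports.sum()
    if total <= 0:
        raise ValueError("total support must be positive")
    return float((values * supports).sum() / total)


def report_from_predictions(y_true: Sequence[str], y_pred: Sequence[str],
                            history: list[tuple] | None = None) -> EvalReport:
    conf = confusion(y_true, y_pred)
    per_class = class_report(conf)
    recalls = [per_class[g]["recall"] for g in GEARS]
    supports = [per_class[g]["support"] for g in GEARS]
    return EvalReport(confusion=conf, per_class=per_class,
                      waa=weighted_average(recalls, supports),
                      history=history or [])


def mean_report(reports: Sequence[EvalReport]) -> EvalReport:
    """Average fold reports (confusion, metrics, WAA, common-prefix history)."""
    if not reports:
        raise ValueError("no reports to average")
    conf = np.mean([r.confusion for r in reports], axis=0)
    per_class = {
        g: {k: float(np.mean([r.per_class[g][k] for r in reports]))
            for k in ("precision", "recall", "f1", "support")}
        for g in GEARS
    }
    waa = float(np.mean([r.waa for r in reports]))
    n_hist = min((len(r.history) for r in reports), default=0)
    history = []
    for i in range(n_hist):
        epoch = reports[0].history[i][0]
        elapsed = float(np.mean([r.history[i][1] for r in reports]))
        h_waa = float(np.mean([r.history[i][2] for r in reports]))
        history.append((epoch, elapsed, h_waa))
    return EvalReport(confusion=conf, per_class=per_class, waa=waa, history=history)


# ---------------------------------------------------------------------------
# cross-validation


def participant_folds(participants: Sequence[str], k: int = 2,
                      seed: int = 0) -> list[list[str]]:
    """Deterministic participant-exclusive, near-balanced fold assignment."""
    participants = sorted(set(participants))
    if len(participants) < k:
        raise ValueError(f"need at least {k} participants, got {len(participants)}")
    rng = np.random.default_rng(seed)
    order = [participants[i] for i in rng.permutation(len(participants))]
    folds: list[list[str]] = [[] for _ in range(k)]
    for i, pid in enumerate(order):
        folds[i % k].append(pid)
    return [sorted(f) for f in folds]


@dataclass
class CVResult:
    """Cross-validation outcome: averaged report plus per-fold detail."""

    mean: EvalReport
    folds: list[EvalReport]
    fold_participants: list[list[str]]
    config_name: str
    seconds_per_epoch: float


def cross_validate(
    windows: WindowSet,
    config: SensorConfig,
    model_spec: ModelSpec = ModelSpec(),
    tspec: TrainSpec = TrainSpec(),
    k: int = 2,
    seed: int = 0,
) -> CVResult:
    """Participant-grouped k-fold CV of one sensor configuration.

    Each fold's normalization statistics are fit on its training windows
    only; the held-out fold serves as the validation set for early
    stopping and reporting.
    """
    channels = channels_for(config)
    sub = windows.select_channels(channels)
    folds = participant_folds(list(windows.groups), k=k, seed=seed)

    fold_reports: list[EvalReport] = []
    epoch_seconds: list[float] = []
    for i, test_pids in enumerate(folds):
        test_mask = np.isin(sub.groups, test_pids)
        train_ws = sub.subset(~test_mask)
        test_ws = sub.subset(test_mask)
        if len(train_ws) == 0 or len(test_ws) == 0:
            raise ValueError(f"fold {i} has an empty split")
        stats = fit_norm(train_ws)
        train_n = apply_norm(train_ws, stats)
        test_n = apply_norm(test_ws, stats)
        model = build_model(sub.steps, len(channels), model_spec,
                            seed=tspec.seed + i)
        model, history = train(model, train_n, test_n, tspec)
        _, pred = predict(model, test_n)
        hist = [(h["epoch"], h["elapsed_s"], h["val_waa"]) for h in history]
        fold_reports.append(report_from_predictions(test_n.labels, pred, hist))
        if history:
            epoch_seconds.append(history[-1]["elapsed_s"] / len(history))

    return CVResult(
        mean=mean_report(fold_reports),
        folds=fold_reports,
        fold_participants=folds,
        config_name=config.name,
        seconds_per_epoch=float(np.mean(epoch_seconds)) if epoch_seconds else 0.0,
    )


def time_to_threshold(history: Sequence, threshold: float = 0.90):
    """First epoch whose validation WAA exceeds ``threshold``.

    Accepts history entries as dicts (``epoch``/``elapsed_s``/``val_waa``),
    ``(epoch, waa)`` pairs, or ``(epoch, elapsed_s, waa)`` triples.
    Returns ``(epoch, elapsed_s)`` (elapsed may be None when the history
    carries no timing), or ``NOT_REACHED`` if the threshold is never beaten.
    """
    if len(history) == 0:
        raise ValueError("history must be non-empty")
    for entry in history:
        if isinstance(entry, dict):
            epoch, elapsed, waa = entry["epoch"], entry.get("elapsed_s"), entry["val_waa"]
        elif len(entry) == 2:
            epoch, waa = entry
            elapsed = None
        else:
            epoch, elapsed, waa = entry[0], entry[1], entry[-1]
        if waa > threshold:
            return (epoch, elapsed)
    return NOT_REACHED


# ---------------------------------------------------------------------------
# ablation


_PRESSURE_ROW_NAMES = ["0P", "2P.1m5m", "2P.1mH", "2P.5mH", "3P.1m5mH", "4P"]
_INERTIAL_COL_NAMES = ["None", "A", "AG", "AGM"]


@dataclass
class AblationGrid:
    """Mean-WAA grid: rows pressure subsets, columns inertial subsets."""

    waa: pd.DataFrame
    seconds_per_epoch: pd.DataFrame
    results: dict[str, CVResult] = field(default_factory=dict)

    @staticmethod
    def empty() -> "AblationGrid":
        frame = pd.DataFrame(np.nan, index=_PRESSURE_ROW_NAMES,
                             columns=_INERTIAL_COL_NAMES)
        return AblationGrid(waa=frame.copy(), seconds_per_epoch=frame.copy())

    def set(self, config: SensorConfig, result: CVResult) -> None:
        row = config.pressure_name
        col = config.inertial_name or "None"
        self.waa.loc[row, col] = result.mean.waa
        self.seconds_per_epoch.loc[row, col] = result.seconds_per_epoch
        self.results[config.name] = result

    @property
    def n_populated(self) -> int:
        return int(self.waa.notna().sum().sum())

    def to_csv(self, path: str | Path) -> None:
        self.waa.to_csv(path, index_label="pressure")

    def cell(self, config: SensorConfig) -> float:
        return float(self.waa.loc[config.pressure_name,
                                  config.inertial_name or "None"])


class AblationError(RuntimeError):
    """A config failed mid-grid; carries the partial grid built so far."""

    def __init__(self, message: str, partial: AblationGrid) -> None:
        super().__init__(message)
        self.partial = partial


def run_ablation(
    windows: WindowSet,
    configs: Sequence[SensorConfig] | None = None,
    model_spec: ModelSpec = ModelSpec(),
    tspec: TrainSpec = TrainSpec(),
    k: int = 2,
    seed: int = 0,
    dump_path: str | Path | None = None,
) -> AblationGrid:
    """Cross-validate every configuration (default: all 23) into a grid.

    A failing configuration aborts with :class:`AblationError` carrying the
    partial grid (also dumped to ``dump_path`` when given).
    """
    if configs is None:
        configs = enumerate_configs()
    grid = AblationGrid.empty()
    for config in configs:
        try:
            result = cross_validate(windows, config, model_spec, tspec,
                                    k=k, seed=seed)
        except Exception as exc:
            if dump_path is not None:
                grid.to_csv(dump_path)
            raise AblationError(
                f"configuration {config.name} failed: {exc}", grid) from exc
        grid.set(config, result)
        logger.info("config %-16s mean WAA %.4f", config.name, result.mean.waa)
    return grid
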
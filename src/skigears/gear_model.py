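"""CNN-LSTM gear classifier.

Architecture: four Conv1D layers (16/32/64/128 filters, kernels
alternating 2 and 3, ReLU, dropout 0.25 after conv-2 and conv-4) feeding
two stacked LSTMs (256 units each, the first sequence-returning), dropout
0.25, then dense 2048 -> 1024 (ReLU) and a 3-way softmax.  Trained with
categorical cross-entropy and RMSprop, batch size 64, early stopping on
validation loss with best-weight restoration.

The default widths match the reference architecture; for quick CPU runs
pass a slimmer :class:`ModelSpec` (same layer sequence, fewer units).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from skigears import _nn
from skigears.io_formats import GEARS
from skigears.preprocessing import WindowSet

_CLASS_INDEX = {g: i for i, g in enumerate(GEARS)}


@dataclass(frozen=True)
class ModelSpec:
    """Layer widths of the CNN-LSTM."""

    conv_filters: tuple[int, ...] = (16, 32, 64, 128)
    kernel_sizes: tuple[int, ...] = (2, 3, 2, 3)
    dropout: float = 0.25
    lstm_units: tuple[int, ...] = (256, 256)
    dense_units: tuple[int, ...] = (2048, 1024)
    n_classes: int = 3

    def __post_init__(self) -> None:
        if len(self.conv_filters) != len(self.kernel_sizes):
            raise ValueError("one kernel size per conv layer required")
        if len(self.lstm_units) < 1:
            raise ValueError("at least one LSTM layer required")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


def reduced_spec() -> ModelSpec:
    """A slim spec with the same layer sequence, sized for CPU-only runs."""
    return ModelSpec(conv_filters=(8, 8, 16, 16), kernel_sizes=(2, 3, 2, 3),
                     lstm_units=(24, 24), dense_units=(64, 32))


@dataclass
class TrainSpec:
    """Training protocol knobs."""

    epochs: int = 50
    batch_size: int = 64
    learning_rate: float = 1e-3
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class GearModel:
    """A built network plus the input contract it was compiled for."""

    net: _nn.Sequential
    spec: ModelSpec
    steps: int
    n_channels: int
    channel_names: list[str] | None = None


def build_model(steps: int, n_channels: int, spec: ModelSpec = ModelSpec(),
                seed: int = 0) -> GearModel:
    """Assemble the CNN-LSTM for inputs of shape (steps, n_channels)."""
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if steps < max(4, max(spec.kernel_sizes)):
        raise ValueError(f"steps={steps} too short for the conv receptive field")
    rng = np.random.default_rng(seed)
    layers: list[_nn.Layer] = []
    n_in = n_channels
    for idx, (filters, kernel) in enumerate(zip(spec.conv_filters, spec.kernel_sizes)):
        layers.append(_nn.Conv1D(n_in, filters, kernel, rng))
        layers.append(_nn.ReLU())
        if idx % 2 == 1:  # after conv-2 and conv-4
            layers.append(_nn.Dropout(spec.dropout))
        n_in = filters
    for i, units in enumerate(spec.lstm_units):
        last = i == len(spec.lstm_units) - 1
        layers.append(_nn.LSTM(n_in, units, return_sequences=not last, rng=rng))
        n_in = units
    layers.append(_nn.Dropout(spec.dropout))
    for units in spec.dense_units:
        layers.append(_nn.Dense(n_in, units, rng))
        layers.append(_nn.ReLU())
        n_in = units
    layers.append(_nn.Dense(n_in, spec.n_classes, rng))  # logits; softmax in loss
    return GearModel(net=_nn.Sequential(layers), spec=spec, steps=steps,
                     n_channels=n_channels)


def _check_channels(model: GearModel, ws: WindowSet) -> None:
    if ws.tensor.shape[2] != model.n_channels:
        raise ValueError(
            f"WindowSet has {ws.tensor.shape[2]} channels, model expects "
            f"{model.n_channels}")
    if model.channel_names is not None and list(ws.channel_names) != list(
            model.channel_names):
        raise ValueError("channel names differ from the model's training set")


def _onehot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    idx = np.array([_CLASS_INDEX[l] for l in labels])
    out = np.zeros((len(idx), n_classes))
    out[np.arange(len(idx)), idx] = 1.0
    return out


def predict(model: GearModel, ws: WindowSet, batch_size: int = 256
            ) -> tuple[np.ndarray, np.ndarray]:
    """Per-window class probabilities and argmax gear labels.

    Deterministic; ties broken toward the earlier class in canonical order.
    """
    _check_channels(model, ws)
    x = ws.tensor.astype(np.float64)
    probs = np.empty((len(ws), model.spec.n_classes))
    for i in range(0, len(ws), batch_size):
        logits = model.net.forward(x[i:i + batch_size], train=False)
        probs[i:i + batch_size] = _nn.softmax(logits)
    labels = np.array([GEARS[j] for j in probs.argmax(axis=1)], dtype=object)
    return probs, labels


def _evaluate(model: GearModel, ws: WindowSet) -> tuple[float, float]:
    """(cross-entropy loss, WAA) on a WindowSet."""
    probs, pred = predict(model, ws)
    onehot = _onehot(ws.labels, model.spec.n_classes)
    eps = 1e-12
    loss = -float((onehot * np.log(probs + eps)).sum() / len(ws))
    waa = float((pred == ws.labels).mean())
    return loss, waa


def train(model: GearModel, train_ws: WindowSet, val_ws: WindowSet,
          tspec: TrainSpec = TrainSpec(), verbose: bool = False
          ) -> tuple[GearModel, list[dict]]:
    """Train in place; returns the model and a per-epoch history.

    History entries carry epoch (1-based), cumulative elapsed seconds,
    training loss, validation loss, and validation WAA.  Early stopping
    watches validation loss with ``tspec.patience`` and restores the best
    weights.
    """
    _check_channels(model, train_ws)
    _check_channels(model, val_ws)
    if list(train_ws.channel_names) != list(val_ws.channel_names):
        raise ValueError("train and validation channel sets differ")
    present = set(train_ws.labels)
    missing = [g for g in GEARS if g not in present]
    if missing:
        raise ValueError(f"classes absent from training labels: {missing}")

    model.channel_names = list(train_ws.channel_names)
    rng = np.random.default_rng(tspec.seed)
    x = train_ws.tensor.astype(np.float64)
    y = _onehot(train_ws.labels, model.spec.n_classes)
    opt = _nn.RMSprop(model.net.params, lr=tspec.learning_rate)

    history: list[dict] = []
    best_loss = np.inf
    best_weights = model.net.get_weights()
    best_epoch = 0
    bad_epochs = 0
    t0 = time.perf_counter()
    n = len(train_ws)
    for epoch in range(1, tspec.epochs + 1):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, tspec.batch_size):
            batch = order[i:i + tspec.batch_size]
            logits = model.net.forward(x[batch], train=True, rng=rng)
            loss, dlogits = _nn.softmax_cross_entropy(logits, y[batch])
            model.net.backward(dlogits)
            opt.step(model.net.grads)
            losses.append(loss)
        val_loss, val_waa = _evaluate(model, val_ws)
        entry = {
            "epoch": epoch,
            "elapsed_s": time.perf_counter() - t0,
            "train_loss": float(np.mean(losses)),
            "val_loss": val_loss,
            "val_waa": val_waa,
        }
        history.append(entry)
        if verbose:
            print(f"epoch {epoch:3d}  loss {entry['train_loss']:.4f}  "
                  f"val_loss {val_loss:.4f}  val_waa {val_waa:.4f}")
        if val_loss < best_loss - 1e-9:
            best_loss = val_loss
            best_weights = model.net.get_weights()
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= tspec.patience:
                break
    model.net.set_weights(best_weights)
    for entry in history:
        entry["best"] = entry["epoch"] == best_epoch
    return model, history
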
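"""Dataset-level plumbing: manifest loading and whole-dataset preprocessing."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from skigears.io_formats import LabelTrack, Recording, read_labels, read_recording
from skigears.preprocessing import PreprocessParams, WindowSet, preprocess_recording


def load_manifest(data_dir: str | Path) -> dict:
    data_dir = Path(data_dir)
    path = data_dir / "manifest.json" if data_dir.is_dir() else data_dir
    return json.loads(path.read_text())


def load_dataset(data_dir: str | Path) -> list[tuple[Recording, LabelTrack]]:
    """Load every (recording, labels) pair listed in a dataset manifest."""
    data_dir = Path(data_dir)
    manifest = load_manifest(data_dir)
    root = data_dir if data_dir.is_dir() else data_dir.parent
    pairs = []
    for entry in manifest["entries"]:
        rec = read_recording(root / entry["recording"])
        track = read_labels(root / entry["labels"])
        pairs.append((rec, track))
    return pairs


def preprocess_dataset(
    data_dir: str | Path,
    params: PreprocessParams = PreprocessParams(),
) -> WindowSet:
    """Condition and segment every run in a dataset into one WindowSet."""
    sets = [preprocess_recording(rec, track, params)
            for rec, track in load_dataset(data_dir)]
    return WindowSet.concatenate(sets)


def save_windows(ws: WindowSet, path: str | Path) -> None:
    """Persist a WindowSet as NPZ plus a JSON sidecar of its parameters."""
    path = Path(path)
    np.savez_compressed(path, tensor=ws.tensor,
                        labels=np.array(ws.labels, dtype=str),
                        groups=np.array(ws.groups, dtype=str))
    sidecar = {
        "channel_names": list(ws.channel_names),
        "window_ms": ws.window_ms,
        "stride_ms": ws.stride_ms,
        "subframe_ms": ws.subframe_ms,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def load_windows(path: str | Path) -> WindowSet:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    with np.load(path) as data:
        tensor = data["tensor"]
        labels = data["labels"].astype(object)
        groups = data["groups"].astype(object)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return WindowSet(tensor=tensor, labels=labels, groups=groups,
                     channel_names=sidecar["channel_names"],
                     window_ms=sidecar["window_ms"],
                     stride_ms=sidecar["stride_ms"],
                     subframe_ms=sidecar["subframe_ms"])
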
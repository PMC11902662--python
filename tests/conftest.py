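import numpy as np
import pytest

from skigears import SimulationParams, make_dataset
from skigears.pipeline import preprocess_dataset
from skigears.preprocessing import PreprocessParams, WindowSet


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_windowset(labels, groups, steps=10, n_channels=4, seed=0,
                   channel_names=None, shift_by_class=1.0):
    """A small random WindowSet whose classes are linearly separable by a
    per-class mean shift."""
    r = np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=object)
    class_ids = {"G2R": 0, "G3": 1, "G2L": 2}
    tensor = r.normal(size=(len(labels), steps, n_channels))
    for i, lab in enumerate(labels):
        tensor[i] += shift_by_class * class_ids[lab]
    if channel_names is None:
        channel_names = ["R_BT", "R_1m", "R_5m", "R_H"][:n_channels]
    return WindowSet(
        tensor=tensor,
        labels=labels,
        groups=np.asarray(groups, dtype=object),
        channel_names=channel_names,
        window_ms=steps * 50,
        stride_ms=50,
        subframe_ms=50,
    )


@pytest.fixture(scope="session")
def small_dataset_dir(tmp_path_factory):
    """2 participants x 3 gears x 1 run of 20 s — shared across model and
    evaluation tests to amortize simulation cost."""
    out = tmp_path_factory.mktemp("data") / "ds"
    make_dataset(2, ["G2R", "G3", "G2L"], 1, 20000, seed=7, out_dir=out)
    return out


@pytest.fixture(scope="session")
def small_windows(small_dataset_dir):
    return preprocess_dataset(small_dataset_dir, PreprocessParams(stride_ms=500))
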
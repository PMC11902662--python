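# skigears

Classification of cross-country skating gears (G2R, G3, G2L) from
instrumented-insole signals: a synthetic signal simulator, the full
preprocessing/segmentation chain, a CNN-LSTM classifier, and a
participant-grouped evaluation harness with a 23-configuration
sensor-ablation grid.

Recordings are per-foot multichannel time series at 100 Hz with 26
canonical channels (per foot: big-toe / first-metatarsal /
fifth-metatarsal / heel pressure in kg/cm², plus 3-axis accelerometer,
gyroscope, and magnetometer). Sensor configurations pair one of six
pressure subsets with one of the nested inertial subsets (none / A / AG /
AGM), giving 23 named combinations such as `2P.1m5m + AG` or `4P`.

The neural network (Conv1D ×4 → LSTM ×2 → dense ×2 → softmax) is
implemented in pure NumPy (`skigears._nn`) with backpropagation and
RMSprop, so the package has no deep-learning framework dependency and runs
on a single CPU.

## CLI

Every command takes a YAML config plus `--seed` and `--out-dir`;
`--verbose` routes diagnostics to stderr.

```bash
# 1. generate a labeled synthetic dataset (CSV recordings + label tracks)
skigears simulate --config sim.yaml --seed 42 --out-dir data/

# 2. condition + segment into a window tensor bundle (NPZ + JSON sidecar)
skigears preprocess --data-dir data/ --out-dir prep/

# 3. cross-validate one sensor configuration
skigears evaluate --windows prep/windows.npz --sensor-config "4P + AGM" \
    --seed 42 --out-dir results/

# 4. the full 23-configuration ablation grid
skigears ablate --windows prep/windows.npz --all-23 --out-dir results/
```

Example `sim.yaml`:

```yaml
n_participants: 4
gears: [G2R, G3, G2L]
runs_per_gear: 3
run_ms: 60000
```

Model/training sizes are configurable, e.g.

```yaml
model: {preset: reduced}        # slim CPU-sized network, same layer sequence
training: {epochs: 15, patience: 5}
```

## Package layout

| module | contents |
|---|---|
| `skigears.io_formats` | `Recording`/`LabelTrack`/`EvalReport` types, CSV/JSON readers and writers |
| `skigears.sensor_configs` | the 23 sensor combinations: enumeration, name parsing, channel resolution |
| `skigears.synthetic_data` | gear-morphology signal simulator, mirror symmetry, dataset builder |
| `skigears.preprocessing` | offset removal, cleaning, EMA smoothing, windowed segmentation, normalization |
| `skigears.gear_model` | CNN-LSTM builder, training loop (early stopping, best-weight restore), prediction |
| `skigears.evaluation` | confusion/report/WAA metrics, participant-grouped CV, ablation grid |
| `skigears._nn` | minimal NumPy layers/optimizer backing the model |
| `skigears.pipeline` | dataset-level manifest loading and batch preprocessing |
| `skigears.cli` | `skigears simulate|preprocess|train|evaluate|ablate` |
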
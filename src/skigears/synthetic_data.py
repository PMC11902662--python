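"""Synthetic instrumented-insole recordings with gear-specific morphology.

Each simulated gait cycle alternates a contact and a non-contact phase per
foot (feet half a cycle out of phase).  Within the contact phase the four
pressure sensors fire as raised-cosine bumps with staggered onsets — heel
first, then first metatarsal and big toe, finally the fifth metatarsal —
so pressure flows heel -> forefoot -> lateral push-off.  Asymmetric gears
load one side harder: in G2R the left-foot pressure (and gyroscope burst)
is scaled by the ``asymmetry`` factor, G2L is the exact mirror image, and
G3 is symmetric.  IMU channels are phase-locked sinusoids at the cycle
frequency plus a propulsion-phase gyroscope burst; the magnetometer drifts
slowly and carries the least gear information.  Additive Gaussian noise,
constant per-sensor pressure offsets, and optional missing cells complete
the raw-signal morphology.

G2L generation is *defined* as ``mirror(G2R)`` at equal seed, so the
mirror symmetry holds exactly, channel for channel.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from skigears.io_formats import (
    CHANNELS,
    GEARS,
    LabelTrack,
    Recording,
    write_labels,
    write_recording,
)

#: Channels whose sign flips under a left/right mirror (lateral axis and the
#: roll/yaw rotation senses).
LATERAL_CHANNELS: tuple[str, ...] = ("Ay", "Gx", "Gz", "My")

#: Relative peak scale of each pressure sensor within a contact bump.
_PRESSURE_SCALE = {"H": 1.0, "1m": 0.9, "BT": 0.7, "5m": 0.8}


def _default_onset_lags() -> dict[str, float]:
    # heel strikes first, forefoot next, fifth metatarsal last
    return {"H": 0.0, "1m": 60.0, "BT": 80.0, "5m": 180.0}


def _default_noise_sd() -> dict[str, float]:
    return {"pressure": 0.02, "accel": 0.05, "gyro": 2.0, "mag": 0.02}


def _default_offsets() -> dict[str, float]:
    return {"BT": 0.05, "1m": 0.05, "5m": 0.05, "H": 0.05}


@dataclass
class SimulationParams:
    """Waveform parameters for one simulated run."""

    gear: str = "G2R"
    cycle_ms: int = 1400
    duty: float = 0.55
    peak_pressure_kg_cm2: float = 2.0
    asymmetry: float = 1.3
    onset_lags_ms: dict[str, float] = field(default_factory=_default_onset_lags)
    noise_sd: dict[str, float] = field(default_factory=_default_noise_sd)
    offset: dict[str, float] = field(default_factory=_default_offsets)
    missing_rate: float = 0.0
    rate_hz: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gear not in GEARS:
            raise ValueError(f"unknown gear: {self.gear!r}")
        if not 0.0 < self.duty < 1.0:
            raise ValueError("duty must lie in (0, 1)")
        if self.asymmetry < 1.0:
            raise ValueError("asymmetry must be >= 1")
        if any(v < 0 for v in self.noise_sd.values()):
            raise ValueError("noise_sd values must be >= 0")
        if any(v < 0 for v in self.offset.values()):
            raise ValueError("pressure offsets must be >= 0")
        lags = self.onset_lags_ms
        if not lags["H"] <= lags["1m"] <= lags["5m"]:
            raise ValueError("onset lag order must satisfy H <= 1m <= 5m")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


def _bump(phase: np.ndarray, start: float, width: float) -> np.ndarray:
    """Raised-cosine bump over [start, start+width) of the unit cycle phase."""
    u = (phase - start) % 1.0
    inside = u < width
    out = np.zeros_like(phase)
    out[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * u[inside] / width))
    return out


def contact_mask(params: SimulationParams, n: int, foot: str) -> np.ndarray:
    """Boolean mask of ticks where ``foot`` ('R' or 'L') is in contact."""
    t_ms = np.arange(n) * 1000.0 / params.rate_hz
    phase = (t_ms / params.cycle_ms + (0.5 if foot == "L" else 0.0)) % 1.0
    return phase < params.duty


def simulate_recording(
    params: SimulationParams,
    duration_ms: int,
    participant_id: str = "S01",
    run_id: str = "r1",
) -> tuple[Recording, LabelTrack]:
    """Simulate one labeled single-gear run of ``duration_ms``.

    Returns a full 26-channel Recording and a LabelTrack covering the whole
    duration with the configured gear.
    """
    if duration_ms < params.cycle_ms:
        raise ValueError("duration_ms must cover at least one cycle")

    if params.gear == "G2L":
        base = replace(params, gear="G2R")
        rec, _ = simulate_recording(base, duration_ms, participant_id, run_id)
        track = LabelTrack([(0, int(duration_ms), "G2L")])
        return mirror(rec), track

    rng = np.random.default_rng(params.seed)
    n = int(round(duration_ms * params.rate_hz / 1000.0))
    t_s = np.arange(n) / params.rate_hz
    f_cyc = 1000.0 / params.cycle_ms  # cycle frequency, Hz

    # side loading: G2R loads the left ski harder; G3 is symmetric
    side_gain = {"R": 1.0, "L": params.asymmetry if params.gear == "G2R" else 1.0}
    # small gear-dependent phase shifts the magnetometer baseline
    mag_phase = {"G2R": 0.0, "G3": 2.0}[params.gear]

    duty_ms = params.duty * params.cycle_ms
    data = np.zeros((n, len(CHANNELS)))
    cols = {name: i for i, name in enumerate(CHANNELS)}

    for foot in ("R", "L"):
        foot_shift = 0.5 if foot == "L" else 0.0
        phase = (t_s * f_cyc + foot_shift) % 1.0
        gain = side_gain[foot]

        # --- pressure: staggered raised-cosine bumps inside the contact phase
        for sensor in ("BT", "1m", "5m", "H"):
            lag = params.onset_lags_ms[sensor] / params.cycle_ms
            width = params.duty - lag
            if width <= 0:
                raise ValueError(f"onset lag of {sensor} exceeds the contact phase")
            amp = params.peak_pressure_kg_cm2 * _PRESSURE_SCALE[sensor] * gain
            sig = amp * _bump(phase, lag, width) + params.offset[sensor]
            sig = sig + rng.normal(0.0, params.noise_sd["pressure"], n)
            data[:, cols[f"{foot}_{sensor}"]] = np.clip(sig, 0.0, None)

        # --- accelerometer (g): cycle-locked oscillation, gravity on Z
        w = 2.0 * np.pi * (t_s * f_cyc + foot_shift)
        sgn = 1.0 if foot == "R" else -1.0  # lateral axes oppose across feet
        amp_a = 0.4 * gain
        data[:, cols[f"{foot}_Ax"]] = amp_a * np.sin(w) + rng.normal(
            0.0, params.noise_sd["accel"], n)
        data[:, cols[f"{foot}_Ay"]] = sgn * 0.6 * amp_a * np.sin(w + 1.1) + rng.normal(
            0.0, params.noise_sd["accel"], n)
        data[:, cols[f"{foot}_Az"]] = 1.0 + amp_a * np.cos(w) + rng.normal(
            0.0, params.noise_sd["accel"], n)

        # --- gyroscope (dps): sinusoid + external-rotation burst in late contact
        burst = _bump(phase, 0.7 * params.duty, 0.35 * params.duty)
        amp_g = 40.0 * gain
        data[:, cols[f"{foot}_Gx"]] = sgn * 0.5 * amp_g * np.sin(w + 0.4) + rng.normal(
            0.0, params.noise_sd["gyro"], n)
        data[:, cols[f"{foot}_Gy"]] = 0.7 * amp_g * np.cos(w + 0.9) + rng.normal(
            0.0, params.noise_sd["gyro"], n)
        data[:, cols[f"{foot}_Gz"]] = sgn * (2.0 * amp_g * burst
                                             + 0.3 * amp_g * np.sin(w)) + rng.normal(
            0.0, params.noise_sd["gyro"], n)

        # --- magnetometer (gauss): slow orientation drift, gear-shifted phase
        slow = 2.0 * np.pi * 0.2 * t_s
        data[:, cols[f"{foot}_Mx"]] = 0.3 * np.sin(slow + mag_phase) + rng.normal(
            0.0, params.noise_sd["mag"], n)
        data[:, cols[f"{foot}_My"]] = sgn * 0.3 * np.cos(slow + mag_phase) + rng.normal(
            0.0, params.noise_sd["mag"], n)
        data[:, cols[f"{foot}_Mz"]] = 0.4 + 0.1 * np.sin(slow) + rng.normal(
            0.0, params.noise_sd["mag"], n)

    if params.missing_rate > 0.0:
        mask = rng.random(data.shape) < params.missing_rate
        data[mask] = np.nan

    rec = Recording(
        participant_id=participant_id,
        run_id=run_id,
        channels=list(CHANNELS),
        samples=data,
        rate_hz=params.rate_hz,
    )
    track = LabelTrack([(0, int(duration_ms), params.gear)])
    return rec, track


def mirror(rec: Recording) -> Recording:
    """Swap the R_/L_ channel pairs and flip lateral-axis signs.

    An involution: ``mirror(mirror(rec))`` equals ``rec`` exactly.
    """
    swapped = {}
    for name in rec.channels:
        foot, sensor = name.split("_", 1)
        other = ("L" if foot == "R" else "R") + "_" + sensor
        if other not in rec.channels:
            raise ValueError(f"cannot mirror: {name} has no partner {other}")
        swapped[other] = name

    out = np.empty_like(rec.samples)
    for j, name in enumerate(rec.channels):
        src = rec.channels.index(swapped[name])
        sensor = name.split("_", 1)[1]
        sign = -1.0 if sensor in LATERAL_CHANNELS else 1.0
        out[:, j] = sign * rec.samples[:, src]
    return rec.with_samples(out)


def make_dataset(
    n_participants: int,
    gears: list[str],
    runs_per_gear: int,
    run_ms: int,
    seed: int,
    out_dir: str | Path,
    base_params: SimulationParams | None = None,
    overwrite: bool = False,
) -> dict:
    """Write a multi-participant dataset of recording/label CSV pairs.

    Each participant gets a perturbed draw of amplitude (+-15%) and cycle
    length (+-10%) from the master seed, so participant-grouped folds see
    genuinely different signal scales.  Returns (and writes) a manifest.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    for g in gears:
        if g not in GEARS:
            raise ValueError(f"unknown gear: {g!r}")
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()):
        if not overwrite:
            raise FileExistsError(
                f"{out_dir} is not empty; pass overwrite=True to replace it"
            )
        shutil.rmtree(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    base = base_params if base_params is not None else SimulationParams()
    master = np.random.SeedSequence(seed)
    part_seqs = master.spawn(n_participants)

    entries = []
    for p_idx, p_seq in enumerate(part_seqs):
        pid = f"S{p_idx + 1:02d}"
        p_rng = np.random.default_rng(p_seq)
        amp_factor = p_rng.uniform(0.85, 1.15)
        cycle_factor = p_rng.uniform(0.90, 1.10)
        for gear in gears:
            for r_idx in range(runs_per_gear):
                run_seed = int(p_rng.integers(0, 2**31 - 1))
                params = replace(
                    base,
                    gear=gear,
                    seed=run_seed,
                    peak_pressure_kg_cm2=base.peak_pressure_kg_cm2 * amp_factor,
                    cycle_ms=int(round(base.cycle_ms * cycle_factor)),
                )
                run_id = f"{gear}_r{r_idx + 1}"
                rec, track = simulate_recording(params, run_ms, pid, run_id)
                rec_path = out_dir / f"{pid}_{run_id}.csv"
                lab_path = out_dir / f"{pid}_{run_id}_labels.csv"
                write_recording(rec, rec_path)
                write_labels(track, lab_path)
                entries.append({
                    "participant_id": pid,
                    "run_id": run_id,
                    "gear": gear,
                    "recording": rec_path.name,
                    "labels": lab_path.name,
                })

    manifest = {
        "seed": seed,
        "n_participants": n_participants,
        "gears": list(gears),
        "runs_per_gear": runs_per_gear,
        "run_ms": run_ms,
        "entries": entries,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
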
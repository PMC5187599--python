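"""Seeded synthetic foot-mounted sensor trials with ground truth.

Emulates two walking protocols with a foot-mounted IMU and heel/toe foot
switches, sampled at 200 Hz:

* stairs scenario — level bout, 6 steps ascending stairs (14 cm rise per
  step), level bout, a turn, level bout, 6 steps descending, level bout;
* ramp scenario — level bout, 8–10 steps ascending a 6-degree ramp, a
  turn, 8–10 steps descending, level bout.

Each gait cycle is stance (foot stationary, flat on its surface) followed
by swing.  The vertical foot trajectory in swing is a smooth minimum-jerk
rise/drop to the next surface plus a quartic clearance arc; vertical
velocity and acceleration are its analytic derivatives, so the
zero-velocity-update front end can be validated against exact truth.
Foot pitch blends between the surface inclinations (±grade on the ramp,
0 elsewhere) with a mode-specific toe-up/toe-down sweep during swing:
stepping up needs early strong dorsiflexion to clear the step edge,
stepping down a toe-down reach toward the lower surface.  White Gaussian
noise is added to the emitted acceleration and pitch channels; the truth
tracks stay clean.

The generator is fully deterministic in (seed, scenario, subject, trial).
Per-subject kinematic parameters (stride time, stride length, clearance,
pitch sweep magnitude) are jittered once per subject and held constant
across that subject's trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .decision import ModeLabel
from .streams import G, SensorStream, write_stream_csv

__all__ = ["ScenarioConfig", "TrialTruth", "generate_trial", "generate_study"]

_SCENARIOS = ("stairs", "ramp")


@dataclass
class ScenarioConfig:
    """Study-protocol and noise settings for the generator."""

    scenario: str = "stairs"
    fs: float = 200.0                 # Hz
    step_rise: float = 0.14           # m per stair step
    ramp_grade: float = 6.0           # degrees
    stride_time: float = 1.1          # s per gait cycle (per-subject jitter ±0.1)
    stride_length: float = 1.2        # m per gait cycle (sets ramp rise per step)
    swing_fraction: float = 0.4
    clearance: float = 0.05           # m swing arc height
    noise_accel_sd: float = 0.3       # m/s²
    noise_pitch_sd: float = 1.0       # degrees
    stand_time: float = 1.0           # s of quiet standing at either end
    n_subjects: int = 5
    n_trials: int = 3
    seed: int = 42

    def __post_init__(self) -> None:
        if self.scenario not in _SCENARIOS:
            raise ValueError(f"scenario must be one of {_SCENARIOS}")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not 0 < self.swing_fraction < 1:
            raise ValueError("swing_fraction must lie in (0, 1)")
        if self.step_rise < 0:
            raise ValueError("step_rise must be nonnegative")
        if self.noise_accel_sd < 0 or self.noise_pitch_sd < 0:
            raise ValueError("noise SDs must be nonnegative")


@dataclass
class TrialTruth:
    """Per-sample ground truth and per-step events for one generated trial."""

    v_z: np.ndarray               # m/s, exact
    theta: np.ndarray             # degrees, noise-free
    mode: np.ndarray              # int ModeLabel per sample
    stance: np.ndarray            # bool, foot stationary
    z: np.ndarray | None = None   # m, analytic foot height
    steps: list[dict] = field(default_factory=list)
    # each step: heel_strike, swing_start, next_heel_strike, mode, kind

    @property
    def stance_windows(self) -> list[tuple[int, int]]:
        padded = np.concatenate(([False], self.stance, [False])).astype(int)
        d = np.diff(padded)
        return list(zip(np.flatnonzero(d == 1).tolist(), np.flatnonzero(d == -1).tolist()))


# swing pitch sweep magnitude (degrees, +toe-up) per (scenario, step kind)
_PITCH_SWEEP = {
    ("stairs", "level"): 12.0,
    ("stairs", "ascend"): 30.0,
    ("stairs", "descend"): -25.0,
    ("stairs", "turn"): 8.0,
    ("ramp", "level"): 12.0,
    ("ramp", "ascend"): 18.0,
    ("ramp", "descend"): -12.0,
    ("ramp", "turn"): 8.0,
}

_KIND_TO_MODE = {"level": ModeLabel.Level, "turn": ModeLabel.Level,
                 "ascend": ModeLabel.Ascent, "descend": ModeLabel.Descent}


def _minjerk(tau: np.ndarray):
    """Minimum-jerk displacement profile and its first two derivatives."""
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    ds = 30 * tau**2 - 60 * tau**3 + 30 * tau**4
    dds = 60 * tau - 180 * tau**2 + 120 * tau**3
    return s, ds, dds


def _arc(tau: np.ndarray):
    """Clearance arc sin³(πτ): 0 at both ends, 1 at mid-swing, with zero
    velocity *and* acceleration at the boundaries (keeps the emitted
    acceleration continuous across stance–swing transitions)."""
    s, c = np.sin(np.pi * tau), np.cos(np.pi * tau)
    b = s**3
    db = 3 * np.pi * s**2 * c
    ddb = 3 * np.pi**2 * (2 * s * c**2 - s**3)
    return b, db, ddb


def _pitch_bump(tau: np.ndarray) -> np.ndarray:
    """Asymmetric swing sweep peaking in early–mid swing (tau ≈ 0.375)."""
    raw = tau**1.5 * (1 - tau)**2.5
    return raw / (0.375**1.5 * 0.625**2.5)


def _step_kinds(cfg: ScenarioConfig, rng: np.random.Generator) -> list[str]:
    def level():
        return ["level"] * int(rng.integers(3, 5))
    if cfg.scenario == "stairs":
        return (level() + ["ascend"] * 6 + level() + ["turn"] * 2
                + level() + ["descend"] * 6 + level())
    n_up = int(rng.integers(8, 11))
    n_down = int(rng.integers(8, 11))
    return level() + ["ascend"] * n_up + ["turn"] * 2 + ["descend"] * n_down + level()


def _surface_after(cfg: ScenarioConfig, kind: str) -> float:
    """Surface pitch (degrees) the foot lands on after a swing of this kind."""
    if cfg.scenario == "ramp" and kind == "ascend":
        return cfg.ramp_grade
    if cfg.scenario == "ramp" and kind == "descend":
        return -cfg.ramp_grade
    return 0.0


def _rise(cfg: ScenarioConfig, kind: str, stride_length: float) -> float:
    """Net foot elevation change over one swing of this kind, m."""
    if kind == "ascend":
        return cfg.step_rise if cfg.scenario == "stairs" else \
            stride_length * np.tan(np.radians(cfg.ramp_grade))
    if kind == "descend":
        return -cfg.step_rise if cfg.scenario == "stairs" else \
            -stride_length * np.tan(np.radians(cfg.ramp_grade))
    return 0.0


def _subject_params(cfg: ScenarioConfig, subject_id: int) -> dict:
    """Per-subject kinematic jitter, constant across that subject's trials."""
    rng = np.random.default_rng([cfg.seed, 7001, subject_id])
    return {
        "stride_time": cfg.stride_time + rng.uniform(-0.1, 0.1),
        "stride_length": cfg.stride_length * rng.uniform(0.9, 1.1),
        "clearance": cfg.clearance * rng.uniform(0.9, 1.1),
        "sweep_gain": rng.uniform(0.9, 1.1),
    }


def generate_trial(cfg: ScenarioConfig, subject_id: int = 1,
                   trial_id: int = 1) -> tuple[SensorStream, TrialTruth]:
    """Synthesize one trial: raw sensor stream plus exact ground truth."""
    p = _subject_params(cfg, subject_id)
    scen = _SCENARIOS.index(cfg.scenario)
    rng = np.random.default_rng([cfg.seed, scen, subject_id, trial_id])
    kinds = _step_kinds(cfg, rng)

    fs = cfg.fs
    n_stand = int(round(cfg.stand_time * fs))

    segs = []  # (n, kind_of_segment, payload)

    # quiet standing, then a lead-in level swing onto the first surface
    segs.append(("stand", n_stand, {"pitch0": 0.0, "z0": 0.0}))
    z = 0.0
    T = p["stride_time"]
    n_swing0 = int(round(cfg.swing_fraction * T * fs))
    segs.append(("swing", n_swing0, {
        "z0": z, "dz": 0.0, "clearance": p["clearance"],
        "pitch0": 0.0, "pitch1": 0.0,
        "sweep": p["sweep_gain"] * _PITCH_SWEEP[(cfg.scenario, "level")],
        "label": int(ModeLabel.Level), "dur": cfg.swing_fraction * T,
    }))

    step_meta = []
    surface = 0.0
    for kind in kinds:
        T_k = T * (1.5 if kind == "turn" else 1.0)
        n_stance = int(round((1 - cfg.swing_fraction) * T_k * fs))
        n_swing = int(round(cfg.swing_fraction * T_k * fs))
        dz = _rise(cfg, kind, p["stride_length"])
        next_surface = _surface_after(cfg, kind)
        label = int(_KIND_TO_MODE[kind])
        segs.append(("stance", n_stance, {"pitch0": surface, "z0": z, "label": label}))
        segs.append(("swing", n_swing, {
            "z0": z, "dz": dz,
            "clearance": p["clearance"] * (0.6 if kind == "turn" else 1.0),
            "pitch0": surface, "pitch1": next_surface,
            "sweep": p["sweep_gain"] * _PITCH_SWEEP[(cfg.scenario, kind)],
            "label": label, "dur": cfg.swing_fraction * T_k,
        }))
        step_meta.append({"kind": kind, "mode": label})
        z += dz
        surface = next_surface
    segs.append(("stand", n_stand, {"pitch0": surface, "z0": z}))

    n_total = sum(n for _, n, _ in segs)
    a_z = np.full(n_total, G)
    z_track = np.zeros(n_total)
    v_z = np.zeros(n_total)
    theta = np.zeros(n_total)
    mode = np.full(n_total, int(ModeLabel.Level))
    stance_flag = np.zeros(n_total, dtype=bool)
    heel = np.zeros(n_total, dtype=bool)
    toe = np.zeros(n_total, dtype=bool)

    events = []   # (segment kind, start index) for stance/swing
    i = 0
    for seg_kind, n, pay in segs:
        sl = slice(i, i + n)
        if seg_kind in ("stand", "stance"):
            theta[sl] = pay["pitch0"]
            z_track[sl] = pay["z0"]
            stance_flag[sl] = True
            if seg_kind == "stand":
                heel[sl] = toe[sl] = True
            else:
                # heel contact from heel strike to heel-off; toe contact from
                # foot-flat to toe-off (= stance end)
                heel[i:i + int(0.75 * n)] = True
                toe[i + int(0.08 * n):i + n] = True
                mode[sl] = pay["label"]
                events.append(("stance", i))
        else:  # swing
            # interior grid: swing samples sit strictly between the lift-off
            # and landing instants, which themselves coincide with stance samples
            tau = (np.arange(n) + 1.0) / (n + 1.0)
            dur = pay["dur"]
            s, ds, dds = _minjerk(tau)
            b, db, ddb = _arc(tau)
            z_track[sl] = pay["z0"] + pay["dz"] * s + pay["clearance"] * b
            v_z[sl] = (pay["dz"] * ds + pay["clearance"] * db) / dur
            a_z[sl] = G + (pay["dz"] * dds + pay["clearance"] * ddb) / dur**2
            theta[sl] = (pay["pitch0"] + (pay["pitch1"] - pay["pitch0"]) * s
                         + pay["sweep"] * _pitch_bump(tau))
            mode[sl] = pay["label"]
            events.append(("swing", i))
        i += n

    # per-step events: heel strike = stance start, toe-off = following swing start
    stance_starts = [idx for k, idx in events if k == "stance"]
    swing_starts = [idx for k, idx in events if k == "swing"][1:]  # drop lead-in
    steps = []
    for j, meta in enumerate(step_meta):
        next_hs = stance_starts[j + 1] if j + 1 < len(stance_starts) else n_total - n_stand
        steps.append({"heel_strike": stance_starts[j], "swing_start": swing_starts[j],
                      "next_heel_strike": next_hs, **meta})
    # terminal standing begins at the last heel strike
    steps[-1]["next_heel_strike"] = n_total - n_stand

    truth = TrialTruth(v_z=v_z.copy(), theta=theta.copy(), mode=mode,
                       stance=stance_flag, z=z_track, steps=steps)

    a_noisy = a_z + rng.normal(0.0, cfg.noise_accel_sd, n_total)
    th_noisy = theta + rng.normal(0.0, cfg.noise_pitch_sd, n_total)

    half = np.radians(th_noisy) / 2.0
    quat = np.column_stack([np.cos(half), np.zeros(n_total),
                            np.sin(half), np.zeros(n_total)])
    # body-frame specific force = R^T (0, 0, a_z)
    cth, sth = np.cos(2 * half), np.sin(2 * half)
    accel_body = np.column_stack([-sth * a_noisy, np.zeros(n_total), cth * a_noisy])

    t = np.arange(n_total) / fs
    stream = SensorStream(t=t, fs=fs, fsr_heel=heel, fsr_toe=toe,
                          quat=quat, accel_body=accel_body)
    return stream, truth


def generate_study(cfg: ScenarioConfig, out_dir=None) -> dict:
    """Generate the full study for one scenario: n_subjects × n_trials.

    Trial 1 of each subject is flagged as the training split.  Returns
    ``{(subject, trial): (stream, truth, is_train)}``; when ``out_dir`` is
    given, also writes each trial as CSV (stream + ``*_truth.csv``) and a
    ``manifest.yaml`` listing files, splits and the generator settings.
    """
    trials = {}
    manifest = {"scenario": cfg.scenario, "seed": cfg.seed, "fs": cfg.fs, "trials": []}
    for subject in range(1, cfg.n_subjects + 1):
        for trial in range(1, cfg.n_trials + 1):
            stream, truth = generate_trial(cfg, subject, trial)
            is_train = trial == 1
            trials[(subject, trial)] = (stream, truth, is_train)
            if out_dir is not None:
                stem = f"{cfg.scenario}_s{subject:02d}_t{trial}"
                write_stream_csv(stream, f"{out_dir}/{stem}.csv")
                pd.DataFrame({
                    "v_z": truth.v_z, "theta": truth.theta,
                    "mode": truth.mode, "stance": truth.stance.astype(int),
                }).to_csv(f"{out_dir}/{stem}_truth.csv", index=False)
                manifest["trials"].append({
                    "subject": subject, "trial": trial, "split":
                        "train" if is_train else "test",
                    "stream": f"{stem}.csv", "truth": f"{stem}_truth.csv",
                })
    if out_dir is not None:
        with open(f"{out_dir}/manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
    return trials
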
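"""Sensor-stream containers and CSV I/O.

A trial is a synchronized set of channels sampled at a fixed rate from a
foot-mounted inertial measurement unit (IMU) and two force-sensitive
resistors (FSRs) under the heel and ball of the foot.  Orientation is taken
as given per sample (a body-to-world unit quaternion); no on-line
orientation filtering is performed here.

Two CSV dialects are supported:

* full:    ``t,qw,qx,qy,qz,ax,ay,az,fsr_heel,fsr_toe``
* reduced: ``t,accel_z_world,pitch_deg,fsr_heel,fsr_toe`` for data whose
  rotation to the world frame was done upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SensorStream", "ProcessedSignals", "read_stream_csv", "write_stream_csv"]

_FULL_COLUMNS = ["t", "qw", "qx", "qy", "qz", "ax", "ay", "az", "fsr_heel", "fsr_toe"]
_REDUCED_COLUMNS = ["t", "accel_z_world", "pitch_deg", "fsr_heel", "fsr_toe"]

#: standard gravity, m/s^2
G = 9.81


@dataclass
class SensorStream:
    """Synchronized raw sensor channels at a fixed sampling rate.

    Either ``quat`` + ``accel_body`` (full dialect) or the pre-rotated
    ``accel_z_world`` + ``pitch_deg`` pair (reduced dialect) is present;
    the FSR contact states are always present.
    """

    t: np.ndarray                      # seconds, uniform spacing 1/fs
    fs: float                          # Hz
    fsr_heel: np.ndarray               # bool, ground contact under the heel
    fsr_toe: np.ndarray                # bool, ground contact under the toe
    quat: np.ndarray | None = None     # (n, 4) unit quaternions (w, x, y, z)
    accel_body: np.ndarray | None = None   # (n, 3) m/s^2, body frame
    accel_z_world: np.ndarray | None = None  # (n,) m/s^2, world z (includes g)
    pitch_deg: np.ndarray | None = None      # (n,) degrees, +toe-up

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.fsr_heel = np.asarray(self.fsr_heel).astype(bool)
        self.fsr_toe = np.asarray(self.fsr_toe).astype(bool)
        n = self.t.size
        if n < 1:
            raise ValueError("stream must contain at least one sample")
        if self.fsr_heel.size != n or self.fsr_toe.size != n:
            raise ValueError("FSR channels must match the time base length")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if np.max(np.abs(dt - 1.0 / self.fs)) > 1e-9:
                raise ValueError("timestamps must be uniformly spaced at 1/fs")
        if self.quat is not None:
            self.quat = np.atleast_2d(np.asarray(self.quat, dtype=float))
            norms = np.linalg.norm(self.quat, axis=1)
            if np.max(np.abs(norms - 1.0)) > 1e-6:
                raise ValueError("quaternions must be unit norm (|‖q‖-1| <= 1e-6)")
        if self.accel_body is not None:
            self.accel_body = np.atleast_2d(np.asarray(self.accel_body, dtype=float))

    def __len__(self) -> int:
        return self.t.size


@dataclass
class ProcessedSignals:
    """The two classifier inputs derived from a :class:`SensorStream`.

    ``v_z`` is the ZUPT-corrected vertical foot velocity and ``theta`` the
    sagittal foot pitch.  ``zero_instances`` are the sample indices at which
    the foot was taken as stationary; ``v_z`` is exactly zero there.
    """

    v_z: np.ndarray          # m/s
    theta: np.ndarray        # degrees, +toe-up
    zero_instances: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    fs: float = 200.0

    def __len__(self) -> int:
        return self.v_z.size


def read_stream_csv(path, fs: float | None = None) -> SensorStream:
    """Read a trial from CSV in either the full or the reduced dialect.

    The sampling rate is inferred from the time column unless given.
    """
    df = pd.read_csv(path)
    cols = list(df.columns)
    t = df["t"].to_numpy(dtype=float)
    if fs is None:
        if t.size < 2:
            raise ValueError("cannot infer fs from a single-sample stream; pass fs")
        fs = 1.0 / float(np.median(np.diff(t)))
    heel = df["fsr_heel"].to_numpy()
    toe = df["fsr_toe"].to_numpy()
    if set(_FULL_COLUMNS) <= set(cols):
        return SensorStream(
            t=t, fs=fs, fsr_heel=heel, fsr_toe=toe,
            quat=df[["qw", "qx", "qy", "qz"]].to_numpy(dtype=float),
            accel_body=df[["ax", "ay", "az"]].to_numpy(dtype=float),
        )
    if set(_REDUCED_COLUMNS) <= set(cols):
        return SensorStream(
            t=t, fs=fs, fsr_heel=heel, fsr_toe=toe,
            accel_z_world=df["accel_z_world"].to_numpy(dtype=float),
            pitch_deg=df["pitch_deg"].to_numpy(dtype=float),
        )
    raise ValueError(
        f"unrecognized CSV schema {cols!r}; expected columns "
        f"{_FULL_COLUMNS} or {_REDUCED_COLUMNS}"
    )


def write_stream_csv(stream: SensorStream, path) -> None:
    """Write a trial as CSV, choosing the dialect from the populated fields."""
    if stream.quat is not None and stream.accel_body is not None:
        df = pd.DataFrame({
            "t": stream.t,
            "qw": stream.quat[:, 0], "qx": stream.quat[:, 1],
            "qy": stream.quat[:, 2], "qz": stream.quat[:, 3],
            "ax": stream.accel_body[:, 0], "ay": stream.accel_body[:, 1],
            "az": stream.accel_body[:, 2],
            "fsr_heel": stream.fsr_heel.astype(int),
            "fsr_toe": stream.fsr_toe.astype(int),
        })
    elif stream.accel_z_world is not None and stream.pitch_deg is not None:
        df = pd.DataFrame({
            "t": stream.t,
            "accel_z_world": stream.accel_z_world,
            "pitch_deg": stream.pitch_deg,
            "fsr_heel": stream.fsr_heel.astype(int),
            "fsr_toe": stream.fsr_toe.astype(int),
        })
    else:
        raise ValueError("stream has neither full nor reduced channel set")
    df.to_csv(path, index=False)
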
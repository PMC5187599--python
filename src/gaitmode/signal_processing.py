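"""Raw IMU/FSR streams → classifier inputs.

Converts body-frame acceleration to the world frame, extracts the sagittal
foot pitch from the orientation quaternion, detects zero-velocity instances
(mid-stance samples where the foot is stationary), and integrates vertical
acceleration into vertical foot velocity with zero-velocity updates (ZUPT)
to suppress integration drift.

The stationarity test is ``|a_z - g| < eps_g`` held for at least
``min_dwell`` consecutive samples, where ``a_z`` is world-frame vertical
acceleration (gravity included) and ``g`` = 9.81 m/s².  When sensor noise
prevents the test from firing during a stance period, a fail-safe uses the
foot switches: the midpoint of any interval where both heel and toe FSRs
are on is taken as a zero-velocity instance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .streams import G, ProcessedSignals, SensorStream

__all__ = [
    "ZuptConfig",
    "NoZeroInstanceError",
    "rotate_to_world",
    "compute_pitch",
    "detect_zero_accel_instances",
    "estimate_vertical_velocity",
    "tune_eps_g",
    "process_stream",
]


class NoZeroInstanceError(ValueError):
    """Raised when no sample can anchor the velocity integration to zero."""


@dataclass
class ZuptConfig:
    """Zero-velocity-update settings.

    eps_g : stationarity threshold on |a_z - g|, m/s².
    min_dwell : samples the stationarity condition must persist
        (rejects single-sample noise crossings).
    drift_mode : ``"linear_detrend"`` distributes the accumulated drift
        linearly over the interval since the previous zero event (standard
        ZUPT practice); ``"reset"`` discards it at the event.
    """

    eps_g: float = 0.3
    g: float = G
    min_dwell: int = 5
    drift_mode: str = "linear_detrend"

    def __post_init__(self) -> None:
        if not self.eps_g > 0:
            raise ValueError("eps_g must be positive")
        if self.min_dwell < 1:
            raise ValueError("min_dwell must be >= 1")
        if self.drift_mode not in ("reset", "linear_detrend"):
            raise ValueError(f"unknown drift_mode {self.drift_mode!r}")


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrices for an (n, 4) array of (w, x, y, z) quaternions."""
    w, x, y, z = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    R = np.empty(q.shape[:-1] + (3, 3))
    R[..., 0, 0] = 1 - 2 * (y * y + z * z)
    R[..., 0, 1] = 2 * (x * y - w * z)
    R[..., 0, 2] = 2 * (x * z + w * y)
    R[..., 1, 0] = 2 * (x * y + w * z)
    R[..., 1, 1] = 1 - 2 * (x * x + z * z)
    R[..., 1, 2] = 2 * (y * z - w * x)
    R[..., 2, 0] = 2 * (x * z - w * y)
    R[..., 2, 1] = 2 * (y * z + w * x)
    R[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return R


def rotate_to_world(quat: np.ndarray, accel_body: np.ndarray) -> np.ndarray:
    """Rotate body-frame acceleration into the world frame.

    ``quat`` is the body→world unit quaternion (w, x, y, z); accepts single
    vectors or per-sample arrays.  Norm-preserving by construction.
    """
    quat = np.asarray(quat, dtype=float)
    accel_body = np.asarray(accel_body, dtype=float)
    if not (np.all(np.isfinite(quat)) and np.all(np.isfinite(accel_body))):
        raise ValueError("non-finite input")
    norms = np.linalg.norm(quat, axis=-1)
    if np.max(np.abs(norms - 1.0)) > 1e-6:
        raise ValueError("quaternion is not unit norm within 1e-6")
    R = _quat_to_matrix(quat)
    return np.einsum("...ij,...j->...i", R, accel_body)


def compute_pitch(quat: np.ndarray) -> np.ndarray:
    """Sagittal foot pitch in degrees from the orientation quaternion.

    Convention: pitch is the rotation about the mediolateral (world y)
    axis, positive toe-up, computed with the aerospace Z-Y-X sequence:
    ``pitch = asin(2(wy - xz))``, clamped into [-1, 1] near the gimbal
    singularity.  Result lies in [-90°, +90°].
    """
    quat = np.asarray(quat, dtype=float)
    norms = np.linalg.norm(quat, axis=-1)
    if np.max(np.abs(norms - 1.0)) > 1e-6:
        raise ValueError("quaternion is not unit norm within 1e-6")
    w, x, y, z = quat[..., 0], quat[..., 1], quat[..., 2], quat[..., 3]
    s = np.clip(2.0 * (w * y - x * z), -1.0, 1.0)
    return np.degrees(np.arcsin(s))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of True runs in a boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False])).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def detect_zero_accel_instances(
    accel_z_world: np.ndarray,
    fsr_heel: np.ndarray,
    fsr_toe: np.ndarray,
    cfg: ZuptConfig,
) -> np.ndarray:
    """Sample indices at which the foot is taken as stationary.

    Primary rule: ``|a_z - g| < eps_g`` for at least ``min_dwell``
    consecutive samples.  Fail-safe: any both-FSRs-on interval containing
    no primary index contributes its midpoint sample, so every stance
    period yields at least one index.

    Raises :class:`NoZeroInstanceError` if neither rule fires anywhere.
    """
    a = np.asarray(accel_z_world, dtype=float)
    heel = np.asarray(fsr_heel, dtype=bool)
    toe = np.asarray(fsr_toe, dtype=bool)
    if not (a.size == heel.size == toe.size):
        raise ValueError("series must share length")

    quiet = np.abs(a - cfg.g) < cfg.eps_g
    primary = np.zeros(a.size, dtype=bool)
    for start, stop in _runs(quiet):
        if stop - start >= cfg.min_dwell:
            primary[start:stop] = True

    indices = set(np.flatnonzero(primary).tolist())
    for start, stop in _runs(heel & toe):
        if not any(primary[start:stop]):
            indices.add((start + stop - 1) // 2)

    if not indices:
        raise NoZeroInstanceError(
            "no stationary sample found: the stationarity test never fired and "
            "no both-FSR-on stance interval exists; velocity cannot be anchored"
        )
    return np.array(sorted(indices), dtype=int)


def estimate_vertical_velocity(
    accel_z_world: np.ndarray,
    zero_instances: np.ndarray,
    fs: float,
    cfg: ZuptConfig | None = None,
) -> np.ndarray:
    """ZUPT-corrected vertical velocity from world-frame vertical acceleration.

    Trapezoidal integration of (a_z - g), recalibrated to exactly zero at
    every zero-velocity instance.  Contiguous instances form events; within
    an event the velocity is pinned at zero.  Between consecutive events
    the accumulated end error is removed either as a linear ramp
    (``linear_detrend``, default) or as a jump at the event (``reset``).
    Samples before the first event are anchored by subtracting the first
    event's accumulated value.
    """
    cfg = cfg or ZuptConfig()
    a = np.asarray(accel_z_world, dtype=float)
    zi = np.asarray(zero_instances, dtype=int)
    if zi.size == 0:
        raise NoZeroInstanceError("zero_instances is empty")
    n = a.size

    # raw cumulative trapezoidal integral of (a_z - g); segment values are
    # taken as differences of this, so integration restarts at every anchor
    da = a - cfg.g
    c = np.zeros(n)
    c[1:] = np.cumsum(0.5 * (da[1:] + da[:-1])) / fs

    events = _runs(np.isin(np.arange(n), zi))
    v = np.zeros(n)

    first_start = events[0][0]
    v[:first_start] = c[:first_start] - c[first_start]

    for (ps, pe), (cs, ce) in zip(events[:-1], events[1:]):
        anchor = pe - 1             # last pinned sample of the previous event
        gap = slice(pe, cs)
        w = c[pe:cs] - c[anchor]    # integral restarted at the anchor
        err = c[cs] - c[anchor]     # accumulated value at the next event
        if cfg.drift_mode == "linear_detrend":
            v[gap] = w - err * (np.arange(pe, cs) - anchor) / (cs - anchor)
        else:  # reset: keep the drifted segment, discard err at the event
            v[gap] = w

    last_end = events[-1][1]
    v[last_end:] = c[last_end:] - c[last_end - 1]
    return v


def tune_eps_g(
    accel_z_world: np.ndarray,
    stance_windows: list[tuple[int, int]],
    cfg: ZuptConfig | None = None,
    grid: np.ndarray | None = None,
) -> tuple[float, bool]:
    """Pick the stationarity threshold from training data.

    Returns the largest grid value of ``eps_g`` whose primary detections
    all fall inside the given stance windows (half-open index ranges), so
    zero-velocity instances only occur mid-stance.  The grid defaults to 30
    log-spaced values in [0.01, 2.0] m/s².  If every grid value produces a
    detection outside stance, the grid minimum is returned with the warning
    flag set.

    Returns ``(eps_g, clean)`` where ``clean`` is False in the fallback case.
    """
    if not stance_windows:
        raise ValueError("stance_windows is empty")
    cfg = cfg or ZuptConfig()
    if grid is None:
        grid = np.logspace(np.log10(0.01), np.log10(2.0), 30)
    a = np.asarray(accel_z_world, dtype=float)
    in_stance = np.zeros(a.size, dtype=bool)
    for start, stop in stance_windows:
        in_stance[start:stop] = True

    for eps in sorted(grid, reverse=True):
        quiet = np.abs(a - cfg.g) < eps
        ok = True
        for start, stop in _runs(quiet):
            if stop - start >= cfg.min_dwell and not np.all(in_stance[start:stop]):
                ok = False
                break
        if ok:
            return float(eps), True
    return float(np.min(grid)), False


def process_stream(stream: SensorStream, cfg: ZuptConfig | None = None) -> ProcessedSignals:
    """Full front end: raw stream → (v_z, pitch, zero instances).

    Uses the pre-rotated channels when present, otherwise rotates the body
    acceleration with the quaternion and extracts pitch from it.
    """
    cfg = cfg or ZuptConfig()
    if stream.accel_z_world is not None and stream.pitch_deg is not None:
        a_z = stream.accel_z_world
        theta = stream.pitch_deg
    elif stream.quat is not None and stream.accel_body is not None:
        a_world = rotate_to_world(stream.quat, stream.accel_body)
        a_z = a_world[:, 2]
        theta = compute_pitch(stream.quat)
    else:
        raise ValueError("stream carries neither pre-rotated nor quaternion channels")
    zi = detect_zero_accel_instances(a_z, stream.fsr_heel, stream.fsr_toe, cfg)
    v_z = estimate_vertical_velocity(a_z, zi, stream.fs, cfg)
    return ProcessedSignals(v_z=v_z, theta=np.asarray(theta, float), zero_instances=zi, fs=stream.fs)
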
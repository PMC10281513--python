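"""Raw-recording I/O, artifact removal and the two downsampling primitives.

A raw recording is the delimited text a tracking system writes: one row per
camera frame with columns ``frame,t,x,y,led`` (time in seconds, positions in
cm in the arena-centered frame, LED state 0/1).  All downstream analyses
operate on :class:`Trajectory` objects read from such files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "Zone",
    "TrialAnnotation",
    "RawRecordingError",
    "ArtifactRemovalError",
    "read_raw_recording",
    "write_raw_recording",
    "remove_artifacts",
    "downsample_time",
    "downsample_distance",
]

REQUIRED_COLUMNS = ("frame", "t", "x", "y", "led")


class RawRecordingError(ValueError):
    """A raw recording file violates the expected csv contract."""


class ArtifactRemovalError(ValueError):
    """Artifact removal left too little data to analyse."""


@dataclass
class Trajectory:
    """Time-ordered 2-D positions with optional stimulation-LED state.

    ``frame`` tags the coordinate system: ``"arena"`` (arena-centered cm)
    or ``"fictive"`` (translated by the displacement vector).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    led: np.ndarray | None = None
    frame: str = "arena"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.led is not None:
            self.led = np.asarray(self.led, dtype=int)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if self.led is not None and len(self.led) != len(self.t):
            raise ValueError("led must match t in length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if len(self.t) and not (
            np.all(np.isfinite(self.t))
            and np.all(np.isfinite(self.x))
            and np.all(np.isfinite(self.y))
        ):
            raise ValueError("non-finite sample values")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def take(self, idx) -> "Trajectory":
        """Subsequence at integer indices ``idx`` (order preserved)."""
        led = self.led[idx] if self.led is not None else None
        return Trajectory(self.t[idx], self.x[idx], self.y[idx], led, self.frame)

    def window(self, t0: float, t1: float) -> "Trajectory":
        """Samples with t in [t0, t1]."""
        return self.take((self.t >= t0) & (self.t <= t1))

    def path_length(self) -> float:
        if len(self) < 2:
            return 0.0
        return float(np.sum(np.hypot(np.diff(self.x), np.diff(self.y))))


@dataclass(frozen=True)
class Zone:
    """A circular region: center (x, y) in cm and radius in cm."""

    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("zone radius must be > 0")

    def contains(self, x, y) -> np.ndarray:
        """Closed-disc membership (boundary counts as inside)."""
        return np.hypot(np.asarray(x) - self.center[0],
                        np.asarray(y) - self.center[1]) <= self.radius


@dataclass
class TrialAnnotation:
    """Per-trial metadata of a displacement experiment.

    ``displacement_interval`` is the manually annotated (t_start, t_end) of
    the passive slider pull; ``displacement_vector`` is
    position(t_end) - position(t_start) of the trajectory.
    """

    reward_zone: Zone
    displacement_interval: tuple[float, float]
    displacement_vector: tuple[float, float]
    condition: str = "rewarded"  # rewarded | non-rewarded
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t0, t1 = self.displacement_interval
        if not t0 < t1:
            raise ValueError("displacement interval must satisfy t_start < t_end")
        if self.condition not in ("rewarded", "non-rewarded"):
            raise ValueError(f"unknown condition {self.condition!r}")


def read_raw_recording(path) -> Trajectory:
    """Read a ``frame,t,x,y,led`` csv into a :class:`Trajectory`.

    Malformed (non-numeric or incomplete) rows and non-monotone timestamps
    raise :class:`RawRecordingError` naming the offending file lines
    (1-based, counting the header as line 1).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise RawRecordingError(f"{path}: missing columns {missing}")
    num = df[list(REQUIRED_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    bad = num[["t", "x", "y"]].isna().any(axis=1)
    if bad.any():
        lines = (num.index[bad] + 2).tolist()  # +1 header, +1 one-based
        raise RawRecordingError(f"{path}: malformed rows at lines {lines}")
    dt = np.diff(num["t"].to_numpy())
    nonmono = np.nonzero(dt <= 0)[0]
    if nonmono.size:
        line = int(nonmono[0]) + 3  # second row of the offending pair
        raise RawRecordingError(
            f"{path}: non-monotone timestamp at line {line}"
        )
    led = num["led"].to_numpy()
    led = None if np.isnan(led).all() else np.nan_to_num(led).astype(int)
    return Trajectory(num["t"].to_numpy(), num["x"].to_numpy(),
                      num["y"].to_numpy(), led)


def write_raw_recording(traj: Trajectory, path) -> None:
    """Write a trajectory in the raw-recording csv dialect."""
    led = traj.led if traj.led is not None else np.zeros(len(traj), dtype=int)
    df = pd.DataFrame(
        {
            "frame": np.arange(len(traj)),
            "t": traj.t,
            "x": traj.x,
            "y": traj.y,
            "led": led,
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def remove_artifacts(
    traj: Trajectory,
    max_speed: float = 50.0,
    exclude_intervals: list[tuple[float, float]] | None = None,
) -> Trajectory:
    """Drop falsely detected points (tracking glitches, reflections).

    A sample is dropped when the instantaneous speed from the last *kept*
    sample exceeds ``max_speed`` (cm/s); an isolated teleporting point is
    thus removed while the resumed true track is kept.  Samples inside any
    of ``exclude_intervals`` (explicit manual exclusion windows, in s) are
    dropped first.  Raises :class:`ArtifactRemovalError` when fewer than two
    samples survive or more than half were speed-outliers.
    """
    if max_speed <= 0:
        raise ValueError("max_speed must be > 0")
    if exclude_intervals:
        mask = np.ones(len(traj), dtype=bool)
        for a, b in exclude_intervals:
            mask &= ~((traj.t >= a) & (traj.t <= b))
        traj = traj.take(mask)
    n = len(traj)
    if n == 0:
        raise ArtifactRemovalError("empty trajectory")
    keep = [0]
    for i in range(1, n):
        j = keep[-1]
        dist = float(np.hypot(traj.x[i] - traj.x[j], traj.y[i] - traj.y[j]))
        if dist <= max_speed * (traj.t[i] - traj.t[j]):
            keep.append(i)
    if len(keep) < 2 or len(keep) < n / 2:
        raise ArtifactRemovalError(
            f"artifact removal kept {len(keep)}/{n} samples; recording unusable"
        )
    return traj.take(np.asarray(keep))


def downsample_time(traj: Trajectory, dt: float) -> Trajectory:
    """Keep the first sample of each dt-length bin anchored at the first t.

    Timestamps of kept samples are preserved.  If ``dt`` does not exceed
    the native frame interval every sample lands in its own bin and the
    input is returned unchanged.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if len(traj) == 0:
        return traj
    # nudge ratios sitting a rounding error below a bin edge up onto it
    bins = np.floor((traj.t - traj.t[0]) / dt + 1e-6).astype(int)
    first = np.ones(len(traj), dtype=bool)
    first[1:] = bins[1:] != bins[:-1]
    return traj.take(first)


def downsample_distance(traj: Trajectory, step: float) -> Trajectory:
    """Resample by cumulative path length: one sample per ``step`` cm walked.

    Emits the first sample, then each subsequent existing sample at which
    the path length accumulated since the last emitted sample first reaches
    ``step``.  No positions are interpolated.  Stationary periods add no
    path length and therefore vanish from the output, which is the purpose:
    stop bouts are removed from the data.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if len(traj) == 0:
        return traj
    seg = np.hypot(np.diff(traj.x), np.diff(traj.y))
    cs = np.concatenate([[0.0], np.cumsum(seg)])
    eps = 1e-9 * step  # tolerate float rounding at exact step multiples
    keep = [0]
    j = 0
    while True:
        nxt = int(np.searchsorted(cs, cs[j] + step - eps, side="left"))
        if nxt >= len(cs):
            break
        keep.append(nxt)
        j = nxt
    return traj.take(np.asarray(keep))


def translate(traj: Trajectory, dx: float, dy: float, frame: str | None = None) -> Trajectory:
    """Rigidly translate all positions; optionally re-tag the frame."""
    out = replace(traj, x=traj.x + dx, y=traj.y + dy)
    if frame is not None:
        out.frame = frame
    return out
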
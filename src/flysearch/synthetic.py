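"""Synthetic raw recordings with known ground truth.

Generates trajectories emulating the displacement- and pheromone-experiment
protocols so every pipeline stage can be exercised and validated without
real recordings.  Walkers are discrete-time correlated random walks (heading
persistence plus turn noise) with an optional steering bias toward a target
point; local search is rendered as that bias toward the search center,
producing looping dwells.  No claim of kinematic realism is made — the
generator provides the statistical structure (stops, noise, outliers,
displacement, goal-directed search) the analyses are designed to detect.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .trajectory import Trajectory, TrialAnnotation, Zone, write_raw_recording

__all__ = [
    "AgentSpec",
    "GroundTruth",
    "generate_displacement_trial",
    "generate_pheromone_trial",
    "write_trial",
]

BEHAVIORS = ("pi-searcher", "site-fixed-searcher", "random-walker")

#: displacement-segment length distribution, cm (truncated positive)
DISPLACEMENT_MEAN_CM = 9.2
DISPLACEMENT_SD_CM = 2.78

DEFAULT_ARENA = Zone((0.0, 0.0), 30.0)          # 60 cm diameter arena
DEFAULT_RZ = Zone((-9.8, 6.7), 2.8)             # stimulation zone
DEFAULT_PHEROMONE_ARENA = Zone((0.0, 0.0), 10.0)  # 20 cm diameter arena
DEFAULT_PHEROMONE_RZ = Zone((0.0, 5.0), 1.0)    # emitter chamber site


@dataclass
class AgentSpec:
    """Synthetic walker parameters.

    ``behavior`` selects the test-period strategy: a *pi-searcher* loops
    around the fictive reward zone (path-integration ground truth), a
    *site-fixed-searcher* around the actual zone (cue-following ground
    truth), and a *random-walker* just diffuses.  Rates are per second of
    simulated time except ``outlier_rate`` (per frame).
    """

    behavior: str = "pi-searcher"
    speed: float = 1.5            # cm/s, typical walking pace
    stop_rate: float = 0.05       # stop bouts per s
    stop_duration: float = 4.0    # mean stop length, s
    search_spread: float = 2.0    # cm, scale of search loops
    noise_sd: float = 0.02        # cm, tracking noise
    outlier_rate: float = 0.0     # per frame, artifact injection
    frame_rate: float = 25.0      # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.behavior not in BEHAVIORS:
            raise ValueError(f"unknown behavior {self.behavior!r}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        for name in ("speed", "stop_rate", "stop_duration", "noise_sd",
                     "outlier_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """What the generator actually did, for validating the pipeline."""

    displacement_vector: tuple[float, float]
    search_center: tuple[float, float] | None
    stop_intervals: list = field(default_factory=list)
    outlier_indices: list = field(default_factory=list)
    displacement_interval: tuple[float, float] = (0.0, 0.0)


def _walk(
    rng: np.random.Generator,
    start: tuple[float, float],
    heading: float,
    n: int,
    dt: float,
    speed: float,
    arena: Zone,
    target: tuple[float, float] | None = None,
    steer_gain: float = 0.0,
    turn_sd: float = 0.5,
    stop_rate: float = 0.0,
    stop_duration: float = 0.0,
    stop_log: list | None = None,
    t0: float = 0.0,
) -> tuple[np.ndarray, float]:
    """Correlated random walk with optional steering bias and stop bouts.

    Returns the (n, 2) position array (start excluded) and final heading.
    ``steer_gain`` in [0, 1] pulls the heading toward the bearing to
    ``target`` each step; walls reflect by steering back toward the arena
    center.
    """
    xy = np.empty((n, 2))
    x, y = start
    stop_left = 0.0
    turns = rng.normal(0.0, turn_sd * math.sqrt(dt), size=n)
    u = rng.random(n)
    step = speed * dt
    p_stop = stop_rate * dt
    stop_start = None
    for i in range(n):
        if stop_left > 0:
            stop_left -= dt
            if stop_left <= 0 and stop_log is not None and stop_start is not None:
                stop_log.append((stop_start, t0 + i * dt))
                stop_start = None
        else:
            if p_stop > 0 and u[i] < p_stop and stop_duration > 0:
                stop_left = rng.exponential(stop_duration)
                stop_start = t0 + i * dt
            else:
                heading += turns[i]
                if target is not None and steer_gain > 0:
                    bearing = math.atan2(target[1] - y, target[0] - x)
                    d = (bearing - heading + math.pi) % (2 * math.pi) - math.pi
                    heading += steer_gain * d
                x += step * math.cos(heading)
                y += step * math.sin(heading)
                r = math.hypot(x - arena.center[0], y - arena.center[1])
                if r > arena.radius - 0.5:
                    # heat-barrier wall: turn back toward the arena center
                    heading = math.atan2(arena.center[1] - y,
                                         arena.center[0] - x)
                    scale = (arena.radius - 0.5) / r
                    x = arena.center[0] + (x - arena.center[0]) * scale
                    y = arena.center[1] + (y - arena.center[1]) * scale
        xy[i] = (x, y)
    if stop_log is not None and stop_start is not None:
        stop_log.append((stop_start, t0 + n * dt))
    return xy, heading


def generate_displacement_trial(
    spec: AgentSpec,
    arena: Zone = DEFAULT_ARENA,
    reward_zone: Zone = DEFAULT_RZ,
    baseline_s: float = 300.0,
    stim_s: float = 60.0,
    post_stim_s: float = 20.0,
    test_s: float = 120.0,
) -> tuple[Trajectory, TrialAnnotation, GroundTruth]:
    """One synthetic displacement trial emulating the experimental timeline.

    Phases: baseline wandering that converges on the reward zone; a dwell
    inside the zone with the LED on whenever the fly is inside (stimulation);
    a short post-stimulation walk onto the slider pickup point; a straight
    passive displacement whose length is drawn from the measured
    Normal(9.2, 2.78) cm (truncated positive, re-drawn until the endpoint
    stays inside the arena); then the behavior-dependent test period.
    Gaussian tracking noise and outlier artifacts are added at the
    specified rates; the accompanying :class:`GroundTruth` records the true
    displacement, search center, stop intervals and outlier indices.
    """
    rng = np.random.default_rng(spec.seed)
    dt = 1.0 / spec.frame_rate
    stops: list = []
    segments: list[np.ndarray] = []
    led_segments: list[np.ndarray] = []

    rzc = reward_zone.center
    start = (rzc[0] + rng.uniform(-10, 10), rzc[1] + rng.uniform(-10, 10))
    heading = rng.uniform(-math.pi, math.pi)

    # baseline: wander with a weak pull so the fly finds the reward zone
    n_base = int(round(baseline_s * spec.frame_rate))
    xy, heading = _walk(rng, start, heading, n_base, dt, spec.speed, arena,
                        target=rzc, steer_gain=0.05, stop_rate=spec.stop_rate,
                        stop_duration=spec.stop_duration, stop_log=stops,
                        t0=0.0)
    segments.append(xy)
    led_segments.append(np.zeros(n_base, dtype=int))

    # stimulation: tight search keeps the fly dwelling in/near the zone
    n_stim = int(round(stim_s * spec.frame_rate))
    xy, heading = _walk(rng, tuple(xy[-1]), heading, n_stim, dt, spec.speed,
                        arena, target=rzc, steer_gain=0.25, turn_sd=2.0)
    segments.append(xy)
    inside = reward_zone.contains(xy[:, 0], xy[:, 1])
    led_segments.append(inside.astype(int))

    # post-stimulation: walk out to the slider pickup point
    pick_ang = rng.uniform(-math.pi, math.pi)
    pickup = (rzc[0] + 3.8 * math.cos(pick_ang), rzc[1] + 3.8 * math.sin(pick_ang))
    n_post = int(round(post_stim_s * spec.frame_rate))
    xy, heading = _walk(rng, tuple(xy[-1]), heading, n_post, dt, spec.speed,
                        arena, target=pickup, steer_gain=0.3)
    segments.append(xy)
    led_segments.append(np.zeros(n_post, dtype=int))

    # passive displacement: straight pull at ~3 cm/s
    p0 = xy[-1]
    for _ in range(1000):
        length = rng.normal(DISPLACEMENT_MEAN_CM, DISPLACEMENT_SD_CM)
        ang = rng.uniform(-math.pi, math.pi)
        if length <= 0:
            continue
        p1 = p0 + length * np.array([math.cos(ang), math.sin(ang)])
        if math.hypot(p1[0] - arena.center[0], p1[1] - arena.center[1]) \
                < arena.radius - 4.0:
            break
    else:  # pragma: no cover - geometry ample for the default arena
        raise ValueError("arena too small for a displacement draw")
    disp_s = max(length / 3.0, 2 * dt)
    n_disp = int(round(disp_s * spec.frame_rate))
    frac = np.linspace(1.0 / n_disp, 1.0, n_disp)[:, None]
    xy = p0 + frac * (p1 - p0)
    segments.append(xy)
    led_segments.append(np.zeros(n_disp, dtype=int))
    n_before = n_base + n_stim + n_post
    t_disp = (n_before * dt, (n_before + n_disp) * dt)
    v_true = (float(p1[0] - p0[0]), float(p1[1] - p0[1]))

    # test period
    n_test = int(round(test_s * spec.frame_rate))
    if spec.behavior == "pi-searcher":
        center = (rzc[0] + v_true[0], rzc[1] + v_true[1])
    elif spec.behavior == "site-fixed-searcher":
        center = rzc
    else:
        center = None
    gain = 0.0 if center is None else min(0.6, 1.2 / max(spec.search_spread, 0.5))
    xy, heading = _walk(rng, tuple(xy[-1]), rng.uniform(-math.pi, math.pi),
                        n_test, dt, spec.speed, arena, target=center,
                        steer_gain=gain, turn_sd=1.2,
                        stop_rate=spec.stop_rate,
                        stop_duration=spec.stop_duration, stop_log=stops,
                        t0=t_disp[1])
    segments.append(xy)
    led_segments.append(np.zeros(n_test, dtype=int))

    xy = np.vstack(segments)
    led = np.concatenate(led_segments)
    n = len(xy)
    t = dt * np.arange(1, n + 1)
    noisy = xy + rng.normal(0.0, spec.noise_sd, size=xy.shape)
    i0 = int(np.searchsorted(t, t_disp[0], side="left"))
    i1 = int(np.searchsorted(t, t_disp[1], side="left"))

    outliers = []
    if spec.outlier_rate > 0:
        # endpoints of the displacement define the annotated vector; keep
        # them artifact-free so the annotation stays meaningful
        hits = np.nonzero(rng.random(n) < spec.outlier_rate)[0]
        hits = hits[(hits != i0) & (hits != i1)]
        for i in hits:
            r = rng.uniform(0.6 * arena.radius, arena.radius)
            a = rng.uniform(-math.pi, math.pi)
            noisy[i] = (arena.center[0] + r * math.cos(a),
                        arena.center[1] + r * math.sin(a))
        outliers = hits.tolist()

    traj = Trajectory(t, noisy[:, 0], noisy[:, 1], led)
    v_meas = (float(traj.x[i1] - traj.x[i0]), float(traj.y[i1] - traj.y[i0]))
    condition = "non-rewarded" if spec.behavior == "random-walker" else "rewarded"
    ann = TrialAnnotation(
        reward_zone=reward_zone,
        displacement_interval=(float(t[i0]), float(t[i1])),
        displacement_vector=v_meas,
        condition=condition,
    )
    truth = GroundTruth(
        displacement_vector=v_true,
        search_center=center,
        stop_intervals=stops,
        outlier_indices=outliers,
        displacement_interval=t_disp,
    )
    return traj, ann, truth


def generate_pheromone_trial(
    group_size: int = 12,
    condition: str = "without-emitter",
    attraction_strength: float = 0.0,
    seed: int = 0,
    duration_s: float = 1800.0,
    frame_rate: float = 25.0,
    arena: Zone = DEFAULT_PHEROMONE_ARENA,
    zone: Zone = DEFAULT_PHEROMONE_RZ,
    inactive_max_s: float = 360.0,
    speed: float = 1.0,
) -> list[Trajectory]:
    """A group of naive test flies in the pheromone-experiment arena.

    Each fly is an independent correlated random walker with a
    biased-turning attraction toward the reward-zone center of strength
    ``attraction_strength`` (0 = no emitter was present).  Each fly starts
    with an inactive sitting period (uniform up to ``inactive_max_s``),
    emulating the observed initial inactivity that motivates excluding the
    first minutes of the test stage.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    if condition == "with-emitter" and attraction_strength == 0.0:
        pass  # allowed: labels and mechanics are independent
    rng = np.random.default_rng(seed)
    dt = 1.0 / frame_rate
    n = int(round(duration_s * frame_rate))
    out = []
    for _ in range(group_size):
        a = rng.uniform(-math.pi, math.pi)
        r = arena.radius * math.sqrt(rng.random()) * 0.95
        start = (arena.center[0] + r * math.cos(a),
                 arena.center[1] + r * math.sin(a))
        n_sit = int(round(rng.uniform(0.0, inactive_max_s) * frame_rate))
        n_sit = min(n_sit, n - 1)
        xy_sit = np.tile(start, (n_sit, 1))
        xy, _ = _walk(rng, start, rng.uniform(-math.pi, math.pi), n - n_sit,
                      dt, speed, arena, target=zone.center,
                      steer_gain=attraction_strength, turn_sd=1.0,
                      stop_rate=0.02, stop_duration=3.0)
        xy = np.vstack([xy_sit, xy]) + rng.normal(0.0, 0.02, size=(n, 2))
        t = dt * np.arange(1, n + 1)
        out.append(Trajectory(t, xy[:, 0], xy[:, 1],
                              np.zeros(n, dtype=int)))
    return out


def write_trial(
    out_dir,
    name: str,
    traj: Trajectory,
    ann: TrialAnnotation,
    truth: GroundTruth | None = None,
) -> None:
    """Write a trial as raw-recording csv + annotation (+ ground truth) json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_raw_recording(traj, out_dir / f"{name}.csv")
    ann_d = {
        "reward_zone": {"center": list(ann.reward_zone.center),
                        "radius": ann.reward_zone.radius},
        "displacement_interval": list(ann.displacement_interval),
        "displacement_vector": list(ann.displacement_vector),
        "condition": ann.condition,
    }
    (out_dir / f"{name}.annotation.json").write_text(
        json.dumps(ann_d, indent=1))
    if truth is not None:
        d = {
            "displacement_vector": list(truth.displacement_vector),
            "search_center": (list(truth.search_center)
                              if truth.search_center else None),
            "stop_intervals": [list(s) for s in truth.stop_intervals],
            "outlier_indices": list(truth.outlier_indices),
            "displacement_interval": list(truth.displacement_interval),
        }
        (out_dir / f"{name}.truth.json").write_text(json.dumps(d, indent=1))


def read_annotation(path) -> TrialAnnotation:
    """Read an annotation sidecar written by :func:`write_trial`."""
    d = json.loads(Path(path).read_text())
    return TrialAnnotation(
        reward_zone=Zone(tuple(d["reward_zone"]["center"]),
                         d["reward_zone"]["radius"]),
        displacement_interval=tuple(d["displacement_interval"]),
        displacement_vector=tuple(d["displacement_vector"]),
        condition=d["condition"],
    )
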
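"""Displacement- and pheromone-experiment trajectory analysis.

The displacement analysis asks whether a rewarded fly, passively displaced
away from the site of an optogenetic reward, returns to the *fictive*
reward zone (the actual zone translated by the displacement vector, i.e.
the place path integration predicts) or to the *actual*, possibly
scent-marked zone.  The pheromone analysis asks whether naive flies
accumulate where previous "emitter" flies were rewarded.

Conventions: positions in cm, arena-centered coordinates, y up; zone
membership is the closed disc; occupancy grids are anchored at the arena
center with bin edges on integer multiples of the bin size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pingouin
from scipy import stats
from scipy.spatial import cKDTree

from .trajectory import (
    Trajectory,
    TrialAnnotation,
    Zone,
    downsample_distance,
    downsample_time,
    remove_artifacts,
    translate,
)

__all__ = [
    "OccupancyHistogram",
    "DirectionSample",
    "AnalysisReport",
    "PheromoneTrial",
    "fictive_zone",
    "to_fictive_frame",
    "occupancy_histogram",
    "fraction_in_zone",
    "visited",
    "initial_direction",
    "mean_trajectory_vector",
    "mean_direction",
    "rayleigh_test",
    "two_proportion_z",
    "welch_t",
    "paired_t",
    "intersection_score",
    "analyze_displacement_condition",
    "analyze_pheromone_condition",
]

TIME_STEP_S = 0.1      # time-downsampling interval for all analyses
DISTANCE_STEP_CM = 0.1  # 1 mm distance-downsampling step (walking histograms)


@dataclass
class OccupancyHistogram:
    """2-D relative-frequency grid over square arena-floor bins."""

    grid: np.ndarray
    xedges: np.ndarray
    yedges: np.ndarray
    bin_size: float
    frame: str
    mode: str  # residency | walking


@dataclass
class DirectionSample:
    """Per-fly initial walking direction after displacement."""

    angle: float            # absolute direction of net motion, radians
    reference: float        # direction from release point to fictive RZ center
    window_s: float

    @property
    def relative(self) -> float:
        """Angle relative to the fictive-RZ direction, wrapped to (-pi, pi]."""
        return _wrap_angle(self.angle - self.reference)


@dataclass
class TestResult:
    name: str
    statistic: float
    p: float
    n: tuple

    def as_dict(self) -> dict:
        return {"name": self.name, "statistic": self.statistic, "p": self.p,
                "n": list(self.n)}


@dataclass
class AnalysisReport:
    """Machine-readable per-trial and pooled outputs of an analysis run."""

    per_trial: list = field(default_factory=list)
    tests: dict = field(default_factory=dict)
    histograms: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def as_dict(self) -> dict:
        def conv(o):
            if isinstance(o, dict):
                return {k: conv(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [conv(v) for v in o]
            if isinstance(o, TestResult):
                return o.as_dict()
            if isinstance(o, DirectionSample):
                return {"angle": o.angle, "reference": o.reference,
                        "relative": o.relative, "window_s": o.window_s}
            if isinstance(o, OccupancyHistogram):
                return {"grid": o.grid.tolist(), "xedges": o.xedges.tolist(),
                        "yedges": o.yedges.tolist(), "bin_size": o.bin_size,
                        "frame": o.frame, "mode": o.mode}
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            return o
        return conv({"per_trial": self.per_trial, "tests": self.tests,
                     "histograms": self.histograms, "config": self.config,
                     "warnings": self.warnings})


def _wrap_angle(a: float) -> float:
    """Wrap to (-pi, pi]."""
    a = (a + math.pi) % (2 * math.pi) - math.pi
    return math.pi if a == -math.pi else a


# ---------------------------------------------------------------------------
# fictive-frame geometry

def fictive_zone(actual: Zone, displacement_vector: tuple[float, float]) -> Zone:
    """Zone predicted by path integration: the actual zone translated by the
    displacement vector, radius unchanged."""
    dx, dy = displacement_vector
    return Zone((actual.center[0] + dx, actual.center[1] + dy), actual.radius)


def to_fictive_frame(traj: Trajectory, displacement_vector: tuple[float, float]) -> Trajectory:
    """Translate a trajectory by minus the displacement vector.

    Distances from the translated trajectory to the *actual* zone equal
    distances from the original trajectory to the *fictive* zone, so
    analyses may equivalently translate either the data or the zone.
    """
    dx, dy = displacement_vector
    return translate(traj, -dx, -dy, frame="fictive")


# ---------------------------------------------------------------------------
# occupancy

def occupancy_histogram(
    trajs: list[Trajectory],
    bin_size: float = 1.0,
    mode: str = "residency",
    average: str = "pooled",
    extent: tuple[float, float, float, float] | None = None,
) -> OccupancyHistogram:
    """Spatial occupancy over square bins.

    ``mode="residency"`` counts all time-downsampled points (0.1 s);
    ``mode="walking"`` first time- then distance-downsamples (1 mm), which
    removes stop bouts so only walking contributes.  ``average="pooled"``
    normalises the pooled counts of all trajectories (per-condition pooling);
    ``average="trials"`` normalises each trajectory's histogram first and
    then averages them (per-trial weighting).
    """
    if not trajs:
        raise ValueError("no trajectories given")
    if len({tr.frame for tr in trajs}) != 1:
        raise ValueError("all trajectories must share one coordinate frame")
    if mode not in ("residency", "walking"):
        raise ValueError(f"unknown histogram mode {mode!r}")
    if average not in ("pooled", "trials"):
        raise ValueError(f"unknown averaging scheme {average!r}")

    processed = []
    for tr in trajs:
        tr = downsample_time(tr, TIME_STEP_S)
        if mode == "walking":
            tr = downsample_distance(tr, DISTANCE_STEP_CM)
        processed.append(tr)

    if extent is None:
        xs = np.concatenate([tr.x for tr in processed])
        ys = np.concatenate([tr.y for tr in processed])
        # snap to the integer-bin lattice anchored at the arena center
        extent = (
            math.floor(xs.min() / bin_size) * bin_size,
            math.ceil(xs.max() / bin_size) * bin_size,
            math.floor(ys.min() / bin_size) * bin_size,
            math.ceil(ys.max() / bin_size) * bin_size,
        )
    x0, x1, y0, y1 = extent
    xedges = np.arange(x0, x1 + bin_size / 2, bin_size)
    yedges = np.arange(y0, y1 + bin_size / 2, bin_size)

    def hist(tr: Trajectory) -> np.ndarray:
        h, _, _ = np.histogram2d(tr.x, tr.y, bins=[xedges, yedges])
        return h

    if average == "pooled":
        total = sum(hist(tr) for tr in processed)
        grid = total / total.sum() if total.sum() else total
    else:
        grids = []
        for tr in processed:
            h = hist(tr)
            if h.sum():
                grids.append(h / h.sum())
        if not grids:
            raise ValueError("no occupied bins in any trial")
        grid = np.mean(grids, axis=0)
    return OccupancyHistogram(grid, xedges, yedges, bin_size,
                              processed[0].frame, mode)


# ---------------------------------------------------------------------------
# zone statistics

def fraction_in_zone(
    traj: Trajectory,
    zone: Zone,
    window: tuple[float, float] | None = None,
    dt: float = TIME_STEP_S,
) -> float:
    """Fraction of time-downsampled samples inside the (closed) zone disc."""
    tr = downsample_time(traj, dt)
    if window is not None:
        tr = tr.window(*window)
    if len(tr) == 0:
        raise ValueError("no samples in the requested window")
    return float(np.mean(zone.contains(tr.x, tr.y)))


def visited(
    traj: Trajectory,
    zone: Zone,
    window: tuple[float, float] | None = None,
    dt: float = TIME_STEP_S,
) -> bool:
    """True iff any (time-downsampled) sample in the window lies inside."""
    return fraction_in_zone(traj, zone, window, dt) > 0.0


# ---------------------------------------------------------------------------
# initial walking direction

def initial_direction(
    traj: Trajectory,
    release_point: tuple[float, float],
    t_release: float | None = None,
    window_s: float = 5.0,
) -> float | None:
    """Direction (radians) of net motion in the first ``window_s`` seconds.

    The endpoint is the last existing sample with t <= t_release + window_s
    (no interpolation); the angle is that of endpoint - release_point.
    Returns ``None`` (with a warning) when the fly has not moved, whose
    direction is undefined.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    t0 = traj.t[0] if t_release is None else t_release
    sel = np.nonzero(traj.t <= t0 + window_s)[0]
    if sel.size == 0:
        raise ValueError("no samples within the initial window")
    end = sel[-1]
    dx = traj.x[end] - release_point[0]
    dy = traj.y[end] - release_point[1]
    if dx == 0 and dy == 0:
        warnings.warn("fly stationary in initial window; direction undefined")
        return None
    return math.atan2(dy, dx)


def mean_trajectory_vector(endpoints: np.ndarray) -> tuple[float, float]:
    """Vector sum of per-fly endpoint offsets from the release point."""
    endpoints = np.asarray(endpoints, dtype=float)
    return float(endpoints[:, 0].sum()), float(endpoints[:, 1].sum())


def mean_direction(angles) -> float | None:
    """Angular component of the unit-vector average; None if degenerate."""
    angles = np.asarray(angles, dtype=float)
    c, s = np.cos(angles).mean(), np.sin(angles).mean()
    if math.hypot(c, s) < 1e-12:
        return None
    return math.atan2(s, c)


# ---------------------------------------------------------------------------
# statistical tests

def rayleigh_test(angles) -> TestResult:
    """Rayleigh test for unimodal deviation from circular uniformity.

    z = n * R**2 with R the mean resultant length; the p-value uses the
    standard Zar series approximation (so printed p's are comparable to
    the circular-statistics literature).
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size < 2:
        raise ValueError("Rayleigh test needs at least 2 angles")
    if not np.all(np.isfinite(angles)):
        raise ValueError("angles must be finite")
    z, p = pingouin.circ_rayleigh(angles)
    return TestResult("rayleigh", float(z), float(p), (angles.size,))


def two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> TestResult:
    """Two-proportion z-test with pooled variance, two-tailed normal p.

    z = (p1 - p2) / sqrt(phat (1 - phat) (1/n1 + 1/n2)) with
    phat = (k1 + k2) / (n1 + n2).
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0 or not 0 <= k <= n:
            raise ValueError("counts must satisfy 0 <= k <= n, n > 0")
    phat = (k1 + k2) / (n1 + n2)
    if phat in (0.0, 1.0):
        raise ValueError("pooled proportion is degenerate (0 or 1); z undefined")
    se = math.sqrt(phat * (1 - phat) * (1 / n1 + 1 / n2))
    z = (k1 / n1 - k2 / n2) / se
    p = 2 * stats.norm.sf(abs(z))
    return TestResult("two_proportion_z", float(z), float(p), (n1, n2))


def welch_t(a, b) -> TestResult:
    """Two-tailed Welch's t-test for unpaired samples of unequal variance."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        raise ValueError("both samples constant and equal; t undefined")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return TestResult("welch_t", float(t), float(p), (a.size, b.size))


def paired_t(a, b) -> TestResult:
    """Two-tailed paired t-test (one-sample t on the differences)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("paired t needs n >= 2")
    if np.std(a - b) == 0:
        raise ValueError("zero-variance differences; t undefined")
    t, p = stats.ttest_rel(a, b)
    return TestResult("paired_t", float(t), float(p), (a.size,))


# ---------------------------------------------------------------------------
# trail-retracing (intersection) score

def intersection_score(
    before: Trajectory,
    after: Trajectory,
    center: tuple[float, float],
    window_radius: float = 2.0,
    prox: float = 0.25,
    endpoint_metric: str = "euclidean",
) -> float:
    """Maximal extent of post-displacement retracing of the prior path.

    Both trajectories are restricted to the ``window_radius`` (cm) disc
    around ``center`` (the fly's location at displacement).  Each 'after'
    point is labeled overlapping iff some 'before' point lies closer than
    ``prox`` (cm).  The score is the maximum, over maximal contiguous runs
    of overlapping 'after' points, of the distance between the run's end
    points — Euclidean by default, along-path with
    ``endpoint_metric="path"`` — and 0 when nothing overlaps.
    """
    if len(before) == 0 or len(after) == 0:
        raise ValueError("both trajectories must be non-empty")
    if endpoint_metric not in ("euclidean", "path"):
        raise ValueError(f"unknown endpoint metric {endpoint_metric!r}")
    cx, cy = center
    b_in = np.hypot(before.x - cx, before.y - cy) <= window_radius
    a_in = np.hypot(after.x - cx, after.y - cy) <= window_radius
    bxy = before.xy[b_in]
    if bxy.shape[0] == 0 or not a_in.any():
        return 0.0
    tree = cKDTree(bxy)
    dist, _ = tree.query(after.xy)
    # runs must be contiguous in the original sample order and stay in-window
    overlap = a_in & (dist < prox)
    best = 0.0
    i = 0
    n = len(overlap)
    while i < n:
        if overlap[i]:
            j = i
            while j + 1 < n and overlap[j + 1]:
                j += 1
            if endpoint_metric == "euclidean":
                d = float(np.hypot(after.x[j] - after.x[i],
                                   after.y[j] - after.y[i]))
            else:
                d = float(np.sum(np.hypot(np.diff(after.x[i:j + 1]),
                                          np.diff(after.y[i:j + 1]))))
            best = max(best, d)
            i = j + 1
        else:
            i += 1
    return best


# ---------------------------------------------------------------------------
# end-to-end analyses

def analyze_displacement_condition(
    trials: list[tuple[Trajectory, TrialAnnotation]],
    test_window_s: float = 100.0,
    direction_window_s: float = 5.0,
    max_speed: float = 50.0,
    bin_size: float = 1.0,
) -> AnalysisReport:
    """Full displacement-experiment analysis over a batch of trials.

    Per trial: artifact removal, actual/fictive reward-zone occupancy
    fractions and visit indicators over the first ``test_window_s`` seconds
    after displacement, the initial walking direction, and the trail
    intersection score.  Per condition: paired t-test of fictive vs actual
    fractions, Rayleigh test of initial directions relative to the fictive
    zone, mean trajectory vector, pooled walking-frequency histograms in
    the fictive frame.  Across conditions: two-proportion z-tests of
    fictive- and actual-zone visit counts.  Stage failures are recorded
    per-trial without aborting the batch.
    """
    if not trials:
        raise ValueError("empty trial list")
    report = AnalysisReport(config={
        "test_window_s": test_window_s,
        "direction_window_s": direction_window_s,
        "max_speed_cm_s": max_speed,
        "bin_size_cm": bin_size,
        "time_step_s": TIME_STEP_S,
        "distance_step_cm": DISTANCE_STEP_CM,
    })
    by_cond: dict[str, dict] = {}
    test_trajs_fictive: dict[str, list[Trajectory]] = {}

    for idx, (traj, ann) in enumerate(trials):
        row: dict = {"trial": idx, "condition": ann.condition}
        try:
            clean = remove_artifacts(traj, max_speed=max_speed)
            t_dis0, t_dis1 = ann.displacement_interval
            t_end = min(t_dis1 + test_window_s, clean.t[-1])
            if t_end < t_dis1 + test_window_s:
                row["truncated_window"] = True
                report.warnings.append(
                    f"trial {idx}: recording ends {t_dis1 + test_window_s - t_end:.1f}s "
                    "before the full test window")
            window = (t_dis1, t_end)
            actual = ann.reward_zone
            fict = fictive_zone(actual, ann.displacement_vector)
            row["fraction_actual"] = fraction_in_zone(clean, actual, window)
            row["fraction_fictive"] = fraction_in_zone(clean, fict, window)
            row["visited_actual"] = row["fraction_actual"] > 0
            row["visited_fictive"] = row["fraction_fictive"] > 0

            test_seg = clean.window(*window)
            release = (float(test_seg.x[0]), float(test_seg.y[0]))
            ref = math.atan2(fict.center[1] - release[1],
                             fict.center[0] - release[0])
            ang = initial_direction(test_seg, release, window[0],
                                    direction_window_s)
            if ang is not None:
                row["direction"] = DirectionSample(ang, ref, direction_window_s)

            # retracing happens on the displaced slider surface: undo the
            # displacement on the test segment before comparing paths
            before = clean.window(clean.t[0], t_dis0)
            after_slider = to_fictive_frame(test_seg, ann.displacement_vector)
            if len(before):
                pickup = (float(before.x[-1]), float(before.y[-1]))
                row["intersection_cm"] = intersection_score(
                    before, after_slider, pickup)
            test_trajs_fictive.setdefault(ann.condition, []).append(
                to_fictive_frame(test_seg, ann.displacement_vector))
        except (ValueError, ArithmeticError) as exc:  # keep the batch going
            row["error"] = str(exc)
            report.warnings.append(f"trial {idx}: {exc}")
        report.per_trial.append(row)
        by_cond.setdefault(ann.condition, {"rows": []})["rows"].append(row)

    for cond, d in by_cond.items():
        rows = [r for r in d["rows"] if "error" not in r]
        fa = np.array([r["fraction_actual"] for r in rows])
        ff = np.array([r["fraction_fictive"] for r in rows])
        tests: dict = {}
        if len(rows) >= 2:
            try:
                tests["paired_t_fictive_vs_actual"] = paired_t(ff, fa)
            except ValueError as exc:
                report.warnings.append(f"{cond}: paired t skipped ({exc})")
            rel = [r["direction"].relative for r in rows if "direction" in r]
            if len(rel) >= 2:
                tests["rayleigh_initial_direction"] = rayleigh_test(rel)
                tests["mean_direction_rad"] = mean_direction(rel)
        report.tests[cond] = tests
        if cond in test_trajs_fictive:
            report.histograms[cond] = occupancy_histogram(
                test_trajs_fictive[cond], bin_size, mode="walking",
                average="pooled")

    conds = sorted(by_cond)
    if len(conds) == 2:
        c1, c2 = "rewarded", "non-rewarded"
        if c1 in by_cond and c2 in by_cond:
            for which in ("fictive", "actual"):
                k = {}
                n = {}
                for c in (c1, c2):
                    rows = [r for r in by_cond[c]["rows"] if "error" not in r]
                    k[c] = sum(r[f"visited_{which}"] for r in rows)
                    n[c] = len(rows)
                try:
                    report.tests[f"visits_{which}_z"] = two_proportion_z(
                        k[c1], n[c1], k[c2], n[c2])
                except ValueError as exc:
                    report.warnings.append(f"visit z-test ({which}): {exc}")
    return report


@dataclass
class PheromoneTrial:
    """One pheromone-experiment trial: a group of naive-fly trajectories."""

    trajectories: list[Trajectory]
    condition: str  # "with-emitter" | "without-emitter"


def analyze_pheromone_condition(
    trials: list[PheromoneTrial],
    zone: Zone,
    exclude_initial_s: float = 300.0,
    sample_rate_hz: float = 10.0,
    bin_size: float = 1.0,
) -> AnalysisReport:
    """Pheromone-experiment residency analysis.

    Trajectories are time-downsampled to ``sample_rate_hz`` and the first
    ``exclude_initial_s`` seconds of the test stage are discarded (the
    freshly introduced flies sit still at random places at first).  Per
    trial: pooled reward-zone occupancy fraction and a normalised residency
    histogram.  Per condition: the average of per-trial histograms.  Across
    conditions: Welch's t-test of the per-trial zone fractions.
    """
    if not trials:
        raise ValueError("empty trial list")
    report = AnalysisReport(config={
        "exclude_initial_s": exclude_initial_s,
        "sample_rate_hz": sample_rate_hz,
        "bin_size_cm": bin_size,
        "zone": {"center": list(zone.center), "radius": zone.radius},
    })
    dt = 1.0 / sample_rate_hz
    per_cond_fracs: dict[str, list[float]] = {}
    per_trial_trajs: dict[str, list[list[Trajectory]]] = {}
    for idx, trial in enumerate(trials):
        row: dict = {"trial": idx, "condition": trial.condition}
        try:
            kept: list[Trajectory] = []
            n_in = n_tot = 0
            for tr in trial.trajectories:
                t_cut = tr.t[0] + exclude_initial_s
                if t_cut >= tr.t[-1]:
                    raise ValueError(
                        "exclusion window longer than the recording")
                ds = downsample_time(tr, dt).window(t_cut, np.inf)
                kept.append(ds)
                inside = zone.contains(ds.x, ds.y)
                n_in += int(inside.sum())
                n_tot += len(ds)
            frac = n_in / n_tot
            row["fraction_in_zone"] = frac
            per_cond_fracs.setdefault(trial.condition, []).append(frac)
            per_trial_trajs.setdefault(trial.condition, []).append(kept)
        except ValueError as exc:
            row["error"] = str(exc)
            report.warnings.append(f"trial {idx}: {exc}")
        report.per_trial.append(row)

    # common grid extent over all surviving data, then one normalised
    # histogram per trial (group of flies) averaged within each condition
    all_trs = [tr for groups in per_trial_trajs.values()
               for kept in groups for tr in kept]
    if all_trs:
        xs = np.concatenate([tr.x for tr in all_trs])
        ys = np.concatenate([tr.y for tr in all_trs])
        extent = (
            math.floor(xs.min() / bin_size) * bin_size,
            math.ceil(xs.max() / bin_size) * bin_size,
            math.floor(ys.min() / bin_size) * bin_size,
            math.ceil(ys.max() / bin_size) * bin_size,
        )
        for cond, groups in per_trial_trajs.items():
            grids = [occupancy_histogram(kept, bin_size, mode="residency",
                                         average="pooled", extent=extent)
                     for kept in groups]
            report.histograms[cond] = OccupancyHistogram(
                np.mean([g.grid for g in grids], axis=0),
                grids[0].xedges, grids[0].yedges, bin_size,
                grids[0].frame, "residency")
    if len(per_cond_fracs) == 2:
        (c1, a), (c2, b) = sorted(per_cond_fracs.items())
        try:
            report.tests["zone_fraction_welch_t"] = welch_t(a, b)
            report.tests["zone_fraction_welch_t"].name = f"welch_t[{c1} vs {c2}]"
        except ValueError as exc:
            report.warnings.append(f"Welch t skipped ({exc})")
    return report
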
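"""Agent-based pheromone model of local search in an annular channel.

A single fly agent walks on a discrete 1-D lattice of integer body-length
(BL) positions wrapped around a circular channel.  Time advances in discrete
steps of ``dt`` seconds; every moving step covers one BL.  The agent starts
in *global search* (continuous forward walking) and switches permanently to
*local search* (run-and-reversal walking) upon its first reward contact.

Whenever the agent eats at an activated reward zone it pauses, deposits a
pheromone droplet at the reward position, and continues in the same
direction with a freshly drawn short run length.  Droplet odor decays
linearly from 1 to 0 over ``tau`` steps; stepping onto a droplet with
positive odor ("smelling") re-draws the run length from an odor-scaled
distribution.  When a run is exhausted the agent reverses and draws a new
run length from the wide baseline distribution.  The agent has no spatial
memory: pheromone deposits are the only carrier of location information,
which is the point of the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SimParams",
    "Droplet",
    "AgentState",
    "RewardZoneState",
    "SimRecord",
    "odor_value",
    "sample_run_length",
    "step_agent",
    "run_circling_experiment",
    "run_multi_reward_experiment",
    "compute_run_midpoints",
]

#: events, in decreasing precedence when co-occurring on one step
EATING = "eating"
SMELLING = "smelling"
REVERSAL = "reversal"

_MAX_RESAMPLE = 64  # cap on the resample-until->=1BL loop (odor -> 0 limit)


@dataclass
class SimParams:
    """Parameters of the channel model.

    Run-length distributions are Normal(mu, sigma) in BL, truncated below at
    one step length (1 BL) by resampling.  ``mu0/sigma0`` govern baseline
    reversal runs, ``mu_rew/sigma_rew`` post-eating runs, and smelling runs
    use Normal(k_mu * odor, k_sigma * odor) for the current odor value.
    Durations (``tau``, ``eat_pause``, ``refractory``, ``ap_duration``,
    ``post_ap_duration``) are in time steps of ``dt`` seconds each.
    """

    mu0: float = 80.0
    sigma0: float = 20.0
    mu_rew: float = 4.125
    sigma_rew: float = 2.625
    k_mu: float = 3.0
    k_sigma: float = 3.0
    tau: int = 500
    dt: float = 0.5
    eat_pause: int = 10
    refractory: int = 16
    circumference: int = 26
    reward_positions: tuple[int, ...] = (0, 13)
    ap_duration: int = 600
    post_ap_duration: int = 600
    n_trials: int = 6
    seed: int = 0
    deposit: bool = True

    def __post_init__(self) -> None:
        for name in ("sigma0", "sigma_rew", "k_mu", "k_sigma", "tau", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.circumference <= 0:
            raise ValueError("circumference must be > 0")
        if self.ap_duration < 0 or self.post_ap_duration < 0:
            raise ValueError("period durations must be >= 0")
        for p in self.reward_positions:
            if not 0 <= p < self.circumference:
                raise ValueError("reward positions must lie in [0, circumference)")


@dataclass
class Droplet:
    """A pheromone droplet deposited at ``position`` at time step ``t_ph``."""

    position: int
    t_ph: int


@dataclass
class AgentState:
    position: int = 0
    direction: int = 1
    mode: str = "global-search"
    run_remaining: float = math.inf
    pause_remaining: int = 0
    last_event: str | None = None


@dataclass
class RewardZoneState:
    position: int
    active: bool = True
    refractory_until: int = 0


@dataclass
class SimRecord:
    """Per-trial log: one entry per time step plus event summaries."""

    trial: int
    circumference: int
    t: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    position: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    direction: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    event: list = field(default_factory=list)
    reversals: list = field(default_factory=list)  # (t, position)
    droplets: list = field(default_factory=list)  # released during this trial
    zone_position: int | None = None


def odor_value(droplet: Droplet, t: int, tau: float) -> float:
    """Odor of ``droplet`` at time step ``t``: linear decay 1 -> 0 over ``tau``.

    Raises if the droplet is queried before its release.
    """
    if t < droplet.t_ph:
        raise ValueError(
            f"droplet queried at t={t} before its release at t_ph={droplet.t_ph}"
        )
    return float(np.clip(1.0 - (t - droplet.t_ph) / tau, 0.0, 1.0))


def sample_run_length(
    event: str,
    odor: float | None,
    params: SimParams,
    rng: np.random.Generator,
) -> float:
    """Draw a run length (BL) for the given triggering event.

    reversal -> Normal(mu0, sigma0); eating -> Normal(mu_rew, sigma_rew);
    smelling -> Normal(k_mu * odor, k_sigma * odor).  Draws are truncated
    below at one step length by resampling; after ``_MAX_RESAMPLE`` failed
    attempts (possible only when nearly all mass lies below 1 BL, i.e.
    odor -> 0) the floor value 1.0 is returned.
    """
    if event == REVERSAL:
        mu, sigma = params.mu0, params.sigma0
    elif event == EATING:
        mu, sigma = params.mu_rew, params.sigma_rew
    elif event == SMELLING:
        if odor is None:
            raise ValueError("smelling requires the current odor value")
        mu, sigma = params.k_mu * odor, params.k_sigma * odor
    else:
        raise ValueError(f"unknown run-length event kind: {event!r}")
    if sigma <= 0:
        return max(mu, 1.0)
    for _ in range(_MAX_RESAMPLE):
        r = rng.normal(mu, sigma)
        if r >= 1.0:
            return float(r)
    return 1.0


def step_agent(
    state: AgentState,
    zones: list[RewardZoneState],
    droplets: list[Droplet],
    t: int,
    params: SimParams,
    rng: np.random.Generator,
    *,
    rewarding: bool = True,
    _odor_index: dict[int, int] | None = None,
) -> tuple[AgentState, list[RewardZoneState], list[Droplet], str | None]:
    """Advance the agent by one time step; returns the triggered event, if any.

    Priority when several triggers coincide on the new position:
    eating > smelling > reversal.  ``rewarding`` gates whether zones can
    deliver reward (False outside the activation period).  ``_odor_index``
    is an optional {position: latest t_ph} cache; the freshest droplet at a
    site always carries the maximal odor, so it suffices for lookups.
    """
    if state.pause_remaining > 0:
        state.pause_remaining -= 1
        return state, zones, droplets, None

    state.position = (state.position + state.direction) % params.circumference
    pos = state.position

    zone_here = None
    if rewarding:
        for z in zones:
            if z.position == pos and z.active and t >= z.refractory_until:
                zone_here = z
                break

    if zone_here is not None:
        state.pause_remaining = params.eat_pause
        if params.deposit:
            droplets.append(Droplet(position=pos, t_ph=t))
            if _odor_index is not None:
                _odor_index[pos] = t
        state.run_remaining = sample_run_length(EATING, None, params, rng)
        zone_here.refractory_until = t + params.refractory
        state.mode = "local-search"
        state.last_event = EATING
        return state, zones, droplets, EATING

    if state.mode == "local-search":
        if _odor_index is not None:
            t_ph = _odor_index.get(pos)
            odor = odor_value(Droplet(pos, t_ph), t, params.tau) if t_ph is not None else 0.0
        else:
            odor = max(
                (odor_value(d, t, params.tau) for d in droplets if d.position == pos),
                default=0.0,
            )
        if odor > 0.0:
            state.run_remaining = sample_run_length(SMELLING, odor, params, rng)
            state.last_event = SMELLING
            return state, zones, droplets, SMELLING

        state.run_remaining -= 1.0
        if state.run_remaining <= 0.0:
            state.direction = -state.direction
            state.run_remaining = sample_run_length(REVERSAL, None, params, rng)
            state.last_event = REVERSAL
            return state, zones, droplets, REVERSAL

    return state, zones, droplets, None


def _run_trial(
    trial: int,
    state: AgentState,
    zones: list[RewardZoneState],
    droplets: list[Droplet],
    odor_index: dict[int, int],
    t0: int,
    params: SimParams,
    rng: np.random.Generator,
) -> SimRecord:
    n = params.ap_duration + params.post_ap_duration
    ts = np.arange(t0, t0 + n)
    pos = np.empty(n, dtype=int)
    dirs = np.empty(n, dtype=int)
    events: list[str | None] = []
    rec = SimRecord(trial=trial, circumference=params.circumference)
    n_drop0 = len(droplets)
    for i in range(n):
        t = t0 + i
        rewarding = i < params.ap_duration
        state, zones, droplets, ev = step_agent(
            state, zones, droplets, t, params, rng,
            rewarding=rewarding, _odor_index=odor_index,
        )
        pos[i] = state.position
        dirs[i] = state.direction
        events.append(ev)
        if ev == REVERSAL:
            rec.reversals.append((t, state.position))
    rec.t, rec.position, rec.direction, rec.event = ts, pos, dirs, events
    rec.droplets = list(droplets[n_drop0:])
    return rec


def run_circling_experiment(
    params: SimParams | None = None,
    rng: np.random.Generator | None = None,
) -> list[SimRecord]:
    """Alternating-reward protocol: ``n_trials`` trials on one agent.

    The single activation zone alternates between the two diametrically
    opposite coordinates in ``params.reward_positions`` on every trial.
    Each trial is an activation period (AP) followed by a post-AP period;
    the zone rewards only during AP.  The agent state, droplets and their
    decay clocks persist across trial boundaries.
    """
    params = params if params is not None else SimParams()
    if len(params.reward_positions) != 2:
        raise ValueError("circling protocol needs exactly 2 alternating zone positions")
    rng = rng if rng is not None else np.random.default_rng(params.seed)

    state = AgentState(
        position=int(rng.integers(params.circumference)),
        direction=int(rng.choice([-1, 1])),
    )
    droplets: list[Droplet] = []
    odor_index: dict[int, int] = {}
    records = []
    steps_per_trial = params.ap_duration + params.post_ap_duration
    for trial in range(params.n_trials):
        zone_pos = params.reward_positions[trial % 2]
        zones = [RewardZoneState(position=zone_pos)]
        rec = _run_trial(
            trial, state, zones, droplets, odor_index,
            trial * steps_per_trial, params, rng,
        )
        rec.zone_position = zone_pos
        records.append(rec)
    return records


def run_multi_reward_experiment(
    params: SimParams | None = None,
    rng: np.random.Generator | None = None,
) -> SimRecord:
    """Three-reward protocol: one trial, all zones active simultaneously.

    Defaults to a 52 BL channel with rewards at 0 and +-5 BL; each zone
    keeps its own refractory clock.
    """
    if params is None:
        params = SimParams(circumference=52, reward_positions=(0, 5, 47), n_trials=1)
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    state = AgentState(
        position=int(rng.integers(params.circumference)),
        direction=int(rng.choice([-1, 1])),
    )
    zones = [RewardZoneState(position=p) for p in params.reward_positions]
    rec = _run_trial(0, state, zones, [], {}, 0, params, rng)
    rec.zone_position = params.reward_positions[0]
    return rec


def compute_run_midpoints(record: SimRecord) -> list[float]:
    """Midpoints of the travelled arc between consecutive reversals.

    Between two reversals the agent walks unidirectionally (possibly several
    laps, pauses excluded); the midpoint is the point half the travelled arc
    beyond the first reversal, wrapped to [0, circumference).  Fewer than two
    reversals yield an empty list.
    """
    if len(record.reversals) < 2:
        return []
    C = record.circumference
    t_index = {int(t): i for i, t in enumerate(record.t)}
    mids = []
    for (t1, p1), (t2, _p2) in zip(record.reversals, record.reversals[1:]):
        i1, i2 = t_index[t1], t_index[t2]
        seg = record.position[i1 : i2 + 1]
        moved = np.count_nonzero(seg[1:] != seg[:-1])  # 1 BL per moving step
        direction = record.direction[i1]  # constant between the reversals
        mids.append(float((p1 + direction * moved / 2.0) % C))
    return mids


def replicate_circling(
    n_replicates: int,
    params: SimParams | None = None,
    seed: int | None = None,
) -> list[list[SimRecord]]:
    """Run the circling protocol on ``n_replicates`` independent agents."""
    params = params if params is not None else SimParams()
    base = params.seed if seed is None else seed
    out = []
    for i in range(n_replicates):
        rng = np.random.default_rng(base + i)
        out.append(run_circling_experiment(replace(params, seed=base + i), rng))
    return out
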
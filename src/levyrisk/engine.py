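"""Episode simulator: searcher lifetimes, captures, deaths, encounter rates.

One episode is a single searcher lifetime: the searcher starts at a uniform
position (rejection-sampled clear of predators), forages until it either
survives to the maximum search time ``T_max`` or dies on its first predator
encounter.  A batch repeats independent episodes, each with a freshly drawn
landscape, predator layout and searcher start, until the cumulative searcher-
alive time reaches a total simulated-time budget, and summarizes the raw
counts as encounter rates:

* ``eta``   -- targets captured per unit searcher-alive time,
* ``gamma`` -- predator encounters (deaths) per unit searcher-alive time,
* ``k``     -- expected predator encounters per lifetime, ``gamma * T_max``.

Seeding is hierarchical: the environment and placement streams depend only on
(batch seed, episode index), while the movement stream also depends on the
searcher strategy kind, so two strategies compared under the same batch seed
see identical landscapes episode by episode (common random numbers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernels
from .environment import Environment, EnvironmentConfig, generate_environment
from .geometry import Point2D, _dist
from .walks import WalkStrategy

_EVENT_NAMES = {_kernels.EV_CAPTURE: "capture",
                _kernels.EV_DEATH: "death",
                _kernels.EV_REGEN: "regeneration"}

# stream tags for SeedSequence-derived substreams
_ENV_STREAM = 11
_PRED_STREAM = 17
_SEARCHER_STREAM = 23
_DYNAMICS_STREAM = 29


@dataclass
class AgentState:
    """Kinematic state of a searcher or predator."""

    position: Point2D
    heading: float = 0.0
    residual_step: float = 0.0
    path_length: float = 0.0
    age: float = 0.0
    alive: bool = True
    # composite-Brownian bookkeeping
    cbw_extensive: bool = False
    length_since_capture: float = 0.0


@dataclass(frozen=True)
class EngineConfig:
    """Batch/episode parameters.

    ``total_time`` is the cumulative searcher-alive time budget over which a
    batch accumulates encounters; ``T_max`` the maximum lifetime per episode.
    ``substep_fraction`` bounds the combined displacement per moving-moving
    proximity check to that fraction of the encounter radius.  When
    ``re_randomize_predators`` is false, predator positions are drawn once
    and reused across episodes instead of being re-drawn each lifetime.
    """

    searcher_strategy: WalkStrategy = field(
        default_factory=lambda: WalkStrategy.levy(2.0))
    predator_strategy: WalkStrategy = field(
        default_factory=WalkStrategy.stationary)
    n_predators: int = 0
    T_max: float = 1.0e4
    total_time: float = 1.0e7
    substep_fraction: float = 0.2
    seed: int = 0
    re_randomize_predators: bool = True
    min_clearance: Optional[float] = None  # default: predator encounter radius

    def __post_init__(self) -> None:
        if not self.T_max > 0:
            raise ValueError("T_max must be positive")
        if self.total_time < self.T_max:
            raise ValueError("total_time must be at least T_max")
        if not (0.0 < self.substep_fraction <= 0.5):
            raise ValueError("substep_fraction must lie in (0, 0.5]")
        if self.n_predators < 0:
            raise ValueError("n_predators must be non-negative")


@dataclass(frozen=True)
class EpisodeResult:
    """Outcome of a single searcher lifetime."""

    duration: float
    n_captures: int
    died: bool
    death_time: Optional[float] = None
    events: Optional[pd.DataFrame] = None


@dataclass
class EncounterStats:
    """Encounter rates estimated from a batch of episodes.

    Per-episode arrays are kept for bootstrap confidence intervals.
    """

    eta: float
    gamma: float
    k: float
    mean_search_time: float
    T_max: float
    n_episodes: int
    total_time_observed: float
    total_captures: int
    total_deaths: int
    durations: np.ndarray
    captures: np.ndarray
    died: np.ndarray
    events: Optional[pd.DataFrame] = None

    @property
    def n_units(self) -> float:
        """Number of unit-time pieces per lifetime (unit time = 1)."""
        return self.T_max

    @classmethod
    def from_episodes(cls, durations, captures, died, T_max: float) -> "EncounterStats":
        durations = np.asarray(durations, dtype=float)
        captures = np.asarray(captures, dtype=np.int64)
        died = np.asarray(died, dtype=bool)
        total = float(durations.sum())
        n_cap = int(captures.sum())
        n_die = int(died.sum())
        eta = n_cap / total
        gamma = n_die / total
        return cls(
            eta=eta,
            gamma=gamma,
            k=gamma * T_max,
            mean_search_time=total / len(durations),
            T_max=T_max,
            n_episodes=len(durations),
            total_time_observed=total,
            total_captures=n_cap,
            total_deaths=n_die,
            durations=durations,
            captures=captures,
            died=died,
        )


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

def place_predators(cfg: EngineConfig, env: Environment,
                    rng: np.random.Generator) -> np.ndarray:
    """Initial predator positions: i.i.d. uniform on the arena, shape (N, 2)."""
    return rng.uniform(0.0, env.cfg.L, size=(cfg.n_predators, 2))


def place_searcher(
    env: Environment,
    predator_xy: np.ndarray,
    rng: np.random.Generator,
    min_clearance: Optional[float] = None,
    forced_distance: Optional[float] = None,
    max_attempts: int = 100_000,
) -> AgentState:
    """Place the searcher uniformly at random, clear of all predators.

    With ``forced_distance`` set, the searcher is instead placed exactly that
    far from one predator (chosen uniformly) while remaining at least
    ``forced_distance`` from every other, so the *nearest*-predator distance
    is controlled — the initial-distance experiment.
    """
    L = env.cfg.L
    if min_clearance is None:
        min_clearance = env.cfg.predator_encounter_radius
    px = predator_xy[:, 0] if len(predator_xy) else np.empty(0)
    py = predator_xy[:, 1] if len(predator_xy) else np.empty(0)

    def clear_of_all(x, y, d):
        for i in range(len(px)):
            if _dist(x, y, px[i], py[i], L) < d:
                return False
        return True

    if forced_distance is not None:
        if len(predator_xy) == 0:
            raise ValueError("forced_distance requires at least one predator")
        if forced_distance < min_clearance:
            raise ValueError("forced_distance must be >= min_clearance")
        for _ in range(max_attempts):
            j = int(rng.integers(len(px)))
            a = rng.uniform(-math.pi, math.pi)
            x = (px[j] + forced_distance * math.cos(a)) % L
            y = (py[j] + forced_distance * math.sin(a)) % L
            ok = True
            for i in range(len(px)):
                if i != j and _dist(x, y, px[i], py[i], L) < forced_distance:
                    ok = False
                    break
            if ok:
                return AgentState(position=Point2D(x, y))
        raise RuntimeError("could not place searcher at the forced distance")

    for _ in range(max_attempts):
        x = rng.uniform(0.0, L)
        y = rng.uniform(0.0, L)
        if clear_of_all(x, y, min_clearance):
            return AgentState(position=Point2D(x, y))
    raise RuntimeError("could not place searcher clear of predators")


# ---------------------------------------------------------------------------
# episode / batch drivers
# ---------------------------------------------------------------------------

def _strategy_scalars(s: WalkStrategy):
    return (
        s.kind_code,
        float(s.mu) if s.mu is not None else 2.0,
        float(s.l0),
        float(s.velocity),
        float(s.crw_shape) if s.crw_shape is not None else 0.0,
        float(s.giving_up_length) if s.giving_up_length is not None else 0.0,
    )


def _kernel_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def _run_kernel(env: Environment, cfg: EngineConfig, predator_xy: np.ndarray,
                searcher: AgentState, kseed: int,
                initial_heading: float = math.nan,
                record_events: bool = False,
                mutate_env: bool = False):
    ecfg = env.cfg
    tx = env.target_x if mutate_env else env.target_x.copy()
    ty = env.target_y if mutate_env else env.target_y.copy()
    tactive = env.target_active if mutate_env else env.target_active.copy()
    px = np.ascontiguousarray(predator_xy[:, 0]) if len(predator_xy) else np.empty(0)
    py = np.ascontiguousarray(predator_xy[:, 1]) if len(predator_xy) else np.empty(0)
    cap = 100_000 if record_events else 0
    ev_t = np.empty(cap)
    ev_code = np.empty(cap, dtype=np.int64)
    ev_x = np.empty(cap)
    ev_y = np.empty(cap)
    ev_aux = np.empty(cap, dtype=np.int64)
    s = _strategy_scalars(cfg.searcher_strategy)
    p = _strategy_scalars(cfg.predator_strategy)
    out = _kernels.run_episode_kernel(
        kseed, ecfg.L,
        tx, ty, tactive, env.target_patch,
        env.patch_x, env.patch_y, ecfg.patch_radius,
        env.patch_ptr, env.patch_members,
        ecfg.regeneration_path_length,
        ecfg.target_encounter_radius, ecfg.predator_encounter_radius,
        s[0], s[1], s[2], s[3], s[4], s[5],
        float(searcher.position.x), float(searcher.position.y),
        float(initial_heading),
        p[0], p[1], p[2], p[3], p[4],
        px, py,
        float(cfg.T_max), float(cfg.substep_fraction),
        record_events, ev_t, ev_code, ev_x, ev_y, ev_aux,
    )
    duration, n_captures, died, death_time, n_ev = out
    events = None
    if record_events:
        events = pd.DataFrame({
            "t": ev_t[:n_ev],
            "event": [_EVENT_NAMES[c] for c in ev_code[:n_ev]],
            "x": ev_x[:n_ev],
            "y": ev_y[:n_ev],
            "aux": ev_aux[:n_ev],
        })
    return EpisodeResult(
        duration=float(duration),
        n_captures=int(n_captures),
        died=bool(died),
        death_time=float(death_time) if died else None,
        events=events,
    )


def run_episode(
    env: Environment,
    cfg: EngineConfig,
    rng: np.random.Generator,
    *,
    searcher_start: Optional[AgentState] = None,
    initial_heading: float = math.nan,
    forced_initial_distance: Optional[float] = None,
    predator_xy: Optional[np.ndarray] = None,
    record_events: bool = False,
) -> EpisodeResult:
    """Simulate one searcher lifetime in the given environment.

    Predators and the searcher are placed with ``rng`` (or passed explicitly
    for controlled set-ups); the movement randomness is driven by a kernel
    seed drawn from the same generator, so the call is reproducible from the
    generator state.  The environment is not mutated (the kernel works on
    copies).
    """
    if predator_xy is None:
        predator_xy = place_predators(cfg, env, rng)
    else:
        predator_xy = np.atleast_2d(np.asarray(predator_xy, dtype=float))
        if predator_xy.size == 0:
            predator_xy = np.empty((0, 2))
    if searcher_start is None:
        searcher_start = place_searcher(
            env, predator_xy, rng,
            min_clearance=cfg.min_clearance,
            forced_distance=forced_initial_distance,
        )
    kseed = int(rng.integers(0, 2**31))
    return _run_kernel(env, cfg, predator_xy, searcher_start, kseed,
                       initial_heading=initial_heading,
                       record_events=record_events)


def run_batch(
    env_cfg: EnvironmentConfig,
    cfg: EngineConfig,
    *,
    forced_initial_distance: Optional[float] = None,
    record_events: bool = False,
) -> EncounterStats:
    """Accumulate episodes until the searcher-alive time reaches the budget.

    Every episode draws a fresh landscape, predator layout (unless
    ``re_randomize_predators`` is off) and searcher start from streams
    derived deterministically from ``cfg.seed`` and the episode index.
    """
    durations = []
    captures = []
    died_flags = []
    all_events = []
    total = 0.0
    ep = 0
    strat_code = cfg.searcher_strategy.kind_code
    fixed_predators: Optional[np.ndarray] = None
    while total < cfg.total_time:
        env_rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, _ENV_STREAM, ep]))
        env = generate_environment(env_cfg, env_rng)
        if cfg.re_randomize_predators or fixed_predators is None:
            pred_rng = np.random.default_rng(
                np.random.SeedSequence([cfg.seed, _PRED_STREAM, ep]))
            predator_xy = place_predators(cfg, env, pred_rng)
            if not cfg.re_randomize_predators:
                fixed_predators = predator_xy
        else:
            predator_xy = fixed_predators
        searcher_rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, _SEARCHER_STREAM, ep]))
        searcher = place_searcher(
            env, predator_xy, searcher_rng,
            min_clearance=cfg.min_clearance,
            forced_distance=forced_initial_distance,
        )
        kseed = _kernel_seed(
            np.random.SeedSequence([cfg.seed, _DYNAMICS_STREAM, strat_code, ep]))
        res = _run_kernel(env, cfg, predator_xy, searcher, kseed,
                          record_events=record_events)
        durations.append(res.duration)
        captures.append(res.n_captures)
        died_flags.append(res.died)
        if record_events and res.events is not None:
            ev = res.events.copy()
            ev.insert(0, "episode", ep)
            all_events.append(ev)
        total += res.duration
        ep += 1
    stats = EncounterStats.from_episodes(durations, captures, died_flags, cfg.T_max)
    if record_events:
        stats.events = pd.concat(all_events, ignore_index=True) if all_events \
            else pd.DataFrame(columns=["episode", "t", "event", "x", "y", "aux"])
    return stats


def with_strategy(cfg: EngineConfig, strategy: WalkStrategy) -> EngineConfig:
    """A copy of ``cfg`` with a different searcher strategy (same seed, so the
    two batches see matched environments episode by episode)."""
    return replace(cfg, searcher_strategy=strategy)
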
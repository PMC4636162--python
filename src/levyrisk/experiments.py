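"""Parameter-grid experiments: relative fitness and encounter-rate curves.

Each grid cell simulates a focal searcher strategy (a Levy exponent ``mu``, a
CRW shape parameter, or a CBW giving-up length) against the Brownian-walk
baseline under a given predator count and speed ratio, with common random
numbers: both strategies see the same sequence of landscapes and predator
layouts, which removes most of the between-strategy layout noise from the
ratios.  Confidence intervals come from an episode-level bootstrap.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import EncounterStats, EngineConfig, run_batch
from .environment import EnvironmentConfig
from .fitness import relative_fitness_type1, relative_fitness_type2
from .walks import WalkStrategy

logger = logging.getLogger(__name__)

PREDATOR_KINDS = ("stationary", "levy_mu2", "brownian")


@dataclass(frozen=True)
class ExperimentGrid:
    """A sweep over searcher parameter x predator count x predator speed.

    ``searcher_param`` selects the focal family: ``"mu"`` (Levy exponent),
    ``"crw_shape"`` or ``"giving_up_length"``.  A speed ratio of 0 forces
    sit-and-wait (stationary) predators regardless of ``predator_kind``.
    """

    searcher_param: str = "mu"
    searcher_param_values: Sequence[float] = field(
        default_factory=lambda: tuple(np.round(np.arange(1.1, 3.01, 0.1), 2)))
    predator_counts: Sequence[int] = (0, 30, 60, 90, 120)
    predator_speed_ratios: Sequence[float] = (0.0,)
    predator_kind: str = "levy_mu2"
    total_time: float = 1.0e6
    T_max: float = 1.0e4
    n_boot: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.searcher_param not in ("mu", "crw_shape", "giving_up_length"):
            raise ValueError(f"unknown searcher_param {self.searcher_param!r}")
        if self.predator_kind not in PREDATOR_KINDS:
            raise ValueError(f"unknown predator_kind {self.predator_kind!r}")
        if not self.searcher_param_values or not self.predator_counts \
                or not self.predator_speed_ratios:
            raise ValueError("grids must be non-empty")
        for v in self.predator_speed_ratios:
            if v < 0:
                raise ValueError("speed ratios must be non-negative")


def searcher_strategy(param: str, value: float, velocity: float = 1.0) -> WalkStrategy:
    if param == "mu":
        return WalkStrategy.levy(float(value), velocity=velocity)
    if param == "crw_shape":
        return WalkStrategy.crw(float(value), velocity=velocity)
    if param == "giving_up_length":
        return WalkStrategy.cbw(float(value), velocity=velocity)
    raise ValueError(param)


def predator_strategy(kind: str, speed_ratio: float, v_s: float = 1.0) -> WalkStrategy:
    if speed_ratio == 0.0 or kind == "stationary":
        return WalkStrategy.stationary()
    v = speed_ratio * v_s
    if kind == "levy_mu2":
        return WalkStrategy.levy(2.0, velocity=v)
    if kind == "brownian":
        return WalkStrategy.brownian(velocity=v)
    raise ValueError(kind)


def _cell_seed(root: int, *idx: int) -> int:
    return int(np.random.SeedSequence([root, *idx]).generate_state(
        1, dtype=np.uint32)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ratio_ci(
    stats_a: EncounterStats,
    stats_b: EncounterStats,
    which: str,
    rng: np.random.Generator,
    n_boot: int = 1000,
    level: float = 0.95,
):
    """Percentile bootstrap CI of a ratio of batch statistics.

    ``which`` is one of ``"eta"``, ``"gamma"``, ``"phi_I"``, ``"phi_II"``,
    ``"tbar"``.  Episodes are resampled independently within each batch.
    Replicates where the denominator rate is zero are dropped (they carry no
    ratio information); if all are degenerate the CI is (nan, nan).
    """
    ia = rng.integers(0, stats_a.n_episodes, size=(n_boot, stats_a.n_episodes))
    ib = rng.integers(0, stats_b.n_episodes, size=(n_boot, stats_b.n_episodes))
    dur_a = stats_a.durations[ia].sum(axis=1)
    dur_b = stats_b.durations[ib].sum(axis=1)
    eta_a = stats_a.captures[ia].sum(axis=1) / dur_a
    eta_b = stats_b.captures[ib].sum(axis=1) / dur_b
    gam_a = stats_a.died.astype(np.int64)[ia].sum(axis=1) / dur_a
    gam_b = stats_b.died.astype(np.int64)[ib].sum(axis=1) / dur_b
    T = stats_a.T_max
    with np.errstate(divide="ignore", invalid="ignore"):
        if which == "eta":
            vals = eta_a / eta_b
            ok = eta_b > 0
        elif which == "gamma":
            vals = gam_a / gam_b
            ok = gam_b > 0
        elif which == "phi_I":
            vals = relative_fitness_type1(eta_a, gam_a * T, np.where(eta_b > 0, eta_b, np.nan), gam_b * T)
            ok = eta_b > 0
        elif which == "phi_II":
            vals = relative_fitness_type2(eta_a, gam_a * T, np.where(eta_b > 0, eta_b, np.nan), gam_b * T)
            ok = eta_b > 0
        elif which == "tbar":
            vals = (dur_a / stats_a.n_episodes) / (dur_b / stats_b.n_episodes)
            ok = np.ones_like(vals, dtype=bool)
        else:
            raise ValueError(which)
    vals = np.asarray(vals, dtype=float)[ok]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan"), float("nan")
    alpha = (1.0 - level) / 2.0
    return (float(np.quantile(vals, alpha)), float(np.quantile(vals, 1.0 - alpha)))


# ---------------------------------------------------------------------------
# cell and grid runners
# ---------------------------------------------------------------------------

def run_cell(
    focal: WalkStrategy,
    n_predators: int,
    pred_strategy: WalkStrategy,
    env_cfg: EnvironmentConfig,
    total_time: float,
    T_max: float,
    cell_seed: int,
    n_boot: int = 1000,
    baseline: Optional[WalkStrategy] = None,
    forced_initial_distance: Optional[float] = None,
) -> dict:
    """Run one grid cell: focal strategy and BW baseline on matched seeds."""
    if baseline is None:
        baseline = WalkStrategy.brownian(velocity=focal.velocity)
    cfg = EngineConfig(
        searcher_strategy=focal,
        predator_strategy=pred_strategy,
        n_predators=n_predators,
        T_max=T_max,
        total_time=total_time,
        seed=cell_seed,
    )
    t0 = time.perf_counter()
    stats_f = run_batch(env_cfg, cfg,
                        forced_initial_distance=forced_initial_distance)
    stats_b = run_batch(env_cfg, replace(cfg, searcher_strategy=baseline),
                        forced_initial_distance=forced_initial_distance)
    boot_rng = np.random.default_rng(np.random.SeedSequence([cell_seed, 101]))
    row = {
        "n_predators": n_predators,
        "v_ratio": (pred_strategy.velocity / focal.velocity
                    if focal.velocity else 0.0),
        "eta": stats_f.eta,
        "gamma": stats_f.gamma,
        "k": stats_f.k,
        "eta_bw": stats_b.eta,
        "gamma_bw": stats_b.gamma,
        "k_bw": stats_b.k,
        "tbar": stats_f.mean_search_time,
        "tbar_bw": stats_b.mean_search_time,
        "n_episodes": stats_f.n_episodes,
        "n_episodes_bw": stats_b.n_episodes,
        "seed": cell_seed,
    }
    if stats_b.eta > 0:
        row["eta_ratio"] = stats_f.eta / stats_b.eta
        row["phi_ratio_I"] = relative_fitness_type1(
            stats_f.eta, stats_f.k, stats_b.eta, stats_b.k)
        row["phi_ratio_II"] = relative_fitness_type2(
            stats_f.eta, stats_f.k, stats_b.eta, stats_b.k)
    else:
        row["eta_ratio"] = row["phi_ratio_I"] = row["phi_ratio_II"] = float("nan")
    row["gamma_ratio"] = (stats_f.gamma / stats_b.gamma
                          if stats_b.gamma > 0 else float("nan"))
    row["tbar_ratio"] = stats_f.mean_search_time / stats_b.mean_search_time
    for which, name in (("gamma", "gamma_ratio"), ("eta", "eta_ratio"),
                        ("phi_I", "phi_ratio_I"), ("phi_II", "phi_ratio_II")):
        lo, hi = bootstrap_ratio_ci(stats_f, stats_b, which, boot_rng, n_boot)
        row[f"{name}_ci_lo"] = lo
        row[f"{name}_ci_hi"] = hi
    row["_stats_focal"] = stats_f
    row["_stats_baseline"] = stats_b
    logger.info("cell Np=%d v=%.2g done in %.1fs (%d+%d episodes)",
                n_predators, pred_strategy.velocity, time.perf_counter() - t0,
                stats_f.n_episodes, stats_b.n_episodes)
    return row


def run_grid(grid: ExperimentGrid,
             env_cfg: Optional[EnvironmentConfig] = None) -> pd.DataFrame:
    """Run every cell of the grid; per-cell failures are recorded, not fatal.

    Returns a tidy frame, one row per (searcher value, predator count, speed
    ratio), with encounter rates for the focal strategy and the BW baseline,
    relative fitness under both life cycles, and bootstrap CIs.
    """
    env_cfg = env_cfg or EnvironmentConfig()
    rows = []
    for iv, value in enumerate(grid.searcher_param_values):
        for inp, n_p in enumerate(grid.predator_counts):
            for ir, ratio in enumerate(grid.predator_speed_ratios):
                cell_seed = _cell_seed(grid.seed, iv, inp, ir)
                try:
                    row = run_cell(
                        searcher_strategy(grid.searcher_param, value),
                        n_p,
                        predator_strategy(grid.predator_kind, ratio),
                        env_cfg, grid.total_time, grid.T_max,
                        cell_seed, grid.n_boot)
                    row.pop("_stats_focal")
                    row.pop("_stats_baseline")
                    row[grid.searcher_param] = value
                    row["v_ratio"] = ratio
                    row["error"] = ""
                except Exception as exc:  # cell failure is not fatal
                    logger.exception("cell failed: %s=%s Np=%d", grid.searcher_param,
                                     value, n_p)
                    row = {grid.searcher_param: value, "n_predators": n_p,
                           "v_ratio": ratio, "seed": cell_seed, "error": str(exc)}
                rows.append(row)
    df = pd.DataFrame(rows)
    lead = [grid.searcher_param, "n_predators", "v_ratio"]
    return df[lead + [c for c in df.columns if c not in lead]]


def encounter_rate_curves(
    mu_values: Sequence[float],
    predator_counts: Sequence[int] = (30, 120),
    speed_ratio: float = 0.0,
    predator_kind: str = "levy_mu2",
    env_cfg: Optional[EnvironmentConfig] = None,
    total_time: float = 1.0e6,
    T_max: float = 1.0e4,
    seed: int = 0,
    n_boot: int = 1000,
) -> pd.DataFrame:
    """eta_LW/eta_BW and gamma_LW/gamma_BW as functions of mu, per predator
    density — the density-invariance comparison of the relative predator-
    encounter rate."""
    grid = ExperimentGrid(
        searcher_param="mu",
        searcher_param_values=tuple(mu_values),
        predator_counts=tuple(predator_counts),
        predator_speed_ratios=(speed_ratio,),
        predator_kind=predator_kind,
        total_time=total_time,
        T_max=T_max,
        n_boot=n_boot,
        seed=seed,
    )
    df = run_grid(grid, env_cfg)
    keep = ["mu", "n_predators", "v_ratio", "eta_ratio", "eta_ratio_ci_lo",
            "eta_ratio_ci_hi", "gamma_ratio", "gamma_ratio_ci_lo",
            "gamma_ratio_ci_hi", "k_bw", "seed", "error"]
    return df[[c for c in keep if c in df.columns]]


def initial_distance_experiment(
    d_values: Sequence[float],
    mu_values: Sequence[float],
    n_predators: int = 100,
    env_cfg: Optional[EnvironmentConfig] = None,
    total_time: float = 1.0e6,
    T_max: float = 1.0e4,
    seed: int = 0,
    n_boot: int = 1000,
) -> pd.DataFrame:
    """gamma_LW/gamma_BW versus the enforced initial nearest-predator
    distance, with sit-and-wait predators."""
    env_cfg = env_cfg or EnvironmentConfig()
    rows = []
    for idx_d, d in enumerate(d_values):
        if not d > 0:
            raise ValueError("initial distances must be positive")
        for idx_m, mu in enumerate(mu_values):
            cell_seed = _cell_seed(seed, idx_d, idx_m)
            row = run_cell(
                WalkStrategy.levy(float(mu)),
                n_predators,
                WalkStrategy.stationary(),
                env_cfg, total_time, T_max, cell_seed, n_boot,
                forced_initial_distance=float(d))
            row.pop("_stats_focal")
            row.pop("_stats_baseline")
            row["mu"] = mu
            row["d_n"] = d
            rows.append(row)
    df = pd.DataFrame(rows)
    lead = ["d_n", "mu", "n_predators"]
    return df[lead + [c for c in df.columns if c not in lead]]


def write_outputs(df: pd.DataFrame, outdir, name: str, metadata: dict) -> None:
    """CSV result table plus a JSON run-metadata sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df.to_csv(outdir / f"{name}.csv", index=False)
    meta = dict(metadata)
    meta.setdefault("package", "levyrisk")
    with open(outdir / f"{name}.meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
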
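"""Patchy target landscape: generation, depletion and regeneration.

Targets are points grouped into circular patches on the torus.  A target is
captured (depleted) when the searcher passes within the target encounter
radius; every time the searcher's cumulative path length crosses a multiple of
the regeneration path length, all currently depleted targets are restored at
freshly drawn uniform positions within their original patches, so the target
density returns to its nominal value while the patch structure is preserved.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .geometry import Point2D, Torus, torus_distance


@dataclass(frozen=True)
class EnvironmentConfig:
    """Arena and target-field parameters.

    Defaults are the sparse patchy landscape used throughout: a 500 x 500
    periodic arena with 1000 targets spread over 50 patches of radius 10
    (20 targets per patch on average), target regeneration every 500 units of
    searcher path length, and unit encounter radii (body plus perception
    radius folded into a single sum) for both targets and predators.  The
    resulting mean free paths are lambda_target = 125 and lambda_patch = 2500.
    """

    L: float = 500.0
    n_targets: int = 1000
    n_patches: int = 50
    patch_radius: float = 10.0
    regeneration_path_length: float = 500.0
    target_encounter_radius: float = 1.0
    predator_encounter_radius: float = 1.0

    def __post_init__(self) -> None:
        if not self.L > 0:
            raise ValueError("arena side L must be positive")
        if self.n_patches < 1 or self.n_targets < self.n_patches:
            raise ValueError("need n_targets >= n_patches >= 1")
        for name in ("patch_radius", "regeneration_path_length",
                     "target_encounter_radius", "predator_encounter_radius"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def torus(self) -> Torus:
        return Torus(self.L)


@dataclass(frozen=True)
class Patch:
    center: Point2D
    radius: float


class Environment:
    """Mutable snapshot of the target landscape.

    Holds patch centres and target positions as numpy arrays (the engine
    kernels operate on these directly), the active/depleted flags, and the
    regeneration bookkeeping keyed to the searcher's path-length odometer.
    """

    def __init__(
        self,
        cfg: EnvironmentConfig,
        patch_xy: np.ndarray,
        target_xy: np.ndarray,
        target_patch: np.ndarray,
        target_active: np.ndarray | None = None,
    ) -> None:
        self.cfg = cfg
        self.patch_x = np.ascontiguousarray(patch_xy[:, 0], dtype=np.float64)
        self.patch_y = np.ascontiguousarray(patch_xy[:, 1], dtype=np.float64)
        self.target_x = np.ascontiguousarray(target_xy[:, 0], dtype=np.float64)
        self.target_y = np.ascontiguousarray(target_xy[:, 1], dtype=np.float64)
        self.target_patch = np.ascontiguousarray(target_patch, dtype=np.int64)
        if target_active is None:
            target_active = np.ones(len(self.target_x), dtype=np.bool_)
        self.target_active = np.ascontiguousarray(target_active, dtype=np.bool_)
        if len(self.patch_x) != cfg.n_patches or len(self.target_x) != cfg.n_targets:
            raise ValueError("array sizes inconsistent with configuration")
        # CSR layout of targets grouped by patch, for the engine's patch prefilter
        order = np.argsort(self.target_patch, kind="stable")
        counts = np.bincount(self.target_patch, minlength=cfg.n_patches)
        self.patch_ptr = np.concatenate(([0], np.cumsum(counts))).astype(np.int64)
        self.patch_members = order.astype(np.int64)
        # regeneration / audit bookkeeping
        self._next_regen = cfg.regeneration_path_length
        self._last_odometer = 0.0
        self.depletion_log: List[Tuple[int, float]] = []

    # -- basic views --------------------------------------------------------
    @property
    def n_active(self) -> int:
        return int(self.target_active.sum())

    @property
    def patches(self) -> List[Patch]:
        return [
            Patch(Point2D(x, y), self.cfg.patch_radius)
            for x, y in zip(self.patch_x, self.patch_y)
        ]

    def target_position(self, target_id: int) -> Point2D:
        return Point2D(self.target_x[target_id], self.target_y[target_id])

    # -- depletion / regeneration ------------------------------------------
    def deplete_target(self, target_id: int, odometer: float = 0.0) -> None:
        """Mark a captured target as depleted; double capture is an error."""
        if not self.target_active[target_id]:
            raise ValueError(f"target {target_id} is already depleted")
        self.target_active[target_id] = False
        self.depletion_log.append((int(target_id), float(odometer)))

    def regenerate_targets(self, searcher_path_length: float, rng: np.random.Generator) -> int:
        """Apply the regeneration rule up to the given odometer reading.

        Each time the odometer crosses a multiple of the regeneration path
        length, every depleted target is restored at a new uniform position
        within its original patch.  The odometer must be non-decreasing across
        calls.  Returns the number of regeneration events applied.
        """
        if searcher_path_length < self._last_odometer:
            raise ValueError("searcher path length must be non-decreasing")
        self._last_odometer = float(searcher_path_length)
        events = 0
        while searcher_path_length >= self._next_regen:
            inactive = np.flatnonzero(~self.target_active)
            if inactive.size:
                pid = self.target_patch[inactive]
                r = self.cfg.patch_radius * np.sqrt(rng.random(inactive.size))
                a = rng.uniform(-math.pi, math.pi, inactive.size)
                self.target_x[inactive] = (self.patch_x[pid] + r * np.cos(a)) % self.cfg.L
                self.target_y[inactive] = (self.patch_y[pid] + r * np.sin(a)) % self.cfg.L
                self.target_active[inactive] = True
            self._next_regen += self.cfg.regeneration_path_length
            events += 1
        return events

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        """Snapshot (patches, targets, flags) as JSON for reproducibility."""
        return json.dumps(
            {
                "config": {
                    "L": self.cfg.L,
                    "n_targets": self.cfg.n_targets,
                    "n_patches": self.cfg.n_patches,
                    "patch_radius": self.cfg.patch_radius,
                    "regeneration_path_length": self.cfg.regeneration_path_length,
                    "target_encounter_radius": self.cfg.target_encounter_radius,
                    "predator_encounter_radius": self.cfg.predator_encounter_radius,
                },
                "patch_x": self.patch_x.tolist(),
                "patch_y": self.patch_y.tolist(),
                "target_x": self.target_x.tolist(),
                "target_y": self.target_y.tolist(),
                "target_patch": self.target_patch.tolist(),
                "target_active": self.target_active.astype(int).tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Environment":
        d = json.loads(text)
        cfg = EnvironmentConfig(**d["config"])
        patch_xy = np.column_stack([d["patch_x"], d["patch_y"]])
        target_xy = np.column_stack([d["target_x"], d["target_y"]])
        return cls(
            cfg,
            patch_xy,
            target_xy,
            np.asarray(d["target_patch"]),
            np.asarray(d["target_active"], dtype=bool),
        )

    # -- validation helper used in tests ------------------------------------
    def targets_within_patches(self, tol: float = 1e-9) -> bool:
        t = self.cfg.torus
        for i in range(self.cfg.n_targets):
            p = self.target_patch[i]
            d = torus_distance(
                (self.target_x[i], self.target_y[i]),
                (self.patch_x[p], self.patch_y[p]),
                t,
            )
            if d > self.cfg.patch_radius + tol:
                return False
        return True


def generate_environment(cfg: EnvironmentConfig, rng: np.random.Generator) -> Environment:
    """Draw a fresh landscape: patch centres i.i.d. uniform on the arena, each
    target assigned to a uniformly random patch and placed uniformly within
    the patch disk.  All targets start active."""
    patch_xy = rng.uniform(0.0, cfg.L, size=(cfg.n_patches, 2))
    target_patch = rng.integers(0, cfg.n_patches, size=cfg.n_targets)
    r = cfg.patch_radius * np.sqrt(rng.random(cfg.n_targets))
    a = rng.uniform(-math.pi, math.pi, cfg.n_targets)
    tx = (patch_xy[target_patch, 0] + r * np.cos(a)) % cfg.L
    ty = (patch_xy[target_patch, 1] + r * np.sin(a)) % cfg.L
    return Environment(cfg, patch_xy, np.column_stack([tx, ty]), target_patch)


def mean_free_path(L: float, R: float, N: float) -> float:
    """Mean free path ``lambda = L**2 / (2 R N)`` between N objects of
    encounter distance R in a 2-D arena of side L."""
    if not (L > 0 and R > 0 and N > 0):
        raise ValueError("L, R and N must all be positive")
    return L * L / (2.0 * R * N)
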
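"""Ideal-gas encounter-rate benchmarks.

Closed-form 2-D encounter rates for straight-line ("ideal gas") movers, used
as independent oracles for the simulation engine:

* a stationary searcher among ballistic predators of speed ``v_p`` and number
  density ``rho`` is encountered at rate ``2 rho R v_p``;
* a ballistic searcher among ballistic predators of equal speed ``v`` is
  encountered at rate ``8 rho R v / pi``;

so the equal-speed/stationary ratio is ``4 / pi``.  Only these two printed
special cases are provided; the general two-speed kernel (an elliptic
integral over the relative-speed distribution) is deliberately not
implemented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class IdealGasSetting:
    """Parameters of the ideal-gas encounter problem."""

    rho: float  # predator number density, count per unit area
    R: float  # encounter distance
    v_s: float  # searcher speed
    v_p: float  # predator speed

    def __post_init__(self) -> None:
        if self.rho < 0 or self.R < 0 or self.v_s < 0 or self.v_p < 0:
            raise ValueError("all parameters must be non-negative")
        if self.v_s == 0 and self.v_p == 0:
            raise ValueError("at least one of the speeds must be positive")


def rate_stationary_searcher(rho: float, R: float, v_p: float) -> float:
    """Encounter rate ``2 rho R v_p`` of a stationary searcher among
    straight-moving predators of speed ``v_p``."""
    if rho < 0 or R < 0 or v_p < 0:
        raise ValueError("inputs must be non-negative")
    return 2.0 * rho * R * v_p


def rate_equal_speeds(rho: float, R: float, v: float) -> float:
    """Encounter rate ``8 rho R v / pi`` when searcher and predators move
    ballistically at the same speed ``v``."""
    if rho < 0 or R < 0 or v < 0:
        raise ValueError("inputs must be non-negative")
    return 8.0 * rho * R * v / math.pi
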
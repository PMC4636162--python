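"""Movement strategies: step-length and turning-angle samplers.

A strategy is a rule for producing the next straight-line move of an agent.
Supported kinds:

``levy``
    Levy walk.  Step lengths follow a power law ``P(l) ~ l**-mu`` with
    ``1 < mu <= 3`` and minimum step ``l0``, sampled by inverse transform
    ``l = l0 * u**(1/(1-mu))`` for ``u`` uniform on (0, 1].  ``mu -> 1``
    approaches ballistic motion, ``mu >= 3`` is effectively diffusive.
``brownian``
    Thin-tailed walk: step lengths drawn from Normal(mean ``l0``, variance 1)
    conditioned on positivity (negative draws are rejected and redrawn).
``crw``
    Correlated random walk: constant step ``l0`` with wrapped-Cauchy turning
    angles of mean resultant length ``crw_shape`` (0 = uniform turning,
    1 = straight line).
``cbw``
    Composite Brownian walk: two Brownian modes, intensive (step scale
    ``l0``) entered on target capture, switched to extensive (step scale
    ``10*l0``) after travelling ``giving_up_length`` without a capture.
``ballistic``
    Straight-line motion that never turns; the analytic ideal-gas benchmark
    mover.
``stationary``
    Never moves (``velocity = 0``); the sit-and-wait predator.

After each completed step the Levy/Brownian/CBW walker turns by an angle
uniform on [-pi, pi].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

VALID_KINDS = ("stationary", "levy", "brownian", "crw", "cbw", "ballistic")

# integer codes shared with the numba kernels
KIND_CODES = {k: i for i, k in enumerate(VALID_KINDS)}

#: step-length scale of the extensive CBW mode, in units of l0
CBW_EXTENSIVE_SCALE = 10.0


@dataclass(frozen=True)
class WalkStrategy:
    """A searcher's or predator's movement rule."""

    kind: str
    mu: Optional[float] = None
    l0: float = 1.0
    velocity: float = 1.0
    crw_shape: Optional[float] = None
    giving_up_length: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown strategy kind {self.kind!r}")
        if not self.l0 > 0:
            raise ValueError("minimum step length l0 must be positive")
        if self.velocity < 0:
            raise ValueError("velocity must be non-negative")
        if self.kind == "stationary":
            if self.velocity != 0:
                raise ValueError("stationary strategy requires velocity = 0")
        elif self.velocity == 0:
            raise ValueError(f"{self.kind} strategy requires velocity > 0")
        if self.kind == "levy":
            if self.mu is None or not (1.0 < self.mu <= 3.0):
                raise ValueError("levy strategy requires 1 < mu <= 3")
        if self.kind == "crw":
            if self.crw_shape is None or not (0.0 <= self.crw_shape <= 1.0):
                raise ValueError("crw strategy requires crw_shape in [0, 1]")
        if self.kind == "cbw":
            if self.giving_up_length is None or not self.giving_up_length > 0:
                raise ValueError("cbw strategy requires giving_up_length > 0")

    # -- convenience constructors ------------------------------------------
    @classmethod
    def levy(cls, mu: float, l0: float = 1.0, velocity: float = 1.0) -> "WalkStrategy":
        return cls(kind="levy", mu=mu, l0=l0, velocity=velocity)

    @classmethod
    def brownian(cls, l0: float = 1.0, velocity: float = 1.0) -> "WalkStrategy":
        return cls(kind="brownian", l0=l0, velocity=velocity)

    @classmethod
    def stationary(cls) -> "WalkStrategy":
        return cls(kind="stationary", velocity=0.0)

    @classmethod
    def crw(cls, crw_shape: float, l0: float = 1.0, velocity: float = 1.0) -> "WalkStrategy":
        return cls(kind="crw", crw_shape=crw_shape, l0=l0, velocity=velocity)

    @classmethod
    def cbw(cls, giving_up_length: float, l0: float = 1.0, velocity: float = 1.0) -> "WalkStrategy":
        return cls(kind="cbw", giving_up_length=giving_up_length, l0=l0, velocity=velocity)

    @classmethod
    def ballistic(cls, velocity: float = 1.0, l0: float = 1.0) -> "WalkStrategy":
        return cls(kind="ballistic", l0=l0, velocity=velocity)

    @property
    def kind_code(self) -> int:
        return KIND_CODES[self.kind]


def sample_levy_step(u, mu: float, l0: float = 1.0):
    """Inverse-transform power-law step: ``l = l0 * u**(1/(1-mu))``.

    ``u`` is a uniform variate on (0, 1] (scalar or array); the result has
    survival function ``P(l > x) = (x/l0)**(1-mu)`` for ``x >= l0``.
    """
    if not (1.0 < mu <= 3.0):
        raise ValueError(f"mu must lie in (1, 3], got {mu}")
    if not l0 > 0:
        raise ValueError("l0 must be positive")
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr <= 0.0) or np.any(u_arr > 1.0):
        raise ValueError("u must lie in (0, 1] (u = 0 is excluded)")
    out = l0 * u_arr ** (1.0 / (1.0 - mu))
    return float(out) if np.isscalar(u) or out.ndim == 0 else out


def sample_brownian_step(rng: np.random.Generator, l0: float = 1.0) -> float:
    """Positive step length from Normal(mean l0, variance 1) truncated at 0."""
    while True:
        x = rng.normal(l0, 1.0)
        if x > 0.0:
            return float(x)


def sample_turn_angle(rng: np.random.Generator) -> float:
    """Turning angle uniform on [-pi, pi]; new heading = old heading + angle."""
    return float(rng.uniform(-math.pi, math.pi))


def sample_crw_turn(rng: np.random.Generator, crw_shape: float) -> float:
    """Wrapped-Cauchy turning angle centred on 0 with mean resultant length
    ``crw_shape``; 0 reduces to uniform turning, 1 to straight-line motion."""
    if not (0.0 <= crw_shape <= 1.0):
        raise ValueError(f"crw_shape must lie in [0, 1], got {crw_shape}")
    if crw_shape >= 1.0:
        return 0.0
    u = rng.random()
    f = (1.0 - crw_shape) / (1.0 + crw_shape)
    return 2.0 * math.atan(f * math.tan(math.pi * (u - 0.5)))


def next_move(state, strategy: WalkStrategy, rng: np.random.Generator) -> Tuple[float, float]:
    """Draw the agent's next straight-line segment: ``(step length, heading)``.

    ``state`` carries the current heading and, for CBW, the mode bookkeeping
    (``cbw_extensive`` flag and ``length_since_capture`` odometer); the mode
    switch to extensive is applied here once the giving-up length is exceeded
    without a capture.  Stationary agents never move and raise ``ValueError``.
    """
    kind = strategy.kind
    if kind == "stationary":
        raise ValueError("stationary agents never move")
    if kind == "levy":
        u = rng.random()
        while u <= 0.0:
            u = rng.random()
        length = sample_levy_step(u, strategy.mu, strategy.l0)
        heading = state.heading + sample_turn_angle(rng)
    elif kind == "brownian":
        length = sample_brownian_step(rng, strategy.l0)
        heading = state.heading + sample_turn_angle(rng)
    elif kind == "crw":
        length = strategy.l0
        heading = state.heading + sample_crw_turn(rng, strategy.crw_shape)
    elif kind == "cbw":
        if state.length_since_capture > strategy.giving_up_length:
            state.cbw_extensive = True
        scale = CBW_EXTENSIVE_SCALE * strategy.l0 if state.cbw_extensive else strategy.l0
        length = scale * sample_brownian_step(rng, 1.0)
        heading = state.heading + sample_turn_angle(rng)
    elif kind == "ballistic":
        length = strategy.l0
        heading = state.heading
    else:  # pragma: no cover
        raise ValueError(kind)
    return float(length), float(heading)
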
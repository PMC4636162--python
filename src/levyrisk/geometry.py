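"""Periodic-boundary (torus) geometry and continuous encounter detection.

The simulation arena is the half-open square ``[0, L) x [0, L)`` with periodic
boundary conditions, i.e. a flat torus.  Distances use the minimum-image
convention, and encounters between a moving point and a detection disk are
resolved *continuously* by exact segment-circle intersection, so that a long
ballistic step cannot tunnel through a disk between discrete position updates.

A straight segment longer than ``L/4`` is split internally into sub-segments of
at most ``L/4`` and the minimum image is taken per sub-segment; together with
the requirement ``radius < L/4`` this keeps the nearest periodic image of the
circle centre unambiguous along each piece.

The scalar workhorses are numba-compiled and shared with the episode engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Tuple

from numba import njit


class Point2D(NamedTuple):
    """A position on the arena, in length units."""

    x: float
    y: float


@dataclass(frozen=True)
class Torus:
    """Flat torus of side ``L`` (the arena is ``[0, L)^2``)."""

    L: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.L) and self.L > 0):
            raise ValueError(f"torus side L must be finite and positive, got {self.L}")


@njit(cache=True, inline="always")
def _min_image(d, L):
    """Signed displacement folded into [-L/2, L/2)."""
    return d - L * math.floor(d / L + 0.5)


@njit(cache=True, inline="always")
def _wrap1(x, L):
    r = x - L * math.floor(x / L)
    if r >= L:  # guard against floating-point landing exactly on L
        r -= L
    if r < 0.0:
        r = 0.0
    return r


@njit(cache=True, inline="always")
def _dist(ax, ay, bx, by, L):
    dx = _min_image(bx - ax, L)
    dy = _min_image(by - ay, L)
    return math.hypot(dx, dy)


@njit(cache=True, inline="always")
def _chunk_hit(ox, oy, hx, hy, chunk, cx, cy, r, L):
    """First s in [0, chunk] at which the point (ox,oy) + s*(hx,hy) is within
    distance r of centre (cx,cy) under the minimum image taken at s=0.

    Assumes chunk <= L/4 and r < L/4.  Returns -1.0 for no hit; 0.0 when the
    start point is already inside the disk.
    """
    dx = _min_image(cx - ox, L)
    dy = _min_image(cy - oy, L)
    c2 = dx * dx + dy * dy - r * r
    if c2 <= 0.0:
        return 0.0
    b = dx * hx + dy * hy
    if b <= 0.0:
        return -1.0
    disc = b * b - c2
    if disc < 0.0:
        return -1.0
    s = b - math.sqrt(disc)
    if s <= chunk:
        return s
    return -1.0


@njit(cache=True)
def _first_hit(sx, sy, hx, hy, travel, cx, cy, r, L):
    """First s in [0, travel] at which the moving point enters the disk, or -1.

    Splits the segment into sub-segments of at most L/4 so the minimum-image
    convention stays valid even when the segment crosses the periodic seam or
    wraps the torus several times.
    """
    cap = 0.25 * L
    s0 = 0.0
    while True:
        ox = _wrap1(sx + hx * s0, L)
        oy = _wrap1(sy + hy * s0, L)
        rem = travel - s0
        chunk = rem if rem < cap else cap
        if chunk < 0.0:
            chunk = 0.0
        s = _chunk_hit(ox, oy, hx, hy, chunk, cx, cy, r, L)
        if s >= 0.0:
            return s0 + s
        s0 += chunk
        if s0 >= travel or chunk == 0.0:
            return -1.0


def _as_xy(p) -> Tuple[float, float]:
    x, y = p
    return float(x), float(y)


def wrap(p, torus: Torus) -> Point2D:
    """Map a point with arbitrary finite coordinates into ``[0, L)^2``."""
    x, y = _as_xy(p)
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ValueError(f"cannot wrap non-finite coordinates ({x}, {y})")
    return Point2D(_wrap1(x, torus.L), _wrap1(y, torus.L))


def torus_distance(a, b, torus: Torus) -> float:
    """Minimum-image Euclidean distance between two points on the torus."""
    ax, ay = _as_xy(a)
    bx, by = _as_xy(b)
    return _dist(ax, ay, bx, by, torus.L)


def first_circle_hit(
    start,
    heading: float,
    travel: float,
    center,
    radius: float,
    torus: Torus,
) -> Optional[Tuple[float, Point2D]]:
    """Continuous detection of a moving point entering a circle on the torus.

    The point starts at ``start`` and moves ``travel`` length units along
    ``heading`` (radians, measured from the +x axis).  Returns ``(s, hit)``
    where ``s`` is the distance along the path at which the point first comes
    within ``radius`` of ``center`` (``s = 0`` if it starts inside), and
    ``hit`` the wrapped position there; or ``None`` if no entry occurs.

    ``radius`` must be positive and smaller than ``L/4`` so the nearest
    periodic image is unambiguous.
    """
    if travel < 0:
        raise ValueError("travel must be non-negative")
    if not radius > 0:
        raise ValueError("radius must be positive")
    if radius >= 0.25 * torus.L:
        raise ValueError(
            f"radius {radius} >= L/4 = {0.25 * torus.L}: periodic images ambiguous"
        )
    sx, sy = _as_xy(start)
    cx, cy = _as_xy(center)
    s = _first_hit(
        sx, sy, math.cos(heading), math.sin(heading), float(travel), cx, cy,
        float(radius), torus.L,
    )
    if s < 0.0:
        return None
    hit = wrap(Point2D(sx + math.cos(heading) * s, sy + math.sin(heading) * s), torus)
    return float(s), hit
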
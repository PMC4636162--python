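"""Numba-compiled episode kernels.

One searcher forages on patchy targets while exposed to predators on the
torus.  Movement is event-driven: the searcher advances in straight legs
(pieces of its current step, truncated at the maximum search time and at each
regeneration odometer mark), target captures and encounters with *stationary*
objects are resolved by exact segment-circle intersection, and encounters
between two simultaneously moving agents are resolved by synchronized
sub-steps whose combined displacement is at most ``substep_fraction`` times
the encounter radius.  When a death and a capture fall in the same sub-step,
death wins (predation dominates ties).

All randomness comes from numba's per-thread RNG seeded once per episode, so
an episode is fully reproducible from its integer seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .geometry import _chunk_hit, _first_hit, _min_image, _wrap1

# strategy kind codes; must match walks.KIND_CODES
K_STATIONARY = 0
K_LEVY = 1
K_BROWNIAN = 2
K_CRW = 3
K_CBW = 4
K_BALLISTIC = 5

# event codes in the optional audit log
EV_CAPTURE = 1
EV_DEATH = 2
EV_REGEN = 3

_BIG_STEP = 1.0e12  # effective step length of a ballistic mover
_CBW_EXT = 10.0  # extensive-mode step scale in units of l0


@njit(cache=True, inline="always")
def _uniform(a, b):
    return a + (b - a) * np.random.random()


@njit(cache=True)
def _draw_step(kind, mu, l0, scale):
    """Next step length for a strategy; ``scale`` is the Brownian/CBW mode scale."""
    if kind == K_LEVY:
        u = np.random.random()
        while u <= 0.0:
            u = np.random.random()
        return l0 * u ** (1.0 / (1.0 - mu))
    if kind == K_BROWNIAN or kind == K_CBW:
        x = np.random.normal(1.0, 1.0)
        while x <= 0.0:
            x = np.random.normal(1.0, 1.0)
        return scale * x
    if kind == K_CRW:
        return l0
    return _BIG_STEP


@njit(cache=True)
def _draw_turn(kind, rho):
    """Heading increment applied when a step completes."""
    if kind == K_BALLISTIC:
        return 0.0
    if kind == K_CRW:
        if rho >= 1.0:
            return 0.0
        u = np.random.random()
        f = (1.0 - rho) / (1.0 + rho)
        return 2.0 * math.atan(f * math.tan(math.pi * (u - 0.5)))
    return _uniform(-math.pi, math.pi)


@njit(cache=True)
def _regenerate(tx, ty, tactive, tpatch, pcx, pcy, patch_radius, L):
    """Restore every depleted target at a fresh uniform position in its patch."""
    n = 0
    for i in range(tx.size):
        if not tactive[i]:
            rr = patch_radius * math.sqrt(np.random.random())
            aa = _uniform(-math.pi, math.pi)
            p = tpatch[i]
            tx[i] = _wrap1(pcx[p] + rr * math.cos(aa), L)
            ty[i] = _wrap1(pcy[p] + rr * math.sin(aa), L)
            tactive[i] = True
            n += 1
    return n


@njit(cache=True)
def _scan_leg(sx, sy, hx, hy, leg, L,
              tx, ty, tactive, Rt,
              pcx, pcy, patch_scan_r, patch_ptr, patch_members,
              spx, spy, n_static_pred, Rp):
    """Earliest event on a straight searcher leg against static objects.

    Returns ``(code, s, target_id)`` with code 0 = nothing, 1 = capture,
    2 = death by stationary predator; when both fall in the same sub-segment
    the earlier wins and an exact tie goes to death.  Targets are prefiltered
    by patch disk (radius patch_radius + Rt), which is conservative because
    every target lies within its patch.
    """
    cap = 0.25 * L
    s0 = 0.0
    while True:
        ox = _wrap1(sx + hx * s0, L)
        oy = _wrap1(sy + hy * s0, L)
        rem = leg - s0
        chunk = rem if rem < cap else cap
        if chunk < 0.0:
            chunk = 0.0
        best_t = -1.0
        best_i = -1
        for p in range(pcx.size):
            sp = _chunk_hit(ox, oy, hx, hy, chunk, pcx[p], pcy[p], patch_scan_r, L)
            if sp < 0.0:
                continue
            for j in range(patch_ptr[p], patch_ptr[p + 1]):
                i = patch_members[j]
                if not tactive[i]:
                    continue
                s = _chunk_hit(ox, oy, hx, hy, chunk, tx[i], ty[i], Rt, L)
                if s >= 0.0 and (best_t < 0.0 or s < best_t):
                    best_t = s
                    best_i = i
        best_p = -1.0
        for i in range(n_static_pred):
            s = _chunk_hit(ox, oy, hx, hy, chunk, spx[i], spy[i], Rp, L)
            if s >= 0.0 and (best_p < 0.0 or s < best_p):
                best_p = s
        if best_p >= 0.0 and (best_t < 0.0 or best_p <= best_t):
            return 2, s0 + best_p, -1
        if best_t >= 0.0:
            return 1, s0 + best_t, best_i
        s0 += chunk
        if s0 >= leg or chunk == 0.0:
            return 0, -1.0, -1


@njit(cache=True)
def _advance_predators(px, py, ph, pres, kind, mu, l0, rho, v, dt, L):
    """Move every predator forward by ``dt`` time units along its own walk."""
    for i in range(px.size):
        t = dt
        while t > 1e-15:
            if pres[i] <= 0.0:
                pres[i] = _draw_step(kind, mu, l0, l0)
                ph[i] += _draw_turn(kind, rho)
            d = v * t
            if d <= pres[i]:
                px[i] = _wrap1(px[i] + math.cos(ph[i]) * d, L)
                py[i] = _wrap1(py[i] + math.sin(ph[i]) * d, L)
                pres[i] -= d
                t = 0.0
            else:
                px[i] = _wrap1(px[i] + math.cos(ph[i]) * pres[i], L)
                py[i] = _wrap1(py[i] + math.sin(ph[i]) * pres[i], L)
                t -= pres[i] / v
                pres[i] = 0.0


@njit(cache=True)
def _substep_death(sx, sy, hx, hy, s_v, t_stop, dt_sub,
                   px, py, ph, pres, p_kind, p_mu, p_l0, p_rho, p_v, Rp, L):
    """Moving-moving detection over a searcher leg of duration ``t_stop``.

    Advances the predators in place in sub-steps of at most ``dt_sub`` and
    checks the pair distance after each; returns the (discretized) death time
    relative to the leg start, or -1.0 for no encounter.
    """
    t = 0.0
    r2 = Rp * Rp
    while t < t_stop - 1e-15:
        h = dt_sub if dt_sub < (t_stop - t) else (t_stop - t)
        _advance_predators(px, py, ph, pres, p_kind, p_mu, p_l0, p_rho, p_v, h, L)
        t += h
        cx = _wrap1(sx + hx * s_v * t, L)
        cy = _wrap1(sy + hy * s_v * t, L)
        for i in range(px.size):
            dx = _min_image(px[i] - cx, L)
            dy = _min_image(py[i] - cy, L)
            if dx * dx + dy * dy < r2:
                return t
    return -1.0


@njit(cache=True)
def _stationary_searcher_episode(sx, sy, T_max,
                                 px, py, ph,
                                 p_kind, p_mu, p_l0, p_v, p_rho,
                                 Rp, L):
    """Exact first-encounter time for a non-moving searcher.

    Predators are mutually independent, so each one's path is walked alone by
    exact segment-circle intersection against the searcher's detection disk
    and the earliest hit over predators is taken.
    """
    best = T_max + 1.0
    for i in range(px.size):
        t_acc = 0.0
        x = px[i]
        y = py[i]
        hh = ph[i]
        res = 0.0
        horizon = T_max if T_max < best else best
        while t_acc < horizon:
            if res <= 0.0:
                res = _draw_step(p_kind, p_mu, p_l0, p_l0)
                hh += _draw_turn(p_kind, p_rho)
            leg = res
            cap = p_v * (horizon - t_acc)
            if leg > cap:
                leg = cap
            hx = math.cos(hh)
            hy = math.sin(hh)
            s = _first_hit(x, y, hx, hy, leg, sx, sy, Rp, L)
            if s >= 0.0:
                th = t_acc + s / p_v
                if th < best:
                    best = th
                break
            x = _wrap1(x + hx * leg, L)
            y = _wrap1(y + hy * leg, L)
            t_acc += leg / p_v
            res -= leg
            horizon = T_max if T_max < best else best
    return best


@njit(cache=True)
def run_episode_kernel(seed, L,
                       tx, ty, tactive, tpatch,
                       pcx, pcy, patch_radius, patch_ptr, patch_members,
                       regen_len, Rt, Rp,
                       s_kind, s_mu, s_l0, s_v, s_rho, s_gul,
                       sx, sy, s_heading0,
                       p_kind, p_mu, p_l0, p_v, p_rho,
                       px, py,
                       T_max, substep_frac,
                       record, ev_t, ev_code, ev_x, ev_y, ev_aux):
    """Simulate one searcher lifetime; mutates target/predator arrays in place.

    Returns ``(duration, n_captures, died, death_time, n_events)``.
    ``s_heading0`` may be NaN to draw the initial heading uniformly.
    """
    np.random.seed(seed)
    n_ev = 0
    n_p = px.size
    ph = np.empty(n_p)
    pres = np.zeros(n_p)
    for i in range(n_p):
        ph[i] = _uniform(-math.pi, math.pi)
    heading = s_heading0
    if not np.isfinite(heading):
        heading = _uniform(-math.pi, math.pi)

    # -- immobile searcher: pure survival problem --------------------------
    if s_kind == K_STATIONARY or s_v == 0.0:
        if n_p == 0 or p_v == 0.0:
            return T_max, 0, 0, -1.0, 0
        best = _stationary_searcher_episode(
            sx, sy, T_max, px, py, ph, p_kind, p_mu, p_l0, p_v, p_rho, Rp, L)
        if best <= T_max:
            if record and n_ev < ev_t.size:
                ev_t[n_ev] = best
                ev_code[n_ev] = EV_DEATH
                ev_x[n_ev] = sx
                ev_y[n_ev] = sy
                ev_aux[n_ev] = -1
                n_ev += 1
            return best, 0, 1, best, n_ev
        return T_max, 0, 0, -1.0, n_ev

    mobile_pred = n_p > 0 and p_v > 0.0
    n_static_pred = n_p if (n_p > 0 and p_v == 0.0) else 0
    dt_sub = substep_frac * Rp / (s_v + p_v) if mobile_pred else 0.0
    patch_scan_r = patch_radius + Rt

    age = 0.0
    odometer = 0.0
    next_regen = regen_len
    captures = 0
    died = False
    death_time = -1.0
    extensive = False
    since_cap = 0.0

    while age < T_max - 1e-12 and not died:
        # draw the next step of the searcher
        if s_kind == K_CBW:
            if since_cap > s_gul:
                extensive = True
            scale = _CBW_EXT * s_l0 if extensive else s_l0
            step_left = _draw_step(K_CBW, 0.0, s_l0, scale)
        else:
            step_left = _draw_step(s_kind, s_mu, s_l0, s_l0)
        captured = False

        while step_left > 1e-12 and age < T_max - 1e-12:
            room = next_regen - odometer
            if room <= 1e-9:
                n = _regenerate(tx, ty, tactive, tpatch, pcx, pcy, patch_radius, L)
                if record and n_ev < ev_t.size:
                    ev_t[n_ev] = age
                    ev_code[n_ev] = EV_REGEN
                    ev_x[n_ev] = sx
                    ev_y[n_ev] = sy
                    ev_aux[n_ev] = n
                    n_ev += 1
                next_regen += regen_len
                continue
            leg = step_left
            t_cap = s_v * (T_max - age)
            if leg > t_cap:
                leg = t_cap
            if leg > room:
                leg = room
            hx = math.cos(heading)
            hy = math.sin(heading)
            code, s_ev, idx = _scan_leg(
                sx, sy, hx, hy, leg, L, tx, ty, tactive, Rt,
                pcx, pcy, patch_scan_r, patch_ptr, patch_members,
                px, py, n_static_pred, Rp)
            s_stop = leg if code == 0 else s_ev
            if mobile_pred:
                td = _substep_death(
                    sx, sy, hx, hy, s_v, s_stop / s_v, dt_sub,
                    px, py, ph, pres, p_kind, p_mu, p_l0, p_rho, p_v, Rp, L)
                if td >= 0.0:
                    died = True
                    death_time = age + td
                    sx = _wrap1(sx + hx * s_v * td, L)
                    sy = _wrap1(sy + hy * s_v * td, L)
                    odometer += s_v * td
                    if record and n_ev < ev_t.size:
                        ev_t[n_ev] = death_time
                        ev_code[n_ev] = EV_DEATH
                        ev_x[n_ev] = sx
                        ev_y[n_ev] = sy
                        ev_aux[n_ev] = -1
                        n_ev += 1
                    break
            if code == 2:
                died = True
                death_time = age + s_ev / s_v
                sx = _wrap1(sx + hx * s_ev, L)
                sy = _wrap1(sy + hy * s_ev, L)
                odometer += s_ev
                if record and n_ev < ev_t.size:
                    ev_t[n_ev] = death_time
                    ev_code[n_ev] = EV_DEATH
                    ev_x[n_ev] = sx
                    ev_y[n_ev] = sy
                    ev_aux[n_ev] = -1
                    n_ev += 1
                break
            if code == 1:
                # capture: truncate the step at the capture point, deplete the
                # target, re-draw direction uniformly; a fresh step length is
                # drawn by the outer loop
                sx = _wrap1(sx + hx * s_ev, L)
                sy = _wrap1(sy + hy * s_ev, L)
                age += s_ev / s_v
                odometer += s_ev
                since_cap = 0.0
                extensive = False
                tactive[idx] = False
                captures += 1
                if record and n_ev < ev_t.size:
                    ev_t[n_ev] = age
                    ev_code[n_ev] = EV_CAPTURE
                    ev_x[n_ev] = sx
                    ev_y[n_ev] = sy
                    ev_aux[n_ev] = idx
                    n_ev += 1
                heading = _uniform(-math.pi, math.pi)
                captured = True
                break
            # uneventful leg: move through it
            sx = _wrap1(sx + hx * leg, L)
            sy = _wrap1(sy + hy * leg, L)
            age += leg / s_v
            odometer += leg
            since_cap += leg
            step_left -= leg

        if not died and not captured and age < T_max - 1e-12:
            heading += _draw_turn(s_kind, s_rho)

    duration = death_time if died else T_max
    return duration, captures, (1 if died else 0), death_time, n_ev
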
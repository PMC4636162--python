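"""Analytical fitness layer: first-encounter law, mean search time, fitness.

With a constant per-unit-time predator-encounter probability ``gamma``, the
first encounter falls on time unit ``m`` with geometric probability
``(1 - gamma)**(m-1) * gamma``.  Over a lifetime of ``n`` unit-time pieces
(``T_max = n`` with unit time 1) the mean search time is

    Tbar = (1 - (1 - gamma)**n) / gamma,

well approximated for small ``gamma`` by ``n (1 - exp(-k)) / k`` where
``k = n * gamma`` is the expected number of predator encounters per lifetime.

Fitness of a searcher with target-encounter rate ``eta`` and fitness
increment ``alpha`` per target:

* life-cycle type I  (fitness accrues per target found):
      phi = alpha * eta * Tbar ~= alpha * eta * n * (1 - exp(-k)) / k
* life-cycle type II (fitness only if the searcher survives to T_max):
      phi ~= alpha * eta * n * exp(-k)

The relative fitness of two strategies A and B,

    type I:  (eta_A / eta_B) * [k_B (1 - e^-k_A)] / [k_A (1 - e^-k_B)]
    type II: (eta_A / eta_B) * exp(-(k_A - k_B)),

is independent of ``T_max``.  All functions accept scalars or numpy arrays.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_SMALL_K = 1.0e-8


def _phi_factor(k):
    """(1 - exp(-k)) / k with the k -> 0 limit 1, evaluated stably.

    Below ``k = 1e-8`` the two-term series ``1 - k/2`` is used to avoid the
    0/0 form.
    """
    k = np.asarray(k, dtype=float)
    small = k < _SMALL_K
    safe = np.where(small, 1.0, k)
    out = np.where(small, 1.0 - k / 2.0, -np.expm1(-safe) / safe)
    return out if out.ndim else float(out)


def encounter_probability_at(m, gamma):
    """Probability the first predator encounter falls on time unit ``m``
    (geometric law ``(1-gamma)**(m-1) * gamma``)."""
    m = np.asarray(m)
    g = np.asarray(gamma, dtype=float)
    if np.any(m < 1) or np.any(m != np.floor(m)):
        raise ValueError("m must be a positive integer")
    if np.any(g < 0) or np.any(g > 1):
        raise ValueError("gamma must lie in [0, 1]")
    out = (1.0 - g) ** (np.asarray(m, dtype=float) - 1.0) * g
    return out if out.ndim else float(out)


def mean_search_time_exact(gamma, n):
    """Exact mean search time ``(1 - (1-gamma)**n) / gamma``.

    Equals the explicit sum ``sum_m m (1-gamma)**(m-1) gamma`` plus the
    survivor term ``n (1-gamma)**n``.  The ``gamma = 0`` limit returns ``n``.
    """
    g = np.asarray(gamma, dtype=float)
    n_arr = np.asarray(n, dtype=float)
    if np.any(g < 0) or np.any(g > 1):
        raise ValueError("gamma must lie in [0, 1]")
    if np.any(n_arr < 1):
        raise ValueError("n must be at least 1")
    safe = np.where(g == 0.0, 1.0, g)
    out = np.where(g == 0.0, n_arr, (1.0 - (1.0 - safe) ** n_arr) / safe)
    return out if out.ndim else float(out)


def mean_search_time_approx(k, n):
    """Approximate mean search time ``n (1 - exp(-k)) / k`` (k -> 0 gives n).

    Agrees with the exact form to relative order ``gamma = k/n`` when
    ``gamma`` is small.
    """
    k = np.asarray(k, dtype=float)
    n_arr = np.asarray(n, dtype=float)
    if np.any(k < 0):
        raise ValueError("k must be non-negative")
    out = n_arr * _phi_factor(k)
    return out if out.ndim else float(out)


def fitness_type1(eta, k, n, alpha):
    """Type-I expected fitness ``alpha * eta * n * (1 - exp(-k)) / k``."""
    eta = np.asarray(eta, dtype=float)
    if np.any(eta < 0):
        raise ValueError("eta must be non-negative")
    if not np.all(np.asarray(alpha, dtype=float) > 0):
        raise ValueError("alpha must be positive")
    out = np.asarray(alpha, dtype=float) * eta * mean_search_time_approx(k, n)
    return out if out.ndim else float(out)


def fitness_type2(eta, k, n, alpha):
    """Type-II expected fitness ``alpha * eta * n * exp(-k)`` (survive-to-
    maturity life cycle)."""
    eta = np.asarray(eta, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.any(eta < 0) or np.any(k < 0):
        raise ValueError("eta and k must be non-negative")
    out = np.asarray(alpha, dtype=float) * eta * np.asarray(n, dtype=float) * np.exp(-k)
    return out if out.ndim else float(out)


def _check_ratio_args(eta_a, k_a, eta_b, k_b):
    for name, v in (("eta_A", eta_a), ("k_A", k_a), ("eta_B", eta_b), ("k_B", k_b)):
        if np.any(np.asarray(v, dtype=float) < 0):
            raise ValueError(f"{name} must be non-negative")
    if np.any(np.asarray(eta_b, dtype=float) == 0):
        raise ValueError("eta_B must be positive (ratio undefined)")


def relative_fitness_type1(eta_a, k_a, eta_b, k_b):
    """Type-I relative fitness phi_A / phi_B; independent of T_max.

    Equals ``eta_A k_B (1 - e^-k_A) / (eta_B k_A (1 - e^-k_B))`` with the
    ``k -> 0`` limits handled via ``(1 - e^-k)/k -> 1``.
    """
    _check_ratio_args(eta_a, k_a, eta_b, k_b)
    out = (np.asarray(eta_a, dtype=float) * _phi_factor(k_a)) / (
        np.asarray(eta_b, dtype=float) * _phi_factor(k_b))
    out = np.asarray(out)
    return out if out.ndim else float(out)


def relative_fitness_type2(eta_a, k_a, eta_b, k_b):
    """Type-II relative fitness ``(eta_A / eta_B) * exp(-(k_A - k_B))``."""
    _check_ratio_args(eta_a, k_a, eta_b, k_b)
    out = (np.asarray(eta_a, dtype=float) / np.asarray(eta_b, dtype=float)) * np.exp(
        -(np.asarray(k_a, dtype=float) - np.asarray(k_b, dtype=float)))
    out = np.asarray(out)
    return out if out.ndim else float(out)


def fitness_landscape(eta_ratio_grid, gamma_ratio_grid, k_b, life_cycle) -> pd.DataFrame:
    """Relative-fitness surface over encounter-rate ratios.

    For each cell ``(eta_A/eta_B, gamma_A/gamma_B)`` the focal strategy's
    predator-encounter number is ``k_A = (gamma_A/gamma_B) * k_B`` and the
    relative fitness follows the type I or II formula.  Returns a tidy frame
    with columns ``eta_ratio, gamma_ratio, k_b, life_cycle, phi_ratio``.
    """
    if life_cycle not in ("I", "II"):
        raise ValueError("life_cycle must be 'I' or 'II'")
    if not k_b > 0:
        raise ValueError("k_b must be positive")
    er = np.asarray(eta_ratio_grid, dtype=float)
    gr = np.asarray(gamma_ratio_grid, dtype=float)
    if np.any(er <= 0) or np.any(gr <= 0):
        raise ValueError("ratio grids must be positive")
    E, G = np.meshgrid(er, gr, indexing="ij")
    k_a = G * k_b
    fn = relative_fitness_type1 if life_cycle == "I" else relative_fitness_type2
    phi = fn(E, k_a, 1.0, k_b)
    return pd.DataFrame({
        "eta_ratio": E.ravel(),
        "gamma_ratio": G.ravel(),
        "k_b": k_b,
        "life_cycle": life_cycle,
        "phi_ratio": np.asarray(phi).ravel(),
    })
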
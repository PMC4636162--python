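import math

import numpy as np
import pytest

from conftest import make_bare_environment
from levyrisk.analytic import rate_equal_speeds
from levyrisk.engine import (
    EncounterStats,
    EngineConfig,
    place_predators,
    place_searcher,
    run_batch,
    run_episode,
)
from levyrisk.environment import EnvironmentConfig
from levyrisk.geometry import Point2D, torus_distance
from levyrisk.walks import WalkStrategy
from levyrisk.engine import AgentState


class TestPlacement:
    def test_no_predators_gives_empty_layout(self, env, rng):
        cfg = EngineConfig(n_predators=0)
        assert place_predators(cfg, env, rng).shape == (0, 2)

    def test_layout_reproducible_and_uniform(self, env):
        cfg = EngineConfig(n_predators=100)
        a = place_predators(cfg, env, np.random.default_rng(4))
        b = place_predators(cfg, env, np.random.default_rng(4))
        assert np.array_equal(a, b)
        assert a.min() >= 0 and a.max() < 500

    def test_mean_nearest_predator_distance_matches_poisson(self, env):
        # 1 / (2 sqrt(rho)) = 25 for 100 predators on the 500x500 torus
        cfg = EngineConfig(n_predators=100)
        dists = []
        for seed in range(600):
            r = np.random.default_rng(seed)
            xy = place_predators(cfg, env, r)
            p = r.uniform(0, 500, 2)
            d = [torus_distance(p, q, env.cfg.torus) for q in xy]
            dists.append(min(d))
        assert np.mean(dists) == pytest.approx(25.0, rel=0.05)

    def test_searcher_placed_clear_of_predators(self, env, rng):
        xy = np.array([[250.0, 250.0], [10.0, 10.0]])
        for _ in range(50):
            s = place_searcher(env, xy, rng, min_clearance=5.0)
            assert all(torus_distance(s.position, q, env.cfg.torus) >= 5.0
                       for q in xy)

    def test_forced_initial_distance_controls_nearest(self, env, rng):
        cfg = EngineConfig(n_predators=100)
        xy = place_predators(cfg, env, rng)
        for d in (2.0, 10.0, 40.0):
            s = place_searcher(env, xy, rng, forced_distance=d)
            nearest = min(torus_distance(s.position, q, env.cfg.torus) for q in xy)
            assert nearest == pytest.approx(d, abs=1e-9)


class TestEpisode:
    def test_no_predators_runs_to_t_max(self, env, rng):
        cfg = EngineConfig(n_predators=0, T_max=1e4, total_time=1e4)
        res = run_episode(env, cfg, rng)
        assert not res.died
        assert res.duration == 1e4

    def test_stationary_searcher_among_stationary_predators_is_immortal(self, rng):
        env = make_bare_environment()
        cfg = EngineConfig(
            searcher_strategy=WalkStrategy.stationary(),
            predator_strategy=WalkStrategy.stationary(),
            n_predators=4, T_max=1e4, total_time=1e4)
        xy = np.array([[5.0, 0.0], [0.0, 5.0], [495.0, 0.0], [0.0, 495.0]])
        res = run_episode(env, cfg, rng,
                          searcher_start=AgentState(position=Point2D(0.0, 0.0)),
                          predator_xy=xy)
        assert not res.died and res.n_captures == 0 and res.duration == 1e4

    def test_head_on_approach_dies_at_predicted_time(self, rng):
        # ballistic searcher at unit speed, stationary predator 10 away,
        # encounter radius 1 => death after 9 time units
        env = make_bare_environment()
        cfg = EngineConfig(
            searcher_strategy=WalkStrategy.ballistic(velocity=1.0),
            predator_strategy=WalkStrategy.stationary(),
            n_predators=1, T_max=1e4, total_time=1e4)
        res = run_episode(env, cfg, rng,
                          searcher_start=AgentState(position=Point2D(0.0, 0.0)),
                          initial_heading=0.0,
                          predator_xy=np.array([[10.0, 0.0]]))
        assert res.died
        assert res.death_time == pytest.approx(9.0, abs=1e-9)

    def test_capture_and_death_events_pass_geometric_audit(self, env_cfg):
        cfg = EngineConfig(
            searcher_strategy=WalkStrategy.levy(2.0),
            predator_strategy=WalkStrategy.stationary(),
            n_predators=150, T_max=1e4, total_time=5e4, seed=2)
        stats = run_batch(env_cfg, cfg, record_events=True)
        ev = stats.events
        caps = ev[ev.event == "capture"]
        assert len(caps) == stats.total_captures > 0
        assert stats.total_deaths == (ev.event == "death").sum() > 0
        # every capture point lies within a patch disk (+ encounter radius)
        # of the captured target's home patch
        t = env_cfg.torus
        for ep, sub in caps.groupby("episode"):
            env_rng = np.random.default_rng(
                np.random.SeedSequence([cfg.seed, 11, int(ep)]))
            from levyrisk.environment import generate_environment
            e = generate_environment(env_cfg, env_rng)
            for _, row in sub.iterrows():
                pid = e.target_patch[int(row.aux)]
                d = torus_distance((row.x, row.y),
                                   (e.patch_x[pid], e.patch_y[pid]), t)
                assert d <= env_cfg.patch_radius + env_cfg.target_encounter_radius + 1e-6

    def test_episode_reproducible_from_generator_state(self, env):
        cfg = EngineConfig(n_predators=50, T_max=1e4, total_time=1e4)
        r1 = run_episode(env, cfg, np.random.default_rng(77))
        r2 = run_episode(env, cfg, np.random.default_rng(77))
        assert (r1.duration, r1.n_captures, r1.died) == \
            (r2.duration, r2.n_captures, r2.died)


class TestBatch:
    def test_time_accounting(self, env_cfg):
        cfg = EngineConfig(n_predators=0, T_max=1e4, total_time=5e4, seed=1)
        stats = run_batch(env_cfg, cfg)
        assert stats.total_time_observed == pytest.approx(stats.durations.sum())
        assert stats.total_time_observed >= cfg.total_time
        assert np.all(stats.durations > 0)
        assert np.all(stats.durations <= cfg.T_max)
        assert stats.gamma == 0.0 and stats.k == 0.0
        assert stats.mean_search_time == cfg.T_max

    def test_from_episodes_rates(self):
        stats = EncounterStats.from_episodes(
            durations=[100.0, 50.0, 50.0],
            captures=[3, 1, 0],
            died=[False, True, True],
            T_max=100.0)
        assert stats.eta == pytest.approx(4 / 200)
        assert stats.gamma == pytest.approx(2 / 200)
        assert stats.k == pytest.approx(1.0)
        assert stats.mean_search_time == pytest.approx(200 / 3)

    def test_batch_bit_reproducible(self, env_cfg):
        cfg = EngineConfig(n_predators=30, T_max=1e4, total_time=3e4, seed=9)
        a = run_batch(env_cfg, cfg)
        b = run_batch(env_cfg, cfg)
        assert np.array_equal(a.durations, b.durations)
        assert np.array_equal(a.captures, b.captures)

    def test_fixed_predator_layout_option(self, env_cfg):
        cfg = EngineConfig(n_predators=30, T_max=1e4, total_time=4e4, seed=9,
                           re_randomize_predators=False)
        stats = run_batch(env_cfg, cfg)
        assert stats.n_episodes >= 4  # runs; layout reuse is internal

    def test_gamma_scales_linearly_with_predator_density(self, env_cfg):
        # encounter rate proportional to predator density (ideal-gas law)
        gammas = {}
        for n_p in (60, 120):
            cfg = EngineConfig(
                searcher_strategy=WalkStrategy.levy(2.0),
                predator_strategy=WalkStrategy.stationary(),
                n_predators=n_p, T_max=1e4, total_time=4e5, seed=21)
            gammas[n_p] = run_batch(env_cfg, cfg).gamma
        assert gammas[120] / gammas[60] == pytest.approx(2.0, rel=0.3)

    def test_relative_motion_symmetry_at_equal_speeds(self):
        # swapping which party is called searcher and which predator leaves
        # the encounter rate unchanged when speeds are equal; tested in a
        # near-empty arena because foraging truncates and re-orients the
        # searcher's (but not a predator's) steps
        env_cfg = EnvironmentConfig(n_targets=1, n_patches=1)
        common = dict(n_predators=100, T_max=1e4, total_time=2e5, seed=6)
        g1 = run_batch(env_cfg, EngineConfig(
            searcher_strategy=WalkStrategy.brownian(),
            predator_strategy=WalkStrategy.levy(2.0, velocity=1.0), **common)).gamma
        g2 = run_batch(env_cfg, EngineConfig(
            searcher_strategy=WalkStrategy.levy(2.0),
            predator_strategy=WalkStrategy.brownian(velocity=1.0), **common)).gamma
        assert g1 == pytest.approx(g2, rel=0.3)

    def test_substep_refinement_does_not_change_rates(self, env_cfg):
        # halving the sub-step fraction must leave gamma unchanged beyond
        # Monte-Carlo error (tunneling is already controlled at the default)
        from dataclasses import replace
        base = EngineConfig(
            searcher_strategy=WalkStrategy.levy(2.0),
            predator_strategy=WalkStrategy.levy(2.0, velocity=1.0),
            n_predators=60, T_max=1e4, total_time=2e5, seed=13)
        g_default = run_batch(env_cfg, base).gamma
        g_fine = run_batch(env_cfg, replace(base, substep_fraction=0.1)).gamma
        assert g_fine == pytest.approx(g_default, rel=0.35)

    def test_equal_speed_gamma_near_ideal_gas_rate(self, env_cfg):
        # near-ballistic searcher among ballistic predators at equal speed:
        # the ideal-gas 8 rho R v / pi rate, within Monte-Carlo error
        cfg = EngineConfig(
            searcher_strategy=WalkStrategy.levy(1.05),
            predator_strategy=WalkStrategy.ballistic(velocity=1.0),
            n_predators=100, T_max=1e4, total_time=2e5, seed=5)
        stats = run_batch(env_cfg, cfg)
        expect = rate_equal_speeds(100 / 500**2, 1.0, 1.0)
        assert stats.gamma == pytest.approx(expect, rel=0.2)
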
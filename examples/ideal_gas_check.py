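"""Cross-check the engine against closed-form ideal-gas encounter rates.

A sit-and-wait searcher among ballistic (straight-moving) predators should
be encountered at rate 2 rho R v_p; the printed simulation estimate should
sit within Monte-Carlo error of that.  The equal-speed formula 8 rho R v/pi
then fixes the moving/stationary ratio at 4/pi.
"""

from levyrisk import (
    EngineConfig,
    EnvironmentConfig,
    WalkStrategy,
    rate_equal_speeds,
    rate_stationary_searcher,
    run_batch,
)

n_pred, L = 100, 500.0
rho = n_pred / L**2

stats = run_batch(
    EnvironmentConfig(),
    EngineConfig(
        searcher_strategy=WalkStrategy.stationary(),
        predator_strategy=WalkStrategy.ballistic(velocity=1.0),
        n_predators=n_pred, T_max=1e4, total_time=5e5, seed=3,
    ),
)

expect = rate_stationary_searcher(rho, 1.0, 1.0)
print(f"simulated gamma  = {stats.gamma:.3e}  ({stats.total_deaths} deaths)")
print(f"2 rho R v_p      = {expect:.3e}")
print(f"relative error   = {stats.gamma / expect - 1:+.1%}")
print(f"equal-speed rate = {rate_equal_speeds(rho, 1.0, 1.0):.3e} "
      f"(ratio 4/pi = {rate_equal_speeds(rho, 1, 1) / expect:.4f})")
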
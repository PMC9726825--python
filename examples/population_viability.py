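"""Fit division and death rates from live/dead counts of a birth-death process.

Simulates an exact (Gillespie) linear birth-death culture — every live
cell divides at rate g and dies at rate d per day — then refits (g, d)
from the live and dead trajectories alone, the way viability staining
time courses are analysed.  Also classifies a density panel into the
grow / no-grow phase diagram with its 3000 cells/ml threshold at 5 degC.
"""

from coldlife import load_scenario, synthetic
from coldlife.popdyn import (
    PopulationSeries, fit_birth_death, phase_diagram, simulate_birth_death,
)

g_true, d_true = 0.12, 0.05
via = simulate_birth_death(g_true, d_true, L0=500, horizon_days=30.0, seed=1, n_points=16)
fit = fit_birth_death(via, n_boot=200, seed=1)
print(f"true rates: g={g_true}/day d={d_true}/day")
print(f"fitted:     g={fit.g:.3f}/day (95% CI {fit.ci_g[0]:.3f}-{fit.ci_g[1]:.3f}) "
      f"d={fit.d:.3f}/day (95% CI {fit.ci_d[0]:.3f}-{fit.ci_d[1]:.3f})")

cfg = load_scenario("low_GSH_5C")
pop, _, _ = synthetic.gen_population_series(cfg, seed=1)
panel = [
    PopulationSeries(cfg.temperature_C, s.t_day.to_numpy(), s.density_per_ml.to_numpy(),
                     initial_density=float(s.initial_density_per_ml.iloc[0]),
                     carrying_capacity=float(s.carrying_capacity_per_ml.iloc[0]),
                     condition_id=str(c))
    for c, s in pop.groupby("condition_id")
]
grid = phase_diagram(panel)
print("\n5 degC phase diagram (density-dependent growth):")
print(grid.to_string(index=False))
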
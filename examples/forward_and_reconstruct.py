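"""Acquire and reconstruct one phantom scenario.

Builds the digital body phantom filled at the 4:1 sphere-to-background
scenario, forward-projects it with attenuation and resolution blur, draws
a Poisson realization, reconstructs with OSEM (4 iterations, 32 subsets,
2 mm post-filter) and prints per-sphere recovery coefficients. RC_mean
rises with sphere size — the partial-volume effect the small-sphere set
is designed to probe.
"""

from petinsert import RunConfig, SystemModel, STUDY_SCENARIOS, run_scenario
from petinsert.recon import ReconSettings

cfg = RunConfig(seed=11)
grid = cfg.grid()
model = SystemModel.for_grid(grid)
scenario = STUDY_SCENARIOS[1]  # SBR 4:1: background 5.44, spheres 21.38 kBq/mL

res = run_scenario(
    scenario, model, grid,
    settings=ReconSettings(algorithm="OSEM", iterations=4, subsets=32),
    seed=cfg.seed,
)

print(f"scenario {scenario.label}: resulting SBR = {scenario.resulting_sbr:.2f}, "
      f"{res.sinograms[0].counts.sum():.2e} counts in replicate 1")
print(f"{'sphere (mm)':>12} {'RC_mean':>8} {'+/- SD':>7} {'RC_max':>8}")
for _, row in res.rc_table.sort_values("sphere_mm").iterrows():
    print(f"{row.sphere_mm:12.2f} {row.rc_mean_avg:8.3f} "
          f"{row.rc_mean_sd:7.3f} {row.rc_max_avg:8.3f}")
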
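"""Build one stochastic AVM model and solve its baseline hemodynamics.

Generates a compartmentalized plexiform nidus, attaches it to the extranidal
arterial/venous template, and solves the steady-state flow at systemic
normotension (mean arterial pressure 74 mmHg, CVP 6 mmHg).
"""

from trenshsim import (SimulationConfig, attach_nidus,
                       build_extranidal_template, kirchhoff_residuals,
                       make_pressure_set, node_pressures,
                       nidus_risk_summary, sample_architecture, solve,
                       total_nidal_flow)

config = SimulationConfig()
arch = sample_architecture(seed=1, config=config)
network = attach_nidus(build_extranidal_template(config), arch)

print(f"nidus: {arch.n_compartments} compartments x {arch.n_columns} "
      f"columns, {arch.n_vessels} intranidal vessels")

solution = solve(network, make_pressure_set(config))[0]
pressures = node_pressures(solution)
mean_risk, max_risk = nidus_risk_summary(solution, arch, config.risk)
res = kirchhoff_residuals(solution)

print(f"total nidal flow: {total_nidal_flow(solution):.0f} mL/min "
      "(published family mean ~367)")
print("feeder pressures:",
      ", ".join(f"AF{i} {pressures[f'AF{i}t']:.0f} mmHg"
                for i in range(1, 5)))
print("draining-vein pressures:",
      ", ".join(f"DV{i} {pressures[f'DV{i}t']:.0f} mmHg"
                for i in range(1, 4)))
print(f"rupture risk over intranidal vessels: mean {mean_risk:.1f}%, "
      f"max {max_risk:.1f}%")
print(f"Kirchhoff residuals: node {res.max_node_residual:.1e}, "
      f"cycle {res.max_cycle_residual:.1e} mmHg over {res.n_cycles} cycles")
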
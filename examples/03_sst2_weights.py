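"""Estimate expanded-ensemble weights and compare with the exact answer.

Runs SST2 tempering on a 10-coordinate harmonic solute coupled to a
10-coordinate harmonic bath.  For this system the per-rung free-energy
weights are known in closed form, w_m = (d_solute/2)·ln λ_m, so the
run demonstrates the full estimation pipeline: on-the-fly
extrapolation to reach unvisited rungs, then periodic symmetric
(averaged) refreshes.
"""

import numpy as np

from soltemper import build_ladder
from soltemper.tempering import TemperingSchedule, run_tempering
from soltemper.toysim import IntegratorConfig, ToySystem, ideal_weights

ladder = build_ladder(280.0, 540.0, 300.0, 10, n_below_ref=1)
system = ToySystem(d_solute=10, d_solvent=10, k_solute=1.0, k_solvent=1.0)
schedule = TemperingSchedule(
    method="sst2",
    exchange_interval=40,      # integrator steps between exchange attempts
    n_segments=6000,
    weight_update="averaged",
    weight_refresh_interval=200,
)
integrator = IntegratorConfig(timestep=0.1, friction=1.0, t_ref=300.0, seed=101)

log = run_tempering(system, ladder, schedule, integrator)
est = log.final_weights
exact = ideal_weights(system, ladder.lambdas, 300.0)
exact -= exact[ladder.ref_index]

print("rung   T/K     λ      w_est     w_exact   error")
for r in ladder.rungs:
    print(
        f"{r.index:4d}  {r.temperature:6.1f}  {r.lam:5.2f}  "
        f"{est[r.index]:+8.4f}  {exact[r.index]:+8.4f}  "
        f"{est[r.index] - exact[r.index]:+7.4f}"
    )
acc = log.records.accepted.mean()
print(f"\noverall exchange acceptance: {acc:.2f}")
print(
    "Estimated weights track (d/2)·ln λ to a few 0.01 reduced units;\n"
    "with exact weights the rung walk would be an unbiased random walk\n"
    "(uniform occupancy), which is what makes tempering efficient."
)
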
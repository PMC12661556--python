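"""Sampling enhancement on a double-well solute.

A solute coordinate in a 10 kT double well essentially never crosses
the barrier at the reference temperature on this timescale.  Tempering
lets the walker climb to hot rungs (small λ), cross while the barrier
is effectively scaled down, and return — so both wells are visited.
The well coordinate doubles as a two-state order parameter, and the
committed-transition counter uses a hysteresis band so noise cannot
masquerade as transitions.
"""

import numpy as np

from soltemper import build_ladder, classify_states, count_transitions
from soltemper.tempering import TemperingSchedule, run_tempering
from soltemper.toysim import IntegratorConfig, ToySystem

system = ToySystem(
    d_solute=1, potential_kind="double_well", barrier=10.0, well_separation=2.0
)
integrator = IntegratorConfig(timestep=0.02, friction=1.0, t_ref=1.0, seed=12)

# tempering: 6 rungs, hottest rung scales the barrier down to 3 kT
ladder = build_ladder(1.0, 10.0 / 3.0, 1.0, 6)
schedule = TemperingSchedule(
    exchange_interval=50, n_segments=1500, weight_update="averaged",
    weight_refresh_interval=100,
)
log = run_tempering(system, ladder, schedule, integrator)

# control: identical length, λ pinned to 1 (a degenerate ladder)
flat = build_ladder(1.0, 1.0, 1.0, 2)
log_fixed = run_tempering(
    system, flat,
    TemperingSchedule(exchange_interval=50, n_segments=1500, weight_update="fixed"),
    integrator,
)

for label, lg in [("tempering", log), ("fixed λ=1", log_fixed)]:
    x = lg.records.order_param.to_numpy()
    series = classify_states(x, low=-0.5, high=0.5)  # left well / right well
    k = count_transitions(series)
    print(
        f"{label:10s}: coordinate range [{x.min():+.2f}, {x.max():+.2f}], "
        f"committed well-to-well transitions: {k}"
    )

print(
    "\nThe tempering run shuttles between wells while the fixed-λ run\n"
    "stays trapped — the qualitative signature of enhanced sampling."
)
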
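"""Melting-temperature extraction with effective-temperature correction.

Synthesises a folded-fraction-vs-rung dataset, maps each rung to its
*effective* solute temperature (the corrected temperature interpolating
between the rung's nominal T and the reference according to the
solute–solvent energy ratio), and fits the four-parameter logistic
y = d + (a − d)/(1 + (x/c)^b) whose inflection c is the melting
temperature T_m.
"""

import numpy as np

from soltemper import build_ladder, effective_temperature, fit_melting_curve
from soltemper.analysis import four_parameter_logistic
from soltemper.hamiltonian import EnergyDecomposition

rng = np.random.default_rng(7)
ladder = build_ladder(280.0, 540.0, 300.0, 10, n_below_ref=1)
ref = ladder.ref_rung

# effective temperatures: solute-solvent ratio ~0.5 shifts hot rungs toward T_ref
teff = []
for r in ladder.rungs:
    decomps = [
        EnergyDecomposition(epp1=1.0, epp2=0.2, epw=1.2 + rng.normal(0, 0.05))
        for _ in range(200)
    ]
    res = effective_temperature(decomps, r, ref)
    teff.append(res.t_eff)
    print(
        f"rung {r.index}: nominal T = {r.temperature:6.1f} K  →  "
        f"effective T = {res.t_eff:6.1f} K (ratio {res.ratio_mean:.2f})"
    )

# synthetic stability curve on the effective-temperature axis
true_tm = 345.0
teff = np.array(teff)
fractions = four_parameter_logistic(teff, 1.0, 0.0, true_tm, 12.0)
fractions = np.clip(fractions + rng.normal(0.0, 0.02, size=fractions.shape), 0, 1)

fit = fit_melting_curve(teff, fractions)
print(
    f"\n4PL fit: a = {fit.a:.3f}, d = {fit.d:.3f}, "
    f"b = {fit.b:.2f}, T_m = {fit.c:.1f} ± {fit.ci95_c():.1f} K (95% CI)"
)
print(
    f"generating T_m was {true_tm:.1f} K — the fit recovers the melting\n"
    "temperature from fractions observed at the corrected (effective)\n"
    "solute temperatures, not the nominal rung temperatures."
)
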
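"""Design exponentially spaced temperature/λ ladders.

Builds the three 10-rung ladders used for the hairpin (T_ref = 300 K),
the raised-reference variant (T_ref = 350 K), and the protein–peptide
complex (T_ref = 320 K, hotter top rung).  λ = T_ref/T is the factor
the solute Hamiltonian is scaled by at each rung; λ = 1 is the
physical system, λ > 1 rungs sit below the reference.
"""

from soltemper import build_ladder, choose_split
from soltemper.ladder import format_ladder

for label, (t_min, t_max, t_ref) in {
    "T_ref = 300 K": (280.0, 540.0, 300.0),
    "T_ref = 350 K": (280.0, 540.0, 350.0),
    "T_ref = 320 K": (280.0, 700.0, 320.0),
}.items():
    split = choose_split(t_min, t_max, t_ref, 10)
    lad = build_ladder(t_min, t_max, t_ref, 10, n_below_ref=split)
    print(f"--- {label} ({split} geometric interval(s) below the reference)")
    print(format_ladder(lad))
    print()

print(
    "Each table is a tempering ladder: the walker moves between rungs,\n"
    "heating only the solute by the factor λ while the solvent stays at\n"
    "the reference temperature."
)
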
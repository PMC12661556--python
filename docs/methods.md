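# Methods

## Model and scope

`soltemper` implements expanded-ensemble tempering for a single walker
over a discrete ladder of temperature/λ rungs, in four variants that
differ only in how the potential energy is scaled:

| method | reduced energy g_m(X) = β_sim·E_m(X), coefficients on (E_pp1, E_pp2, E_pw, E_ww) at β_ref |
|--------|----------------------------------------------------------|
| st     | (λ, λ, λ, λ) — plain tempering, everything heats          |
| sst1   | (λ, λ, (1+λ)/2, 1) — original solute tempering            |
| sst2   | (λ, 1, √λ, 1) — REST2-style scaling inside tempering      |
| rest2  | (λ, λ, √λ, 1) — pairwise replica-swap oracle only         |

with λ_m = T_ref/T_m = β_m/β_ref. Writing every method as a reduced
energy at the reference inverse temperature makes the engines
interchangeable: rung m's stationary density is ∝ exp(w_m − g_m(X)),
the move m→n is accepted with min(1, e^Δ), Δ = (g_m − g_n) +
(w_n − w_m), and detailed balance holds exactly for all four by
construction. For SST2 the delta expands to the familiar
(β_m − β_n)·E_pp1 + (√(β_ref β_m) − √(β_ref β_n))·E_pw + Δw. We derive
all acceptance expressions from the scaled Hamiltonians rather than
transcribing per-method formulas; the algebraic identity between the
two forms is asserted in the test suite at 1e-12.

The four-way split E_pp1/E_pp2/E_pw/E_ww is defined *operationally*:
E_pp from a solute-only subsystem, E_ww from a solvent-only subsystem,
E_pw = E_total − E_pp − E_ww. The particle-level evaluator in
`hamiltonian` follows this literally, which is also the numerically
robust recipe for real engines with long-range electrostatics.

Parameter-scaling route: multiplying solute LJ ε by λ, solute charges
by √λ, and scaled proper-torsion constants by λ reproduces the scaled
Hamiltonian exactly **provided** the LJ combination rule uses a
geometric mean on ε (so solute–solute pairs pick up λ and cross pairs
√λ). This is a documented constraint on any adapter; the equivalence is
verified to 1e-10 on randomized systems.

Proline ω exclusion: every proper-torsion term whose middle bond is
C(i−1)–N(i) with residue i a proline (including multiplicity copies)
can be moved from the scaled set E_pp1 to the unscaled set E_pp2, so
hot rungs cannot pump population into the slow-to-escape cis isomer.

## Ladder design

Temperatures are geometric within each of the two segments
[T_min, T_ref] and [T_ref, T_max]; T_k = T_lo·(T_hi/T_lo)^{k/(m−1)}
per segment with the reference rung shared. When the number of cold
intervals is not given it is chosen by equalizing the per-interval
geometric ratio of the two segments in log space (ties toward fewer
cold intervals); this rule reproduces all three published 10-rung
ladders the package is checked against. Internal temperatures are kept
at full precision; printing rounds to 0.1 K and λ to two decimals. β is
always 1/(k_B·T) with k_B an explicit ladder attribute (1 in reduced
units), never implicit. The number of rungs itself is a user choice
(commonly sized from a target acceptance probability with external
tools); the package does not pick it.

## Toy systems and integrator

The built-in model is d_solute harmonic or double-well coordinates plus
a harmonic bath of d_solvent coordinates with optional bilinear
coupling, in reduced units (k_B = 1, unit masses). It stands in for the
solvated peptides of production work: it has the same four-way energy
split and the same estimation problem, but no rugged landscape, no
long-range forces, and no real solvent structure — so passing tests
demonstrates the correctness of the tempering machinery, not force-field
physics.

Dynamics are BAOAB Langevin steps on the λ-scaled effective potential
at T_ref (rung changes enter only through the scaling coefficients).
BAOAB is chosen for its accurate configurational sampling at finite
timestep. Defaults: timestep 0.01 reduced time, friction 1.0 inverse
time — the lighter of the thermostat settings used in production-style
runs, which preserves barrier-crossing dynamics. The tests use timestep
0.1 on harmonic systems (ω·dt = 0.1, discretization bias in the
sampled variance ≪ the statistical tolerances) and 0.02 on the stiffer
double well. Exchange attempts default to every 200 steps, the
toy-unit analogue of attempting a temperature update every couple of
picoseconds. A blow-up (non-finite coordinate or velocity) aborts with
the offending step index.

For the harmonic, uncoupled system, ln Z(λ) is closed-form and the
ideal weights are w_m = ln Z(λ_ref) − ln Z(λ_m) = (d_solute/2)·ln λ_m
(pure harmonic solute); this is the oracle for every weight-recovery
test.

## Weight estimation

Per-rung running means of the four energy components are cumulative
with visit counts. Because g is linear in the components, mean energy
gaps between rungs are evaluated on the mean decomposition — exact, and
the same code path serves all methods.

* **On the fly**: an unvisited neighbour n of a visited rung m gets
  w_n = w_m + ⟨g_n − g_m⟩_m, swept outward so a cold start can reach
  the whole ladder; the estimate is overwritten once rung n has its own
  samples.
* **Averaged**: each link uses the symmetric mean
  (⟨g_{n} − g_m⟩_m + ⟨g_n − g_m⟩_n)/2 — the condition that typical
  forward and backward deltas coincide. One-sided links fall back to
  the on-the-fly form and are flagged.

The default schedule runs on-the-fly until every rung has ≥ 1 visit,
then refreshes the full table every `weight_refresh_interval` segments.
The reference-rung weight is pinned to 0 (gauge choice). The final
weight table appended to the log is recomputed from the records after
discarding the first 10% of segments (burn-in default), so transient
bias from the bootstrap phase drops out.

The trapezoid-like error of the symmetric estimator is O(Δβ³) per link;
on the default 10-rung ladders (per-interval ratio ≈ 1.07) it is far
below the statistical noise.

## Acceptance-energy monitor

Neighbouring-rung exchange in SST2 is governed by the fluctuations of
E_pp + ½·√(β_ref/β_m)·E_pw; the per-rung histograms of this monitor
(exported by `rung_diagnostics`) must overlap between neighbours for
the ladder to be usable. Two readings of the coefficient circulate
(with and without the square root); the default uses the √ form,
consistent with the √λ cross-term of the Hamiltonian, and the
alternative ½·(β_ref/β_m) is available behind `variant="printed"`.

## Analysis conventions

* **Effective temperature**: ⟨β′⟩ = β_m·(1 + (β_ref/β_m − 1)·
  ⟨E_pw/(E_pp+E_pw)⟩), the ratio averaged framewise (not the ratio of
  averages, which differs for fluctuating denominators). Fixed points:
  E_pw ≡ 0 gives T_m, ratio ≡ 1 gives T_ref.
* **States**: two disjoint thresholds (defaults 0.2/0.25 nm for
  folding, 0.5/1.0 nm for binding); the band in between is
  *intermediate* and carries no assignment. Transition counting is a
  hysteresis automaton over committed definite states, so
  threshold-chatter can never inflate counts; it is invariant under
  time reversal. Counts can be normalised per total simulated time or
  per reference-rung time — the field is ambiguous about the
  convention, so both are reported.
* **Folded fractions**: intermediate frames are excluded from numerator
  and denominator; binomial 95% CIs per rung; frames flagged cis
  (|ω| < 90°, the symmetric separatrix — no published numeric cutoff
  exists) are excluded before fractions and counts. Gaussian smoothing
  of display traces is a plotting matter and never enters counting.
* **4PL melting fit**: y = d + (a − d)/(1 + (x/c)^b) via bounded
  least squares. Initialisation a = max(y), d = min(y), c at the
  half-height point, b = 10; bounds a,d ∈ [−0.2, 1.2], b > 0, c within
  the data span ± 20%. Flat data (range < 1e-3) raises "no sigmoid";
  a fitted c outside the data span is flagged as extrapolation.
* **RMSD**: Kabsch superposition on a fit selection, deviation over a
  (possibly different) measurement selection without refitting — the
  align-on-receptor / measure-ligand convention. Floppy termini are
  handled by residue-range selections.

## Interface and reproducibility

A run is fully specified by one YAML config (method, ladder,
integrator, schedule, system, flags); unknown keys are rejected. One
seeded RNG stream drives thermostat noise, move proposals, and
acceptance draws in a fixed order, so identical (config, seed) produce
byte-identical logs. Logs are tab-separated text with a commented JSON
header and a trailing record-count marker; floats are written at full
precision and re-parsed round-trip exactly. At the ladder ends the
out-of-range neighbour is still proposed with probability ½ and
auto-rejected, keeping the proposal symmetric.

## Problem sizes

The test suite exercises: harmonic systems of 10+10 coordinates with
the 10-rung default ladder (weight recovery to 0.15 reduced units,
uniform occupancy by χ² on decorrelated rung samples over 4×10⁴
segments), a 100-oscillator batch for distributional checks (10⁵
samples, KS distance < 0.01), a 6-rung double well (10 kT barrier) for
the sampling-enhancement contrast, and exact 6-state transition-matrix
enumeration for detailed balance at 1e-10.

## Known limitations

The toy bath is harmonic and bilinearly coupled: it produces no
solvation-shell structure, no entropy–enthalpy compensation, and its
E_pw is small and Gaussian, so acceptance rates here are optimistic
relative to solvated proteins. No reciprocal-space electrostatics or
neutralizing-background correction exists in the core — a real-engine
adapter must supply it (and must use geometric-mean ε combination for
the scaling equivalence to hold). Replica-parallel REST2 is provided
only as a pairwise swap criterion, not a multi-replica driver. WHAM or
MBAR-style reweighting across rungs is out of scope; weights come from
the two estimators above.
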
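"""Analytically tractable solute/solvent model systems and Langevin dynamics.

The model potential is a solute of ``d_solute`` coordinates (harmonic or
double-well), a harmonic bath of ``d_solvent`` coordinates, and an
optional bilinear solute–bath coupling:

    U(x, y) = U_solute(x) + ½·k_restraint·Σ x²  (unscaled solute part)
            + ½·k_solvent·Σ y² + coupling·Σ x_i·y_i

Everything is in reduced units (k_B = 1, unit masses).  The harmonic
variant has a closed-form partition function at every λ, which makes it
the oracle for weight recovery; the double-well variant supplies a
two-state order parameter with a tunable barrier for sampling-
enhancement checks.  Dynamics are BAOAB Langevin steps on the λ-scaled
effective potential at the reference temperature, so a tempering engine
only ever changes λ, never the thermostat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .hamiltonian import EnergyDecomposition, effective_coefficients

__all__ = [
    "ToySystem",
    "SimState",
    "IntegratorConfig",
    "decompose_energy",
    "step_langevin",
    "analytic_log_partition",
    "ideal_weights",
    "initial_state",
]


@dataclass(frozen=True)
class ToySystem:
    """Solute/solvent-partitioned model potential (reduced units).

    ``k_restraint`` adds an unscaled harmonic term on the solute
    (reported as epp2), standing in for the bonds/angles/improper
    torsions a real solute keeps at full strength at every rung.
    For the double well, wells sit at ±well_separation/2 and ``barrier``
    is the energy at the top (x = 0) relative to the wells.
    """

    d_solute: int = 1
    d_solvent: int = 0
    potential_kind: str = "harmonic"
    k_solute: float = 1.0
    k_solvent: float = 1.0
    barrier: float = 0.0
    well_separation: float = 2.0
    coupling: float = 0.0
    k_restraint: float = 0.0

    def __post_init__(self) -> None:
        if self.d_solute < 1 or self.d_solvent < 0:
            raise ValueError("dimension error")
        if self.k_solute <= 0 or self.k_solvent <= 0:
            raise ValueError("spring constants must be positive")
        if self.barrier < 0:
            raise ValueError("barrier must be non-negative")
        if self.potential_kind not in ("harmonic", "double_well"):
            raise ValueError(f"unknown potential: {self.potential_kind!r}")

    @property
    def n_dof(self) -> int:
        return self.d_solute + self.d_solvent

    @property
    def n_coupled(self) -> int:
        return min(self.d_solute, self.d_solvent)


@dataclass
class SimState:
    """Coordinates, velocities, time, and the RNG that drives the noise."""

    coords: np.ndarray
    velocities: np.ndarray
    time: float
    rng: np.random.Generator

    def copy(self) -> "SimState":
        return SimState(
            coords=self.coords.copy(),
            velocities=self.velocities.copy(),
            time=self.time,
            rng=_clone_rng(self.rng),
        )


def _clone_rng(rng: np.random.Generator) -> np.random.Generator:
    bg = type(rng.bit_generator)()
    bg.state = rng.bit_generator.state
    return np.random.Generator(bg)


@dataclass(frozen=True)
class IntegratorConfig:
    """BAOAB Langevin parameters.

    Defaults mirror a light thermostat (friction 1 in reduced inverse
    time, the choice that preserved sampling efficiency best among the
    frictions tried for solute tempering) and a conservative timestep.
    """

    timestep: float = 0.01
    friction: float = 1.0
    t_ref: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.friction <= 0:
            raise ValueError("friction must be positive")
        if self.t_ref <= 0:
            raise ValueError("invalid temperature")


def initial_state(system: ToySystem, cfg: IntegratorConfig) -> SimState:
    """Fresh state: coordinates at a minimum, Maxwellian velocities."""
    rng = np.random.default_rng(cfg.seed)
    coords = np.zeros(system.n_dof)
    if system.potential_kind == "double_well":
        coords[: system.d_solute] = -0.5 * system.well_separation
    velocities = rng.normal(0.0, math.sqrt(cfg.t_ref), size=system.n_dof)
    return SimState(coords=coords, velocities=velocities, time=0.0, rng=rng)


def _split(system: ToySystem, coords: np.ndarray):
    return coords[..., : system.d_solute], coords[..., system.d_solute :]


def _solute_potential(system: ToySystem, x: np.ndarray) -> float:
    """Scalable solute terms (epp1)."""
    if system.potential_kind == "harmonic":
        return 0.5 * system.k_solute * float(np.sum(x * x))
    a = 0.5 * system.well_separation
    u = (x * x) / (a * a) - 1.0
    return system.barrier * float(np.sum(u * u))


def _solute_force(system: ToySystem, x: np.ndarray) -> np.ndarray:
    if system.potential_kind == "harmonic":
        return -system.k_solute * x
    a = 0.5 * system.well_separation
    u = (x * x) / (a * a) - 1.0
    return -4.0 * system.barrier * u * x / (a * a)


def decompose_energy(system: ToySystem, coords) -> EnergyDecomposition:
    """Four-way energy split of one configuration.

    epp1: scalable solute terms; epp2: the unscaled solute restraint;
    epw: the bilinear coupling (total minus subsystem energies); eww:
    the bath.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (system.n_dof,):
        raise ValueError("dimension error")
    x, y = _split(system, coords)
    epp1 = _solute_potential(system, x)
    epp2 = 0.5 * system.k_restraint * float(np.sum(x * x))
    eww = 0.5 * system.k_solvent * float(np.sum(y * y))
    nc = system.n_coupled
    epw = system.coupling * float(np.sum(x[:nc] * y[:nc])) if nc else 0.0
    return EnergyDecomposition(epp1=epp1, epp2=epp2, epw=epw, eww=eww)


def _effective_force(
    system: ToySystem, coords: np.ndarray, lam: float, method: str
) -> np.ndarray:
    """Force of the reduced-energy potential (per unit β_ref) at λ."""
    c1, c2, cw, cww = effective_coefficients(lam, method)
    x, y = _split(system, coords)
    fx = c1 * _solute_force(system, x) - c2 * system.k_restraint * x
    fy = -cww * system.k_solvent * y
    nc = system.n_coupled
    if nc and system.coupling:
        fx = fx.copy()
        fy = fy.copy()
        fx[:nc] -= cw * system.coupling * y[:nc]
        fy[:nc] -= cw * system.coupling * x[:nc]
    return np.concatenate([fx, fy])


def effective_potential(
    system: ToySystem, coords, lam: float, method: str = "sst2"
) -> float:
    """λ-scaled effective potential (the reduced energy divided by β_ref)."""
    d = decompose_energy(system, np.asarray(coords, dtype=float))
    c1, c2, cw, cww = effective_coefficients(lam, method)
    return c1 * d.epp1 + c2 * d.epp2 + cw * d.epw + cww * d.eww


def step_langevin(
    system: ToySystem,
    state: SimState,
    cfg: IntegratorConfig,
    lam: float,
    n_steps: int,
    method: str = "sst2",
) -> SimState:
    """Advance BAOAB Langevin dynamics on the λ-scaled effective potential.

    The state is advanced in place and also returned.  Unit masses; the
    thermostat temperature is always ``cfg.t_ref`` — rung changes enter
    only through λ and the method's scaling coefficients.
    """
    if lam <= 0:
        raise ValueError("invalid scaling factor")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    dt = cfg.timestep
    c1 = math.exp(-cfg.friction * dt)
    c2 = math.sqrt((1.0 - c1 * c1) * cfg.t_ref)
    x = state.coords
    v = state.velocities
    rng = state.rng
    f = _effective_force(system, x, lam, method)
    half_dt = 0.5 * dt
    for step in range(n_steps):
        v = v + half_dt * f
        x = x + half_dt * v
        v = c1 * v + c2 * rng.standard_normal(system.n_dof)
        x = x + half_dt * v
        f = _effective_force(system, x, lam, method)
        v = v + half_dt * f
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(v))):
            raise FloatingPointError(f"integration blow-up at step {step}")
    state.coords = x
    state.velocities = v
    state.time += n_steps * dt
    return state


def analytic_log_partition(system: ToySystem, lam: float, t_ref: float) -> float:
    """Closed-form ln Z(λ) of the harmonic, uncoupled system under SST2.

    Each solute coordinate sees an effective spring λ·k_solute +
    k_restraint at inverse temperature β_ref, each bath coordinate
    k_solvent; the velocity part is λ-independent and dropped (it
    cancels in every weight difference).
    """
    if system.potential_kind != "harmonic" or system.coupling != 0.0:
        raise ValueError("no closed form")
    beta = 1.0 / t_ref
    k_eff = lam * system.k_solute + system.k_restraint
    lnz = 0.5 * system.d_solute * math.log(2.0 * math.pi / (beta * k_eff))
    if system.d_solvent:
        lnz += 0.5 * system.d_solvent * math.log(
            2.0 * math.pi / (beta * system.k_solvent)
        )
    return lnz


def ideal_weights(system: ToySystem, lambdas, t_ref: float) -> np.ndarray:
    """Exact expanded-ensemble weights w_m = −ln Z(λ_m) + ln Z(λ_ref).

    With these weights the rung occupancy of a converged tempering run
    is uniform.  For the pure harmonic solute (no restraint) they reduce
    to (d_solute/2)·ln λ_m.
    """
    lnz = np.array([analytic_log_partition(system, lam, t_ref) for lam in lambdas])
    lnz_ref = analytic_log_partition(system, 1.0, t_ref)
    return lnz_ref - lnz
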
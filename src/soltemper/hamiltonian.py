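"""λ-scaled effective Hamiltonians and the four-way energy decomposition.

Solute-tempering methods act on a single split of the potential energy:

* ``epp1`` — scaled solute intramolecular energy (LJ, Coulomb, proper
  torsions),
* ``epp2`` — unscaled solute intramolecular energy (bonds, angles,
  improper torsions, and any proper torsions deliberately excluded from
  scaling such as proline ω terms),
* ``epw``  — solute–solvent interaction energy,
* ``eww``  — solvent intramolecular energy.

The effective Hamiltonian of rung *m* multiplies these components by
method-specific functions of λ_m = β_m/β_ref.  The SST2 Hamiltonian is

    E_m = λ·E_pp1 + E_pp2 + √λ·E_pw + E_ww,

the √λ on the cross term being exactly what scaling every solute partial
charge by √λ produces.  All acceptance deltas elsewhere in the package
are derived from these Hamiltonians, so the scaling rules here are the
single source of truth.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .ladder import Rung

__all__ = [
    "EnergyDecomposition",
    "TorsionPartition",
    "scaled_energy",
    "reduced_energy",
    "effective_coefficients",
    "monitor_energy",
    "scale_solute_parameters",
    "partition_torsions",
    "Atom",
    "TorsionTerm",
    "ParameterSet",
    "particle_energy",
    "decompose_particle_energy",
]

METHODS = ("st", "sst1", "sst2", "rest2")


@dataclass(frozen=True)
class EnergyDecomposition:
    """Four-way potential-energy split of one configuration."""

    epp1: float
    epp2: float = 0.0
    epw: float = 0.0
    eww: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.epp1, self.epp2, self.epw, self.eww):
            if not math.isfinite(v):
                raise ValueError("non-finite energy component")

    @property
    def solute(self) -> float:
        """Total solute intramolecular energy E_pp = E_pp1 + E_pp2."""
        return self.epp1 + self.epp2

    @property
    def total(self) -> float:
        return self.epp1 + self.epp2 + self.epw + self.eww


def effective_coefficients(lam: float, method: str) -> tuple[float, float, float, float]:
    """Coefficients (c_pp1, c_pp2, c_pw, c_ww) of the reduced energy.

    The reduced (dimensionless) energy of rung *m* is
    g_m(X) = β_ref · [c_pp1·epp1 + c_pp2·epp2 + c_pw·epw + c_ww·eww],
    i.e. β_sim,m · E_m(X) where β_sim,m is the inverse temperature the
    rung is actually propagated at (β_m for st/sst1, β_ref for
    sst2/rest2).  Expressing every method at β_ref makes the four
    engines interchangeable downstream.
    """
    if method == "st":
        return lam, lam, lam, lam
    if method == "sst1":
        return lam, lam, 0.5 * (1.0 + lam), 1.0
    if method == "sst2":
        return lam, 1.0, math.sqrt(lam), 1.0
    if method == "rest2":
        return lam, lam, math.sqrt(lam), 1.0
    raise ValueError(f"unsupported method: {method!r}")


def scaled_energy(
    decomp: EnergyDecomposition, rung: Rung, ref: Rung, method: str
) -> float:
    """Effective potential energy E_m^method(X) of the given rung.

    For sst2/rest2 this is the Hamiltonian the rung is simulated with at
    T_ref; for st it is the plain potential; for sst1 it is the
    temperature-dependent Hamiltonian of the original solute-tempering
    scheme, run at T_m.
    """
    lam = rung.lam
    if method == "sst2":
        return lam * decomp.epp1 + decomp.epp2 + math.sqrt(lam) * decomp.epw + decomp.eww
    if method == "rest2":
        return lam * decomp.solute + math.sqrt(lam) * decomp.epw + decomp.eww
    if method == "sst1":
        br_over_bm = ref.beta / rung.beta
        return (
            decomp.solute
            + 0.5 * (br_over_bm + 1.0) * decomp.epw
            + br_over_bm * decomp.eww
        )
    if method == "st":
        return decomp.total
    raise ValueError(f"unsupported method: {method!r}")


def reduced_energy(
    decomp: EnergyDecomposition, rung: Rung, ref: Rung, method: str
) -> float:
    """Dimensionless energy g_m(X) = β_sim,m · E_m^method(X).

    This is the quantity that enters every acceptance ratio and weight
    estimate: rung m's stationary density is ∝ exp(w_m − g_m(X)).
    """
    c1, c2, cw, cww = effective_coefficients(rung.lam, method)
    return ref.beta * (
        c1 * decomp.epp1 + c2 * decomp.epp2 + cw * decomp.epw + cww * decomp.eww
    )


def monitor_energy(
    decomp: EnergyDecomposition, rung: Rung, ref: Rung, variant: str = "radical"
) -> float:
    """Acceptance-ratio energy whose inter-rung overlap diagnoses the ladder.

    Neighbouring-rung exchange in SST2 is governed by the fluctuation of
    E_pp + ½·√(β_ref/β_m)·E_pw (``variant="radical"``, the default,
    consistent with the √λ cross-term of the Hamiltonian); the
    non-radical reading ½·(β_ref/β_m) is kept behind
    ``variant="printed"``.
    """
    ratio = ref.beta / rung.beta
    if variant == "radical":
        coeff = 0.5 * math.sqrt(ratio)
    elif variant == "printed":
        coeff = 0.5 * ratio
    else:
        raise ValueError(f"unknown monitor variant: {variant!r}")
    return decomp.solute + coeff * decomp.epw


# ---------------------------------------------------------------------------
# Torsion partitioning (proline ω exclusion)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TorsionPartition:
    """Disjoint split of the solute proper-torsion terms.

    ``scaled_terms`` contribute to E_pp1 (force constants multiplied by
    λ); ``unscaled_terms`` stay in E_pp2 at full strength.
    """

    scaled_terms: frozenset
    unscaled_terms: frozenset

    def __post_init__(self) -> None:
        if self.scaled_terms & self.unscaled_terms:
            raise ValueError("torsion partition overlaps")


@dataclass(frozen=True)
class TorsionTopologyTerm:
    """One proper-torsion term of a solute topology.

    ``residue_index``/``residue_name`` identify residue *i*, the residue
    owning the atom at position 3 of the term; ``atom_names`` lists the
    four atoms in bonded order.
    """

    term_id: str
    residue_index: int
    residue_name: str
    atom_names: tuple[str, str, str, str]

    def __post_init__(self) -> None:
        if len(self.atom_names) != 4:
            raise ValueError("malformed torsion term")


def partition_torsions(
    topology: Iterable[TorsionTopologyTerm], exclude_omega: bool = False
) -> TorsionPartition:
    """Split proper torsions into λ-scaled and unscaled sets.

    With ``exclude_omega`` set, every term whose middle bond is
    C(i−1)–N(i) with residue *i* a proline — the ω dihedral and all its
    multiplicity copies — is left unscaled, so cis/trans isomerisation
    barriers stay at full height at every rung and hot rungs cannot pump
    population into the slow-to-escape cis state.
    """
    scaled, unscaled = set(), set()
    for term in topology:
        if len(term.atom_names) != 4:
            raise ValueError("malformed torsion term")
        is_omega = (
            term.residue_name.upper() == "PRO"
            and term.atom_names[1].upper() == "C"
            and term.atom_names[2].upper() == "N"
        )
        if exclude_omega and is_omega:
            unscaled.add(term.term_id)
        else:
            scaled.add(term.term_id)
    return TorsionPartition(frozenset(scaled), frozenset(unscaled))


def read_torsion_table(path) -> list[TorsionTopologyTerm]:
    """Read a torsion topology from a delimited table.

    Columns: term_id, residue_index, residue_name, atom1..atom4
    (tab- or comma-separated; lines starting with '#' ignored).
    """
    terms = []
    with open(path, newline="") as fh:
        sample = fh.read()
    delim = "\t" if "\t" in sample else ","
    for row in csv.reader(
        (l for l in sample.splitlines() if l.strip() and not l.startswith("#")),
        delimiter=delim,
    ):
        if len(row) != 7:
            raise ValueError("malformed torsion term")
        terms.append(
            TorsionTopologyTerm(
                term_id=row[0].strip(),
                residue_index=int(row[1]),
                residue_name=row[2].strip(),
                atom_names=tuple(a.strip() for a in row[3:7]),
            )
        )
    return terms


# ---------------------------------------------------------------------------
# Particle parameter sets and the λ-scaling of force-field parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Atom:
    """Point particle with nonbonded parameters (reduced units)."""

    name: str
    charge: float
    lj_epsilon: float
    lj_sigma: float
    is_solute: bool


@dataclass(frozen=True)
class TorsionTerm:
    """Proper torsion k·(1 + cos(n·φ − φ0)) over four atom indices."""

    term_id: str
    atoms: tuple[int, int, int, int]
    k: float
    periodicity: int = 1
    phase: float = 0.0


@dataclass(frozen=True)
class ParameterSet:
    """A minimal nonbonded + proper-torsion parameter set.

    LJ pair parameters combine with a geometric mean on ε — required for
    per-atom ε-scaling by λ to produce exact λ (solute–solute) and √λ
    (solute–solvent) pair factors — and an arithmetic mean on σ.
    ``scaled_torsion_ids`` is the E_pp1 partition; ``None`` means every
    proper torsion is scaled.
    """

    atoms: tuple[Atom, ...]
    torsions: tuple[TorsionTerm, ...] = ()
    scaled_torsion_ids: Optional[frozenset] = None

    def torsion_is_scaled(self, term: TorsionTerm) -> bool:
        if self.scaled_torsion_ids is None:
            return True
        return term.term_id in self.scaled_torsion_ids


def scale_solute_parameters(params: ParameterSet, lam: float) -> ParameterSet:
    """Apply the λ-scaling rules to solute parameters.

    Solute LJ ε × λ, solute partial charges × √λ, force constants of
    proper torsions in the scaled partition × λ.  Bonds, angles,
    improper torsions (absent from this toy parameter set by
    construction) and all solvent parameters are untouched.
    """
    if lam <= 0:
        raise ValueError("invalid scaling factor")
    sqrt_lam = math.sqrt(lam)
    atoms = tuple(
        replace(a, charge=a.charge * sqrt_lam, lj_epsilon=a.lj_epsilon * lam)
        if a.is_solute
        else a
        for a in params.atoms
    )
    torsions = tuple(
        replace(t, k=t.k * lam)
        if params.torsion_is_scaled(t) and _all_solute(params, t)
        else t
        for t in params.torsions
    )
    return replace(params, atoms=atoms, torsions=torsions)


def _all_solute(params: ParameterSet, term: TorsionTerm) -> bool:
    return all(params.atoms[i].is_solute for i in term.atoms)


def signed_dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle (degrees, in (−180, 180]) of four points."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12 or norm_b2 < 1e-12:
        raise ValueError("undefined dihedral")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / norm_b2)
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def _pair_energy(params: ParameterSet, coords: np.ndarray, mask: np.ndarray) -> float:
    """Sum of LJ + Coulomb over all pairs with both atoms in ``mask``."""
    idx = np.flatnonzero(mask)
    e = 0.0
    for a_pos in range(len(idx)):
        for b_pos in range(a_pos + 1, len(idx)):
            i, j = idx[a_pos], idx[b_pos]
            ai, aj = params.atoms[i], params.atoms[j]
            r = float(np.linalg.norm(coords[i] - coords[j]))
            eps = math.sqrt(ai.lj_epsilon * aj.lj_epsilon)
            sig = 0.5 * (ai.lj_sigma + aj.lj_sigma)
            sr6 = (sig / r) ** 6
            e += 4.0 * eps * (sr6 * sr6 - sr6) + ai.charge * aj.charge / r
    return e


def _torsion_energy(params: ParameterSet, coords: np.ndarray, terms) -> float:
    e = 0.0
    for t in terms:
        phi = math.radians(signed_dihedral(*(coords[i] for i in t.atoms)))
        e += t.k * (1.0 + math.cos(t.periodicity * phi - math.radians(t.phase)))
    return e


def particle_energy(params: ParameterSet, coords) -> float:
    """Total potential energy of the parameter set at ``coords`` (N×3)."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (len(params.atoms), 3):
        raise ValueError("dimension error")
    mask = np.ones(len(params.atoms), dtype=bool)
    return _pair_energy(params, coords, mask) + _torsion_energy(
        params, coords, params.torsions
    )


def decompose_particle_energy(params: ParameterSet, coords) -> EnergyDecomposition:
    """Four-way decomposition via the subsystem construction.

    E_pp is evaluated on a solute-only copy, E_ww on a solvent-only
    copy, and E_pw is recovered as E_total − E_pp − E_ww — the same
    operational definition used for real systems, where it keeps
    long-range electrostatics consistent across the three evaluations.
    Proper torsions follow the scaled/unscaled partition into
    epp1/epp2.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (len(params.atoms), 3):
        raise ValueError("dimension error")
    solute = np.array([a.is_solute for a in params.atoms])
    solute_terms = [t for t in params.torsions if _all_solute(params, t)]
    scaled = [t for t in solute_terms if params.torsion_is_scaled(t)]
    unscaled = [t for t in solute_terms if not params.torsion_is_scaled(t)]

    epp_nb = _pair_energy(params, coords, solute)
    epp1 = epp_nb + _torsion_energy(params, coords, scaled)
    epp2 = _torsion_energy(params, coords, unscaled)
    eww = _pair_energy(params, coords, ~solute) + _torsion_energy(
        params, coords, [t for t in params.torsions if t not in solute_terms]
    )
    total = particle_energy(params, coords)
    epw = total - epp1 - epp2 - eww
    return EnergyDecomposition(epp1=epp1, epp2=epp2, epw=epw, eww=eww)
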
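"""Expanded-ensemble tempering engines and weight estimation.

A tempering run alternates Langevin segments on the current rung's
effective Hamiltonian with Metropolis moves along the ladder.  Rung *m*
samples the density ∝ exp(w_m − g_m(X)), where g_m = β_sim·E_m is the
method's reduced energy; the move m→n is accepted with
min(1, e^Δ),  Δ_mn = (g_m − g_n) + (w_n − w_m),
which is exact detailed balance for every method.  For SST2 this
expands to Δ = (β_m−β_n)·E_pp1 + (√(β_ref β_m) − √(β_ref β_n))·E_pw +
(w_n − w_m).

Weights can be estimated on the fly (extrapolation from the last
visited rung's mean energies, enough to bootstrap the walk into
unvisited territory) or by the symmetric averaged estimator
w_{n} − w_{m} = (⟨g_n − g_m⟩_m + ⟨g_n − g_m⟩_n)/2,
the balance condition that makes typical forward and backward deltas
equal.  Both reduce to the familiar (β_{m+1}−β_m)⟨E⟩ forms for plain
simulated tempering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .hamiltonian import (
    EnergyDecomposition,
    monitor_energy,
    reduced_energy,
    scaled_energy,
)
from .ladder import LadderSpec, Rung
from .logio import RECORD_COLUMNS, TrajectoryLog
from .toysim import (
    IntegratorConfig,
    SimState,
    ToySystem,
    decompose_energy,
    initial_state,
    step_langevin,
)

__all__ = [
    "TemperState",
    "MoveRecord",
    "TemperingSchedule",
    "delta_rung",
    "attempt_move",
    "update_weights_on_the_fly",
    "update_weights_averaged",
    "estimate_weights_from_records",
    "rest2_pair_delta",
    "run_tempering",
]

_COMPONENTS = ("epp1", "epp2", "epw", "eww")


@dataclass
class TemperState:
    """Walker position, per-rung running energy means, and weight table."""

    current_rung: int
    weights: np.ndarray
    counts: np.ndarray
    sums: dict
    step: int = 0
    ref_index: int = 0
    fallback_links: list = field(default_factory=list)

    @classmethod
    def fresh(
        cls,
        ladder: LadderSpec,
        start_rung: Optional[int] = None,
        weights: Optional[Sequence[float]] = None,
    ) -> "TemperState":
        n = ladder.n_rungs
        w = np.zeros(n) if weights is None else np.asarray(weights, dtype=float).copy()
        if len(w) != n:
            raise ValueError("weights length does not match ladder")
        w = w - w[ladder.ref_index]  # pin the reference-rung weight to 0
        return cls(
            current_rung=ladder.ref_index if start_rung is None else start_rung,
            weights=w,
            counts=np.zeros(n, dtype=np.int64),
            sums={c: np.zeros(n) for c in _COMPONENTS},
            ref_index=ladder.ref_index,
        )

    def accumulate(self, rung_index: int, decomp: EnergyDecomposition) -> None:
        self.counts[rung_index] += 1
        for c in _COMPONENTS:
            self.sums[c][rung_index] += getattr(decomp, c)

    def mean_decomp(self, rung_index: int) -> EnergyDecomposition:
        n = self.counts[rung_index]
        if n == 0:
            raise ValueError("insufficient statistics")
        return EnergyDecomposition(
            **{c: self.sums[c][rung_index] / n for c in _COMPONENTS}
        )

    @property
    def mean_epp1(self) -> np.ndarray:
        return _safe_mean(self.sums["epp1"], self.counts)

    @property
    def mean_epw(self) -> np.ndarray:
        return _safe_mean(self.sums["epw"], self.counts)

    @property
    def mean_total(self) -> np.ndarray:
        tot = sum(self.sums[c] for c in _COMPONENTS)
        return _safe_mean(tot, self.counts)

    @property
    def visit_counts(self) -> np.ndarray:
        return self.counts


def _safe_mean(s: np.ndarray, n: np.ndarray) -> np.ndarray:
    out = np.full_like(s, np.nan, dtype=float)
    np.divide(s, n, out=out, where=n > 0)
    return out


@dataclass(frozen=True)
class MoveRecord:
    """One exchange attempt along the ladder."""

    from_rung: int
    to_rung: int
    delta: float
    accepted: bool
    monitor: float
    step: int

    def __post_init__(self) -> None:
        if abs(self.to_rung - self.from_rung) > 1:
            raise ValueError("illegal move")


def delta_rung(
    decomp: EnergyDecomposition,
    m: Rung,
    n: Rung,
    ref: Rung,
    weights: Sequence[float],
    method: str,
) -> float:
    """Log acceptance ratio Δ_mn for the rung move m→n at fixed X.

    ``decomp`` is the configuration's unscaled (λ=1) decomposition; the
    method's Hamiltonian scaling is applied here.
    """
    if abs(m.index - n.index) > 1:
        raise ValueError("illegal move")
    g_m = reduced_energy(decomp, m, ref, method)
    g_n = reduced_energy(decomp, n, ref, method)
    return (g_m - g_n) + (float(weights[n.index]) - float(weights[m.index]))


def attempt_move(
    state: TemperState,
    decomp: EnergyDecomposition,
    ladder: LadderSpec,
    rng: np.random.Generator,
    method: str,
    monitor_variant: str = "radical",
) -> MoveRecord:
    """Metropolis rung move with symmetric ±1 proposals.

    The up/down neighbour is proposed with probability ½ each; at the
    ladder ends the out-of-range proposal is an automatic rejection,
    which keeps the proposal symmetric and the acceptance ratio
    weight-free.  Draw order from the single stream: (1) proposal
    direction, (2) acceptance uniform — the latter only when the
    proposal is in range and Δ < 0.  The running means of the rung
    occupied during the preceding segment are updated before the move.
    """
    m_idx = state.current_rung
    state.accumulate(m_idx, decomp)
    ref = ladder.ref_rung
    mon = monitor_energy(decomp, ladder.rungs[m_idx], ref, monitor_variant)
    direction = -1 if rng.random() < 0.5 else 1
    n_idx = m_idx + direction
    step = state.step
    state.step += 1
    if n_idx < 0 or n_idx >= ladder.n_rungs:
        return MoveRecord(m_idx, m_idx, float("-inf"), False, mon, step)
    delta = delta_rung(
        decomp, ladder.rungs[m_idx], ladder.rungs[n_idx], ref, state.weights, method
    )
    accepted = delta >= 0 or rng.random() < math.exp(delta)
    if accepted:
        state.current_rung = n_idx
    return MoveRecord(m_idx, n_idx, delta, accepted, mon, step)


def _mean_gap(
    state: TemperState, ladder: LadderSpec, sample_rung: int, a: int, b: int, method: str
) -> float:
    """⟨g_b − g_a⟩ under rung ``sample_rung``'s accumulated samples.

    g is linear in the four energy components, so the mean gap is the
    gap of the mean decomposition.
    """
    d = state.mean_decomp(sample_rung)
    ref = ladder.ref_rung
    return reduced_energy(d, ladder.rungs[b], ref, method) - reduced_energy(
        d, ladder.rungs[a], ref, method
    )


def update_weights_on_the_fly(
    state: TemperState, ladder: LadderSpec, method: str
) -> TemperState:
    """Extrapolate weights into rungs that have never been visited.

    An unvisited neighbour n of a visited rung m gets
    w_n = w_m + ⟨g_n − g_m⟩_m; the estimate is provisional and is
    overwritten as soon as rung n acquires its own samples (by the
    averaged estimator) — here it is recomputed on every call, sweeping
    outward so a chain of unvisited rungs is filled in one pass.
    """
    if not np.any(state.counts > 0):
        raise ValueError("insufficient statistics")
    visited = state.counts > 0
    known = visited.copy()
    changed = True
    while changed:
        changed = False
        for m in range(ladder.n_rungs):
            if not known[m]:
                continue
            src = m if visited[m] else _nearest_visited(visited, m)
            for n in (m - 1, m + 1):
                if 0 <= n < ladder.n_rungs and not known[n]:
                    state.weights[n] = state.weights[m] + _mean_gap(
                        state, ladder, src, m, n, method
                    )
                    known[n] = True
                    changed = True
    state.weights -= state.weights[state.ref_index]
    return state


def _nearest_visited(visited: np.ndarray, m: int) -> int:
    idx = np.flatnonzero(visited)
    return int(idx[np.argmin(np.abs(idx - m))])


def update_weights_averaged(
    state: TemperState, ladder: LadderSpec, method: str
) -> TemperState:
    """Refresh the whole weight table with the symmetric estimator.

    Each link uses the average of the forward and backward mean gaps;
    a link with samples on only one side falls back to the one-sided
    (on-the-fly) estimate and is flagged in ``state.fallback_links``;
    a link with no samples at all keeps its previous increment.  The
    reference-rung weight is re-pinned to 0.
    """
    old = state.weights.copy()
    new = np.zeros_like(old)
    state.fallback_links = []
    for m in range(ladder.n_rungs - 1):
        n = m + 1
        has_m, has_n = state.counts[m] > 0, state.counts[n] > 0
        if has_m and has_n:
            dw = 0.5 * (
                _mean_gap(state, ladder, m, m, n, method)
                + _mean_gap(state, ladder, n, m, n, method)
            )
        elif has_m:
            dw = _mean_gap(state, ladder, m, m, n, method)
            state.fallback_links.append(m)
        elif has_n:
            dw = _mean_gap(state, ladder, n, m, n, method)
            state.fallback_links.append(m)
        else:
            dw = old[n] - old[m]
            state.fallback_links.append(m)
        new[n] = new[m] + dw
    state.weights = new - new[state.ref_index]
    return state


def estimate_weights_from_records(
    records: pd.DataFrame,
    ladder: LadderSpec,
    method: str,
    burn_in_fraction: float = 0.1,
) -> np.ndarray:
    """Averaged-estimator weights recomputed from logged segments.

    The first ``burn_in_fraction`` of the records is discarded before
    the per-rung means are formed.
    """
    if not 0 <= burn_in_fraction < 1:
        raise ValueError("burn_in_fraction must be in [0, 1)")
    start = int(len(records) * burn_in_fraction)
    tail = records.iloc[start:]
    state = TemperState.fresh(ladder)
    for row in tail.itertuples(index=False):
        d = EnergyDecomposition(row.epp1, row.epp2, row.epw, row.eww)
        state.accumulate(int(row.rung_index), d)
    update_weights_averaged(state, ladder, method)
    return state.weights


def rest2_pair_delta(
    decomp_m: EnergyDecomposition,
    decomp_n: EnergyDecomposition,
    m: Rung,
    n: Rung,
    ref: Rung,
) -> float:
    """Exact pairwise REST2 swap criterion between two replicas.

    Δ = −β_ref·[E_m(X_n) + E_n(X_m) − E_m(X_m) − E_n(X_n)] with the
    λ-scaled REST2 Hamiltonians; the weights of replica exchange cancel.
    """

    def e(d: EnergyDecomposition, r: Rung) -> float:
        return scaled_energy(d, r, ref, "rest2")

    return -ref.beta * (
        e(decomp_n, m) + e(decomp_m, n) - e(decomp_m, m) - e(decomp_n, n)
    )


@dataclass(frozen=True)
class TemperingSchedule:
    """Exchange/weight-update schedule of a tempering run.

    ``weight_update``:
      * ``"averaged"`` (default) — on-the-fly extrapolation until every
        rung has been visited, then a full averaged refresh every
        ``weight_refresh_interval`` segments;
      * ``"on_the_fly"`` — extrapolation only, no refreshes;
      * ``"fixed"`` — ``initial_weights`` frozen for the whole run.

    ``exchange_interval`` counts integrator steps per segment (the
    toy-unit analogue of attempting a temperature update every couple of
    picoseconds).  ``burn_in_fraction`` of the records is discarded
    before the final weight estimate appended to the log.
    """

    method: str = "sst2"
    exchange_interval: int = 200
    n_segments: int = 1000
    weight_update: str = "averaged"
    weight_refresh_interval: int = 100
    burn_in_fraction: float = 0.1
    initial_weights: Optional[tuple] = None
    monitor_variant: str = "radical"
    start_rung: Optional[int] = None

    def __post_init__(self) -> None:
        if self.method not in ("st", "sst1", "sst2"):
            raise ValueError(f"unsupported method: {self.method!r}")
        if self.weight_update not in ("on_the_fly", "averaged", "fixed"):
            raise ValueError(f"unknown weight_update: {self.weight_update!r}")
        if self.exchange_interval < 1 or self.n_segments < 0:
            raise ValueError("invalid schedule")
        if not 0 <= self.burn_in_fraction < 1:
            raise ValueError("burn_in_fraction must be in [0, 1)")


def run_tempering(
    system: ToySystem,
    ladder: LadderSpec,
    schedule: TemperingSchedule,
    integrator: Optional[IntegratorConfig] = None,
    header_extra: Optional[dict] = None,
) -> TrajectoryLog:
    """Run a full tempering simulation on a toy system.

    Alternates ``exchange_interval`` BAOAB steps on the current rung's
    effective Hamiltonian with one Metropolis rung move, applying the
    configured weight schedule.  Fully reproducible from (config, seed):
    a single RNG stream drives thermostat noise, proposals, and
    acceptance draws, in that order within each segment.
    """
    if integrator is None:
        integrator = IntegratorConfig(t_ref=ladder.t_ref, seed=0)
    if abs(integrator.t_ref - ladder.t_ref) > 1e-9 * ladder.t_ref:
        raise ValueError("integrator t_ref must match the ladder reference")
    state = TemperState.fresh(
        ladder, start_rung=schedule.start_rung, weights=schedule.initial_weights
    )
    sim = initial_state(system, integrator)
    rows: list[list] = []
    weights_history: list = [(0, state.weights.tolist())]
    all_visited = False
    for seg in range(schedule.n_segments):
        rung = ladder.rungs[state.current_rung]
        try:
            step_langevin(
                system, sim, integrator, rung.lam, schedule.exchange_interval,
                method=schedule.method,
            )
        except FloatingPointError as exc:
            raise FloatingPointError(
                f"integration blow-up in segment {seg} at rung {rung.index}"
            ) from exc
        decomp = decompose_energy(system, sim.coords)
        rec = attempt_move(
            state, decomp, ladder, sim.rng, schedule.method, schedule.monitor_variant
        )
        rows.append(
            [
                rec.step,
                sim.time,
                rec.from_rung,
                rung.lam,
                decomp.epp1,
                decomp.epp2,
                decomp.epw,
                decomp.eww,
                rec.monitor,
                rec.to_rung,
                rec.delta,
                int(rec.accepted),
                float(sim.coords[0]),
            ]
        )
        if schedule.weight_update == "fixed":
            continue
        if not all_visited:
            update_weights_on_the_fly(state, ladder, schedule.method)
            all_visited = bool(np.all(state.counts > 0))
            if all_visited:
                weights_history.append((state.step, state.weights.tolist()))
        elif (
            schedule.weight_update == "averaged"
            and (seg + 1) % schedule.weight_refresh_interval == 0
        ):
            update_weights_averaged(state, ladder, schedule.method)
            weights_history.append((state.step, state.weights.tolist()))

    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    if schedule.weight_update != "fixed" and len(records):
        final = estimate_weights_from_records(
            records, ladder, schedule.method, schedule.burn_in_fraction
        )
        weights_history.append((state.step, final.tolist()))
    header = {
        "format": "soltemper-log v1",
        "unit_system": f"reduced kb={ladder.kb}",
        "seed": integrator.seed,
        "method": schedule.method,
        "ladder": {
            "t_min": ladder.t_min,
            "t_max": ladder.t_max,
            "t_ref": ladder.t_ref,
            "n_rungs": ladder.n_rungs,
            "n_below_ref": ladder.n_below_ref,
            "kb": ladder.kb,
        },
        "integrator": {
            "timestep": integrator.timestep,
            "friction": integrator.friction,
            "t_ref": integrator.t_ref,
            "seed": integrator.seed,
        },
        "schedule": {
            "exchange_interval": schedule.exchange_interval,
            "n_segments": schedule.n_segments,
            "weight_update": schedule.weight_update,
            "weight_refresh_interval": schedule.weight_refresh_interval,
            "burn_in_fraction": schedule.burn_in_fraction,
            "monitor_variant": schedule.monitor_variant,
        },
        "system": {
            "d_solute": system.d_solute,
            "d_solvent": system.d_solvent,
            "potential_kind": system.potential_kind,
            "k_solute": system.k_solute,
            "k_solvent": system.k_solvent,
            "barrier": system.barrier,
            "well_separation": system.well_separation,
            "coupling": system.coupling,
            "k_restraint": system.k_restraint,
        },
    }
    if header_extra:
        header.update(header_extra)
    return TrajectoryLog(header=header, records=records, weights_history=weights_history)
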
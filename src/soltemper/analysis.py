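"""Post-processing of tempering runs.

Covers the analyses that turn a rung/order-parameter trajectory into
thermodynamic observables: the effective solute temperature of a scaled
rung, two-threshold (hysteresis) state classification and transition
counting, folded-fraction stability curves, the four-parameter logistic
melting fit, ω-dihedral cis/trans classification, backbone RMSD with
Kabsch superposition, and rung-level exchange diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial.transform import Rotation

from .hamiltonian import EnergyDecomposition, signed_dihedral
from .ladder import LadderSpec, Rung
from .logio import TrajectoryLog

__all__ = [
    "StateSeries",
    "MeltingFit",
    "EffectiveTemperatureResult",
    "effective_temperature",
    "classify_states",
    "count_transitions",
    "folded_fraction_curve",
    "fit_melting_curve",
    "four_parameter_logistic",
    "omega_angle",
    "cis_mask",
    "backbone_rmsd",
    "rung_diagnostics",
    "FitError",
]

FOLDED, INTERMEDIATE, UNFOLDED = "folded", "intermediate", "unfolded"

# default hysteresis bands (nm): folded below / unfolded above,
# bound below / unbound above
FOLDING_THRESHOLDS = (0.2, 0.25)
BINDING_THRESHOLDS = (0.5, 1.0)


class FitError(RuntimeError):
    """Raised when the melting-curve fit cannot be performed."""


@dataclass
class StateSeries:
    """Per-frame order parameter, rung index, and two-state assignment."""

    times: np.ndarray
    values: np.ndarray
    states: np.ndarray
    rungs: Optional[np.ndarray] = None
    thresholds: tuple = FOLDING_THRESHOLDS

    def __post_init__(self) -> None:
        n = len(self.times)
        if len(self.values) != n or len(self.states) != n:
            raise ValueError("series lengths differ")
        if self.rungs is not None and len(self.rungs) != n:
            raise ValueError("series lengths differ")


@dataclass
class EffectiveTemperatureResult:
    """Corrected solute temperature of one rung."""

    rung: int
    beta_eff: float
    t_eff: float
    ratio_mean: float


@dataclass
class MeltingFit:
    """Four-parameter logistic fit y = d + (a − d)/(1 + (x/c)^b).

    ``c`` is the melting temperature T_m (curve inflection), ``b`` the
    Hill slope, ``a``/``d`` the low-/high-temperature plateaus.
    """

    a: float
    d: float
    c: float
    b: float
    covariance: np.ndarray
    extrapolated: bool = False

    @property
    def t_m(self) -> float:
        return self.c

    def ci95_c(self) -> float:
        """Half-width of the 95% normal CI on the melting temperature."""
        return 1.96 * math.sqrt(self.covariance[2, 2])


def effective_temperature(
    decomps: Iterable[EnergyDecomposition], m: Rung, ref: Rung
) -> EffectiveTemperatureResult:
    """Corrected solute temperature of rung *m*.

    In solute tempering only E_pp1 (and partially E_pw) is heated, so
    the real solute temperature lies between T_m and T_ref:
    ⟨β′⟩ = β_m·(1 + (β_ref/β_m − 1)·⟨E_pw/(E_pp + E_pw)⟩),
    the ratio averaged framewise.  Frames with E_pp + E_pw = 0 are
    skipped; if every frame is degenerate the ratio is undefined.
    """
    ratios = []
    for d in decomps:
        denom = d.solute + d.epw
        if denom != 0.0:
            ratios.append(d.epw / denom)
    if not ratios:
        raise ValueError("undefined ratio")
    ratio_mean = float(np.mean(ratios))
    beta_eff = m.beta * (1.0 + (ref.beta / m.beta - 1.0) * ratio_mean)
    kb = 1.0 / (m.beta * m.temperature)
    return EffectiveTemperatureResult(
        rung=m.index,
        beta_eff=beta_eff,
        t_eff=1.0 / (kb * beta_eff),
        ratio_mean=ratio_mean,
    )


def classify_states(
    values,
    low: float = FOLDING_THRESHOLDS[0],
    high: float = FOLDING_THRESHOLDS[1],
    times=None,
    rungs=None,
) -> StateSeries:
    """Two-threshold classification of an order-parameter series.

    value < low → folded (bound); value > high → unfolded (unbound);
    the band in between is left intermediate so that threshold chatter
    cannot masquerade as transitions.
    """
    if low >= high:
        raise ValueError("invalid hysteresis band")
    values = np.asarray(values, dtype=float)
    states = np.where(
        values < low, FOLDED, np.where(values > high, UNFOLDED, INTERMEDIATE)
    )
    times = np.arange(len(values), dtype=float) if times is None else np.asarray(times)
    rungs = None if rungs is None else np.asarray(rungs)
    return StateSeries(
        times=times, values=values, states=states, rungs=rungs, thresholds=(low, high)
    )


def count_transitions(series: StateSeries, mask=None) -> int:
    """Committed folded↔unfolded switches of the hysteresis automaton.

    Intermediate frames never change the committed state; a switch is
    counted only when the series reaches the opposite definite state.
    ``mask`` (e.g. a cis-proline flag) excludes frames entirely.
    """
    states = series.states
    if mask is not None:
        states = states[~np.asarray(mask, dtype=bool)]
    if len(states) == 0:
        raise ValueError("no data")
    committed = None
    n = 0
    for s in states:
        if s == INTERMEDIATE:
            continue
        if committed is not None and s != committed:
            n += 1
        committed = s
    return n


def transitions_per_time(
    series: StateSeries, total_time: float, ref_rung_time: Optional[float] = None
) -> dict:
    """Transition counts normalised by simulated time.

    Reports both conventions: per unit of total simulated time across
    all rungs, and (when the time spent at the reference rung is given)
    per unit of reference-rung time.
    """
    k = count_transitions(series)
    out = {"count": k, "per_total_time": k / total_time if total_time else math.nan}
    if ref_rung_time:
        out["per_ref_rung_time"] = k / ref_rung_time
    return out


def folded_fraction_curve(
    series: StateSeries,
    ladder: LadderSpec,
    effective_temps: Optional[Sequence[float]] = None,
    mask=None,
) -> pd.DataFrame:
    """Per-rung folded fraction with binomial confidence intervals.

    Intermediate frames are excluded from both numerator and
    denominator (the definite states are defined by disjoint
    thresholds; the band carries no assignment).  The temperature axis
    uses per-rung effective temperatures when supplied, raw rung
    temperatures otherwise.  Rungs without definite frames are emitted
    with a missing fraction.
    """
    if series.rungs is None:
        raise ValueError("per-frame rung index required")
    states = series.states
    rungs = series.rungs
    if mask is not None:
        keep = ~np.asarray(mask, dtype=bool)
        states, rungs = states[keep], rungs[keep]
    rows = []
    for r in ladder.rungs:
        sel = states[rungs == r.index]
        n_f = int(np.sum(sel == FOLDED))
        n_u = int(np.sum(sel == UNFOLDED))
        n = n_f + n_u
        temp = (
            effective_temps[r.index] if effective_temps is not None else r.temperature
        )
        if n == 0:
            rows.append((r.index, temp, math.nan, math.nan, 0))
            continue
        p = n_f / n
        ci = 1.96 * math.sqrt(p * (1.0 - p) / n)
        rows.append((r.index, temp, p, ci, n))
    return pd.DataFrame(
        rows, columns=["rung_index", "temperature", "fraction", "ci95", "n_frames"]
    )


def four_parameter_logistic(x, a, d, c, b):
    """y = d + (a − d) / (1 + (x/c)^b)."""
    return d + (a - d) / (1.0 + (np.asarray(x, dtype=float) / c) ** b)


def fit_melting_curve(temperatures, fractions, sigma=None) -> MeltingFit:
    """Least-squares 4PL fit of a folded-fraction-vs-temperature curve.

    Initialisation: a = max(y), d = min(y), c = the temperature closest
    to the half-height, b = 10; bounds keep the plateaus in [−0.2, 1.2],
    the slope positive, and T_m within the data span ± 20%.
    """
    x = np.asarray(temperatures, dtype=float)
    y = np.asarray(fractions, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if sigma is not None:
        sigma = np.asarray(sigma, dtype=float)[keep]
    if len(x) < 5:
        raise FitError("fit failed: need at least 5 points")
    if float(np.ptp(y)) < 1e-3:
        raise FitError("no sigmoid")
    a0, d0 = float(np.max(y)), float(np.min(y))
    half = 0.5 * (a0 + d0)
    c0 = float(x[np.argmin(np.abs(y - half))])
    span = float(np.ptp(x))
    lo = [-0.2, -0.2, float(np.min(x)) - 0.2 * span, 1e-6]
    hi = [1.2, 1.2, float(np.max(x)) + 0.2 * span, np.inf]
    c0 = min(max(c0, lo[2]), hi[2])
    try:
        popt, pcov = curve_fit(
            four_parameter_logistic,
            x,
            y,
            p0=[a0, d0, c0, 10.0],
            sigma=sigma,
            bounds=(lo, hi),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"fit failed: {exc}") from exc
    a, d, c, b = (float(v) for v in popt)
    extrapolated = not (float(np.min(x)) <= c <= float(np.max(x)))
    return MeltingFit(a=a, d=d, c=c, b=b, covariance=pcov, extrapolated=extrapolated)


def omega_angle(p1, p2, p3, p4) -> float:
    """Backbone ω dihedral Cα(i−1)–C(i−1)–N(i)–Cα(i), degrees in (−180, 180].

    trans (the overwhelmingly common peptide-bond geometry) is ±180°,
    cis is 0°.
    """
    return signed_dihedral(p1, p2, p3, p4)


def cis_mask(omega_series) -> np.ndarray:
    """Flag frames whose ω angle is cis (|ω| < 90°).

    90° is the symmetric separatrix between the two planar isomers.
    """
    om = np.asarray(omega_series, dtype=float)
    return np.abs(om) < 90.0


def backbone_rmsd(
    coords,
    ref_coords,
    selection=None,
    rmsd_selection=None,
) -> float:
    """RMSD after least-squares (Kabsch) superposition.

    ``selection`` indexes the atoms used for the fit (default: all);
    ``rmsd_selection`` the atoms the deviation is computed over
    (default: the fit selection).  Passing a receptor selection for the
    fit and a ligand selection for the RMSD reproduces the
    align-on-receptor / measure-ligand convention used for
    protein–peptide complexes: the ligand is *not* refit.
    """
    coords = np.asarray(coords, dtype=float)
    ref = np.asarray(ref_coords, dtype=float)
    if coords.shape != ref.shape or coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("selection mismatch")
    sel = np.arange(len(coords)) if selection is None else np.asarray(selection)
    out_sel = sel if rmsd_selection is None else np.asarray(rmsd_selection)
    if np.max(sel) >= len(coords) or np.max(out_sel) >= len(coords):
        raise ValueError("selection mismatch")
    mob, fix = coords[sel], ref[sel]
    mob_c, fix_c = mob.mean(axis=0), fix.mean(axis=0)
    rot, _ = Rotation.align_vectors(fix - fix_c, mob - mob_c)
    moved = rot.apply(coords - mob_c) + fix_c
    diff = moved[out_sel] - ref[out_sel]
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def rung_diagnostics(log: TrajectoryLog, n_bins: int = 40) -> dict:
    """Exchange diagnostics of a tempering log.

    Returns per-rung transition (acceptance) probability, per-rung
    monitor-energy histograms, the rung-occupancy histogram, and the
    overall acceptance.  Healthy ladders show neighbouring monitor
    histograms with substantial overlap and acceptance well away from
    zero at every rung.
    """
    rec = log.records
    if len(rec) == 0:
        raise ValueError("empty log")
    by_rung = rec.groupby("rung_index")
    acc = by_rung["accepted"].agg(["mean", "count"]).reset_index()
    acc.columns = ["rung_index", "acceptance", "n_attempts"]
    occupancy = by_rung.size().rename("n_segments").reset_index()
    mon = rec["monitor"].to_numpy()
    edges = np.histogram_bin_edges(mon, bins=n_bins)
    hists = {}
    for rung_idx, grp in by_rung:
        counts, _ = np.histogram(grp["monitor"].to_numpy(), bins=edges)
        hists[int(rung_idx)] = counts
    hist_df = pd.DataFrame(hists)
    hist_df.insert(0, "bin_left", edges[:-1])
    hist_df.insert(1, "bin_right", edges[1:])
    return {
        "acceptance": acc,
        "occupancy": occupancy,
        "monitor_histograms": hist_df,
        "overall_acceptance": float(rec["accepted"].mean()),
    }
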
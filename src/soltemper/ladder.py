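"""Temperature / λ ladder construction for solute-tempering runs.

A ladder is an ordered set of temperature rungs, exponentially spaced
within each of the two segments [t_min, t_ref] and [t_ref, t_max].  The
reference temperature need not be the coldest rung: solute tempering
benefits from one or more rungs *below* the physical temperature of
interest, so the reference sits inside the ladder and the scaling factor
λ_m = T_ref / T_m = β_m / β_ref is > 1 on the cold side and < 1 on the
hot side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

__all__ = [
    "Rung",
    "LadderSpec",
    "build_ladder",
    "choose_split",
    "lambda_of_temperature",
]


@dataclass(frozen=True)
class Rung:
    """One level of a tempering ladder.

    Attributes
    ----------
    index : int
        0-based position in the ladder (cold to hot).
    temperature : float
        Rung temperature, kelvin (or kelvin-equivalent reduced units).
    beta : float
        Inverse temperature 1/(k_B T) in the ladder's unit system.
    lam : float
        Hamiltonian scaling factor λ_m = T_ref/T_m = β_m/β_ref.
    weight : float
        Expanded-ensemble weight w_m (gauge: 0 at the reference rung).
    """

    index: int
    temperature: float
    beta: float
    lam: float
    weight: float = 0.0

    def __post_init__(self) -> None:
        if self.temperature <= 0 or self.beta <= 0:
            raise ValueError("invalid temperature")


@dataclass(frozen=True)
class LadderSpec:
    """An ordered temperature/λ ladder with a designated reference rung.

    ``kb`` fixes the unit system: 1.0 for reduced units (the toy engine),
    0.008314462618 for kJ/mol with temperatures in kelvin.  β is always
    1/(kb·T); the unit system is explicit, never implied.
    """

    t_min: float
    t_max: float
    t_ref: float
    n_rungs: int
    n_below_ref: int
    rungs: tuple[Rung, ...]
    kb: float = 1.0

    @property
    def ref_index(self) -> int:
        return self.n_below_ref

    @property
    def ref_rung(self) -> Rung:
        return self.rungs[self.n_below_ref]

    @property
    def temperatures(self) -> list[float]:
        return [r.temperature for r in self.rungs]

    @property
    def lambdas(self) -> list[float]:
        return [r.lam for r in self.rungs]

    def with_weights(self, weights: Sequence[float]) -> "LadderSpec":
        """Return a copy with per-rung weights attached."""
        if len(weights) != self.n_rungs:
            raise ValueError("weights length does not match ladder")
        new = tuple(replace(r, weight=float(w)) for r, w in zip(self.rungs, weights))
        return replace(self, rungs=new)


def lambda_of_temperature(t: float, t_ref: float) -> float:
    """λ scaling factor of a rung at temperature ``t``: T_ref / t."""
    if t <= 0 or t_ref <= 0:
        raise ValueError("invalid temperature")
    return t_ref / t


def _segment(lo: float, hi: float, n_intervals: int) -> list[float]:
    """Geometric progression lo..hi with n_intervals intervals (inclusive)."""
    if n_intervals == 0:
        return [lo]
    ratio = hi / lo
    return [lo * ratio ** (k / n_intervals) for k in range(n_intervals + 1)]


def choose_split(t_min: float, t_max: float, t_ref: float, n_rungs: int) -> int:
    """Pick the number of geometric intervals between t_min and t_ref.

    Scans every admissible split and returns the one that makes the
    per-interval geometric ratio of the cold segment closest (in log
    space) to that of the hot segment; ties break toward fewer cold
    intervals.  Degenerate references (t_ref equal to an endpoint) pin
    the split to that endpoint.
    """
    _check_bounds(t_min, t_max, t_ref, n_rungs)
    if t_ref == t_min:
        return 0
    if t_ref == t_max:
        return n_rungs - 1
    log_below = math.log(t_ref / t_min)
    log_above = math.log(t_max / t_ref)
    best, best_cost = None, None
    for nb in range(1, n_rungs - 1):
        na = n_rungs - 1 - nb
        cost = abs(log_below / nb - log_above / na)
        if best_cost is None or cost < best_cost:
            best, best_cost = nb, cost
    if best is None:
        raise ValueError("rung budget exhausted")
    return best


def _check_bounds(t_min: float, t_max: float, t_ref: float, n_rungs: int) -> None:
    if not (0 < t_min <= t_ref <= t_max):
        raise ValueError("invalid ladder bounds")
    if n_rungs < 2:
        raise ValueError("invalid ladder bounds: n_rungs must be >= 2")


def build_ladder(
    t_min: float,
    t_max: float,
    t_ref: float,
    n_rungs: int,
    n_below_ref: Optional[int] = None,
    kb: float = 1.0,
) -> LadderSpec:
    """Build an exponentially spaced ladder with an interior reference.

    Temperatures follow T_k = T_lo · (T_hi/T_lo)^{k/(m−1)} within each
    segment; the two segments share the reference rung.  ``n_below_ref``
    is the number of geometric intervals between ``t_min`` and ``t_ref``
    (0 only when they coincide); when omitted it is chosen by
    :func:`choose_split`.
    """
    _check_bounds(t_min, t_max, t_ref, n_rungs)
    if n_below_ref is None:
        n_below_ref = choose_split(t_min, t_max, t_ref, n_rungs)
    if n_below_ref < 0 or n_below_ref > n_rungs - 1:
        raise ValueError("rung budget exhausted")
    if t_ref == t_min and n_below_ref != 0:
        raise ValueError("invalid ladder bounds: t_ref = t_min requires n_below_ref = 0")
    if t_ref > t_min and n_below_ref == 0:
        raise ValueError("invalid ladder bounds: interior t_ref needs n_below_ref >= 1")
    n_above = n_rungs - 1 - n_below_ref
    if t_ref < t_max and n_above == 0:
        raise ValueError("rung budget exhausted")
    if t_ref == t_max and t_ref != t_min and n_above != 0:
        raise ValueError("invalid ladder bounds: t_ref = t_max requires n_below_ref = n_rungs - 1")

    temps = _segment(t_min, t_ref, n_below_ref)
    temps += _segment(t_ref, t_max, n_above)[1:] if n_above else []
    # guard against drift at the shared endpoints
    temps[0], temps[n_below_ref], temps[-1] = t_min, t_ref, t_max

    rungs = tuple(
        Rung(
            index=i,
            temperature=t,
            beta=1.0 / (kb * t),
            lam=lambda_of_temperature(t, t_ref),
        )
        for i, t in enumerate(temps)
    )
    return LadderSpec(
        t_min=t_min,
        t_max=t_max,
        t_ref=t_ref,
        n_rungs=n_rungs,
        n_below_ref=n_below_ref,
        rungs=rungs,
        kb=kb,
    )


def format_ladder(ladder: LadderSpec) -> str:
    """Two-column table (temperature K to 0.1, λ to 2 decimals)."""
    lines = ["index\ttemperature\tlambda"]
    for r in ladder.rungs:
        lines.append(f"{r.index}\t{r.temperature:.1f}\t{r.lam:.2f}")
    return "\n".join(lines)
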
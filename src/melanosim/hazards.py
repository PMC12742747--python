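"""Piecewise-constant hazard functions over age, with exact inversion sampling.

All event-time distributions in the simulator are driven by hazards that are
piecewise constant over age.  For such a hazard the cumulative hazard is
piecewise linear, so event times can be sampled exactly by inverting the
cumulative hazard at a unit-exponential deviate -- no time-step discretisation
error is introduced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["PiecewiseHazard", "NEVER"]

#: Sentinel age returned when the cumulative hazard is exhausted before the
#: event occurs (the event never happens).
NEVER = math.inf


@dataclass(frozen=True)
class PiecewiseHazard:
    """A hazard that is constant on intervals ``[edges[i], edges[i+1])``.

    Parameters
    ----------
    edges:
        Strictly increasing breakpoints (ages, years).  The last segment
        ``[edges[-1], inf)`` carries ``rates[-1]``.
    rates:
        Non-negative hazard rates per person-year, ``len(rates) == len(edges)``.
    """

    edges: tuple
    rates: tuple

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edges)
        rates = tuple(float(r) for r in self.rates)
        if len(edges) != len(rates):
            raise ValueError("edges and rates must have equal length")
        if len(edges) == 0:
            raise ValueError("empty hazard")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("edges must be strictly increasing")
        if any(r < 0 or not math.isfinite(r) for r in rates):
            raise ValueError("hazard rates must be finite and non-negative")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "rates", rates)

    @classmethod
    def constant(cls, rate: float, start: float = 0.0) -> "PiecewiseHazard":
        return cls(edges=(start,), rates=(rate,))

    def rate_at(self, age: float) -> float:
        """Hazard rate at ``age`` (0 before the first edge)."""
        if age < self.edges[0]:
            return 0.0
        idx = np.searchsorted(self.edges, age, side="right") - 1
        return self.rates[idx]

    def cumulative(self, a0: float, a1: float) -> float:
        """Integrated hazard over ``[a0, a1]``."""
        if a1 <= a0:
            return 0.0
        total = 0.0
        edges, rates = self.edges, self.rates
        n = len(edges)
        for i in range(n):
            seg_lo = edges[i]
            seg_hi = edges[i + 1] if i + 1 < n else math.inf
            lo = max(a0, seg_lo)
            hi = min(a1, seg_hi)
            if hi > lo:
                total += rates[i] * (hi - lo)
        return total

    def invert(self, start: float, target: float) -> float:
        """Age ``a >= start`` with cumulative hazard ``target`` accrued since
        ``start``; :data:`NEVER` if the total available hazard is smaller."""
        if target <= 0.0:
            return start
        edges, rates = self.edges, self.rates
        n = len(edges)
        remaining = target
        pos = max(start, edges[0])
        # segment containing pos
        i = int(np.searchsorted(edges, pos, side="right")) - 1
        i = max(i, 0)
        while i < n:
            seg_hi = edges[i + 1] if i + 1 < n else math.inf
            rate = rates[i]
            if rate > 0.0:
                span = seg_hi - pos
                need = remaining / rate
                if need <= span:
                    return pos + need
                remaining -= rate * span
            pos = seg_hi
            i += 1
        return NEVER

    def sample(self, start: float, rng: np.random.Generator) -> float:
        """Draw an event age ``> start`` by exact inversion; :data:`NEVER` if
        the event does not occur in finite time."""
        e = rng.standard_exponential()
        return self.invert(start, e)

    def scaled(self, factor: float) -> "PiecewiseHazard":
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return PiecewiseHazard(self.edges, tuple(r * factor for r in self.rates))

    def plus(self, other: "PiecewiseHazard") -> "PiecewiseHazard":
        """Pointwise sum of two piecewise hazards."""
        edges = sorted(set(self.edges) | set(other.edges))
        rates = tuple(self.rate_at(e) + other.rate_at(e) for e in edges)
        return PiecewiseHazard(tuple(edges), rates)
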
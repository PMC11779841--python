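"""First-order degradation kinetics and the degraded-matrix proportion solver.

The biofilm matrix is degraded by enzymes secreted inside it.  If the
local degradation rate is first order in the substrate concentration,

    d[S]/dt = -k [S]        =>   [S](t) = C0 · exp(-k t),

then the quantity degraded over an interval of length ``t`` in volume
``V`` is

    D = (C0 - [S](t)) · V = C0 (1 - exp(-k t)) · V,

which is identically ``<[S]> · k t · V`` with ``<[S]>`` the time-averaged
concentration — i.e. the amount consumed is linearly proportional to the
average substrate concentration.  Under the simplifying assumption that
proteins and carbohydrates are degraded in the same volume from the same
total biomass, the ratio of a component's degraded quantities on two
consecutive intervals equals the ratio of its compositional percentages
in the degraded matrix on those intervals, which yields a 4-equation
linear system for the percentages (solved in closed form by
:func:`solve_proportions`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSystemError, InconsistentProportionsError, InputError

#: Below this value of k*t the closed form (1 - exp(-kt))/(kt) is evaluated
#: by its Taylor series to avoid catastrophic cancellation.
_SERIES_KT_THRESHOLD = 1e-8


@dataclass(frozen=True)
class FirstOrderModel:
    """First-order decay of a substrate: initial concentration ``c0``
    (arbitrary concentration units), rate constant ``k`` (1/day) and
    reaction volume ``v`` (arbitrary volume units)."""

    c0: float
    k: float
    v: float = 1.0

    def __post_init__(self) -> None:
        if self.c0 < 0:
            raise InputError(f"c0 must be >= 0, got {self.c0}")
        if self.k < 0:
            raise InputError(f"k must be >= 0, got {self.k}")
        if not self.v > 0:
            raise InputError(f"v must be > 0, got {self.v}")


@dataclass(frozen=True)
class DegradationObservation:
    """Observed degraded quantity ``d`` of one component over one interval."""

    component: str
    interval: str
    d: float

    def __post_init__(self) -> None:
        if self.d < 0:
            raise InputError(f"degraded quantity must be >= 0, got {self.d}")


@dataclass(frozen=True)
class ProportionSolution:
    """Compositional percentages of the degraded matrix on two intervals.

    ``p1 + c1 = 100`` and ``p2 + c2 = 100`` by construction.
    """

    p1: float
    p2: float
    c1: float
    c2: float

    def rounded(self) -> tuple[int, int, int, int]:
        """Percentages rounded to integer percent, in (p1, p2, c1, c2) order."""
        return (round(self.p1), round(self.p2), round(self.c1), round(self.c2))


def substrate_concentration(model: FirstOrderModel, t) -> np.ndarray | float:
    """Substrate concentration ``C0 exp(-k t)`` at time ``t`` (days)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InputError("time must be >= 0")
    out = model.c0 * np.exp(-model.k * t)
    return out if out.ndim else float(out)


def average_concentration(model: FirstOrderModel, t) -> np.ndarray | float:
    """Time-averaged concentration over [0, t]:  C0 (1 - exp(-kt)) / (kt).

    A 3-term Taylor series ``C0 (1 - kt/2 + (kt)^2/6)`` replaces the closed
    form when ``kt`` is so small that the subtraction would cancel.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise InputError("time must be > 0 for an interval average")
    kt = model.k * t
    small = kt < _SERIES_KT_THRESHOLD
    with np.errstate(divide="ignore", invalid="ignore"):
        closed = model.c0 * -np.expm1(-kt) / kt
    series = model.c0 * (1.0 - kt / 2.0 + kt * kt / 6.0)
    out = np.where(small, series, closed)
    return out if out.ndim else float(out)


def degraded_quantity(model: FirstOrderModel, t) -> np.ndarray | float:
    """Quantity degraded over [0, t]:  C0 (1 - exp(-kt)) V."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InputError("time must be >= 0")
    out = model.c0 * -np.expm1(-model.k * t) * model.v
    return out if out.ndim else float(out)


def solve_proportions(dp1: float, dp2: float, dc1: float, dc2: float) -> ProportionSolution:
    """Solve the degraded-matrix composition from four degraded quantities.

    ``dp1, dp2`` are the protein quantities degraded on the first and second
    interval; ``dc1, dc2`` the carbohydrate quantities.  With equal volume
    and total biomass on both intervals, the percentages obey

        p1 + c1 = 100,   p2 + c2 = 100,
        p1/p2 = dp1/dp2,   c1/c2 = dc1/dc2,

    whose closed-form solution is ``p2 = 100 (1 - rc) / (rp - rc)`` with
    ``rp = dp1/dp2`` and ``rc = dc1/dc2``.

    Raises
    ------
    DegenerateSystemError
        If ``rp == rc`` within 1e-12 (the system is singular).
    InconsistentProportionsError
        If any percentage leaves [0, 100]: the equal-volume/equal-biomass
        assumption is then violated and the raw values are reported rather
        than clamped.
    """
    for name, val in (("dp1", dp1), ("dp2", dp2), ("dc1", dc1), ("dc2", dc2)):
        if not val > 0:
            raise InputError(f"{name} must be > 0, got {val}")
    rp = dp1 / dp2
    rc = dc1 / dc2
    if math.isclose(rp, rc, rel_tol=1e-12, abs_tol=1e-12):
        raise DegenerateSystemError(
            f"protein ratio {rp!r} equals carbohydrate ratio {rc!r}: system singular"
        )
    p2 = 100.0 * (1.0 - rc) / (rp - rc)
    p1 = rp * p2
    c1 = 100.0 - p1
    c2 = 100.0 - p2
    sol = ProportionSolution(p1=p1, p2=p2, c1=c1, c2=c2)
    for name, val in (("p1", p1), ("p2", p2), ("c1", c1), ("c2", c2)):
        if not (0.0 <= val <= 100.0):
            raise InconsistentProportionsError(
                "proportion solution outside [0, 100]%: "
                f"p1={p1:.6g} p2={p2:.6g} c1={c1:.6g} c2={c2:.6g} "
                "(equal-volume/equal-biomass assumption violated)"
            )
    return sol


def observations_to_solution(observations: list[DegradationObservation]) -> ProportionSolution:
    """Solve proportions from four labeled observations.

    Expects exactly two components; the first sorted unique component label
    containing 'prot' (case-insensitive) is taken as the protein series,
    otherwise the caller should use :func:`solve_proportions` directly.
    """
    if len(observations) != 4:
        raise InputError(f"need exactly 4 observations, got {len(observations)}")
    comps = sorted({o.component for o in observations})
    if len(comps) != 2:
        raise InputError(f"need exactly 2 components, got {comps}")
    prot = next((c for c in comps if "prot" in c.lower()), comps[0])
    carb = next(c for c in comps if c != prot)
    by = {(o.component, o.interval): o.d for o in observations}
    intervals = sorted({o.interval for o in observations})
    if len(intervals) != 2:
        raise InputError(f"need exactly 2 intervals, got {intervals}")
    i1, i2 = intervals
    return solve_proportions(by[(prot, i1)], by[(prot, i2)], by[(carb, i1)], by[(carb, i2)])
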
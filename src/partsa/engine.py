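"""Three-state partitioned survival engine.

State occupancy is read directly off the two survival curves of an arm:
membership in the progression-free state is S_PFS(t) (clamped by S_OS where
extrapolated curves cross), death is 1 - S_OS(t), and progressed disease is
the remainder.  Occupancy is evaluated on a 21-day cycle grid over the model
horizon; discounted life-years, QALYs and costs are accrued per cycle and an
incremental cost-effectiveness ratio compares two arms.

Unit conventions: model time is tracked in months of 30.4375 days
(365.25/12); a 21-day cycle is therefore 21/30.4375 months and 21/365.25
years.  Discounting is continuous-in-time compounding, (1+r)^(-t_years),
evaluated at the occupancy grid times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .survival import DistributionSpec, survival_at

__all__ = [
    "DAYS_PER_MONTH",
    "ModelSettings",
    "OccupancyTrace",
    "CEResult",
    "IcerResult",
    "state_occupancy",
    "discount_factor",
    "accrue",
    "run_arm",
    "icer",
]

DAYS_PER_MONTH = 365.25 / 12.0  # 30.4375


@dataclass(frozen=True)
class ModelSettings:
    """Run settings shared by every deterministic and probabilistic run."""

    cycle_days: float = 21.0
    horizon_years: float = 10.0
    discount_rate_annual: float = 0.05
    half_cycle_correction: bool = False
    wtp_per_qaly: float = 36203.88

    def __post_init__(self):
        if self.horizon_years <= 0:
            raise ValueError("horizon must be positive")
        if not (0.0 <= self.discount_rate_annual <= 1.0):
            raise ValueError("discount rate must lie in [0, 1]")
        if self.cycle_days <= 0:
            raise ValueError("cycle length must be positive")

    @property
    def cycle_months(self) -> float:
        return self.cycle_days / DAYS_PER_MONTH

    @property
    def cycle_years(self) -> float:
        return self.cycle_days / 365.25

    @property
    def n_cycles(self) -> int:
        return int(np.floor(self.horizon_years * 365.25 / self.cycle_days))


@dataclass(frozen=True)
class OccupancyTrace:
    """Per-cycle state membership and discount factors."""

    t_months: np.ndarray
    p_pfs: np.ndarray
    p_pd: np.ndarray
    p_death: np.ndarray
    discount: np.ndarray
    cycle_years: float

    def __post_init__(self):
        total = self.p_pfs + self.p_pd + self.p_death
        if np.max(np.abs(total - 1.0)) > 1e-12:
            raise ValueError("state occupancies must sum to 1 at every cycle")
        if np.any(self.p_pfs < 0) or np.any(self.p_pd < 0) or np.any(self.p_death < 0):
            raise ValueError("state occupancies must be non-negative")
        if np.any(np.diff(self.p_death) < -1e-12):
            raise ValueError("death occupancy must be non-decreasing")

    @property
    def n_cycles(self) -> int:
        return len(self.t_months)


@dataclass(frozen=True)
class CEResult:
    """Discounted totals for one strategy arm."""

    arm: str
    total_cost: float
    ly: float
    qaly: float
    cost_breakdown: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.cost_breakdown:
            if abs(sum(self.cost_breakdown.values()) - self.total_cost) > 1e-6:
                raise ValueError("cost breakdown must sum to the total")


@dataclass(frozen=True)
class IcerResult:
    delta_cost: float
    delta_qaly: float
    icer: float | None
    label: str  # "icer" | "dominant" | "dominated" | "undefined"


def discount_factor(t_years, rate: float):
    """Continuous-compounding present-value factor (1+rate)^(-t)."""
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    t = np.asarray(t_years, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    return (1.0 + rate) ** (-t)


def state_occupancy(pfs: DistributionSpec, os: DistributionSpec,
                    settings: ModelSettings) -> OccupancyTrace:
    """Partition the cohort into PFS / PD / death on the cycle grid.

    With half-cycle correction on, survival is evaluated at cycle midpoints;
    otherwise at cycle starts (including cycle 0, where occupancy is (1,0,0)).
    """
    k = np.arange(settings.n_cycles + 1, dtype=float)
    t_m = k * settings.cycle_months
    if settings.half_cycle_correction:
        t_m = t_m + settings.cycle_months / 2.0
    s_pfs = np.asarray(survival_at(pfs, t_m), float)
    s_os = np.asarray(survival_at(os, t_m), float)
    p_pfs = np.minimum(s_pfs, s_os)  # clamp if extrapolated curves cross
    p_death = 1.0 - s_os
    p_pd = np.maximum(s_os - p_pfs, 0.0)
    t_years = t_m * DAYS_PER_MONTH / 365.25
    df = discount_factor(t_years, settings.discount_rate_annual)
    return OccupancyTrace(t_months=t_m, p_pfs=p_pfs, p_pd=p_pd, p_death=p_death,
                          discount=df, cycle_years=settings.cycle_years)


def accrue(trace: OccupancyTrace, per_cycle_values: dict,
           one_off: dict | None = None) -> float:
    """Discounted sum of state-occupancy-weighted per-cycle values.

    ``per_cycle_values`` maps state name ("pfs", "pd") to either a scalar
    (constant per cycle) or an array over cycles.  ``one_off`` maps a cycle
    index to a lump value applied at that cycle's discount factor.
    """
    total = 0.0
    occ = {"pfs": trace.p_pfs, "pd": trace.p_pd}
    for state in ("pfs", "pd"):
        if state not in per_cycle_values:
            raise KeyError(f"per-cycle values missing state {state!r}")
        v = np.broadcast_to(np.asarray(per_cycle_values[state], float),
                            trace.p_pfs.shape)
        total += float(np.sum(trace.discount * occ[state] * v))
    for cyc, v in (one_off or {}).items():
        total += float(trace.discount[int(cyc)]) * float(v)
    return total


def run_arm(arm, settings: ModelSettings) -> CEResult:
    """Run one strategy arm end to end.

    ``arm`` is a :class:`partsa.valuation.ArmDefinition`: it owns the two
    survival curves, the utility set and the cost streams.  This function
    owns the occupancy, discounting and accrual arithmetic.
    """
    trace = state_occupancy(arm.pfs, arm.os, settings)
    n = trace.n_cycles

    streams = arm.cost_streams(n, settings)
    breakdown = {}
    for name, (per_cycle, one_off) in streams.items():
        breakdown[name] = accrue(trace, per_cycle, one_off)
    total_cost = float(sum(breakdown.values()))

    cyc_y = settings.cycle_years
    ly = float(np.sum(trace.discount * (trace.p_pfs + trace.p_pd))) * cyc_y
    u = arm.utilities
    qaly = accrue(
        trace,
        {"pfs": u.u_pfs * cyc_y, "pd": u.u_pd * cyc_y},
        {0: -arm.sae_qaly_loss(settings)},
    )
    return CEResult(arm=arm.name, total_cost=total_cost, ly=ly, qaly=qaly,
                    cost_breakdown=breakdown)


def icer(intervention: CEResult, comparator: CEResult,
         tol: float = 1e-12) -> IcerResult:
    """Incremental cost-effectiveness ratio on unrounded totals.

    Sign-discordant cases are labelled instead of reported as a ratio:
    cheaper-and-more-effective is "dominant", dearer-and-less-effective is
    "dominated"; a zero QALY difference is "undefined".
    """
    dc = intervention.total_cost - comparator.total_cost
    dq = intervention.qaly - comparator.qaly
    if abs(dq) <= tol:
        return IcerResult(dc, dq, None, "undefined")
    if dc <= 0 and dq > 0:
        return IcerResult(dc, dq, dc / dq, "dominant")
    if dc > 0 and dq < 0:
        return IcerResult(dc, dq, None, "dominated")
    return IcerResult(dc, dq, dc / dq, "icer")
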
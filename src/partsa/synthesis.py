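"""Synthetic two-arm trial data and pseudo-IPD reconstruction.

Two routes produce patient-level (time, event) records:

* :func:`simulate_trial` draws progression and death times per patient from
  the arm's parametric PFS/OS curves, couples them so death never precedes
  progression, and applies administrative censoring from uniform accrual —
  a stand-in for a two-arm randomised trial such as GEMSTONE-302.
* :func:`reconstruct_ipd` inverts a digitized Kaplan–Meier curve plus its
  numbers-at-risk table back into pseudo patient records (the Guyot-style
  algorithm used when only published survival figures are available).

Only the marginal PFS and OS curves matter to the downstream partitioned
survival model; the joint coupling is needed solely to make the simulated
records internally consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import DistributionSpec, quantile_at, survival_at

__all__ = [
    "TrialDesign",
    "DigitizedCurve",
    "simulate_trial",
    "reconstruct_ipd",
    "km_curve",
    "digitize_km",
]


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrialDesign:
    """Two-arm trial layout: per-arm size, accrual, follow-up and curves."""

    n_per_arm: int
    arm_curves: dict  # arm -> {"pfs": DistributionSpec, "os": DistributionSpec}
    accrual_months: float = 0.0
    max_followup_months: float = 120.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_arm < 2:
            raise ValueError("n_per_arm must be >= 2")
        if self.max_followup_months <= 0:
            raise ValueError("max_followup_months must be positive")
        if self.accrual_months < 0:
            raise ValueError("accrual_months must be non-negative")
        for arm, curves in self.arm_curves.items():
            if not {"pfs", "os"} <= set(curves):
                raise ValueError(f"arm {arm!r} needs both 'pfs' and 'os' curves")


@dataclass(frozen=True)
class DigitizedCurve:
    """Digitized K-M coordinates plus (optional) numbers-at-risk table."""

    points: tuple  # ((time_months, survival), ...) sorted by time
    risk_table: tuple = field(default_factory=tuple)  # ((time_months, n_risk), ...)

    def __post_init__(self):
        pts = tuple((float(t), float(s)) for t, s in self.points)
        object.__setattr__(self, "points", pts)
        rt = tuple((float(t), int(n)) for t, n in self.risk_table)
        object.__setattr__(self, "risk_table", rt)
        times = [t for t, _ in pts]
        survs = [s for _, s in pts]
        if sorted(times) != times:
            raise ValueError("digitized times must be sorted")
        if any(s2 > s1 + 1e-9 for s1, s2 in zip(survs, survs[1:])):
            raise ValueError("digitized survival must be non-increasing")
        if any(not (0.0 < s <= 1.0) for s in survs):
            raise ValueError("digitized survival must lie in (0, 1]")
        if rt:
            counts = [n for _, n in rt]
            if any(n2 > n1 for n1, n2 in zip(counts, counts[1:])):
                raise ValueError("numbers at risk must be non-increasing")


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

_MAX_RETRIES = 1000


def _couple_os(pfs: np.ndarray, u: np.ndarray, os_spec: DistributionSpec,
               rng: np.random.Generator) -> np.ndarray:
    """Comonotone OS draw (shared uniform), with conditional redraw of the
    rare records where the OS draw falls below the progression time."""
    os_t = np.asarray(quantile_at(os_spec, u), float)
    bad = os_t < pfs
    tries = 0
    while bad.any():
        tries += 1
        if tries > _MAX_RETRIES:
            raise SimulationError("could not couple OS >= PFS within retry budget")
        # redraw conditional on exceeding the progression time:
        # u' ~ Uniform(F_os(pfs), 1)
        f_at_pfs = 1.0 - np.asarray(survival_at(os_spec, pfs[bad]), float)
        v = rng.uniform(size=int(bad.sum()))
        u_new = f_at_pfs + v * np.clip(1.0 - f_at_pfs, 1e-12, 1.0)
        os_t[bad] = np.asarray(quantile_at(os_spec, np.clip(u_new, 0, 1 - 1e-12)), float)
        bad = os_t < pfs
    return os_t


def simulate_trial(design: TrialDesign) -> pd.DataFrame:
    """Simulate patient-level records for every arm and endpoint.

    Returns a tidy frame with columns ``arm``, ``endpoint`` ("pfs"/"os"),
    ``time_months`` (> 0) and ``event`` (1 = progression/death, 0 = censored).
    Reproducible: the same design (including seed) gives identical output.
    """
    rng = np.random.default_rng(design.seed)
    frames = []
    for arm in sorted(design.arm_curves):
        curves = design.arm_curves[arm]
        n = design.n_per_arm
        u = rng.uniform(size=n)
        pfs_t = np.asarray(quantile_at(curves["pfs"], u), float)
        os_t = _couple_os(pfs_t, u, curves["os"], rng)
        accrual = (rng.uniform(0.0, design.accrual_months, size=n)
                   if design.accrual_months > 0 else np.zeros(n))
        censor = np.maximum(design.max_followup_months - accrual, 1e-9)
        for endpoint, t in (("pfs", pfs_t), ("os", os_t)):
            event = (t <= censor).astype(int)
            obs = np.minimum(t, censor)
            frames.append(pd.DataFrame({
                "arm": arm,
                "endpoint": endpoint,
                "time_months": np.maximum(obs, 1e-9),
                "event": event,
            }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Kaplan-Meier utilities
# ---------------------------------------------------------------------------

def km_curve(times, events) -> pd.DataFrame:
    """Product-limit estimate; rows at each distinct event time."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    n = times.size
    at_risk = n
    s = 1.0
    rows = [(0.0, 1.0)]
    i = 0
    while i < n:
        t = times[i]
        d = c = 0
        while i < n and times[i] == t:
            if events[i] == 1:
                d += 1
            else:
                c += 1
            i += 1
        if d > 0:
            s *= 1.0 - d / at_risk
            rows.append((t, s))
        at_risk -= d + c
    return pd.DataFrame(rows, columns=["time_months", "survival"])


def km_survival_at(km: pd.DataFrame, t) -> np.ndarray:
    """Step-function lookup of a K-M curve at times ``t``."""
    t = np.atleast_1d(np.asarray(t, float))
    idx = np.searchsorted(km["time_months"].to_numpy(), t, side="right") - 1
    return km["survival"].to_numpy()[np.clip(idx, 0, len(km) - 1)]


def digitize_km(times, events, grid_step: float = 0.25,
                risk_times=None) -> DigitizedCurve:
    """Emulate figure digitization: sample the K-M curve on a regular grid
    and tabulate numbers at risk at the requested times."""
    km = km_curve(times, events)
    t_max = float(np.max(times))
    grid = np.arange(0.0, t_max + grid_step, grid_step)
    surv = km_survival_at(km, grid)
    keep = surv > 0
    points = tuple(zip(grid[keep], surv[keep]))
    if risk_times is None:
        risk_times = np.linspace(0.0, t_max, 7)[:-1]
    times = np.asarray(times, float)
    risk = tuple((float(rt), int(np.sum(times >= rt))) for rt in risk_times)
    return DigitizedCurve(points=points, risk_table=risk)


# ---------------------------------------------------------------------------
# Guyot-style pseudo-IPD reconstruction
# ---------------------------------------------------------------------------

def reconstruct_ipd(curve: DigitizedCurve) -> pd.DataFrame:
    """Invert a digitized K-M curve into pseudo patient records.

    Within each numbers-at-risk interval, censorings are spread uniformly
    and event counts are chosen so the reconstructed product-limit curve
    tracks the digitized survival probabilities while the implied number at
    risk matches the published count at the start of the next interval.
    Without a risk table, censoring within follow-up is assumed absent and
    events follow directly from successive survival ratios.

    Returns a frame with ``time_months`` and ``event`` columns.
    """
    pts = list(curve.points)
    if not pts:
        raise ValueError("digitized curve has no points")
    if pts[0][0] > 0:
        pts.insert(0, (0.0, 1.0))
    t = np.array([p[0] for p in pts])
    s = np.array([p[1] for p in pts])

    if curve.risk_table:
        risk = list(curve.risk_table)
    else:
        # degraded mode: single interval, initial n set by curve resolution
        n0 = max(int(round(1.0 / max(1.0 - min(s), 1e-6))), 100)
        risk = [(0.0, n0)]

    records_t: list[float] = []
    records_e: list[int] = []
    end_time = t[-1]
    boundaries = [rt for rt, _ in risk] + [end_time + 1e-9]
    n_current = risk[0][1]
    s_running = 1.0

    for j in range(len(risk)):
        lo, hi = boundaries[j], boundaries[j + 1]
        n_start = n_current
        n_next = risk[j + 1][1] if j + 1 < len(risk) else 0
        in_iv = (t > lo) & (t <= hi) if j > 0 else (t >= lo) & (t <= hi)
        tt = t[in_iv]
        ss = s[in_iv]
        # drop the leading point carrying the running survival value
        seg = [(ti, si) for ti, si in zip(tt, ss) if si < s_running - 1e-12]
        # first pass: events assuming no censoring inside the interval
        n_at = n_start
        s_loc = s_running
        ev_counts = []
        for ti, si in seg:
            d = int(round(n_at * (1.0 - si / s_loc))) if s_loc > 0 else 0
            d = max(min(d, n_at), 0)
            ev_counts.append([ti, d])
            if d:
                s_loc *= 1.0 - d / n_at
            n_at -= d
        total_events = sum(d for _, d in ev_counts)
        if j + 1 < len(risk):
            n_cens = max(n_start - total_events - n_next, 0)
        else:
            # final interval: remaining patients are censored at end of follow-up
            n_cens = max(n_start - total_events, 0)
        # spread censorings uniformly over the interval, then recompute events
        if n_cens > 0 and total_events > 0 and j + 1 < len(risk):
            cens_times = np.linspace(lo, hi, n_cens + 2)[1:-1]
            n_at = n_start
            s_loc = s_running
            ci = 0
            ev_counts2 = []
            for ti, si in seg:
                while ci < n_cens and cens_times[ci] < ti:
                    n_at -= 1
                    ci += 1
                d = int(round(n_at * (1.0 - si / s_loc))) if s_loc > 0 else 0
                d = max(min(d, max(n_at, 0)), 0)
                ev_counts2.append([ti, d])
                if d and n_at > 0:
                    s_loc *= 1.0 - d / n_at
                n_at -= d
            ev_counts = ev_counts2
            total_events = sum(d for _, d in ev_counts)
            n_cens = max(n_start - total_events - n_next, 0)
            cens_times = np.linspace(lo, hi, n_cens + 2)[1:-1]
        elif n_cens > 0 and j + 1 < len(risk):
            cens_times = np.linspace(lo, hi, n_cens + 2)[1:-1]
        else:
            cens_times = np.full(n_cens, end_time)

        for ti, d in ev_counts:
            records_t.extend([ti] * d)
            records_e.extend([1] * d)
        for ct in cens_times:
            records_t.append(float(ct))
            records_e.append(0)
        # update running survival to digitized value at interval end
        if seg:
            s_running = seg[-1][1]
        n_current = n_start - total_events - len(cens_times) if j + 1 < len(risk) else 0
        n_current = max(n_current, 0)
        if j + 1 < len(risk):
            n_current = risk[j + 1][1]

    out = pd.DataFrame({"time_months": records_t, "event": records_e})
    out = out.sort_values("time_months", kind="stable", ignore_index=True)
    out["time_months"] = out["time_months"].clip(lower=1e-9)
    return out
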
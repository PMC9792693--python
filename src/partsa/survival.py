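"""Parametric survival curves, maximum-likelihood fitting and model selection.

Eight families are supported: the five standard parametric models used for
survival extrapolation in health-economic modelling (exponential, Weibull,
Gompertz, log-logistic, log-normal), two cure models (mixture and
non-mixture) and the Royston–Parmar flexible parametric (restricted cubic
spline) model on the log cumulative-hazard scale.

Parameterisations
-----------------
All times are in months.

* ``exponential(rate)``: S(t) = exp(-rate*t)
* ``weibull(shape, scale)``: S(t) = exp(-(t/scale)**shape)
* ``gompertz(shape, rate)``: S(t) = exp(-rate/shape * (exp(shape*t)-1));
  shape may be negative, in which case S plateaus above zero (improper
  distribution) and the fit is flagged.
* ``loglogistic(shape, scale)``: S(t) = 1/(1 + (t/scale)**shape) — the
  AFT/scale form, whose median equals the scale parameter.
* ``lognormal(meanlog, sdlog)``: S(t) = 1 - Phi((ln t - meanlog)/sdlog);
  median = exp(meanlog).
* ``mixture_cure(pi, base)``: S(t) = pi + (1-pi)*S0(t)
* ``nonmixture_cure(pi, base)``: S(t) = pi**(1 - S0(t))
* ``royston_parmar(coeffs, knots)``: ln H(t) = natural cubic spline in ln t
  (proportional-hazards scale); S(t) = exp(-exp(spline(ln t))).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import integrate, optimize, special

__all__ = [
    "DistributionSpec",
    "FitResult",
    "survival_at",
    "density_at",
    "quantile_at",
    "fit_parametric",
    "select_best",
    "restricted_mean",
    "STANDARD_FAMILIES",
    "FAMILIES",
]

STANDARD_FAMILIES = ("exponential", "weibull", "gompertz", "loglogistic", "lognormal")
FAMILIES = STANDARD_FAMILIES + ("mixture_cure", "nonmixture_cure", "royston_parmar")

_N_PARAMS = {
    "exponential": 1,
    "weibull": 2,
    "gompertz": 2,
    "loglogistic": 2,
    "lognormal": 2,
}


class ParameterDomainError(ValueError):
    """A parameter vector violates its family's domain."""


class DegenerateDataError(ValueError):
    """Input data cannot identify the model (e.g. all observations censored)."""


class SelectionError(ValueError):
    """No converged fit available to select from."""


@dataclass(frozen=True)
class DistributionSpec:
    """A parametric survival distribution: family name plus parameter vector.

    For the cure families, ``params`` holds only the cure fraction ``pi`` and
    ``base`` holds the latent (uncured) distribution.  For Royston–Parmar,
    ``params`` holds the spline coefficients and ``knots`` the knot locations
    on the log-time scale (strictly increasing, boundary knots included).
    """

    family: str
    params: tuple = ()
    base: "DistributionSpec | None" = None
    knots: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        object.__setattr__(self, "knots", tuple(float(k) for k in self.knots))
        self._validate()

    def _validate(self) -> None:
        fam, p = self.family, self.params
        if fam not in FAMILIES:
            raise ParameterDomainError(f"unknown family {fam!r}")
        if fam == "exponential":
            if len(p) != 1 or p[0] <= 0:
                raise ParameterDomainError("exponential requires rate > 0")
        elif fam in ("weibull", "loglogistic"):
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise ParameterDomainError(f"{fam} requires shape > 0 and scale > 0")
        elif fam == "gompertz":
            if len(p) != 2 or p[1] <= 0:
                raise ParameterDomainError("gompertz requires rate > 0")
        elif fam == "lognormal":
            if len(p) != 2 or p[1] <= 0:
                raise ParameterDomainError("lognormal requires sdlog > 0")
        elif fam in ("mixture_cure", "nonmixture_cure"):
            if len(p) != 1 or not (0.0 <= p[0] <= 1.0):
                raise ParameterDomainError("cure fraction must lie in [0, 1]")
            if self.base is None or self.base.family not in STANDARD_FAMILIES:
                raise ParameterDomainError("cure models need a standard base family")
        elif fam == "royston_parmar":
            if len(self.knots) < 2 or np.any(np.diff(self.knots) <= 0):
                raise ParameterDomainError("knots must be strictly increasing, >= 2")
            if len(p) != len(self.knots):
                raise ParameterDomainError(
                    "royston_parmar needs len(knots) coefficients "
                    "(intercept, slope, one per internal knot)"
                )

    @property
    def n_params(self) -> int:
        if self.family in _N_PARAMS:
            return _N_PARAMS[self.family]
        if self.family in ("mixture_cure", "nonmixture_cure"):
            return 1 + self.base.n_params
        return len(self.params)

    @property
    def improper(self) -> bool:
        """True when S(t) does not tend to 0 (plateau at t -> inf)."""
        if self.family == "gompertz":
            return self.params[0] < 0
        if self.family in ("mixture_cure", "nonmixture_cure"):
            return self.params[0] > 0 or self.base.improper
        return False

    def to_dict(self) -> dict:
        d: dict = {"family": self.family, "params": list(self.params)}
        if self.base is not None:
            d["base"] = self.base.to_dict()
        if self.knots:
            d["knots"] = list(self.knots)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DistributionSpec":
        base = DistributionSpec.from_dict(d["base"]) if d.get("base") else None
        return cls(
            family=d["family"],
            params=tuple(d.get("params", ())),
            base=base,
            knots=tuple(d.get("knots", ())),
        )


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of one family with information criteria."""

    spec: DistributionSpec
    loglik: float
    aic: float
    bic: float
    n_obs: int
    converged: bool
    flags: tuple = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# Survival / density evaluation
# ---------------------------------------------------------------------------

def _rp_basis(x: np.ndarray, knots: Sequence[float]):
    """Natural cubic spline basis on log time: [1, x, v_1(x), ...] and d/dx."""
    x = np.asarray(x, float)
    kmin, kmax = knots[0], knots[-1]
    cols = [np.ones_like(x), x]
    dcols = [np.zeros_like(x), np.ones_like(x)]
    for kj in knots[1:-1]:
        lam = (kmax - kj) / (kmax - kmin)
        t1, t2, t3 = (
            np.maximum(x - kj, 0.0),
            np.maximum(x - kmin, 0.0),
            np.maximum(x - kmax, 0.0),
        )
        cols.append(t1 ** 3 - lam * t2 ** 3 - (1 - lam) * t3 ** 3)
        dcols.append(3 * t1 ** 2 - 3 * lam * t2 ** 2 - 3 * (1 - lam) * t3 ** 2)
    return np.column_stack(cols), np.column_stack(dcols)


def _log_cumhaz(spec: DistributionSpec, t: np.ndarray):
    B, _ = _rp_basis(np.log(t), spec.knots)
    return B @ np.asarray(spec.params)


def survival_at(spec: DistributionSpec, t) -> np.ndarray | float:
    """Survival probability S(t) at time ``t`` (months, scalar or array)."""
    scalar = np.isscalar(t)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ValueError("survival time must be non-negative")
    fam, p = spec.family, spec.params
    with np.errstate(over="ignore", divide="ignore"):
        if fam == "exponential":
            s = np.exp(-p[0] * t)
        elif fam == "weibull":
            s = np.exp(-((t / p[1]) ** p[0]))
        elif fam == "gompertz":
            a, b = p
            if a == 0:
                s = np.exp(-b * t)
            else:
                s = np.exp(-b / a * (np.expm1(a * t)))
        elif fam == "loglogistic":
            g, lam = p
            s = 1.0 / (1.0 + (t / lam) ** g)
        elif fam == "lognormal":
            mu, sd = p
            s = np.ones_like(t)
            pos = t > 0
            s[pos] = special.ndtr(-(np.log(t[pos]) - mu) / sd)
        elif fam == "mixture_cure":
            pi = p[0]
            s = pi + (1.0 - pi) * survival_at(spec.base, t)
        elif fam == "nonmixture_cure":
            pi = p[0]
            s0 = np.asarray(survival_at(spec.base, t), float)
            if pi == 0.0:
                # limit pi -> 0 of pi**(1-S0): 1 where no hazard accrued, else 0
                s = np.where(s0 >= 1.0, 1.0, 0.0)
            else:
                s = pi ** (1.0 - s0)
        elif fam == "royston_parmar":
            s = np.ones_like(t)
            pos = t > 0
            s[pos] = np.exp(-np.exp(_log_cumhaz(spec, t[pos])))
        else:  # pragma: no cover
            raise ParameterDomainError(fam)
    s = np.clip(s, 0.0, 1.0)
    return float(s[0]) if scalar else s


def density_at(spec: DistributionSpec, t) -> np.ndarray | float:
    """Density f(t) = -dS/dt; needed for the censored log-likelihood."""
    scalar = np.isscalar(t)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t <= 0):
        raise ValueError("density evaluated at t > 0 only")
    fam, p = spec.family, spec.params
    with np.errstate(over="ignore", divide="ignore"):
        if fam == "exponential":
            f = p[0] * np.exp(-p[0] * t)
        elif fam == "weibull":
            k, lam = p
            z = (t / lam) ** k
            f = (k / t) * z * np.exp(-z)
        elif fam == "gompertz":
            a, b = p
            h = b * np.exp(a * t)
            f = h * np.asarray(survival_at(spec, t))
        elif fam == "loglogistic":
            g, lam = p
            z = (t / lam) ** g
            f = (g / t) * z / (1.0 + z) ** 2
        elif fam == "lognormal":
            mu, sd = p
            z = (np.log(t) - mu) / sd
            f = np.exp(-0.5 * z * z) / (t * sd * math.sqrt(2 * math.pi))
        elif fam == "mixture_cure":
            pi = p[0]
            f = (1.0 - pi) * np.asarray(density_at(spec.base, t))
        elif fam == "nonmixture_cure":
            pi = p[0]
            if pi == 0.0:
                f = np.zeros_like(t)  # degenerate limit: all mass at 0+
            else:
                f = (-math.log(pi)) * np.asarray(density_at(spec.base, t)) * np.asarray(
                    survival_at(spec, t)
                )
        elif fam == "royston_parmar":
            x = np.log(t)
            B, dB = _rp_basis(x, spec.knots)
            eta = B @ np.asarray(spec.params)
            deta = dB @ np.asarray(spec.params)
            # f = h * S, h = d/dt exp(eta) = exp(eta) * deta / t
            f = np.exp(eta) * deta / t * np.exp(-np.exp(eta))
            f = np.maximum(f, 0.0)
        else:  # pragma: no cover
            raise ParameterDomainError(fam)
    f = np.where(np.isfinite(f), f, 0.0)
    return float(f[0]) if scalar else f


def quantile_at(spec: DistributionSpec, q) -> np.ndarray | float:
    """Inverse CDF: time t with 1 - S(t) = q.  Infinite for q above the
    attainable event fraction of an improper (plateauing) distribution."""
    scalar = np.isscalar(q)
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any((q < 0) | (q >= 1)):
        raise ValueError("quantile level must lie in [0, 1)")
    fam, p = spec.family, spec.params
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        if fam == "exponential":
            t = -np.log1p(-q) / p[0]
        elif fam == "weibull":
            t = p[1] * (-np.log1p(-q)) ** (1.0 / p[0])
        elif fam == "gompertz":
            a, b = p
            if a == 0:
                t = -np.log1p(-q) / b
            else:
                arg = 1.0 - a / b * np.log1p(-q)
                t = np.where(arg > 0, np.log(np.maximum(arg, 1e-300)) / a, np.inf)
        elif fam == "loglogistic":
            g, lam = p
            t = lam * (q / (1.0 - q)) ** (1.0 / g)
        elif fam == "lognormal":
            mu, sd = p
            t = np.exp(mu + sd * special.ndtri(q))
        elif fam in ("mixture_cure", "nonmixture_cure"):
            pi = p[0]
            if fam == "mixture_cure":
                # 1 - q = pi + (1-pi) S0  =>  S0 = (1 - q - pi)/(1 - pi)
                s0 = (1.0 - q - pi) / (1.0 - pi) if pi < 1 else np.full_like(q, np.nan)
            else:
                # 1 - q = pi**(1-S0)  =>  S0 = 1 - ln(1-q)/ln(pi)
                s0 = 1.0 - np.log1p(-q) / math.log(pi) if 0 < pi < 1 else None
                if pi == 0.0:
                    return quantile_at(spec.base, float(q[0])) if scalar else quantile_at(spec.base, q)
                if pi == 1.0:
                    s0 = np.full_like(q, np.nan)
            out = np.where(
                np.isnan(s0) | (s0 <= 0.0),
                np.inf,
                quantile_at(spec.base, np.clip(1.0 - s0, 0.0, 1.0 - 1e-15)),
            )
            t = out
        elif fam == "royston_parmar":
            t = np.array([_rp_quantile(spec, qi) for qi in q])
        else:  # pragma: no cover
            raise ParameterDomainError(fam)
    t = np.where(q == 0.0, 0.0, t)
    return float(t[0]) if scalar else t


def _rp_quantile(spec: DistributionSpec, qi: float) -> float:
    if qi == 0.0:
        return 0.0
    target = math.log(-math.log1p(-qi))  # ln H at the quantile

    def g(x):
        B, _ = _rp_basis(np.array([x]), spec.knots)
        return float(B @ np.asarray(spec.params)) - target

    lo, hi = spec.knots[0] - 20.0, spec.knots[-1] + 20.0
    if g(lo) > 0 or g(hi) < 0:
        return math.inf
    return math.exp(optimize.brentq(g, lo, hi, xtol=1e-10))


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------

def _logit(p):
    return math.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + math.exp(-x))


def _starting_values(times: np.ndarray, events: np.ndarray, family: str):
    """Method-of-moments style starting values on the unconstrained scale."""
    obs = times[events == 1]
    if obs.size == 0:
        obs = times
    m = float(np.mean(obs))
    lx = np.log(obs)
    mu, sd = float(np.mean(lx)), max(float(np.std(lx)), 0.1)
    if family == "exponential":
        return [math.log(1.0 / m)]
    if family == "weibull":
        return [0.0, math.log(m)]
    if family == "gompertz":
        return [0.01, math.log(1.0 / m)]  # shape untransformed, rate on log scale
    if family == "loglogistic":
        return [math.log(max(1.0 / sd, 0.1)), mu]  # log shape, log scale
    if family == "lognormal":
        return [mu, math.log(sd)]  # meanlog untransformed, log sdlog
    raise ParameterDomainError(family)


def _unpack(theta, family: str) -> DistributionSpec:
    if family == "exponential":
        return DistributionSpec("exponential", (math.exp(theta[0]),))
    if family == "weibull":
        return DistributionSpec("weibull", (math.exp(theta[0]), math.exp(theta[1])))
    if family == "gompertz":
        return DistributionSpec("gompertz", (theta[0], math.exp(theta[1])))
    if family == "loglogistic":
        return DistributionSpec("loglogistic", (math.exp(theta[0]), math.exp(theta[1])))
    if family == "lognormal":
        return DistributionSpec("lognormal", (theta[0], math.exp(theta[1])))
    raise ParameterDomainError(family)


def _neg_loglik(spec: DistributionSpec, times: np.ndarray, events: np.ndarray) -> float:
    ev = events == 1
    ll = 0.0
    if ev.any():
        f = np.asarray(density_at(spec, times[ev]), float)
        if np.any(f <= 0) or not np.all(np.isfinite(f)):
            return np.inf
        ll += float(np.sum(np.log(f)))
    if (~ev).any():
        s = np.asarray(survival_at(spec, times[~ev]), float)
        if np.any(s <= 0) or not np.all(np.isfinite(s)):
            return np.inf
        ll += float(np.sum(np.log(s)))
    return -ll


def _validate_ipd(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape or times.ndim != 1:
        raise ValueError("times and events must be 1-d arrays of equal length")
    if np.any(times <= 0):
        raise ValueError("event/censoring times must be positive")
    if int(events.sum()) < 2:
        raise DegenerateDataError("need at least 2 events to fit a survival model")
    return times, events


def fit_parametric(times, events, family: str, knots: int = 1) -> FitResult:
    """Fit one family to right-censored data by maximum likelihood.

    Parameters
    ----------
    times, events
        Observation times (months, > 0) and event indicators (1 = event,
        0 = right-censored).
    family
        One of :data:`FAMILIES`.  Cure families use the named base family
        syntax ``"mixture_cure:weibull"`` (default base: weibull).
    knots
        Number of internal knots for ``royston_parmar``.
    """
    times, events = _validate_ipd(times, events)
    n = times.size
    base_family = None
    if family.startswith(("mixture_cure", "nonmixture_cure")):
        fam, _, base_family = family.partition(":")
        base_family = base_family or "weibull"
        return _fit_cure(times, events, fam, base_family)
    if family == "royston_parmar":
        return _fit_royston_parmar(times, events, n_internal_knots=knots)
    if family not in STANDARD_FAMILIES:
        raise ParameterDomainError(f"unknown family {family!r}")

    theta0 = _starting_values(times, events, family)

    def nll(theta):
        try:
            spec = _unpack(theta, family)
        except (ParameterDomainError, OverflowError):
            return np.inf
        return _neg_loglik(spec, times, events)

    res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
    res2 = optimize.minimize(nll, res.x, method="BFGS")
    best = res2 if (res2.fun <= res.fun and np.isfinite(res2.fun)) else res
    spec = _unpack(best.x, family)
    return _make_result(spec, -float(best.fun), n, bool(best.success or res.success))


def _make_result(spec, loglik, n, converged) -> FitResult:
    k = spec.n_params
    aic = 2 * k - 2 * loglik
    bic = k * math.log(n) - 2 * loglik
    flags = ("improper_survival",) if spec.improper else ()
    if not converged:
        flags = flags + ("not_converged",)
    return FitResult(spec=spec, loglik=loglik, aic=aic, bic=bic,
                     n_obs=n, converged=converged, flags=flags)


def _fit_cure(times, events, fam, base_family) -> FitResult:
    n = times.size
    base0 = _starting_values(times, events, base_family)
    # start cure fraction at the K-M tail (fraction still at risk & censored)
    tail = max(min(1.0 - events.mean(), 0.8), 0.05)
    theta0 = [_logit(tail)] + list(base0)

    def nll(theta):
        pi = _expit(theta[0])
        try:
            base = _unpack(theta[1:], base_family)
            spec = DistributionSpec(fam, (pi,), base=base)
        except (ParameterDomainError, OverflowError):
            return np.inf
        return _neg_loglik(spec, times, events)

    res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 6000})
    pi = _expit(res.x[0])
    spec = DistributionSpec(fam, (pi,), base=_unpack(res.x[1:], base_family))
    return _make_result(spec, -float(res.fun), n, bool(res.success))


def _fit_royston_parmar(times, events, n_internal_knots: int = 1) -> FitResult:
    """PH-scale spline fit: boundary knots at extreme event log-times,
    internal knots at event log-time quantiles."""
    n = times.size
    ev_t = np.log(times[events == 1])
    qs = np.linspace(0, 1, n_internal_knots + 2)
    knots = tuple(np.quantile(ev_t, qs))
    if len(set(knots)) != len(knots):
        raise DegenerateDataError("tied event times collapse the knot sequence")
    # initialise from a Weibull fit: ln H = k*ln t - k*ln(scale)
    wb = fit_parametric(times, events, "weibull")
    k_w, lam_w = wb.spec.params
    theta0 = np.zeros(len(knots))
    theta0[0] = -k_w * math.log(lam_w)
    theta0[1] = k_w

    def nll(theta):
        try:
            spec = DistributionSpec("royston_parmar", tuple(theta), knots=knots)
        except ParameterDomainError:
            return np.inf
        return _neg_loglik(spec, times, events)

    res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 8000})
    spec = DistributionSpec("royston_parmar", tuple(res.x), knots=knots)
    return _make_result(spec, -float(res.fun), n, bool(res.success))


def fit_all(times, events, families: Sequence[str] = STANDARD_FAMILIES) -> list[FitResult]:
    """Fit every requested family; non-convergence is flagged, not raised."""
    out = []
    for fam in families:
        try:
            out.append(fit_parametric(times, events, fam))
        except (DegenerateDataError, ParameterDomainError):
            raise
    return out


def select_best(fits: Sequence[FitResult]) -> FitResult:
    """Lowest AIC among converged fits; ties by BIC, then by fewer parameters."""
    conv = [f for f in fits if f.converged]
    if not conv:
        raise SelectionError("no converged fits to select from")
    return min(conv, key=lambda f: (f.aic, f.bic, f.spec.n_params))


def restricted_mean(spec: DistributionSpec, horizon: float) -> float:
    """Restricted mean survival time: integral of S(t) from 0 to ``horizon`` months."""
    if horizon < 0:
        raise ValueError("horizon must be non-negative")
    if horizon == 0:
        return 0.0
    val, _ = integrate.quad(lambda t: float(survival_at(spec, t)), 0.0, horizon,
                            limit=200)
    return float(val)
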
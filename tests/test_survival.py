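"""Survival families: functional forms, fitting, selection, restricted means."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import partsa
from partsa import (
    DistributionSpec,
    FitResult,
    fit_parametric,
    quantile_at,
    restricted_mean,
    select_best,
    survival_at,
)
from partsa.survival import DegenerateDataError, ParameterDomainError, SelectionError

LL_SUG_PFS = DistributionSpec("loglogistic", (1.6637, 9.3549))
LN_PLA_OS = DistributionSpec("lognormal", (2.8289, 0.9785))


class TestSurvivalAt:
    @pytest.mark.parametrize("spec", [
        DistributionSpec("exponential", (0.1,)),
        DistributionSpec("weibull", (1.4, 12.0)),
        DistributionSpec("gompertz", (0.05, 0.02)),
        LL_SUG_PFS,
        LN_PLA_OS,
        DistributionSpec("mixture_cure", (0.2,),
                         base=DistributionSpec("exponential", (0.1,))),
    ])
    def test_survival_is_one_at_time_zero(self, spec):
        assert survival_at(spec, 0.0) == pytest.approx(1.0)

    def test_loglogistic_median_equals_scale(self):
        # median of a log-logistic is its scale parameter
        assert survival_at(LL_SUG_PFS, 9.3549) == pytest.approx(0.5, abs=1e-12)

    def test_lognormal_median_is_exp_meanlog(self):
        assert survival_at(LN_PLA_OS, math.exp(2.8289)) == pytest.approx(0.5, abs=1e-12)

    def test_mixture_cure_plateaus_at_cure_fraction(self):
        spec = DistributionSpec("mixture_cure", (0.2,),
                                base=DistributionSpec("exponential", (0.3,)))
        assert survival_at(spec, 1e6) == pytest.approx(0.2, abs=1e-9)

    def test_nonmixture_cure_plateaus_at_cure_fraction(self):
        spec = DistributionSpec("nonmixture_cure", (0.35,),
                                base=DistributionSpec("weibull", (1.2, 8.0)))
        assert survival_at(spec, 1e6) == pytest.approx(0.35, abs=1e-9)

    def test_mixture_cure_with_zero_fraction_is_base_family(self):
        base = DistributionSpec("weibull", (1.3, 10.0))
        cure = DistributionSpec("mixture_cure", (0.0,), base=base)
        t = np.linspace(0, 50, 101)
        np.testing.assert_allclose(survival_at(cure, t), survival_at(base, t),
                                   rtol=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            survival_at(LL_SUG_PFS, -1.0)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ParameterDomainError):
            DistributionSpec("loglogistic", (1.5, 0.0))
        with pytest.raises(ParameterDomainError):
            DistributionSpec("lognormal", (1.0, -0.5))

    def test_cure_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(ParameterDomainError):
            DistributionSpec("mixture_cure", (1.2,),
                             base=DistributionSpec("exponential", (0.1,)))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        family=st.sampled_from(["exponential", "weibull", "gompertz",
                                "loglogistic", "lognormal"]),
        a=st.floats(0.2, 4.0),
        b=st.floats(0.05, 40.0),
    )
    def test_survival_monotone_and_bounded(self, family, a, b):
        if family == "exponential":
            spec = DistributionSpec(family, (b,))
        elif family == "gompertz":
            spec = DistributionSpec(family, (a - 2.0, b))  # allow negative shape
        elif family == "lognormal":
            spec = DistributionSpec(family, (math.log(b), a))
        else:
            spec = DistributionSpec(family, (a, b))
        t = np.linspace(0.0, 200.0, 401)
        s = np.asarray(survival_at(spec, t))
        assert s[0] == pytest.approx(1.0)
        assert np.all((0.0 <= s) & (s <= 1.0))
        assert np.all(np.diff(s) <= 1e-12)

    def test_gompertz_negative_shape_flagged_improper(self):
        spec = DistributionSpec("gompertz", (-0.05, 0.02))
        assert spec.improper
        # plateau: survival stops falling
        assert survival_at(spec, 1e5) > 0.5


class TestQuantile:
    @pytest.mark.parametrize("spec", [
        DistributionSpec("exponential", (0.07,)),
        DistributionSpec("weibull", (1.7, 14.0)),
        LL_SUG_PFS,
        LN_PLA_OS,
        DistributionSpec("gompertz", (0.03, 0.01)),
    ])
    def test_quantile_inverts_survival(self, spec):
        q = np.array([0.05, 0.25, 0.5, 0.75, 0.95])
        t = np.asarray(quantile_at(spec, q))
        np.testing.assert_allclose(1.0 - np.asarray(survival_at(spec, t)), q,
                                   atol=1e-9)

    def test_cure_quantile_beyond_plateau_is_infinite(self):
        spec = DistributionSpec("mixture_cure", (0.3,),
                                base=DistributionSpec("exponential", (0.1,)))
        assert quantile_at(spec, 0.8) == math.inf
        assert np.isfinite(quantile_at(spec, 0.5))


class TestFitting:
    def test_exponential_rate_recovery(self, rng):
        t = rng.exponential(scale=10.0, size=5000)
        fit = fit_parametric(t, np.ones_like(t, dtype=int), "exponential")
        assert fit.converged
        assert fit.spec.params[0] == pytest.approx(0.1, rel=0.05)

    def test_aic_definition_for_exponential(self, rng):
        t = rng.exponential(scale=5.0, size=200)
        fit = fit_parametric(t, np.ones_like(t, dtype=int), "exponential")
        assert fit.aic == pytest.approx(2 - 2 * fit.loglik, abs=1e-9)
        assert fit.bic == pytest.approx(math.log(200) - 2 * fit.loglik, abs=1e-9)

    def test_loglogistic_recovery_under_censoring(self, rng):
        true = DistributionSpec("loglogistic", (1.6637, 9.3549))
        t = np.asarray(quantile_at(true, rng.uniform(size=2000)))
        cutoff = np.quantile(t, 0.7)  # ~30% administrative censoring
        obs, ev = np.minimum(t, cutoff), (t <= cutoff).astype(int)
        fit = fit_parametric(obs, ev, "loglogistic")
        assert fit.spec.params[0] == pytest.approx(1.6637, rel=0.10)
        assert fit.spec.params[1] == pytest.approx(9.3549, rel=0.10)

    def test_lognormal_recovery(self, rng):
        t = rng.lognormal(mean=2.8, sigma=1.0, size=4000)
        fit = fit_parametric(t, np.ones_like(t, dtype=int), "lognormal")
        assert fit.spec.params[0] == pytest.approx(2.8, rel=0.05)
        assert fit.spec.params[1] == pytest.approx(1.0, rel=0.05)

    def test_matches_lifelines_loglik_and_params(self, rng):
        lifelines = pytest.importorskip("lifelines")
        t = rng.weibull(1.5, size=800) * 12.0
        cutoff = 18.0
        obs, ev = np.minimum(t, cutoff), (t <= cutoff).astype(int)
        ours = fit_parametric(obs, ev, "weibull")
        wf = lifelines.WeibullFitter().fit(obs, ev)
        assert ours.spec.params[0] == pytest.approx(wf.rho_, rel=1e-3)
        assert ours.spec.params[1] == pytest.approx(wf.lambda_, rel=1e-3)
        assert ours.loglik == pytest.approx(wf.log_likelihood_, rel=1e-6)

    def test_mixture_cure_recovers_cure_fraction(self, rng):
        true = DistributionSpec("mixture_cure", (0.25,),
                                base=DistributionSpec("weibull", (1.3, 8.0)))
        u = rng.uniform(size=4000) * 0.999
        t = np.asarray(quantile_at(true, u))
        obs, ev = np.minimum(t, 60.0), (t <= 60.0).astype(int)
        fit = fit_parametric(np.maximum(obs, 1e-9), ev, "mixture_cure:weibull")
        assert fit.spec.params[0] == pytest.approx(0.25, abs=0.05)

    def test_royston_parmar_fits_no_worse_than_weibull(self, rng):
        # the spline nests the Weibull (straight line in ln t), so its
        # maximised likelihood cannot be lower
        t = rng.weibull(1.4, size=600) * 10.0
        ev = np.ones_like(t, dtype=int)
        wb = fit_parametric(t, ev, "weibull")
        rp = fit_parametric(t, ev, "royston_parmar")
        assert rp.converged
        assert rp.loglik >= wb.loglik - 1e-3

    def test_all_censored_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            fit_parametric([1.0, 2.0, 3.0], [0, 0, 0], "exponential")

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            fit_parametric([0.0, 2.0, 3.0], [1, 1, 1], "exponential")

    def test_aic_ordering_invariant_to_time_rescaling(self, rng):
        # rescaling time multiplies every density by the same Jacobian, so
        # AIC differences between families are unchanged
        t = rng.weibull(1.5, size=500) * 9.0
        ev = np.ones_like(t, dtype=int)
        fams = ("exponential", "weibull", "loglogistic", "lognormal")
        aic1 = {f: fit_parametric(t, ev, f).aic for f in fams}
        aic2 = {f: fit_parametric(t * 30.4375, ev, f).aic for f in fams}
        d1 = np.array([aic1[f] - aic1["weibull"] for f in fams])
        d2 = np.array([aic2[f] - aic2["weibull"] for f in fams])
        np.testing.assert_allclose(d1, d2, atol=0.05)


class TestSelection:
    def _fr(self, aic, bic, k=2, converged=True):
        spec = DistributionSpec("weibull", (1.0, float(k)))
        return FitResult(spec=spec, loglik=0.0, aic=aic, bic=bic, n_obs=100,
                         converged=converged)

    def test_lowest_aic_wins(self):
        fits = [self._fr(1570.2, 1580.0), self._fr(1567.99, 1575.53),
                self._fr(1580.0, 1590.0)]
        assert select_best(fits).aic == 1567.99

    def test_single_fit_returned(self):
        f = self._fr(100.0, 105.0)
        assert select_best([f]) is f

    def test_aic_tie_broken_by_bic(self):
        fits = [self._fr(100.0, 1576.0), self._fr(100.0, 1575.5)]
        assert select_best(fits).bic == 1575.5

    def test_unconverged_fits_excluded(self):
        fits = [self._fr(90.0, 95.0, converged=False), self._fr(100.0, 105.0)]
        assert select_best(fits).aic == 100.0
        with pytest.raises(SelectionError):
            select_best([self._fr(90.0, 95.0, converged=False)])


class TestRestrictedMean:
    def test_exponential_closed_form(self):
        spec = DistributionSpec("exponential", (0.1,))
        assert restricted_mean(spec, 5000.0) == pytest.approx(10.0, rel=1e-4)

    def test_zero_horizon(self):
        assert restricted_mean(LL_SUG_PFS, 0.0) == 0.0

    def test_against_fine_trapezoid_oracle(self):
        spec = DistributionSpec("loglogistic", (1.3722, 24.9818))
        t = np.linspace(0.0, 120.0, 1_000_001)
        oracle = float(np.trapezoid(np.asarray(survival_at(spec, t)), t))
        assert restricted_mean(spec, 120.0) == pytest.approx(oracle, rel=0.005)

    def test_increasing_in_horizon_and_bounded(self):
        r60 = restricted_mean(LN_PLA_OS, 60.0)
        r120 = restricted_mean(LN_PLA_OS, 120.0)
        assert 0 < r60 < r120 <= 120.0


def test_spec_serialization_round_trip():
    spec = DistributionSpec("nonmixture_cure", (0.15,),
                            base=DistributionSpec("gompertz", (0.02, 0.01)))
    assert DistributionSpec.from_dict(spec.to_dict()) == spec
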
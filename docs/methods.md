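# Methods

## Model

`partsa` implements a three-state partitioned survival analysis (PartSA) for
two-arm oncology comparisons, configured here for first-line sugemalimab +
platinum-doublet chemotherapy versus chemotherapy alone in metastatic NSCLC,
evaluated from the Chinese health-system perspective (direct medical costs
only, USD at 6.71 CNY/USD).

State occupancy is read directly off the two marginal survival curves of an
arm, with no transition-rate structure:

    p_PFS(t)   = min{S_PFS(t), S_OS(t)}
    p_death(t) = 1 − S_OS(t)
    p_PD(t)    = S_OS(t) − p_PFS(t)   (clamped at 0)

The `min` clamp handles extrapolated curve crossings; consequently occupancy
always sums to one and death is monotone — both asserted at run time with a
1e−12 tolerance. PartSA assumes the PFS and OS curves are externally valid
marginals; it imposes no joint distribution, so only the marginals of the
synthetic trial generator matter downstream.

Occupancy is evaluated on a 21-day cycle grid (matching the dosing cycle)
over a 10-year horizon (about 99% cohort mortality under the base curves).
Model months are 365.25/12 = 30.4375 days. Costs and QALYs accrue per cycle
as occupancy-weighted per-cycle values, discounted at 5%/year for costs and
health outcomes alike with continuous compounding `(1+r)^(−t)` at fractional
years (the cycle is sub-annual, so stepwise annual discounting would
introduce sawtooth artefacts). Discounted life-years use the same rate; the
published LY:QALY ratios are only consistent with discounted LYs.

### Cycle-grid convention and discretisation error

By default state membership is evaluated at cycle starts (the convention of
common TreeAge PartSA layouts); a `half_cycle_correction` flag switches
evaluation to cycle midpoints. Cycle-start evaluation carries an
O(cycle-length) upward bias of roughly 1% on discounted LY relative to a
daily-step reference; midpoint evaluation is within 0.05% of the same
reference. The default remains cycle-start because the reproduction targets
were published under that style of model; the bias is well inside the
reproduction tolerance.

## Survival curves

Eight families are implemented (parameterisations in `survival.py`):
exponential, Weibull, Gompertz, log-logistic (AFT form,
`S(t) = 1/(1+(t/λ)^γ)`, median = λ), log-normal (meanlog/sdlog, median =
exp(meanlog)), mixture cure `π + (1−π)S0`, non-mixture cure `π^(1−S0)`, and
the Royston–Parmar spline (natural cubic spline in log time on the log
cumulative-hazard / proportional-hazards scale; boundary knots at the
extreme event log-times, internal knots at event log-time quantiles, one
internal knot by default).

The base-case curves are the published best fits (all times in months):

| Curve | Family | shape γ | scale λ |
|---|---|---|---|
| sugemalimab PFS | log-logistic | 1.6637 | 9.3549 |
| sugemalimab OS | log-logistic | 1.3722 | 24.9818 |
| placebo PFS | log-logistic | 1.9645 | 5.3347 |
| placebo OS | log-normal | 2.8289 | 0.9785 |

Two labelling conventions deserve note, both adopted because they reproduce
the trial medians: the log-logistic λ enters as an AFT scale (so the median
PFS of 9.35 months matches the trial's 9.0), and the log-normal pair is read
as meanlog/sdlog (median e^2.8289 ≈ 16.9 months against the trial's 17.7).

Fitting maximises the right-censored log-likelihood
`Σ_events ln f(t) + Σ_censored ln S(t)` over unconstrained transformed
parameters (log for positive parameters, logit for the cure fraction),
Nelder–Mead polished by BFGS, with method-of-moments starting values —
chosen for reproducible convergence without analytic gradients. Model
selection is lowest AIC among converged fits, ties broken by BIC then by
parameter count. A Gompertz fit with negative shape (improper, plateauing
survival) is allowed but flagged, as the modelling horizon is finite.
Restricted means use adaptive quadrature.

## Synthetic trial data

`simulate_trial` emulates a GEMSTONE-302-like two-arm trial: per patient, a
progression time from the arm's PFS curve and a death time from its OS curve
coupled comonotonically (one shared uniform), with the rare OS < PFS draws
redrawn from the OS distribution truncated below at the progression time.
Accrual is uniform over the accrual window and censoring is purely
administrative at data cut-off, because the real trial's dropout pattern is
unpublished. Features of real data deliberately not emulated: informative
censoring, the crossover-induced plateau in the comparator's OS tail (see
the scenario-3 caveat below), and digitisation noise. Passing tests
therefore demonstrate internal consistency of the pipeline under the
published parametric curves, not fidelity to the unpublished patient-level
data.

`reconstruct_ipd` inverts a digitized Kaplan–Meier curve (plus
numbers-at-risk table) into pseudo patient records in the spirit of the
Guyot algorithm: within each risk-table interval, censorings are spread
uniformly and event counts chosen so the product-limit curve tracks the
digitized points while matching the published number at risk at the next
interval boundary. Without a risk table it falls back to a
no-censoring-within-follow-up assumption. Round-trip error (simulate →
Kaplan–Meier → digitize at 0.25-month spacing → reconstruct → Kaplan–Meier)
stays within 0.02 survival units at n = 300.

## Costing

All drugs are billed in whole vials (round up, no sharing) — consistent with
the published per-cycle immunotherapy acquisition cost of 2 × 1844.26 =
3688.52 USD. The reference patient has BSA 1.72 m² and GFR 70 mL/min;
carboplatin follows the Calvert formula AUC·(GFR+25) with AUC 5 (475 mg → 5
× 100 mg vials).

On-treatment costs attach to PFS occupancy (treatment continues until
progression or the 35-cycle cap): induction (cycles 1–4) bills the assigned
immunotherapy/placebo plus carboplatin and a histology-weighted backbone
(paclitaxel 175 mg/m² for squamous, pemetrexed 500 mg/m² for non-squamous);
maintenance (cycles 5–35) bills the immunotherapy and continues pemetrexed
for the non-squamous fraction in both arms; hospital management and
follow-up fees attach to every on-treatment cycle. The squamous fraction is
not published for the costing and is exposed as `squamous_fraction`
(default 0.4, approximately the trial composition); it is the main unfixed
economic input and barely moves the ICER (both arms share the backbone).

Post-progression, each cycle of PD occupancy bills the expectation over the
arm's subsequent-treatment mix — docetaxel 75 mg/m² every 3 weeks (guideline
dose; the source names the drug but not the dose), crossover sugemalimab at
full acquisition cost, or best supportive care — plus follow-up. The
crossover component is applied for the whole PD occupancy by default
(`pd_crossover_cap_cycles` can cap it): reproducing the published comparator
arm cost requires the uncapped convention, indicating the source model
costed the mix per PD cycle throughout.

Serious adverse events (grade ≥3, incidence ≥10%) enter as a one-off: the
arm's published aggregate management cost and a QALY decrement
`Σ p_i·|d_i| × (cycle length in years)` — each probability-weighted
disutility held for one 21-day cycle — both applied in the first model
cycle. Utilities are 0.804 (PFS) and 0.321 (PD).

## Sensitivity and scenario analyses

One-way analysis moves each ranged parameter to its bounds alone
(immunotherapy price: 50–100% of list; discount rate: 0–8%; utilities,
disutilities and SAE probabilities: published ranges; other costs: ±20%) and
sorts by tornado width on the ICER scale.

PSA runs second-order Monte Carlo (default 1,000 draws): gamma for costs,
beta for probabilities and utilities, beta on the magnitude (then negated)
for disutilities, each moment-matched to mean = base and
sd = (high − low)/3.92 — a 95%-interval reading of the published ranges,
since the source states no SE convention. Infeasible beta dispersions are
clipped. Rare draws that invert the PFS/PD utility ordering are clipped to
the ordering. Survival-curve parameters and subsequent-treatment mixes
carry no published uncertainty and are held fixed — a documented
limitation. The CEAC reports `P(w·ΔQALY − Δcost > 0)` on a 0–400,000 USD
grid in 2,000-USD steps.

Scenarios rerun the deterministic model with: the immunotherapy price
multiplied by 0.30 and 0.10 (applied to acquisition and crossover use
alike), horizons of 5 and 20 years, and alternative OS extrapolations. For
the latter, mixture cure, non-mixture cure (both Weibull-based) and
Royston–Parmar spline models are refitted to trial-sized synthetic IPD
(320/arm, 12-month accrual, 32-month follow-up) simulated from the base
curves, because the source does not publish those fitted parameters.

**Caveat.** Under these synthetic conditions the cure scenarios robustly
narrow the incremental QALYs, but the accompanying ICER increase reported by
the source analysis is not structurally guaranteed: it was driven by a
plateau in the real comparator K-M curve (27.7% crossover to the
immunotherapy), information that the published parametric curves do not
encode. At trial-sized samples the fitted cure fractions are noisy and the
ICER direction varies with the simulation seed.

## Numerical reproduction

Running the packaged configuration reproduces the published deterministic
ICERs to within 2% (base case, both price cuts, both horizons) and the PSA
acceptance probabilities exactly (0 at the 36,203.88 USD/QALY threshold;
1.0 by 340,000). Per-arm absolute costs, LYs and QALYs land 7–10% below the
published values under every stated convention combination tried; the
residual is consistent with the source's internal digitized curves differing
slightly from what its printed fitted parameters reproduce, and the
acceptance tests therefore use a 10% relative tolerance for absolute totals.

## Known limitations

- No covariate adjustment, interval censoring, or informative censoring.
- PSA ignores survival-parameter uncertainty (none is published).
- The Guyot-style reconstruction assumes within-interval censoring is
  uniform; it does not model reading error in the digitized coordinates.
- Histology-specific regimens are approximated by a single histology-mix
  weight rather than separate squamous/non-squamous cohorts.
- Problem sizes in the test-suite simulations (n up to 10,000 for
  convergence checks, 5,000 for stability of cure-fraction fits) were chosen
  to keep sampling error well below the asserted tolerances.
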
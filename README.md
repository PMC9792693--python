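# partsa

Partitioned-survival cost-utility analysis for two-arm oncology
comparisons, configured for first-line **sugemalimab + platinum-doublet
chemotherapy versus chemotherapy alone in metastatic non-small cell lung
cancer** from the Chinese health-system perspective.

## What it does

Health-technology assessments of immunotherapy regimens commonly use a
three-state partitioned survival model (PartSA): the cohort occupies
progression-free (PFS), progressed (PD) or dead states, with occupancy read
directly off the two survival curves of each arm,

    p_PFS(t) = min{S_PFS(t), S_OS(t)},   p_death(t) = 1 − S_OS(t),
    p_PD(t)  = S_OS(t) − p_PFS(t),

evaluated on a 21-day cycle grid over a 10-year horizon. Discounted (5%/yr)
life-years, QALYs (utilities 0.804 PFS / 0.321 PD, one-off disutility for
grade ≥3 adverse events) and costs (whole-vial drug acquisition, Calvert-dosed
carboplatin, histology-weighted chemotherapy backbone, post-progression
treatment mix, follow-up/hospitalisation fees) accrue per cycle, and two arms
are compared by the incremental cost-effectiveness ratio
ICER = ΔCost/ΔQALY against a willingness-to-pay threshold of 36,203.88
USD/QALY (3× 2021 Chinese per-capita GDP).

The package covers the full pipeline:

- **`partsa.survival`** — eight parametric families (exponential, Weibull,
  Gompertz, log-logistic, log-normal, mixture/non-mixture cure,
  Royston–Parmar spline), right-censored maximum-likelihood fitting, AIC/BIC
  model selection, restricted means.
- **`partsa.synthesis`** — synthetic two-arm trial IPD from parametric
  curves with comonotone PFS/OS coupling and administrative censoring, plus
  Guyot-style pseudo-IPD reconstruction from digitized Kaplan–Meier curves
  and numbers-at-risk tables.
- **`partsa.engine`** — occupancy traces, discounting, accrual, ICER with
  dominance labelling.
- **`partsa.valuation`** — dosing/price/SAE/utility inputs turned into
  per-cycle and one-off value streams per arm.
- **`partsa.uncertainty`** — one-way sensitivity analysis (tornado),
  1,000-draw probabilistic sensitivity analysis with CEAC, and scenario
  analyses (price cuts, horizons, alternative OS extrapolations).
- **`partsa.cli`** — `partsa fit|synth|run|owsa|psa|scenarios`.

See `docs/methods.md` for modelling conventions and limitations.

## Worked example

```python
import partsa

cfg = partsa.load_config()          # packaged base-case inputs
out = partsa.run_base_case(cfg)
for arm, r in out["results"].items():
    print(f"{arm:12s} cost {r.total_cost:10.2f}  LY {r.ly:.2f}  QALY {r.qaly:.2f}")
inc = out["icer"]
print(f"ICER {inc.icer:,.2f} USD/QALY (dCost {inc.delta_cost:,.2f}, dQALY {inc.delta_qaly:.3f})")
```

prints

```
sugemalimab  cost  121159.47  LY 2.87  QALY 1.53
placebo      cost   57866.39  LY 1.98  QALY 0.96
ICER 112,360.77 USD/QALY (dCost 63,293.07, dQALY 0.563)
```

The combination gains 0.56 discounted QALYs at an extra 63,293 USD — an ICER
of roughly 112,000 USD/QALY, about three times the Chinese willingness-to-pay
threshold, so the regimen is not cost-effective at list price. The same
conclusion survives every one-way parameter excursion, a 70% or even 90%
immunotherapy price cut, and horizons of 5–20 years:

```sh
partsa run --out-dir out/            # base-case table
partsa owsa --out-dir out/           # tornado.csv
partsa psa --seed 1 --out-dir out/   # psa_samples.csv, ceac.csv
partsa scenarios --out-dir out/      # scenarios.csv
```

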
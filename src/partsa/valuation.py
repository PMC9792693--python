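"""Costing and utility inputs: turning regimens and prices into value streams.

The two strategies compared are a PD-L1 inhibitor (sugemalimab, 1200 mg flat
every 3 weeks) on top of platinum-doublet chemotherapy versus the doublet
alone.  Induction (4 cycles) uses carboplatin with paclitaxel (squamous
histology) or pemetrexed (non-squamous); maintenance continues the
immunotherapy (plus pemetrexed for non-squamous patients) up to a 35-cycle
treatment cap.  Carboplatin dose follows the Calvert formula AUC*(GFR+25);
other cytotoxics are dosed per body surface area.  Drugs are billed in whole
vials (round up, no sharing).

After progression, a fixed mix of subsequent treatments applies per cycle of
progressed-disease occupancy: docetaxel re-treatment, crossover to the
immunotherapy, or best supportive care — each alongside routine follow-up.

Grade >=3 adverse events with >=10% incidence contribute a one-off cost and a
one-off QALY decrement (probability-weighted disutility held for one cycle)
in the first model cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .engine import ModelSettings
from .survival import DistributionSpec

__all__ = [
    "DosingInputs",
    "PriceList",
    "AdverseEvent",
    "AEProfile",
    "UtilitySet",
    "SubsequentMix",
    "ArmDefinition",
    "carboplatin_dose",
    "drug_admin_cost",
    "oncycle_cost",
    "progression_cost_per_cycle",
    "sae_burden",
]


@dataclass(frozen=True)
class DosingInputs:
    """Reference-patient dosing assumptions."""

    bsa_m2: float = 1.72
    gfr_ml_min: float = 70.0
    carboplatin_auc: float = 5.0
    pemetrexed_mg_per_m2: float = 500.0
    paclitaxel_mg_per_m2: float = 175.0
    docetaxel_mg_per_m2: float = 75.0
    sugemalimab_mg_flat: float = 1200.0
    induction_cycles: int = 4
    max_treatment_cycles: int = 35

    def __post_init__(self):
        for f in ("bsa_m2", "gfr_ml_min", "carboplatin_auc", "pemetrexed_mg_per_m2",
                  "paclitaxel_mg_per_m2", "docetaxel_mg_per_m2", "sugemalimab_mg_flat"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")
        if not (0 < self.induction_cycles <= self.max_treatment_cycles):
            raise ValueError("induction cycles must be positive and <= treatment cap")


@dataclass(frozen=True)
class PriceList:
    """Unit prices (USD).  Vial prices pair with the vial sizes below."""

    sugemalimab_per_vial: float = 1844.26
    carboplatin_per_vial: float = 13.39
    pemetrexed_per_vial: float = 330.23
    paclitaxel_per_vial: float = 51.39
    docetaxel_per_vial: float = 96.65
    hospital_per_cycle: float = 72.43
    followup_per_cycle: float = 199.55
    bsc_per_cycle: float = 320.84
    sae_one_off: float = 0.0  # arm-specific aggregate

    sugemalimab_vial_mg: float = 600.0
    carboplatin_vial_mg: float = 100.0
    pemetrexed_vial_mg: float = 100.0
    paclitaxel_vial_mg: float = 30.0
    docetaxel_vial_mg: float = 20.0

    def __post_init__(self):
        for f, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"{f} must be non-negative")

    def with_price_factor(self, immunotherapy_factor: float) -> "PriceList":
        """Scale only the immunotherapy vial price (scenario analyses)."""
        return replace(self, sugemalimab_per_vial=self.sugemalimab_per_vial
                       * immunotherapy_factor)


@dataclass(frozen=True)
class AdverseEvent:
    name: str
    probability: float
    disutility: float  # <= 0

    def __post_init__(self):
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError("probability must lie in [0, 1]")
        if self.disutility > 0:
            raise ValueError("disutility must be <= 0")


@dataclass(frozen=True)
class AEProfile:
    events: tuple  # of AdverseEvent

    def __post_init__(self):
        object.__setattr__(self, "events", tuple(self.events))


@dataclass(frozen=True)
class UtilitySet:
    u_pfs: float = 0.804
    u_pd: float = 0.321

    def __post_init__(self):
        if not (0.0 <= self.u_pd <= self.u_pfs <= 1.0):
            raise ValueError("need 0 <= u_pd <= u_pfs <= 1")


@dataclass(frozen=True)
class SubsequentMix:
    """Post-progression treatment mix (fractions sum to ~1)."""

    new_anticancer: float  # docetaxel
    crossover_immunotherapy: float
    best_supportive_care: float

    def __post_init__(self):
        fr = (self.new_anticancer, self.crossover_immunotherapy,
              self.best_supportive_care)
        if any(not (0.0 <= f <= 1.0) for f in fr):
            raise ValueError("mix fractions must lie in [0, 1]")
        if abs(sum(fr) - 1.0) > 0.01:
            raise ValueError("mix fractions must sum to 1 (+-0.01)")


# ---------------------------------------------------------------------------
# Elementary costing operations
# ---------------------------------------------------------------------------

def carboplatin_dose(auc: float, gfr: float) -> float:
    """Calvert formula: dose (mg) = AUC * (GFR + 25)."""
    if auc < 0 or gfr < 0:
        raise ValueError("AUC and GFR must be non-negative")
    return auc * (gfr + 25.0)


def drug_admin_cost(dose_mg: float, vial_mg: float, vial_price: float) -> float:
    """Acquisition cost under a whole-vial policy (round up, no sharing)."""
    if dose_mg < 0:
        raise ValueError("dose must be non-negative")
    if vial_mg <= 0:
        raise ValueError("vial size must be positive")
    if dose_mg == 0:
        return 0.0
    return math.ceil(dose_mg / vial_mg - 1e-9) * vial_price


def _component_costs(prices: PriceList, dosing: DosingInputs) -> dict:
    """Per-administration acquisition cost of each drug."""
    return {
        "sugemalimab": drug_admin_cost(dosing.sugemalimab_mg_flat,
                                       prices.sugemalimab_vial_mg,
                                       prices.sugemalimab_per_vial),
        "carboplatin": drug_admin_cost(
            carboplatin_dose(dosing.carboplatin_auc, dosing.gfr_ml_min),
            prices.carboplatin_vial_mg, prices.carboplatin_per_vial),
        "pemetrexed": drug_admin_cost(dosing.pemetrexed_mg_per_m2 * dosing.bsa_m2,
                                      prices.pemetrexed_vial_mg,
                                      prices.pemetrexed_per_vial),
        "paclitaxel": drug_admin_cost(dosing.paclitaxel_mg_per_m2 * dosing.bsa_m2,
                                      prices.paclitaxel_vial_mg,
                                      prices.paclitaxel_per_vial),
        "docetaxel": drug_admin_cost(dosing.docetaxel_mg_per_m2 * dosing.bsa_m2,
                                     prices.docetaxel_vial_mg,
                                     prices.docetaxel_per_vial),
    }


def oncycle_cost(arm: str, squamous_fraction: float, cycle_index: int,
                 prices: PriceList, dosing: DosingInputs,
                 immunotherapy: bool | None = None) -> dict:
    """Drug, administration and follow-up cost of one on-treatment cycle.

    ``cycle_index`` counts treatment cycles from 1.  The chemotherapy
    backbone is histology-weighted: paclitaxel for the squamous fraction,
    pemetrexed for the rest; pemetrexed continues into maintenance for
    non-squamous patients in both arms.  Beyond the treatment cap every
    component is zero.

    Returns a dict with keys ``immunotherapy``, ``chemotherapy``,
    ``administration``, ``follow_up``.
    """
    if not (0.0 <= squamous_fraction <= 1.0):
        raise ValueError("squamous fraction must lie in [0, 1]")
    if cycle_index < 0:
        raise ValueError("cycle index must be >= 0")
    if immunotherapy is None:
        immunotherapy = arm.lower().startswith("sug")
    c = _component_costs(prices, dosing)
    zero = {"immunotherapy": 0.0, "chemotherapy": 0.0,
            "administration": 0.0, "follow_up": 0.0}
    if cycle_index == 0 or cycle_index > dosing.max_treatment_cycles:
        return zero
    immuno = c["sugemalimab"] if immunotherapy else 0.0
    if cycle_index <= dosing.induction_cycles:
        chemo = c["carboplatin"] + (squamous_fraction * c["paclitaxel"]
                                    + (1 - squamous_fraction) * c["pemetrexed"])
    else:
        chemo = (1 - squamous_fraction) * c["pemetrexed"]
    return {"immunotherapy": immuno, "chemotherapy": chemo,
            "administration": prices.hospital_per_cycle,
            "follow_up": prices.followup_per_cycle}


def progression_cost_per_cycle(mix: SubsequentMix, prices: PriceList,
                               dosing: DosingInputs,
                               include_crossover: bool = True) -> dict:
    """Expected post-progression cost per cycle of PD occupancy.

    Returns ``{"progression": drug/BSC expectation, "follow_up": follow-up}``;
    ``include_crossover=False`` drops the crossover-immunotherapy component
    (used when the crossover duration cap has been reached).
    """
    c = _component_costs(prices, dosing)
    drug = (mix.new_anticancer * c["docetaxel"]
            + mix.best_supportive_care * prices.bsc_per_cycle)
    if include_crossover:
        drug += mix.crossover_immunotherapy * c["sugemalimab"]
    return {"progression": drug, "follow_up": prices.followup_per_cycle}


def sae_burden(profile: AEProfile, cost_one_off: float,
               cycle_years: float) -> dict:
    """One-off SAE cost and QALY loss applied in the first model cycle.

    The cost is the arm's printed aggregate; the QALY loss holds each
    probability-weighted disutility for one model cycle.
    """
    qaly_loss = sum(ev.probability * abs(ev.disutility) for ev in profile.events)
    return {"one_off_cost": float(cost_one_off),
            "one_off_qaly_loss": qaly_loss * cycle_years}


# ---------------------------------------------------------------------------
# Arm definition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArmDefinition:
    """Everything the engine needs to run one strategy arm."""

    name: str
    pfs: DistributionSpec
    os: DistributionSpec
    prices: PriceList
    dosing: DosingInputs
    utilities: UtilitySet
    ae_profile: AEProfile
    subsequent: SubsequentMix
    squamous_fraction: float = 0.4
    immunotherapy: bool = False
    pd_crossover_cap_cycles: int | None = None

    def cost_streams(self, n_cycles: int, settings: ModelSettings) -> dict:
        """Per-cycle cost arrays by component, as required by the engine.

        Returns ``{component: ({"pfs": array, "pd": array}, one_off_dict)}``
        over grid rows 0..n_cycles (row k = start of treatment cycle k+1).
        """
        n = n_cycles
        comp = {k: {"pfs": np.zeros(n), "pd": np.zeros(n)}
                for k in ("immunotherapy", "chemotherapy", "administration",
                          "follow_up", "progression")}
        for i in range(n):
            cyc = oncycle_cost(self.name, self.squamous_fraction, i + 1,
                               self.prices, self.dosing,
                               immunotherapy=self.immunotherapy)
            for k in ("immunotherapy", "chemotherapy", "administration",
                      "follow_up"):
                comp[k]["pfs"][i] = cyc[k]
            cap = self.pd_crossover_cap_cycles
            pd_c = progression_cost_per_cycle(
                self.subsequent, self.prices, self.dosing,
                include_crossover=(cap is None or i + 1 <= cap))
            comp["progression"]["pd"][i] = pd_c["progression"]
            comp["follow_up"]["pd"][i] = pd_c["follow_up"]
        streams = {k: (v, {}) for k, v in comp.items()}
        streams["sae"] = ({"pfs": np.zeros(n), "pd": np.zeros(n)},
                          {0: self.prices.sae_one_off})
        return streams

    def sae_qaly_loss(self, settings: ModelSettings) -> float:
        return sae_burden(self.ae_profile, self.prices.sae_one_off,
                          settings.cycle_years)["one_off_qaly_loss"]
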
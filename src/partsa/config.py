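"""Configuration loading, validation, and the sensitivity-parameter registry.

A single YAML document holds every economic input (mirroring the published
input table: base value, one-way range, PSA distribution per parameter).
:func:`load_config` validates it; :func:`build_arms` materialises the two
:class:`~partsa.valuation.ArmDefinition` objects; :func:`parameter_registry`
flattens every ranged input into :class:`ParameterSpec` entries that the
one-way and probabilistic sensitivity analyses can perturb uniformly.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from importlib import resources

import yaml

from .engine import ModelSettings
from .survival import DistributionSpec
from .valuation import (
    AdverseEvent,
    AEProfile,
    ArmDefinition,
    DosingInputs,
    PriceList,
    SubsequentMix,
    UtilitySet,
)

__all__ = [
    "ConfigError",
    "ParameterSpec",
    "default_config",
    "load_config",
    "validate_config",
    "build_settings",
    "build_arms",
    "parameter_registry",
    "set_parameter",
]

ARMS = ("sugemalimab", "placebo")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ParameterSpec:
    """One ranged model input for sensitivity analysis.

    ``path`` addresses the value inside the config mapping; ``role`` decides
    the PSA distribution family (gamma for costs, beta for probabilities,
    utilities and disutility magnitudes, fixed otherwise).
    """

    name: str
    path: tuple
    base: float
    low: float
    high: float
    distribution: str  # "gamma" | "beta" | "fixed"
    role: str  # "cost" | "probability" | "utility" | "disutility" | "rate"

    def __post_init__(self):
        lo, hi = self.low, self.high
        if self.role == "disutility":
            # signed scale: low is the most negative excursion
            if not (lo <= self.base <= hi <= 0):
                raise ConfigError(f"{self.name}: need low <= base <= high <= 0")
        elif not (lo <= self.base <= hi):
            raise ConfigError(f"{self.name}: need low <= base <= high")
        if self.distribution == "gamma" and lo < 0:
            raise ConfigError(f"{self.name}: gamma requires non-negative support")
        if self.distribution == "beta" and self.role in ("probability", "utility"):
            if not (0 <= lo and hi <= 1):
                raise ConfigError(f"{self.name}: beta requires values in [0, 1]")


def default_config() -> dict:
    """The packaged base-case configuration (deep copy, safe to mutate)."""
    text = resources.files("partsa").joinpath("data/base_config.yaml").read_text()
    return yaml.safe_load(text)


def load_config(path: str | None = None) -> dict:
    if path is None:
        cfg = default_config()
    else:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    validate_config(cfg)
    return cfg


def _require(cfg: dict, *keys):
    cur = cfg
    for k in keys:
        if not isinstance(cur, dict) or k not in cur:
            raise ConfigError(f"missing config key: {'.'.join(map(str, keys))}")
        cur = cur[k]
    return cur


def validate_config(cfg: dict) -> None:
    for section in ("settings", "curves", "dosing", "vials", "prices",
                    "utilities", "disutilities", "sae_probabilities",
                    "subsequent", "psa"):
        _require(cfg, section)
    for arm in ARMS:
        for ep in ("pfs", "os"):
            spec = _require(cfg, "curves", arm, ep)
            DistributionSpec.from_dict(spec)  # raises on bad families/params
        mix = _require(cfg, "subsequent", arm)
        SubsequentMix(**mix)  # raises if fractions don't sum to ~1
    for p in parameter_registry(cfg):
        pass  # construction validates each ranged entry
    sf = _require(cfg, "settings", "squamous_fraction")
    if not (0.0 <= sf <= 1.0):
        raise ConfigError("squamous_fraction must lie in [0, 1]")


def build_settings(cfg: dict, **overrides) -> ModelSettings:
    s = cfg["settings"]
    return ModelSettings(
        cycle_days=overrides.get("cycle_days", s["cycle_days"]),
        horizon_years=overrides.get("horizon_years", s["horizon_years"]),
        discount_rate_annual=overrides.get("discount_rate_annual",
                                           s["discount_rate_annual"]),
        half_cycle_correction=overrides.get("half_cycle_correction",
                                            s.get("half_cycle_correction", False)),
        wtp_per_qaly=overrides.get("wtp_per_qaly", s["wtp_per_qaly"]),
    )


def _price_list(cfg: dict, arm: str) -> PriceList:
    p = cfg["prices"]
    v = cfg["vials"]
    sae_key = f"sae_cost_{arm}"
    return PriceList(
        sugemalimab_per_vial=p["sugemalimab_per_vial"]["base"],
        carboplatin_per_vial=p["carboplatin_per_vial"]["base"],
        pemetrexed_per_vial=p["pemetrexed_per_vial"]["base"],
        paclitaxel_per_vial=p["paclitaxel_per_vial"]["base"],
        docetaxel_per_vial=p["docetaxel_per_vial"]["base"],
        hospital_per_cycle=p["hospital_per_cycle"]["base"],
        followup_per_cycle=p["followup_per_cycle"]["base"],
        bsc_per_cycle=p["bsc_per_cycle"]["base"],
        sae_one_off=p[sae_key]["base"],
        **{k: float(v[k]) for k in (
            "sugemalimab_vial_mg", "carboplatin_vial_mg", "pemetrexed_vial_mg",
            "paclitaxel_vial_mg", "docetaxel_vial_mg")},
    )


def _ae_profile(cfg: dict, arm: str) -> AEProfile:
    dis = cfg["disutilities"]
    events = []
    for name, spec in cfg["sae_probabilities"][arm].items():
        if name not in dis:
            raise ConfigError(f"no disutility listed for adverse event {name!r}")
        events.append(AdverseEvent(name=name, probability=spec["base"],
                                   disutility=dis[name]["base"]))
    return AEProfile(events=tuple(events))


def build_arms(cfg: dict, price_factor: float = 1.0) -> dict:
    """Both strategy arms at the config's base values.

    ``price_factor`` scales the immunotherapy vial price in both arms
    (acquisition and crossover use alike), as in the price-cut scenarios.
    """
    utilities = UtilitySet(u_pfs=cfg["utilities"]["pfs"]["base"],
                           u_pd=cfg["utilities"]["pd"]["base"])
    dosing = DosingInputs(**{k: cfg["dosing"][k] for k in (
        "bsa_m2", "gfr_ml_min", "carboplatin_auc", "pemetrexed_mg_per_m2",
        "paclitaxel_mg_per_m2", "docetaxel_mg_per_m2", "sugemalimab_mg_flat",
        "induction_cycles", "max_treatment_cycles")})
    sf = cfg["settings"]["squamous_fraction"]
    cap = cfg["settings"].get("pd_crossover_cap_cycles")
    arms = {}
    for arm in ARMS:
        arms[arm] = ArmDefinition(
            name=arm,
            pfs=DistributionSpec.from_dict(cfg["curves"][arm]["pfs"]),
            os=DistributionSpec.from_dict(cfg["curves"][arm]["os"]),
            prices=_price_list(cfg, arm).with_price_factor(price_factor),
            dosing=dosing,
            utilities=utilities,
            ae_profile=_ae_profile(cfg, arm),
            subsequent=SubsequentMix(**cfg["subsequent"][arm]),
            squamous_fraction=sf,
            immunotherapy=(arm == "sugemalimab"),
            pd_crossover_cap_cycles=cap,
        )
    return arms


def parameter_registry(cfg: dict) -> list[ParameterSpec]:
    """Every ranged input, flattened for the sensitivity analyses."""
    out: list[ParameterSpec] = []
    for name, spec in cfg["prices"].items():
        out.append(ParameterSpec(
            name=f"price.{name}", path=("prices", name, "base"),
            base=spec["base"], low=spec["low"], high=spec["high"],
            distribution=spec.get("dist", "gamma"), role="cost"))
    for state, spec in cfg["utilities"].items():
        out.append(ParameterSpec(
            name=f"utility.{state}", path=("utilities", state, "base"),
            base=spec["base"], low=spec["low"], high=spec["high"],
            distribution=spec.get("dist", "beta"), role="utility"))
    for name, spec in cfg["disutilities"].items():
        out.append(ParameterSpec(
            name=f"disutility.{name}", path=("disutilities", name, "base"),
            base=spec["base"], low=spec["low"], high=spec["high"],
            distribution=spec.get("dist", "beta"), role="disutility"))
    for arm in ARMS:
        for name, spec in cfg["sae_probabilities"][arm].items():
            out.append(ParameterSpec(
                name=f"sae_prob.{arm}.{name}",
                path=("sae_probabilities", arm, name, "base"),
                base=spec["base"], low=spec["low"], high=spec["high"],
                distribution=spec.get("dist", "beta"), role="probability"))
    lo, hi = cfg["settings"].get("discount_rate_range", [0.0, 0.08])
    out.append(ParameterSpec(
        name="settings.discount_rate", path=("settings", "discount_rate_annual"),
        base=cfg["settings"]["discount_rate_annual"], low=lo, high=hi,
        distribution="fixed", role="rate"))
    return out


def set_parameter(cfg: dict, path: tuple, value: float) -> dict:
    """Deep-copied config with one value replaced."""
    new = copy.deepcopy(cfg)
    cur = new
    for k in path[:-1]:
        cur = cur[k]
    cur[path[-1]] = float(value)
    return new
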
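"""The complete model configuration and its structured-text serialization.

One :class:`ModelConfig` equals one reproducible analysis: cohort profile,
risk equations, meta-regression anchors, state-space topology, mortality,
cost/utility schedules, discounting and the PSA parameter table all live in
a single YAML document (plus a lifetable CSV next to it), so a configuration
can be audited line by line and diffed.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from rdncea.errors import ConfigurationError
from rdncea.risk_equations import CalibrationSet, CohortProfile, RiskEquationSpec
from rdncea.treatment_effect import TreatmentEffect
from rdncea.markov_engine import HealthStateSpace, MortalitySpec
from rdncea.economics import CostSchedule, DiscountSpec, UtilitySchedule


@dataclass
class ParamDist:
    """One uncertain parameter: distribution family, moments and config path.

    ``path`` addresses the parameter inside a :class:`ModelConfig`
    (attribute names; dict keys; tuple dict keys written as "cond|phase").
    ``demographic`` marks cohort heterogeneity variables that the PSA can
    hold fixed.
    """

    name: str
    family: str                      # Normal | Beta | Gamma
    mean: float
    se: float
    path: tuple[str, ...]
    demographic: bool = False
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("Normal", "Beta", "Gamma"):
            raise ConfigurationError(f"unknown distribution family {self.family!r}")
        if self.se < 0:
            raise ConfigurationError(f"SE for {self.name!r} must be >= 0")


@dataclass
class ModelConfig:
    cohort: CohortProfile
    equations: dict[str, RiskEquationSpec]
    calibration: CalibrationSet
    effect: TreatmentEffect
    mortality: MortalitySpec
    costs: CostSchedule
    utilities: UtilitySchedule
    discount: DiscountSpec
    space: HealthStateSpace
    horizon_age: float = 110.0
    repeat_procedure_cycle: int | None = None
    psa_params: list[ParamDist] = field(default_factory=list)

    def copy(self) -> "ModelConfig":
        # the lifetable frame and the state space are never mutated in place
        # by scenario/PSA machinery, so they are shared across copies
        memo = {
            id(self.mortality.lifetable): self.mortality.lifetable,
            id(self.space): self.space,
        }
        return copy.deepcopy(self, memo)

    # -- generic parameter access -----------------------------------------
    def _resolve(self, path: tuple[str, ...]):
        obj = self
        for part in path[:-1]:
            obj = _step(obj, part)
        return obj, path[-1]

    def get_param(self, path: tuple[str, ...]):
        obj, last = self._resolve(path)
        return _step(obj, last)

    def set_param(self, path: tuple[str, ...], value) -> None:
        obj, last = self._resolve(path)
        if isinstance(obj, dict):
            key = _dict_key(obj, last)
            old = obj[key]
            # a meta-regression anchor is an (RR_ref, delta_ref) pair; a
            # scalar assignment replaces its RR component
            if isinstance(old, tuple) and not isinstance(value, tuple):
                value = (value,) + old[1:]
            obj[key] = value
        else:
            if not hasattr(obj, last):
                raise ConfigurationError(f"no parameter at path {path!r}")
            setattr(obj, last, value)

    def config_hash(self) -> str:
        payload = json.dumps(to_dict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _dict_key(d: dict, part: str):
    if part in d:
        return part
    if "|" in part:
        key = tuple(part.split("|"))
        return key
    raise ConfigurationError(f"no key {part!r} in mapping")


def _step(obj, part: str):
    if isinstance(obj, dict):
        return obj[_dict_key(obj, part)]
    if not hasattr(obj, part):
        raise ConfigurationError(f"no parameter component {part!r} on {type(obj).__name__}")
    return getattr(obj, part)


# ---------------------------------------------------------------------------
# serialization


def _key_str(k) -> str:
    return "|".join(k) if isinstance(k, tuple) else k


def to_dict(config: ModelConfig) -> dict:
    c = config
    return {
        "cohort": dict(c.cohort.__dict__),
        "equations": {
            e: {
                "intercept": s.intercept,
                "coefficients": dict(s.coefficients),
                "centers": dict(s.centers),
                "native_horizon": s.native_horizon,
                "age_range": list(s.age_range),
                "source": s.source,
            }
            for e, s in c.equations.items()
        },
        "calibration": dict(c.calibration.hazard_ratios),
        "effect": {
            "delta_osbp": c.effect.delta_osbp,
            "anchors": {
                e: (list(a) if a is not None else None)
                for e, a in c.effect.anchors.items()
            },
            "hazard_scale": c.effect.hazard_scale,
            "waning_half_life_years": c.effect.waning_half_life_years,
        },
        "mortality": {
            "scale": c.mortality.scale,
            "excess": {_key_str(k): v for k, v in c.mortality.excess.items()},
            "case_fatality": dict(c.mortality.case_fatality),
            "excess_age_slope": c.mortality.excess_age_slope,
            "excess_ref_age": c.mortality.excess_ref_age,
        },
        "costs": {
            "annual": {_key_str(k): v for k, v in c.costs.annual.items()},
            "one_time": dict(c.costs.one_time),
            "htn_annual": c.costs.htn_annual,
            "procedure": c.costs.procedure,
        },
        "utilities": {
            "values": {_key_str(k): v for k, v in c.utilities.values.items()},
            "htn": c.utilities.htn,
            "combine": c.utilities.combine,
            "scale": c.utilities.scale,
            "cap": c.utilities.cap,
            "age_adjust": c.utilities.age_adjust,
            "age_curve": list(c.utilities.age_curve),
        },
        "discount": {
            "rate_costs": c.discount.rate_costs,
            "rate_effects": c.discount.rate_effects,
        },
        "space": c.space.to_dict(),
        "horizon_age": c.horizon_age,
        "repeat_procedure_cycle": c.repeat_procedure_cycle,
        "psa_params": [
            {
                "name": p.name,
                "family": p.family,
                "mean": p.mean,
                "se": p.se,
                "path": list(p.path),
                "demographic": p.demographic,
                "lower": p.lower,
                "upper": p.upper,
            }
            for p in c.psa_params
        ],
    }


def _tuple_keys(d: dict) -> dict:
    return {(tuple(k.split("|")) if "|" in k else k): v for k, v in d.items()}


def from_dict(d: dict, lifetable: pd.DataFrame) -> ModelConfig:
    eq = {
        e: RiskEquationSpec(
            endpoint=e,
            intercept=s["intercept"],
            coefficients=dict(s["coefficients"]),
            centers=dict(s["centers"]),
            native_horizon=s["native_horizon"],
            age_range=tuple(s["age_range"]),
            source=s.get("source", "config"),
        )
        for e, s in d["equations"].items()
    }
    eff = d["effect"]
    mort = d["mortality"]
    cost = d["costs"]
    util = d["utilities"]
    return ModelConfig(
        cohort=CohortProfile(**d["cohort"]),
        equations=eq,
        calibration=CalibrationSet(hazard_ratios=dict(d["calibration"])),
        effect=TreatmentEffect(
            delta_osbp=eff["delta_osbp"],
            anchors={
                e: (tuple(a) if a is not None else None)
                for e, a in eff["anchors"].items()
            },
            hazard_scale=eff["hazard_scale"],
            waning_half_life_years=eff.get("waning_half_life_years"),
        ),
        mortality=MortalitySpec(
            lifetable=lifetable,
            excess=_tuple_keys(mort["excess"]),
            case_fatality=dict(mort["case_fatality"]),
            scale=mort["scale"],
            excess_age_slope=mort.get("excess_age_slope", 0.0),
            excess_ref_age=mort.get("excess_ref_age", 65.0),
        ),
        costs=CostSchedule(
            annual=_tuple_keys(cost["annual"]),
            one_time=dict(cost["one_time"]),
            htn_annual=cost["htn_annual"],
            procedure=cost["procedure"],
        ),
        utilities=UtilitySchedule(
            values=_tuple_keys(util["values"]),
            htn=util["htn"],
            combine=util["combine"],
            scale=util["scale"],
            cap=util["cap"],
            age_adjust=util["age_adjust"],
            age_curve=tuple(util["age_curve"]),
        ),
        discount=DiscountSpec(**d["discount"]),
        space=HealthStateSpace.from_dict(d["space"]),
        horizon_age=d["horizon_age"],
        repeat_procedure_cycle=d.get("repeat_procedure_cycle"),
        psa_params=[
            ParamDist(
                name=p["name"],
                family=p["family"],
                mean=p["mean"],
                se=p["se"],
                path=tuple(p["path"]),
                demographic=p.get("demographic", False),
                lower=p.get("lower"),
                upper=p.get("upper"),
            )
            for p in d.get("psa_params", [])
        ],
    )


def save_config(config: ModelConfig, path: str | Path) -> Path:
    """Write the YAML config and the lifetable CSV next to it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lt_path = path.with_suffix(".lifetable.csv")
    d = to_dict(config)
    d["lifetable_csv"] = lt_path.name
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)
    config.mortality.lifetable.to_csv(lt_path, index=False)
    return path


def load_config(path: str | Path) -> ModelConfig:
    path = Path(path)
    with open(path) as fh:
        d = yaml.safe_load(fh)
    lt_name = d.get("lifetable_csv")
    if lt_name is None:
        raise ConfigurationError(f"{path}: missing lifetable_csv entry")
    lifetable = pd.read_csv(path.parent / lt_name)
    return from_dict(d, lifetable)
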
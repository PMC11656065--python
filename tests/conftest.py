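import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from rdncea.economics import evaluate
from rdncea.markov_engine import HealthState, HealthStateSpace, MortalitySpec
from rdncea.modelconfig import ModelConfig
from rdncea.risk_equations import CalibrationSet, CohortProfile, RiskEquationSpec
from rdncea.synthetic_data import make_base_fixture
from rdncea.treatment_effect import TreatmentEffect
from rdncea.economics import CostSchedule, DiscountSpec, UtilitySchedule

logging.getLogger("rdncea").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def base_config():
    return make_base_fixture()


@pytest.fixture(scope="session")
def base_bundle(base_config):
    """Full two-arm base-case evaluation, shared across tests."""
    return evaluate(base_config)


def flat_lifetable(q_annual: float) -> pd.DataFrame:
    ages = np.arange(0, 111)
    rows = []
    for sex in ("male", "female"):
        rows.append(pd.DataFrame({"age": ages, "sex": sex, "qx": q_annual}))
    return pd.concat(rows, ignore_index=True)


def toy_space() -> HealthStateSpace:
    """well -> sick (one condition, no tunnels) -> death; 4 states."""
    states = [
        HealthState("htn", frozenset(), None, ()),
        HealthState("hf_post", frozenset({"hf"}), "hf", (("hf", "any"),)),
        HealthState("cv_death", frozenset(), None, (), death="cv"),
        HealthState("noncv_death", frozenset(), None, (), death="noncv"),
    ]
    targets = {(None, "hf"): [("hf_post", 1.0, "hf")]}
    return HealthStateSpace(states=states, targets=targets)


def constant_hazard_equation(endpoint: str, annual_hazard: float) -> RiskEquationSpec:
    """No covariates: a flat annual event hazard."""
    return RiskEquationSpec(
        endpoint=endpoint,
        intercept=float(np.log(annual_hazard)),
        coefficients={},
        centers={},
        native_horizon=10.0,
    )


def toy_config(
    q_event_annual: float = 0.06,
    q_death_annual: float = 0.02,
    case_fatality: float = 0.0,
    excess_annual: float = 0.0,
    delta_osbp: float = 0.0,
    rr10: float = 0.64,
    horizon_age: float = 110.0,
    age: float = 55.0,
) -> ModelConfig:
    """A small single-condition model with flat hazards, for oracle tests."""
    space = toy_space()
    return ModelConfig(
        cohort=CohortProfile(age=age, female_fraction=0.0),
        equations={"hf": constant_hazard_equation("hf", q_event_annual)},
        calibration=CalibrationSet(),
        effect=TreatmentEffect(delta_osbp=delta_osbp, anchors={"hf": (rr10, 10.0)}),
        mortality=MortalitySpec(
            lifetable=flat_lifetable(q_death_annual),
            excess={("hf", "any"): excess_annual} if excess_annual else {},
            case_fatality={"hf": case_fatality} if case_fatality else {},
        ),
        costs=CostSchedule(
            annual={("hf", "any"): 1200.0},
            one_time={"hf": 500.0},
            htn_annual=0.0,
            procedure=6862.0,
        ),
        utilities=UtilitySchedule(
            values={("hf", "any"): 0.7}, htn=1.0, age_adjust=False
        ),
        discount=DiscountSpec(),
        space=space,
        horizon_age=horizon_age,
    )
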
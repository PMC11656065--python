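"""Synthetic inputs: lifetable, base-case fixture, perturbed fixtures.

Everything the model consumes can be generated here without downloads:

* a Gompertz–Makeham lifetable emulating an English national lifetable
  (smooth, monotone age-specific mortality; female below male), used as the
  background (non-CV-attributed) mortality in every alive state;
* the base-case model configuration mirroring the published key-parameter
  table (cohort 55.0 years, 19.9% female, office SBP 163 mmHg; treatment
  effect 4.9 mmHg, SE 0.54; 2022 GBP costs; utilities; 3.5% discounting),
  together with SYNTHETIC risk-equation coefficients — stand-ins for the
  source publications' Framingham/PROCAM/NHANES transcriptions, calibrated
  (scripts/calibrate_fixture.py) so the comparator arm reproduces the
  published comparator-arm 10-year and lifetime event incidences;
* random multiplicative perturbations of a fixture for fuzz testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from rdncea.errors import ConfigurationError
from rdncea.risk_equations import CalibrationSet, CohortProfile, RiskEquationSpec
from rdncea.treatment_effect import TreatmentEffect
from rdncea.markov_engine import MortalitySpec, default_space
from rdncea.economics import CostSchedule, DiscountSpec, UtilitySchedule
from rdncea.modelconfig import ModelConfig, ParamDist

AGE_MAX = 110


@dataclass
class GompertzMakehamParams:
    """Hazard h(age) = makeham + a * exp(b * age), annual scale."""

    a: float
    b: float
    makeham: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b < 0 or self.makeham < 0:
            raise ConfigurationError("Gompertz-Makeham parameters must be positive")


#: chosen for an England-like background: life expectancy at 55 in the
#: 25-32 year band, with the non-CV share of all-cause mortality (the model
#: adds CV deaths through condition states)
DEFAULT_LIFETABLE_PARAMS = {
    "male": GompertzMakehamParams(a=1.059594e-5, b=0.105, makeham=1.001089e-3),
    "female": GompertzMakehamParams(a=6.305809e-6, b=0.107, makeham=6.673933e-4),
}


@dataclass
class SyntheticLifetable:
    table: pd.DataFrame                      # columns: age, sex, qx
    params: dict[str, GompertzMakehamParams]

    def life_expectancy(self, age: float, sex: str) -> float:
        """Remaining life expectancy by survival-curve summation."""
        sub = self.table[self.table["sex"] == sex].sort_values("age")
        ages = sub["age"].to_numpy()
        qx = sub["qx"].to_numpy()
        mask = ages >= age
        surv = np.cumprod(1.0 - qx[mask])
        # trapezoid over whole years, half-year credit in the year of death
        return float(np.sum(surv)) + 0.5


def make_lifetable(
    params: dict[str, GompertzMakehamParams] | None = None, seed: int = 0
) -> SyntheticLifetable:
    """Deterministic synthetic lifetable for ages 0..110 by sex.

    Annual mortality q(age) = 1 - exp(-(makeham + a*exp(b*age))).  ``seed``
    is accepted for interface uniformity; the table is a pure function of
    the parameters.
    """
    params = dict(params or DEFAULT_LIFETABLE_PARAMS)
    rows = []
    ages = np.arange(0, AGE_MAX + 1)
    for sex, p in params.items():
        h = p.makeham + p.a * np.exp(p.b * ages)
        q = 1.0 - np.exp(-h)
        if np.any(~np.isfinite(q)) or np.any(q >= 1.0):
            raise ConfigurationError(
                "lifetable parameters imply annual mortality >= 1 before age 110"
            )
        rows.append(pd.DataFrame({"age": ages, "sex": sex, "qx": q}))
    table = pd.concat(rows, ignore_index=True)
    return SyntheticLifetable(table=table, params=params)


# ---------------------------------------------------------------------------
# calibrated synthetic risk equations
#
# NOT the supplement's coefficient transcriptions.  Log-hazard equations in
# age/sex/SBP/smoking/diabetes whose intercepts and age slopes were fitted by
# scripts/calibrate_fixture.py so the comparator arm reproduces the published
# comparator-arm 10-year (stroke 9.0%, MI 7.5%, AP/CHD 14.5%, HF 5.0%, ESRD
# 0.40%) and lifetime (33.8/38.0/28.0/20.9/1.03%) cumulative incidences at
# the base cohort (55.0 y, 19.9% female, 163 mmHg).  SBP slopes equal the
# meta-regression per-10-mmHg log-RRs; sex/smoking/diabetes slopes are
# epidemiologically plausible round values.

#: linear age slopes are fixed at literature-like mid-life gradients (stroke
#: and HF incidence roughly double per decade); the quadratic term (negative:
#: hazard growth flattens at old age) and the intercept are the calibrated
#: free parameters per endpoint
CALIBRATED_EQUATIONS: dict[str, dict] = {
    "stroke": {
        "intercept": -5.390824,
        "age": 0.085,
        "age_sq": -0.0008551,
        "male": 0.25,
        "sbp": 0.044629,
        "smoking": 0.60,
        "diabetes": 0.40,
    },
    "mi": {
        "intercept": -5.978835,
        "age": 0.070,
        "age_sq": 0.0039140,
        "male": 0.60,
        "sbp": 0.026136,
        "smoking": 0.50,
        "diabetes": 0.60,
    },
    "chd": {
        "intercept": -4.708522,
        "age": 0.030,
        "age_sq": -0.0029020,
        "male": 0.50,
        "sbp": 0.026136,
        "smoking": 0.45,
        "diabetes": 0.50,
    },
    "hf": {
        "intercept": -6.031488,
        "age": 0.085,
        "age_sq": -0.0006704,
        "male": 0.35,
        "sbp": 0.067334,
        "smoking": 0.20,
        "diabetes": 0.60,
    },
    "esrd": {
        "intercept": -8.317698,
        "age": 0.030,
        "age_sq": -0.0009821,
        "male": 0.30,
        "sbp": 0.008338,
        "smoking": 0.30,
        "diabetes": 1.00,
    },
}

#: per-10-mmHg standardized meta-regression RRs; chosen so the model's
#: 10-year event RRs at the 4.9-mmHg base-case effect match the published
#: 0.80 (stroke) / 0.88 (MI) / 0.72 (HF) / 0.89 (CHD) / 0.96 (ESRD)
META_REGRESSION_ANCHORS: dict[str, tuple[float, float]] = {
    "stroke": (0.64, 10.0),
    "mi": (0.77, 10.0),
    "chd": (0.77, 10.0),
    "hf": (0.51, 10.0),
    "esrd": (0.92, 10.0),
}

#: annual excess CV mortality by condition/phase, and acute case fatality by
#: event — post-event survival stand-ins of literature-plausible magnitude,
#: set so CV and all-cause death track the published 10-year 4.9% / 11.1%
EXCESS_MORTALITY: dict[tuple[str, str], float] = {
    ("stroke", "y1"): 0.038863,
    ("stroke", "chronic"): 0.023318,
    ("mi", "early"): 0.023318,
    ("mi", "late"): 0.015545,
    ("chd", "stable"): 0.003887,
    ("chd", "unstable"): 0.011660,
    ("hf", "any"): 0.062183,
    ("esrd", "any"): 0.108818,
}

CASE_FATALITY: dict[str, float] = {
    "stroke": 0.116592,
    "mi": 0.093274,
    "chd": 0.015545,   # unstable angina presentations only
    "hf": 0.031091,
    "esrd": 0.0,
}


#: published validity ranges of the emulated source equations; risks beyond
#: these ages use the clamped-age value rather than extrapolating
EQUATION_AGE_RANGES: dict[str, tuple[float, float]] = {
    "stroke": (30.0, 74.0),
    "mi": (35.0, 70.0),
    "chd": (30.0, 74.0),
    "hf": (30.0, 74.0),
    "esrd": (20.0, 90.0),
}


def _equation(endpoint: str, coeffs: dict) -> RiskEquationSpec:
    c = dict(coeffs)
    return RiskEquationSpec(
        endpoint=endpoint,
        intercept=c.pop("intercept"),
        coefficients=c,
        centers={"age": 55.0, "sbp": 163.0},
        native_horizon=10.0,
        age_range=EQUATION_AGE_RANGES[endpoint],
        source="synthetic-calibrated",
    )


def make_equations() -> dict[str, RiskEquationSpec]:
    return {e: _equation(e, c) for e, c in CALIBRATED_EQUATIONS.items()}


def _table1_costs() -> CostSchedule:
    return CostSchedule(
        annual={
            ("stroke", "y1"): 9926.0,
            ("stroke", "chronic"): 5672.0,
            ("mi", "early"): 944.0,
            ("mi", "late"): 944.0,
            ("chd", "stable"): 417.0,
            ("chd", "unstable"): 417.0,
            ("hf", "any"): 1260.0,
            ("esrd", "any"): 23718.0,
        },
        one_time={
            "stroke": 15327.0,
            "mi": 4344.0,
            "chd_unstable": 2259.0,
            "hf": 280.0,
        },
        htn_annual=279.0,
        procedure=6862.0,
    )


def _table1_utilities() -> UtilitySchedule:
    return UtilitySchedule(
        values={
            ("stroke", "y1"): 0.63,
            ("stroke", "chronic"): 0.63,
            ("mi", "early"): 0.76,
            ("mi", "late"): 0.88,
            ("chd", "stable"): 0.81,
            ("chd", "unstable"): 0.77,
            ("hf", "any"): 0.68,
            ("esrd", "any"): 0.72,
        },
        htn=1.0,
    )


def _psa_params() -> list[ParamDist]:
    P = ParamDist
    return [
        P("age", "Normal", 55.0, 0.53, ("cohort", "age"),
          demographic=True, lower=18.0, upper=100.0),
        P("female_fraction", "Beta", 0.199, 0.022, ("cohort", "female_fraction"),
          demographic=True),
        P("baseline_osbp", "Normal", 163.0, 0.40, ("cohort", "baseline_osbp"),
          demographic=True, lower=90.0, upper=250.0),
        P("treatment_effect", "Normal", 4.9, 0.54, ("effect", "delta_osbp")),
        P("cost_htn", "Gamma", 279.0, 28.0, ("costs", "htn_annual")),
        P("cost_stroke_acute", "Gamma", 15327.0, 1533.0,
          ("costs", "one_time", "stroke")),
        P("cost_stroke_y1", "Gamma", 9926.0, 1083.0,
          ("costs", "annual", "stroke|y1")),
        P("cost_stroke_y2", "Gamma", 5672.0, 567.0,
          ("costs", "annual", "stroke|chronic")),
        P("cost_mi_acute", "Gamma", 4344.0, 96.0, ("costs", "one_time", "mi")),
        P("cost_mi_annual_early", "Gamma", 944.0, 135.0,
          ("costs", "annual", "mi|early")),
        P("cost_mi_annual_late", "Gamma", 944.0, 135.0,
          ("costs", "annual", "mi|late")),
        P("cost_sap_annual", "Gamma", 417.0, 74.0,
          ("costs", "annual", "chd|stable")),
        P("cost_uap_acute", "Gamma", 2259.0, 51.0,
          ("costs", "one_time", "chd_unstable")),
        P("cost_uap_annual", "Gamma", 417.0, 74.0,
          ("costs", "annual", "chd|unstable")),
        P("cost_hf_acute", "Gamma", 280.0, 105.0, ("costs", "one_time", "hf")),
        P("cost_hf_annual", "Gamma", 1260.0, 300.0, ("costs", "annual", "hf|any")),
        P("cost_esrd_annual", "Gamma", 23718.0, 2372.0,
          ("costs", "annual", "esrd|any")),
        P("cost_rdn", "Gamma", 6862.0, 686.0, ("costs", "procedure")),
        P("utility_stroke_y1", "Beta", 0.63, 0.04,
          ("utilities", "values", "stroke|y1")),
        P("utility_stroke_y2", "Beta", 0.63, 0.04,
          ("utilities", "values", "stroke|chronic")),
        P("utility_mi_early", "Beta", 0.76, 0.18,
          ("utilities", "values", "mi|early")),
        P("utility_mi_late", "Beta", 0.88, 0.09,
          ("utilities", "values", "mi|late")),
        P("utility_sap", "Beta", 0.81, 0.02, ("utilities", "values", "chd|stable")),
        P("utility_uap", "Beta", 0.77, 0.04,
          ("utilities", "values", "chd|unstable")),
        P("utility_hf", "Beta", 0.68, 0.01, ("utilities", "values", "hf|any")),
        P("utility_esrd", "Beta", 0.72, 0.37, ("utilities", "values", "esrd|any")),
        # per-10-mmHg meta-regression RRs carry their own estimation
        # uncertainty (published CIs); sampled on the anchor's RR component
        P("rr10_stroke", "Beta", 0.64, 0.035, ("effect", "anchors", "stroke")),
        P("rr10_mi", "Beta", 0.77, 0.040, ("effect", "anchors", "mi")),
        P("rr10_chd", "Beta", 0.77, 0.040, ("effect", "anchors", "chd")),
        P("rr10_hf", "Beta", 0.51, 0.045, ("effect", "anchors", "hf")),
        P("rr10_esrd", "Beta", 0.92, 0.040, ("effect", "anchors", "esrd")),
    ]


def make_base_fixture(seed: int = 0) -> ModelConfig:
    """The full base-case configuration (pure function of the seed)."""
    lifetable = make_lifetable(seed=seed)
    return ModelConfig(
        cohort=CohortProfile(
            age=55.0,
            female_fraction=0.199,
            baseline_osbp=163.0,
            n_medications=1.9,
            smoking_fraction=0.15,
            diabetes_fraction=0.08,
        ),
        equations=make_equations(),
        calibration=CalibrationSet(),
        effect=TreatmentEffect(
            delta_osbp=4.9, anchors=dict(META_REGRESSION_ANCHORS)
        ),
        mortality=MortalitySpec(
            lifetable=lifetable.table,
            excess=dict(EXCESS_MORTALITY),
            case_fatality=dict(CASE_FATALITY),
        ),
        costs=_table1_costs(),
        utilities=_table1_utilities(),
        discount=DiscountSpec(rate_costs=0.035, rate_effects=0.035),
        space=default_space(),
        horizon_age=110.0,
        psa_params=_psa_params(),
    )


# ---------------------------------------------------------------------------
# perturbation


def perturb_fixture(
    fixture: ModelConfig, magnitude: float, seed: int = 0
) -> ModelConfig:
    """Random multiplicative perturbation of all continuous parameters.

    Each parameter in the fixture's PSA table is multiplied by
    ``exp(N(0, magnitude))``, then clipped back into its admissible range
    (probabilities/utilities to [0, 1], ages to the lifetable range, SBP to
    the profile's range).  ``magnitude`` 0 returns an identical fixture.
    """
    if magnitude < 0:
        raise ConfigurationError("magnitude must be >= 0")
    out = fixture.copy()
    if magnitude == 0:
        return out
    rng = np.random.default_rng(seed)
    for p in out.psa_params:
        factor = float(np.exp(rng.normal(0.0, magnitude)))
        value = out.get_param(p.path)
        if isinstance(value, tuple):  # meta-regression anchor: perturb the RR
            value = value[0]
        value = value * factor
        if p.family == "Beta":
            value = min(value, 1.0)
        lo = p.lower if p.lower is not None else 0.0
        hi = p.upper if p.upper is not None else np.inf
        value = float(np.clip(value, lo, hi))
        out.set_param(p.path, value)
    return out
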
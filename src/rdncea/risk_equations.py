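"""Baseline event risks from multivariate risk equations.

Each hypertension sequela (stroke, MI, other CHD/angina, heart failure,
end-stage renal disease) gets a risk equation of the log-hazard form

    p_native = 1 - exp(-H * exp(b0 + sum_i b_i * (x_i - c_i)))

where ``H`` is the equation's native horizon in years, ``exp(b0)`` the
baseline annual event hazard at the covariate centres ``c_i``, and the
covariates are resolved from a :class:`CohortProfile`.  Native-horizon risks
are converted to per-cycle probabilities on the rate (exponential) scale and
can be calibrated with a hazard ratio to vary baseline event risk.

Binary covariates (sex, smoking, diabetes) supplied as cohort fractions are
handled by evaluating the equation in each stratum and mixing the resulting
probabilities by the stratum weights, because the equations are defined for
indicator covariates, not prevalences.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from rdncea.errors import ConfigurationError

logger = logging.getLogger(__name__)

ENDPOINTS = ("stroke", "mi", "chd", "hf", "esrd")

#: covariates that take indicator (0/1) values in the equations but may be
#: supplied as cohort fractions in a profile
BINARY_COVARIATES = ("male", "smoking", "diabetes", "lvh", "bp_treated")


@dataclass
class CohortProfile:
    """Demographic and clinical covariates feeding the risk equations.

    ``age`` is a continuous attained age in years and is advanced by 1/12 per
    model cycle.  Fractions are cohort proportions in [0, 1]; sex-specific
    model runs replace ``female_fraction`` with 0 or 1.
    """

    age: float = 55.0
    female_fraction: float = 0.199
    baseline_osbp: float = 163.0
    n_medications: float = 1.9
    smoking_fraction: float = 0.0
    diabetes_fraction: float = 0.0
    total_chol: float = 5.2        # mmol/L, population mean placeholder
    hdl_chol: float = 1.3          # mmol/L
    lvh_fraction: float = 0.0
    bp_treated: float = 1.0        # on antihypertensive treatment

    def __post_init__(self) -> None:
        if not (18.0 <= self.age <= 110.0):
            raise ConfigurationError(f"age {self.age} outside [18, 110]")
        if not (90.0 <= self.baseline_osbp <= 250.0):
            raise ConfigurationError(
                f"baseline_osbp {self.baseline_osbp} outside [90, 250]"
            )
        for name in ("female_fraction", "smoking_fraction", "diabetes_fraction",
                     "lvh_fraction", "bp_treated"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} = {v} outside [0, 1]")

    def covariate(self, name: str) -> float:
        """Resolve a named equation covariate from the profile."""
        mapping = {
            "age": self.age,
            "male": 1.0 - self.female_fraction,
            "sbp": self.baseline_osbp,
            "smoking": self.smoking_fraction,
            "diabetes": self.diabetes_fraction,
            "total_chol": self.total_chol,
            "hdl_chol": self.hdl_chol,
            "lvh": self.lvh_fraction,
            "bp_treated": self.bp_treated,
            "n_medications": self.n_medications,
        }
        try:
            return mapping[name]
        except KeyError:
            raise ConfigurationError(
                f"covariate {name!r} cannot be resolved from the cohort profile"
            ) from None


@dataclass
class RiskEquationSpec:
    """One endpoint's risk equation.

    ``coefficients`` maps covariate names to slopes on the log-hazard scale;
    ``centers`` holds the covariate values at which the linear predictor is
    zero (so ``exp(intercept)`` is the baseline annual hazard there).
    ``age_range`` is the published validity range: ages outside it are
    clamped, with a log message, rather than extrapolated.
    """

    endpoint: str
    intercept: float
    coefficients: dict[str, float] = field(default_factory=dict)
    centers: dict[str, float] = field(default_factory=dict)
    native_horizon: float = 10.0
    age_range: tuple[float, float] = (18.0, 110.0)
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if self.native_horizon <= 0:
            raise ConfigurationError("native_horizon must be > 0")
        if self.endpoint not in ENDPOINTS:
            raise ConfigurationError(
                f"unknown endpoint {self.endpoint!r}; expected one of {ENDPOINTS}"
            )


@dataclass
class CalibrationSet:
    """Per-endpoint hazard-ratio multipliers on baseline event risk."""

    hazard_ratios: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.hazard_ratios.items():
            if v <= 0:
                raise ConfigurationError(f"hazard ratio for {k!r} must be > 0, got {v}")

    def ratio(self, endpoint: str) -> float:
        return self.hazard_ratios.get(endpoint, 1.0)

    def scaled(self, factor: float) -> "CalibrationSet":
        """All endpoints multiplied by a common event-adjustment factor."""
        hrs = {e: self.ratio(e) * factor for e in ENDPOINTS}
        return CalibrationSet(hazard_ratios=hrs)


def _linear_predictor(spec: RiskEquationSpec, values: dict[str, float | np.ndarray]):
    lp = spec.intercept
    for name, beta in spec.coefficients.items():
        if name not in values:
            raise ConfigurationError(
                f"equation for {spec.endpoint!r} needs covariate {name!r} "
                "which is not resolvable from the cohort profile"
            )
        lp = lp + beta * (values[name] - spec.centers.get(name, 0.0))
    return lp


_CLAMP_WARNED: set[tuple[str, float, float]] = set()


def _clamped_age(spec: RiskEquationSpec, age):
    lo, hi = spec.age_range
    clipped = np.clip(age, lo, hi)
    key = (spec.endpoint, lo, hi)
    if key not in _CLAMP_WARNED and np.any(clipped != np.asarray(age, dtype=float)):
        _CLAMP_WARNED.add(key)
        logger.warning(
            "age outside validity range [%s, %s] of %s equation; clamping "
            "(reported once per equation)",
            lo, hi, spec.endpoint,
        )
    return clipped


def _strata(spec: RiskEquationSpec, profile: CohortProfile):
    """Binary-covariate strata (indicator combos) and their mixing weights."""
    fractional = []
    for name in BINARY_COVARIATES:
        if name not in spec.coefficients:
            continue
        f = profile.covariate(name)
        if f not in (0.0, 1.0):
            fractional.append((name, f))
    if not fractional:
        return [({}, 1.0)]
    combos = []
    for bits in itertools.product((0.0, 1.0), repeat=len(fractional)):
        w = 1.0
        assign = {}
        for (name, f), b in zip(fractional, bits):
            assign[name] = b
            w *= f if b == 1.0 else (1.0 - f)
        combos.append((assign, w))
    return combos


def native_risk(
    spec: RiskEquationSpec,
    profile: CohortProfile,
    ages: np.ndarray | None = None,
):
    """Event probability over the equation's native horizon.

    With ``ages`` given (a vector of attained ages), returns a vector of
    risks re-evaluated at each age with all other covariates fixed — the
    engine uses this to build a time-inhomogeneous chain.  Otherwise a scalar
    at ``profile.age``.
    """
    age = profile.age if ages is None else np.asarray(ages, dtype=float)
    age = _clamped_age(spec, age)
    values: dict[str, float | np.ndarray] = {
        name: profile.covariate(name)
        for name in spec.coefficients
        if name not in ("age", "age_sq")
    }
    values["age"] = age
    if "age_sq" in spec.coefficients:
        # quadratic age term, centred with the linear one
        values["age_sq"] = (age - spec.centers.get("age", 0.0)) ** 2

    total = 0.0
    for assign, w in _strata(spec, profile):
        v = dict(values)
        v.update(assign)
        lp = _linear_predictor(spec, v)
        hazard = np.exp(lp)  # annual
        total = total + w * (1.0 - np.exp(-spec.native_horizon * hazard))
    return float(total) if ages is None else total


def to_cycle_probability(
    p_native: float | np.ndarray,
    native_horizon: float,
    cycle_length: float = 1.0,
) -> float | np.ndarray:
    """Convert a native-horizon risk to a per-cycle probability.

    Rate-scale (exponential) conversion:
    ``1 - (1 - p)**((cycle_length/12) / native_horizon)`` with
    ``cycle_length`` in months and ``native_horizon`` in years.  ``p = 1`` is
    absorbing and returned unchanged with a warning.
    """
    p = np.asarray(p_native, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ConfigurationError("p_native must lie in [0, 1]")
    if np.any(p == 1.0):
        logger.warning("p_native = 1 is absorbing; per-cycle probability is 1")
    frac = (cycle_length / 12.0) / native_horizon
    out = -np.expm1(frac * np.log1p(-p, where=p < 1.0, out=np.full_like(p, -np.inf)))
    out = np.where(p == 1.0, 1.0, out)
    if np.ndim(p_native) == 0:
        return float(out)
    return out


def calibrate(p_cycle: float | np.ndarray, hr: float) -> float | np.ndarray:
    """Apply a hazard ratio on the rate scale: ``1 - (1 - p)**hr``."""
    if hr <= 0:
        raise ConfigurationError(f"hazard ratio must be > 0, got {hr}")
    p = np.asarray(p_cycle, dtype=float)
    out = -np.expm1(hr * np.log1p(-p))
    if np.ndim(p_cycle) == 0:
        return float(out)
    return out


def sex_stratified(profile: CohortProfile) -> list[tuple[str, float, CohortProfile]]:
    """(label, weight, single-sex profile) pairs mixing at ``female_fraction``."""
    out = []
    if profile.female_fraction < 1.0:
        out.append(("male", 1.0 - profile.female_fraction,
                    replace(profile, female_fraction=0.0)))
    if profile.female_fraction > 0.0:
        out.append(("female", profile.female_fraction,
                    replace(profile, female_fraction=1.0)))
    return out
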
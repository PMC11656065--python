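"""Discounted cost and QALY accrual, ICERs and NICE threshold verdicts.

Annual state costs and utilities accrue at 1/12 per cycle with a trapezoidal
half-cycle correction (average of start- and end-of-cycle occupancy) and
mid-cycle discounting at 3.5% per annum for both costs and effects.  Acute
event costs are charged once on the entry transition (no half-cycle
correction).  The one-time procedure cost is charged in the treated arm at
cycle 0 (and again, survival-weighted and discounted, if a repeat procedure
is configured).

Utilities are the product rule of the schedule: a state's weight is the
minimum of its component conditions' utilities (configurable to
multiplicative), scaled by the scenario utility multiplier, capped at 1,
and multiplied by a UK-style population age-utility curve normalized to 1
at the cohort's starting age.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from rdncea.errors import ConfigurationError
from rdncea.markov_engine import (
    CycleTrace,
    HealthStateSpace,
    ModelRun,
    cumulative_incidence,
    run_model,
)

NICE_LOWER = 20_000.0
NICE_UPPER = 30_000.0

VERDICTS = (
    "cost-effective",
    "potentially cost-effective",
    "not cost-effective",
    "dominant",
    "dominated",
)


# ---------------------------------------------------------------------------
# schedules


@dataclass
class CostSchedule:
    """Per-state cost schedule in 2022 GBP.

    ``annual`` maps (condition, phase) keys to annual state costs;
    ``one_time`` maps event keys to acute entry costs; ``htn_annual`` is the
    background hypertension-management cost applied in every alive state;
    ``procedure`` is the one-time RF RDN therapy cost.
    """

    annual: dict[tuple[str, str], float] = field(default_factory=dict)
    one_time: dict[str, float] = field(default_factory=dict)
    htn_annual: float = 279.0
    procedure: float = 6862.0

    def __post_init__(self) -> None:
        vals = list(self.annual.values()) + list(self.one_time.values())
        vals += [self.htn_annual, self.procedure]
        if any(v < 0 for v in vals):
            raise ConfigurationError("costs must be non-negative")

    def scaled(self, factor: float) -> "CostSchedule":
        """All event/management costs scaled; the procedure cost is not."""
        return CostSchedule(
            annual={k: v * factor for k, v in self.annual.items()},
            one_time={k: v * factor for k, v in self.one_time.items()},
            htn_annual=self.htn_annual * factor,
            procedure=self.procedure,
        )

    def state_monthly_costs(self, space: HealthStateSpace) -> np.ndarray:
        out = np.zeros(space.n_states)
        for i, st in enumerate(space.states):
            if st.is_death:
                continue
            c = self.htn_annual
            for key in st.phase_keys:
                if key not in self.annual:
                    raise ConfigurationError(
                        f"no annual cost configured for state component {key}"
                    )
                c += self.annual[key]
            out[i] = c / 12.0
        return out

    def acute_event_costs(self, space: HealthStateSpace) -> np.ndarray:
        """Per-endpoint one-time cost per incident event."""
        out = np.zeros(len(space.endpoints))
        for j, e in enumerate(space.endpoints):
            if e == "chd":
                out[j] = space.unstable_chd_fraction * self.one_time.get(
                    "chd_unstable", 0.0
                )
            else:
                out[j] = self.one_time.get(e, 0.0)
        return out


#: UK population EQ-5D age-utility curve (constant, male, age, age^2), of the
#: published general-population regression form.
DEFAULT_AGE_CURVE = (0.9508566, 0.0212126, -0.0002587, -0.0000332)


@dataclass
class UtilitySchedule:
    """Health-state utility weights and age adjustment."""

    values: dict[tuple[str, str], float] = field(default_factory=dict)
    htn: float = 1.0
    combine: str = "min"               # or "multiplicative"
    scale: float = 1.0
    cap: float = 1.0
    age_adjust: bool = True
    age_curve: tuple[float, float, float, float] = DEFAULT_AGE_CURVE

    def __post_init__(self) -> None:
        for k, v in self.values.items():
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"utility {k} = {v} outside [0, 1]")
        if not (0.0 <= self.htn <= 1.0):
            raise ConfigurationError("hypertension utility outside [0, 1]")
        if self.combine not in ("min", "multiplicative"):
            raise ConfigurationError(f"unknown combine rule {self.combine!r}")

    def state_utilities(self, space: HealthStateSpace) -> np.ndarray:
        out = np.zeros(space.n_states)
        for i, st in enumerate(space.states):
            if st.is_death:
                continue
            if not st.phase_keys:
                u = self.htn
            else:
                comps = []
                for key in st.phase_keys:
                    if key not in self.values:
                        raise ConfigurationError(
                            f"no utility configured for state component {key}"
                        )
                    comps.append(self.values[key])
                u = min(comps) if self.combine == "min" else float(np.prod(comps))
            out[i] = min(u * self.scale, self.cap)
        return out

    def age_multiplier(self, ages: np.ndarray, sex: str, ref_age: float) -> np.ndarray:
        if not self.age_adjust:
            return np.ones_like(ages, dtype=float)
        c0, cm, c1, c2 = self.age_curve
        male = 1.0 if sex == "male" else 0.0

        def curve(a):
            return c0 + cm * male + c1 * a + c2 * a ** 2

        ref = curve(ref_age)
        if ref <= 0:
            raise ConfigurationError("age-utility curve non-positive at start age")
        return np.clip(curve(np.asarray(ages, dtype=float)) / ref, 0.0, None)


@dataclass
class DiscountSpec:
    """Annual discount rates for costs and effects (NICE base: 3.5%)."""

    rate_costs: float = 0.035
    rate_effects: float = 0.035

    def mid_cycle_factors(self, n_cycles: int, rate: float) -> np.ndarray:
        t = (np.arange(n_cycles) + 0.5) / 12.0
        return (1.0 + rate) ** (-t)

    def factor_at(self, years: float, rate: float) -> float:
        return float((1.0 + rate) ** (-years))


# ---------------------------------------------------------------------------
# results containers


@dataclass
class ArmResult:
    """Discounted cost/QALYs and undiscounted life-years for one arm."""

    cost: float
    qalys: float
    life_years: float
    incidence_10y: dict[str, float] = field(default_factory=dict)
    incidence_lifetime: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cost < -1e-9 or self.qalys < -1e-9 or self.life_years < -1e-9:
            raise ConfigurationError("arm results must be non-negative")
        if self.qalys > self.life_years + 1e-9:
            raise ConfigurationError("QALYs cannot exceed life-years")


@dataclass
class CEResult:
    """Incremental comparison of treated vs. control."""

    delta_cost: float
    delta_qalys: float
    icer: float | None
    verdict: str
    icer_defined: bool = True

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ConfigurationError(f"unknown verdict {self.verdict!r}")


def icer(treated: ArmResult, control: ArmResult) -> CEResult:
    """ICER on unrounded values with dominance and NICE banding."""
    dc = treated.cost - control.cost
    dq = treated.qalys - control.qalys
    if abs(dq) < 1e-9:
        verdict = "dominated" if dc > 0 else "dominant"
        return CEResult(dc, dq, None, verdict, icer_defined=False)
    if dq > 0 and dc <= 0:
        return CEResult(dc, dq, dc / dq, "dominant")
    if dq < 0 and dc >= 0:
        return CEResult(dc, dq, dc / dq, "dominated")
    ratio = dc / dq
    if dq > 0:
        if ratio < NICE_LOWER:
            verdict = "cost-effective"
        elif ratio <= NICE_UPPER:
            verdict = "potentially cost-effective"
        else:
            verdict = "not cost-effective"
    else:
        # south-west quadrant: saving money by giving up QALYs
        verdict = "cost-effective" if ratio > NICE_UPPER else "not cost-effective"
    return CEResult(dc, dq, ratio, verdict)


# ---------------------------------------------------------------------------
# accrual


def accrue(
    trace: CycleTrace,
    costs: CostSchedule,
    utilities: UtilitySchedule,
    discount: DiscountSpec,
    horizon_cycles: int | None = None,
    one_time_cycles: tuple[int, ...] = (),
) -> ArmResult:
    """Discounted costs, QALYs and undiscounted life-years for one trace.

    ``one_time_cycles`` charges the procedure cost at those cycles,
    survival-weighted and discounted at the exact cycle time.
    """
    C = trace.n_cycles if horizon_cycles is None else int(horizon_cycles)
    if C > trace.n_cycles:
        raise ConfigurationError("horizon beyond trace length")
    occ_mid = 0.5 * (trace.occupancy[:C] + trace.occupancy[1 : C + 1])
    d_cost = discount.mid_cycle_factors(C, discount.rate_costs)
    d_eff = discount.mid_cycle_factors(C, discount.rate_effects)

    state_cost = costs.state_monthly_costs(trace.space)
    acute = costs.acute_event_costs(trace.space)
    cost = float((occ_mid @ state_cost) @ d_cost)
    cost += float((trace.events[:C] @ acute) @ d_cost)
    for cyc in one_time_cycles:
        if cyc <= C:
            alive = float(trace.alive_fraction()[cyc])
            cost += costs.procedure * alive * discount.factor_at(
                cyc / 12.0, discount.rate_costs
            )

    u = utilities.state_utilities(trace.space)
    mult = utilities.age_multiplier(
        trace.ages[:C] + 0.5 / 12.0, trace.sex, float(trace.ages[0])
    )
    qalys = float(((occ_mid @ u) * mult) @ d_eff) / 12.0

    alive_mid = 1.0 - 0.5 * (
        trace.dead_fraction()[:C] + trace.dead_fraction()[1 : C + 1]
    )
    life_years = float(alive_mid.sum()) / 12.0
    return ArmResult(cost=cost, qalys=qalys, life_years=life_years)


@dataclass
class CEBundle:
    """Full two-arm evaluation: per-arm results, incremental result, run."""

    control: ArmResult
    treated: ArmResult
    ce: CEResult
    run: ModelRun


def _mix(results: dict[str, ArmResult], weights: dict[str, float]) -> ArmResult:
    return ArmResult(
        cost=sum(weights[s] * results[s].cost for s in weights),
        qalys=sum(weights[s] * results[s].qalys for s in weights),
        life_years=sum(weights[s] * results[s].life_years for s in weights),
    )


def evaluate(
    config,
    horizon_cycles: int | None = None,
    run: ModelRun | None = None,
) -> CEBundle:
    """Run (or reuse) the two-arm model and produce the CE comparison."""
    if run is None:
        run = run_model(config)
    one_time = {"control": (), "treated": _procedure_cycles(config)}
    per_arm: dict[str, ArmResult] = {}
    for arm in ("control", "treated"):
        per_sex = {
            sex: accrue(
                run.trace(arm, sex),
                config.costs,
                config.utilities,
                config.discount,
                horizon_cycles=horizon_cycles,
                one_time_cycles=one_time[arm],
            )
            for sex in run.weights
        }
        res = _mix(per_sex, run.weights)
        h10 = min(120, run.trace(arm, next(iter(run.weights))).n_cycles)
        res.incidence_10y = {
            e: run.cumulative_incidence(arm, e, h10)
            for e in config.space.endpoints
        }
        res.incidence_lifetime = {
            e: run.cumulative_incidence(arm, e, None)
            for e in config.space.endpoints
        }
        per_arm[arm] = res
    return CEBundle(
        control=per_arm["control"],
        treated=per_arm["treated"],
        ce=icer(per_arm["treated"], per_arm["control"]),
        run=run,
    )


def _procedure_cycles(config) -> tuple[int, ...]:
    cycles = [0]
    rep = getattr(config, "repeat_procedure_cycle", None)
    if rep is not None:
        cycles.append(int(rep))
    return tuple(cycles)


def time_horizon_sweep(config, horizons_years: list[float]) -> list[CEResult]:
    """CE results at truncated horizons, reusing one lifetime run."""
    run = run_model(config)
    lifetime_cycles = run.trace("control", next(iter(run.weights))).n_cycles
    out = []
    for h in horizons_years:
        hc = int(round(h * 12))
        if hc > lifetime_cycles:
            raise ConfigurationError(
                f"horizon {h} years exceeds the lifetime horizon"
            )
        out.append(evaluate(config, horizon_cycles=hc, run=run).ce)
    return out
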
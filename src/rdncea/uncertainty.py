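"""One-way sensitivity, scenario battery and probabilistic sensitivity.

The PSA samples every parameter in the config's parameter table from its
Table-style distribution (Normal, or Gamma/Beta parameterized by the method
of moments), re-evaluates the full two-arm model per draw, and summarizes
incremental costs and QALYs.  The probability of cost-effectiveness is
computed on net monetary benefit (lambda*dQ - dC > 0), which handles the
dominance quadrants correctly; the mean ICER is the ratio of means
E[dC]/E[dQ] (the mean of per-draw ratios is also reported), and the 95%
credibility interval is taken over per-draw ICERs restricted to the dQ > 0
quadrant, with quadrant counts reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rdncea.errors import ConfigurationError
from rdncea.economics import CEResult, evaluate
from rdncea.modelconfig import ModelConfig, ParamDist

DEFAULT_THRESHOLD_GRID = tuple(range(0, 50_001, 1_000))


# ---------------------------------------------------------------------------
# one-way sensitivity (tornado)


def _default_range(p: ParamDist) -> tuple[float, float]:
    lo = p.mean - 1.96 * p.se
    hi = p.mean + 1.96 * p.se
    if p.family == "Beta":
        lo, hi = max(lo, 1e-6), min(hi, 1.0)
    if p.family == "Gamma":
        lo = max(lo, 0.0)
    if p.lower is not None:
        lo = max(lo, p.lower)
    if p.upper is not None:
        hi = min(hi, p.upper)
    return lo, hi


def one_way_sensitivity(
    config: ModelConfig,
    param_ranges: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """ICER at each parameter's low/high with all else at base.

    Default ranges are the 95% confidence intervals (mean +/- 1.96 SE,
    clipped to each distribution's support).  Output is sorted by ICER span
    descending.
    """
    by_name = {p.name: p for p in config.psa_params}
    if param_ranges is None:
        param_ranges = {p.name: _default_range(p) for p in config.psa_params}
    rows = []
    base = evaluate(config)
    for name, (lo, hi) in param_ranges.items():
        if name not in by_name:
            raise ConfigurationError(f"unknown parameter {name!r}")
        if lo > hi:
            raise ConfigurationError(f"range for {name!r} has low > high")
        p = by_name[name]
        icers = {}
        for label, value in (("low", lo), ("high", hi)):
            cfg = config.copy()
            cfg.set_param(p.path, value)
            icers[label] = evaluate(cfg).ce.icer
        rows.append({
            "parameter": name,
            "low": lo,
            "high": hi,
            "icer_low": icers["low"],
            "icer_high": icers["high"],
            "icer_base": base.ce.icer,
            "span": abs((icers["high"] or np.nan) - (icers["low"] or np.nan)),
        })
    out = pd.DataFrame(rows).sort_values("span", ascending=False, ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# scenarios


@dataclass
class ScenarioSpec:
    """Named overrides of the base configuration."""

    name: str
    overrides: dict[str, float] = field(default_factory=dict)

    KNOWN = (
        "age",
        "female_fraction",
        "baseline_osbp",
        "delta_osbp",
        "cost_scale",
        "utility_scale",
        "event_adjustment",
        "mortality_scale",
        "horizon_years",
        "repeat_procedure_years",
        "procedure_cost",
    )

    def __post_init__(self) -> None:
        for k in self.overrides:
            if k not in self.KNOWN:
                raise ConfigurationError(f"unknown scenario override {k!r}")


def apply_scenario(config: ModelConfig, scenario: ScenarioSpec) -> ModelConfig:
    cfg = config.copy()
    ov = dict(scenario.overrides)
    if "age" in ov:
        cfg.cohort.age = float(ov["age"])
    if "female_fraction" in ov:
        cfg.cohort.female_fraction = float(ov["female_fraction"])
    if "baseline_osbp" in ov:
        cfg.cohort.baseline_osbp = float(ov["baseline_osbp"])
    if "delta_osbp" in ov:
        cfg.effect.delta_osbp = float(ov["delta_osbp"])
    if "cost_scale" in ov:
        cfg.costs = cfg.costs.scaled(float(ov["cost_scale"]))
    if "utility_scale" in ov:
        cfg.utilities.scale = float(ov["utility_scale"])
    if "event_adjustment" in ov:
        cfg.calibration = cfg.calibration.scaled(float(ov["event_adjustment"]))
    if "mortality_scale" in ov:
        cfg.mortality.scale = float(ov["mortality_scale"])
    if "repeat_procedure_years" in ov:
        cfg.repeat_procedure_cycle = int(round(ov["repeat_procedure_years"] * 12))
    if "procedure_cost" in ov:
        cfg.costs.procedure = float(ov["procedure_cost"])
    return cfg


def run_scenario(config: ModelConfig, scenario: ScenarioSpec) -> CEResult:
    """Deterministic CE result under a modified configuration."""
    cfg = apply_scenario(config, scenario)
    horizon_cycles = None
    if "horizon_years" in scenario.overrides:
        horizon_cycles = int(round(scenario.overrides["horizon_years"] * 12))
    return evaluate(cfg, horizon_cycles=horizon_cycles).ce


#: the published scenario battery (effect sizes in mmHg vs. the comparator)
TABLE_SCENARIOS: dict[str, ScenarioSpec] = {
    s.name: s
    for s in [
        ScenarioSpec("base", {}),
        ScenarioSpec("effect_9.9_vs_baseline", {"delta_osbp": 9.9}),
        ScenarioSpec("subcohort_3meds_ous_6.9", {"delta_osbp": 6.9}),
        ScenarioSpec("age_45", {"age": 45.0}),
        ScenarioSpec("age_70", {"age": 70.0}),
        ScenarioSpec("male_100", {"female_fraction": 0.0}),
        ScenarioSpec("female_100", {"female_fraction": 1.0}),
        ScenarioSpec("sbp_140", {"baseline_osbp": 140.0}),
        ScenarioSpec("sbp_180", {"baseline_osbp": 180.0}),
        ScenarioSpec("costs_80pct", {"cost_scale": 0.8}),
        ScenarioSpec("costs_50pct", {"cost_scale": 0.5}),
        ScenarioSpec("costs_120pct", {"cost_scale": 1.2}),
        ScenarioSpec("repeat_procedure_10y", {"repeat_procedure_years": 10.0}),
        ScenarioSpec("utilities_plus10", {"utility_scale": 1.1}),
        ScenarioSpec("utilities_minus10", {"utility_scale": 0.9}),
        ScenarioSpec("event_adjustment_2.0", {"event_adjustment": 2.0}),
        ScenarioSpec("event_adjustment_0.6", {"event_adjustment": 0.6}),
        ScenarioSpec("mortality_plus10", {"mortality_scale": 1.1}),
        ScenarioSpec("mortality_minus10", {"mortality_scale": 0.9}),
        ScenarioSpec("horizon_15y", {"horizon_years": 15.0}),
        ScenarioSpec("offmed_6.6_vs_sham", {"delta_osbp": 6.6}),
        ScenarioSpec("pooled_gen12_4.81", {"delta_osbp": 4.81}),
        ScenarioSpec("pooled_gen2_5.73", {"delta_osbp": 5.73}),
    ]
}


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass
class PSASpec:
    """PSA settings: draw count, seed, demographic handling."""

    n_draws: int = 10_000
    seed: int = 0
    sample_demographics: bool = True
    threshold_grid: tuple[float, ...] = DEFAULT_THRESHOLD_GRID

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ConfigurationError("n_draws must be >= 1")


@dataclass
class PSAResult:
    delta_cost: np.ndarray
    delta_qalys: np.ndarray
    seed: int
    thresholds: np.ndarray
    ceac_curve: np.ndarray

    @property
    def n_draws(self) -> int:
        return self.delta_cost.shape[0]

    @property
    def icer_ratio_of_means(self) -> float:
        return float(self.delta_cost.mean() / self.delta_qalys.mean())

    @property
    def per_draw_icers(self) -> np.ndarray:
        """ICERs for draws in the dQ > 0 quadrant."""
        mask = self.delta_qalys > 0
        return self.delta_cost[mask] / self.delta_qalys[mask]

    @property
    def icer_mean_of_ratios(self) -> float:
        return float(self.per_draw_icers.mean())

    @property
    def quadrant_counts(self) -> dict[str, int]:
        dq, dc = self.delta_qalys, self.delta_cost
        return {
            "more_effective_more_costly": int(np.sum((dq > 0) & (dc > 0))),
            "dominant": int(np.sum((dq > 0) & (dc <= 0))),
            "dominated": int(np.sum((dq <= 0) & (dc >= 0))),
            "less_effective_less_costly": int(np.sum((dq <= 0) & (dc < 0))),
        }

    def credibility_interval(self, level: float = 0.95) -> tuple[float, float]:
        tail = 100.0 * (1.0 - level) / 2.0
        icers = self.per_draw_icers
        return (
            float(np.percentile(icers, tail)),
            float(np.percentile(icers, 100.0 - tail)),
        )

    def prob_below_threshold(self, threshold: float) -> float:
        nmb = threshold * self.delta_qalys - self.delta_cost
        return float(np.mean(nmb > 0))

    def scatter_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"delta_cost": self.delta_cost, "delta_qalys": self.delta_qalys}
        )

    def ceac_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "prob_cost_effective": self.ceac_curve}
        )


def _moment_matched_draws(
    p: ParamDist, n: int, rng: np.random.Generator
) -> np.ndarray:
    if p.se == 0:
        return np.full(n, p.mean)
    if p.family == "Normal":
        x = rng.normal(p.mean, p.se, size=n)
    elif p.family == "Gamma":
        shape = p.mean ** 2 / p.se ** 2
        scale = p.se ** 2 / p.mean
        x = rng.gamma(shape, scale, size=n)
    else:  # Beta
        m = p.mean
        nu = m * (1.0 - m) / p.se ** 2 - 1.0
        if nu <= 0:
            raise ConfigurationError(
                f"Beta moment matching infeasible for {p.name!r}: "
                f"SE {p.se} too large for mean {p.mean}"
            )
        x = rng.beta(m * nu, (1.0 - m) * nu, size=n)
    lo = p.lower if p.lower is not None else -np.inf
    hi = p.upper if p.upper is not None else np.inf
    return np.clip(x, lo, hi)


def run_psa(config: ModelConfig, spec: PSASpec) -> PSAResult:
    """Second-order Monte Carlo over the config's parameter table."""
    rng = np.random.default_rng(spec.seed)
    params = [
        p for p in config.psa_params
        if spec.sample_demographics or not p.demographic
    ]
    draws = {p.name: _moment_matched_draws(p, spec.n_draws, rng) for p in params}
    dc = np.empty(spec.n_draws)
    dq = np.empty(spec.n_draws)
    for k in range(spec.n_draws):
        cfg = config.copy()
        for p in params:
            cfg.set_param(p.path, float(draws[p.name][k]))
        ce = evaluate(cfg).ce
        dc[k] = ce.delta_cost
        dq[k] = ce.delta_qalys
    thresholds = np.asarray(spec.threshold_grid, dtype=float)
    nmb = thresholds[:, None] * dq[None, :] - dc[None, :]
    curve = (nmb > 0).mean(axis=1)
    return PSAResult(
        delta_cost=dc,
        delta_qalys=dq,
        seed=spec.seed,
        thresholds=thresholds,
        ceac_curve=curve,
    )


def ceac(result: PSAResult, thresholds: np.ndarray | list[float]) -> np.ndarray:
    """Probability of cost-effectiveness at each willingness-to-pay."""
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) < 0):
        raise ConfigurationError("thresholds must be sorted ascending")
    nmb = thresholds[:, None] * result.delta_qalys[None, :] - result.delta_cost[None, :]
    return (nmb > 0).mean(axis=1)
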
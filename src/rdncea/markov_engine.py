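"""Monthly-cycle, time-inhomogeneous Markov cohort engine.

The default health-state space has 33 states: hypertension alone; primary
event states for stroke, MI, angina/other CHD (stable and unstable), heart
failure and ESRD with tunnel sub-states encoding time since the event
(acute month, remainder of year one — months 1-6 for MI, year two+);
secondary combined states for the event pairs in the model schematic
(e.g. stroke after MI, HF after ESRD); and two absorbing states
(cardiovascular death, non-cardiovascular death).

Within a cycle, death is evaluated first (background lifetable mortality
plus condition-specific excess, split between CV and non-CV death in
proportion to their hazards); incident events are then allocated among the
survivors; the remainder progresses through tunnel sub-states.  Acute
tunnels last exactly one cycle; longer tunnels (e.g. stroke year one) use a
geometric sojourn whose mean matches the nominal duration.  Acute case
fatality is applied on event entry and counts as CV death; the incident
event is still counted in cumulative incidence.

Repeat events of the same kind are not modelled; deeper event histories map
to the most recent severe state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from rdncea.errors import ConfigurationError, NumericalError
from rdncea import risk_equations as rq
from rdncea import treatment_effect as te

ENDPOINTS = rq.ENDPOINTS
ARMS = ("control", "treated")

_ROW_TOL = 1e-10
_CONS_TOL = 1e-9


# ---------------------------------------------------------------------------
# state space


@dataclass(frozen=True)
class HealthState:
    name: str
    conditions: frozenset[str]
    primary: str | None
    phase_keys: tuple[tuple[str, str], ...]
    tunnel_next: str | None = None
    tunnel_exit_p: float = 0.0
    death: str | None = None  # "cv" | "noncv" | None

    @property
    def is_death(self) -> bool:
        return self.death is not None


@dataclass
class HealthStateSpace:
    """The configured state structure, including event-target topology.

    ``targets`` maps (primary condition or None, endpoint) to a list of
    (target state name, fraction, case-fatality key) entries; fractions for
    one event sum to 1 (the CHD event splits into stable and unstable
    angina presentations).
    """

    states: list[HealthState]
    targets: dict[tuple[str | None, str], list[tuple[str, float, str | None]]]
    unstable_chd_fraction: float = 0.35
    endpoints: tuple[str, ...] = ENDPOINTS

    def __post_init__(self) -> None:
        self.index = {s.name: i for i, s in enumerate(self.states)}
        if len(self.index) != len(self.states):
            raise ConfigurationError("duplicate state names")
        deaths = [s for s in self.states if s.is_death]
        if {s.death for s in deaths} != {"cv", "noncv"}:
            raise ConfigurationError("need exactly one CV and one non-CV death state")
        self.cv_idx = self.index[next(s.name for s in deaths if s.death == "cv")]
        self.ncv_idx = self.index[next(s.name for s in deaths if s.death == "noncv")]
        self.alive_idx = np.array(
            [i for i, s in enumerate(self.states) if not s.is_death], dtype=int
        )
        for (_, _), tgts in self.targets.items():
            for name, frac, _ in tgts:
                if name not in self.index:
                    raise ConfigurationError(f"unknown target state {name!r}")
                if frac <= 0:
                    raise ConfigurationError(f"non-positive target fraction for {name!r}")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def admissible_events(self, state: HealthState) -> list[str]:
        if state.is_death:
            return []
        out = []
        for e in self.endpoints:
            if e in state.conditions:
                continue
            if (state.primary, e) in self.targets:
                out.append(e)
        return out

    # --- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "unstable_chd_fraction": self.unstable_chd_fraction,
            "states": [
                {
                    "name": s.name,
                    "conditions": sorted(s.conditions),
                    "primary": s.primary,
                    "phase_keys": [f"{c}|{p}" for c, p in s.phase_keys],
                    "tunnel_next": s.tunnel_next,
                    "tunnel_exit_p": s.tunnel_exit_p,
                    "death": s.death,
                }
                for s in self.states
            ],
            "targets": {
                f"{src or '-'}>{e}": [[n, f, cf] for n, f, cf in tgts]
                for (src, e), tgts in self.targets.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HealthStateSpace":
        states = [
            HealthState(
                name=s["name"],
                conditions=frozenset(s["conditions"]),
                primary=s["primary"],
                phase_keys=tuple(tuple(k.split("|")) for k in s["phase_keys"]),
                tunnel_next=s["tunnel_next"],
                tunnel_exit_p=s["tunnel_exit_p"],
                death=s["death"],
            )
            for s in d["states"]
        ]
        targets = {}
        for key, tgts in d["targets"].items():
            src, e = key.split(">")
            targets[(None if src == "-" else src, e)] = [
                (n, float(f), cf) for n, f, cf in tgts
            ]
        return cls(
            states=states,
            targets=targets,
            unstable_chd_fraction=d["unstable_chd_fraction"],
        )


def default_space(unstable_chd_fraction: float = 0.35) -> HealthStateSpace:
    """Build the 33-state base-case structure."""
    u = unstable_chd_fraction
    S = HealthState
    f = frozenset
    states = [
        S("htn", f(), None, ()),
        # stroke alone
        S("stroke_acute", f({"stroke"}), "stroke", (("stroke", "y1"),),
          "stroke_y1", 1.0),
        S("stroke_y1", f({"stroke"}), "stroke", (("stroke", "y1"),),
          "stroke_post", 1.0 / 11.0),
        S("stroke_post", f({"stroke"}), "stroke", (("stroke", "chronic"),)),
        # MI alone (utility changes at month 6)
        S("mi_acute", f({"mi"}), "mi", (("mi", "early"),), "mi_m2_6", 1.0),
        S("mi_m2_6", f({"mi"}), "mi", (("mi", "early"),), "mi_post", 1.0 / 5.0),
        S("mi_post", f({"mi"}), "mi", (("mi", "late"),)),
        # angina / other CHD
        S("sap", f({"chd"}), "chd", (("chd", "stable"),)),
        S("uap_acute", f({"chd"}), "chd", (("chd", "unstable"),), "uap_post", 1.0),
        S("uap_post", f({"chd"}), "chd", (("chd", "unstable"),)),
        # heart failure
        S("hf_acute", f({"hf"}), "hf", (("hf", "any"),), "hf_post", 1.0),
        S("hf_post", f({"hf"}), "hf", (("hf", "any"),)),
        # ESRD
        S("esrd", f({"esrd"}), "esrd", (("esrd", "any"),)),
        # combined: stroke after MI
        S("stroke_post_mi_acute", f({"stroke", "mi"}), "stroke",
          (("stroke", "y1"), ("mi", "late")), "stroke_post_mi", 1.0),
        S("stroke_post_mi", f({"stroke", "mi"}), "stroke",
          (("stroke", "chronic"), ("mi", "late"))),
        # MI after stroke
        S("mi_post_stroke_acute", f({"stroke", "mi"}), "mi",
          (("mi", "early"), ("stroke", "chronic")), "mi_post_stroke", 1.0),
        S("mi_post_stroke", f({"stroke", "mi"}), "mi",
          (("mi", "late"), ("stroke", "chronic"))),
        # HF after stroke / MI / angina / ESRD
        S("hf_post_stroke_acute", f({"hf", "stroke"}), "hf",
          (("hf", "any"), ("stroke", "chronic")), "hf_post_stroke", 1.0),
        S("hf_post_stroke", f({"hf", "stroke"}), "hf",
          (("hf", "any"), ("stroke", "chronic"))),
        S("hf_post_mi_acute", f({"hf", "mi"}), "hf",
          (("hf", "any"), ("mi", "late")), "hf_post_mi", 1.0),
        S("hf_post_mi", f({"hf", "mi"}), "hf",
          (("hf", "any"), ("mi", "late"))),
        S("hf_post_chd_acute", f({"hf", "chd"}), "hf",
          (("hf", "any"), ("chd", "stable")), "hf_post_chd", 1.0),
        S("hf_post_chd", f({"hf", "chd"}), "hf",
          (("hf", "any"), ("chd", "stable"))),
        S("hf_post_esrd_acute", f({"hf", "esrd"}), "hf",
          (("hf", "any"), ("esrd", "any")), "hf_post_esrd", 1.0),
        S("hf_post_esrd", f({"hf", "esrd"}), "hf",
          (("hf", "any"), ("esrd", "any"))),
        # stroke / MI after HF
        S("stroke_post_hf_acute", f({"stroke", "hf"}), "stroke",
          (("stroke", "y1"), ("hf", "any")), "stroke_post_hf", 1.0),
        S("stroke_post_hf", f({"stroke", "hf"}), "stroke",
          (("stroke", "chronic"), ("hf", "any"))),
        S("mi_post_hf_acute", f({"mi", "hf"}), "mi",
          (("mi", "early"), ("hf", "any")), "mi_post_hf", 1.0),
        S("mi_post_hf", f({"mi", "hf"}), "mi",
          (("mi", "late"), ("hf", "any"))),
        # late-entry combined singles
        S("esrd_post_event", f({"esrd", "chd"}), "esrd",
          (("esrd", "any"), ("chd", "stable"))),
        S("chd_post_event", f({"chd", "mi"}), "chd",
          (("chd", "stable"), ("mi", "late"))),
        # absorbing
        S("cv_death", f(), None, (), death="cv"),
        S("noncv_death", f(), None, (), death="noncv"),
    ]
    chd_split = [("sap", 1.0 - u, None), ("uap_acute", u, "chd")]
    targets = {
        (None, "stroke"): [("stroke_acute", 1.0, "stroke")],
        (None, "mi"): [("mi_acute", 1.0, "mi")],
        (None, "chd"): chd_split,
        (None, "hf"): [("hf_acute", 1.0, "hf")],
        (None, "esrd"): [("esrd", 1.0, None)],
        ("stroke", "mi"): [("mi_post_stroke_acute", 1.0, "mi")],
        ("stroke", "hf"): [("hf_post_stroke_acute", 1.0, "hf")],
        ("stroke", "esrd"): [("esrd_post_event", 1.0, None)],
        ("stroke", "chd"): [("chd_post_event", 1.0, None)],
        ("mi", "stroke"): [("stroke_post_mi_acute", 1.0, "stroke")],
        ("mi", "hf"): [("hf_post_mi_acute", 1.0, "hf")],
        ("mi", "esrd"): [("esrd_post_event", 1.0, None)],
        ("mi", "chd"): [("chd_post_event", 1.0, None)],
        ("chd", "stroke"): [("stroke_acute", 1.0, "stroke")],
        ("chd", "mi"): [("mi_acute", 1.0, "mi")],
        ("chd", "hf"): [("hf_post_chd_acute", 1.0, "hf")],
        ("chd", "esrd"): [("esrd_post_event", 1.0, None)],
        ("hf", "stroke"): [("stroke_post_hf_acute", 1.0, "stroke")],
        ("hf", "mi"): [("mi_post_hf_acute", 1.0, "mi")],
        ("hf", "esrd"): [("esrd_post_event", 1.0, None)],
        ("hf", "chd"): [("chd_post_event", 1.0, None)],
        ("esrd", "stroke"): [("stroke_acute", 1.0, "stroke")],
        ("esrd", "mi"): [("mi_acute", 1.0, "mi")],
        ("esrd", "hf"): [("hf_post_esrd_acute", 1.0, "hf")],
        ("esrd", "chd"): chd_split,
    }
    return HealthStateSpace(
        states=states, targets=targets, unstable_chd_fraction=u
    )


# ---------------------------------------------------------------------------
# mortality


@dataclass
class MortalitySpec:
    """Background lifetable plus condition-specific excess CV mortality.

    ``lifetable`` has columns age, sex, qx (annual all-cause mortality
    probability); it supplies the background (non-CV-attributed) hazard in
    every alive state.  ``excess`` maps (condition, phase) keys to annual
    excess mortality probabilities at the reference age
    (``excess_ref_age``), attributed to CV death; post-event mortality is
    age-dependent, so the excess hazard scales by
    ``exp(excess_age_slope * (age - excess_ref_age))``.  Hazards add across
    the conditions of combined states.  ``case_fatality`` maps event keys to
    the probability that an incident event is immediately fatal (CV death
    at entry).
    """

    lifetable: pd.DataFrame
    excess: dict[tuple[str, str], float] = field(default_factory=dict)
    case_fatality: dict[str, float] = field(default_factory=dict)
    scale: float = 1.0
    excess_age_slope: float = 0.0
    excess_ref_age: float = 65.0

    def __post_init__(self) -> None:
        req = {"age", "sex", "qx"}
        if not req.issubset(self.lifetable.columns):
            raise ConfigurationError(f"lifetable needs columns {sorted(req)}")
        q = self.lifetable["qx"].to_numpy()
        if np.any(q < 0) or np.any(q > 1):
            raise ConfigurationError("lifetable qx outside [0, 1]")
        for k, v in self.excess.items():
            if not (0.0 <= v < 1.0):
                raise ConfigurationError(f"excess mortality {k} = {v} outside [0, 1)")
        for k, v in self.case_fatality.items():
            if not (0.0 <= v < 1.0):
                raise ConfigurationError(f"case fatality {k} = {v} outside [0, 1)")

    def monthly_background_hazard(self, sex: str, ages: np.ndarray) -> np.ndarray:
        sub = self.lifetable[self.lifetable["sex"] == sex]
        if sub.empty:
            raise ConfigurationError(f"lifetable has no rows for sex {sex!r}")
        sub = sub.sort_values("age")
        if np.max(ages) > sub["age"].max() + 1 or np.min(ages) < sub["age"].min():
            raise ConfigurationError("cohort age outside lifetable range")
        h_annual = -np.log1p(-sub["qx"].to_numpy())
        h = np.interp(ages, sub["age"].to_numpy(), h_annual)
        return self.scale * h / 12.0

    def monthly_excess_hazard(self, state: HealthState) -> float:
        """Summed monthly excess hazard at the reference age."""
        h = 0.0
        for key in state.phase_keys:
            q = self.excess.get(key, 0.0)
            h += -np.log1p(-q) / 12.0
        return h

    def excess_age_factor(self, ages: np.ndarray) -> np.ndarray:
        return np.exp(self.excess_age_slope * (np.asarray(ages, float) - self.excess_ref_age))


# ---------------------------------------------------------------------------
# transition matrices


def _effective_event_probs(
    q_base: np.ndarray,
    space: HealthStateSpace,
    effect: te.TreatmentEffect | None,
) -> np.ndarray:
    """Per-cycle event probabilities, treated-arm RRs applied if requested."""
    if effect is None:
        return q_base
    q = np.empty_like(q_base)
    for j, e in enumerate(space.endpoints):
        if e in effect.anchors:
            rr = te.rr_for_endpoint(effect, e)
            q[:, j] = te.apply_effect(q_base[:, j], rr, effect.hazard_scale)
        else:
            q[:, j] = q_base[:, j]
    return q


def _build_stack(
    space: HealthStateSpace,
    hb: np.ndarray,
    q_events: np.ndarray,
    mortality: MortalitySpec,
    excess_factor: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Build transition matrices for all cycles at once.

    Returns ``T`` of shape (C, S, S) and the incident-event flow array ``Q``
    of shape (S, E, C): ``Q[i, e, c]`` is the probability that a cohort
    member in state i at the start of cycle c has an incident event e during
    the cycle (fatal entries included).
    """
    C = hb.shape[0]
    S = space.n_states
    E = len(space.endpoints)
    # cycle-last layout for contiguous writes; reordered to (C, S, S) at the end
    T = np.zeros((S, S, C))
    Q = np.zeros((S, E, C))
    cv, ncv = space.cv_idx, space.ncv_idx
    eidx = {e: j for j, e in enumerate(space.endpoints)}

    if excess_factor is None:
        excess_factor = np.ones(C)
    hazard_positive = np.any(hb > 0)
    for i, st in enumerate(space.states):
        if st.is_death:
            T[i, i] = 1.0
            continue
        hx0 = mortality.monthly_excess_hazard(st)
        hx = hx0 * excess_factor
        H = hb + hx
        p_die = -np.expm1(-H)
        if hazard_positive or hx0 > 0:
            with np.errstate(invalid="ignore", divide="ignore"):
                frac_cv = np.where(H > 0, hx / np.where(H > 0, H, 1.0), 0.0)
        else:
            frac_cv = 0.0
        T[i, cv] += p_die * frac_cv
        T[i, ncv] += p_die * (1.0 - frac_cv)
        surv = 1.0 - p_die

        events = space.admissible_events(st)
        total_q = np.zeros(C)
        for e in events:
            q = q_events[:, eidx[e]]
            flow = surv * q
            Q[i, eidx[e]] = flow
            total_q += q
            for tgt_name, fracn, cf_key in space.targets[(st.primary, e)]:
                j = space.index[tgt_name]
                cf = mortality.case_fatality.get(cf_key, 0.0) if cf_key else 0.0
                T[i, j] += flow * (fracn * (1.0 - cf))
                if cf:
                    T[i, cv] += flow * (fracn * cf)
        one_minus_q = 1.0 - total_q
        if np.any(one_minus_q < 0):
            c_bad = int(np.argmax(total_q > 1.0))
            raise NumericalError(
                f"competing event probabilities exceed 1 in state {st.name!r} "
                f"at cycle {c_bad} (sum = {total_q.max():.4f})"
            )
        resid = surv * one_minus_q
        if st.tunnel_next is not None:
            j = space.index[st.tunnel_next]
            T[i, j] += resid * st.tunnel_exit_p
            T[i, i] += resid * (1.0 - st.tunnel_exit_p)
        else:
            T[i, i] += resid

    rowsum = T.sum(axis=1)  # (S, C)
    dev = np.abs(rowsum - 1.0)
    if dev.max() > _ROW_TOL:
        i, c = np.unravel_index(int(np.argmax(dev)), dev.shape)
        raise NumericalError(
            f"non-stochastic transition row: state {space.states[i].name!r} at "
            f"cycle {c}, row sum {rowsum[i, c]!r}; row = {T[:, :, c][i]!r}"
        )
    T = np.ascontiguousarray(np.moveaxis(T, 2, 0))
    return T, Q


def _cycle_inputs(config, profile: rq.CohortProfile, n_cycles: int):
    """Ages, background hazards and baseline event probabilities per cycle."""
    ages = profile.age + np.arange(n_cycles) / 12.0
    sex = "female" if profile.female_fraction >= 0.5 else "male"
    hb = config.mortality.monthly_background_hazard(sex, ages)
    E = len(config.space.endpoints)
    q_base = np.zeros((n_cycles, E))
    for j, e in enumerate(config.space.endpoints):
        spec = config.equations.get(e)
        if spec is None:
            continue  # endpoint disabled (zero risk)
        p_nat = rq.native_risk(spec, profile, ages=ages)
        q = rq.to_cycle_probability(p_nat, spec.native_horizon, 1.0)
        q_base[:, j] = rq.calibrate(q, config.calibration.ratio(e))
    return ages, hb, q_base


def build_transition_matrix(
    space: HealthStateSpace,
    profile: rq.CohortProfile,
    effect: te.TreatmentEffect,
    calibration: rq.CalibrationSet,
    mortality: MortalitySpec,
    equations: Mapping[str, rq.RiskEquationSpec],
    cycle_index: int = 0,
    arm: str = "control",
) -> np.ndarray:
    """One cycle's transition matrix (row-stochastic, S x S)."""
    if arm not in ARMS:
        raise ConfigurationError(f"arm must be one of {ARMS}")

    class _Cfg:  # minimal view for _cycle_inputs
        pass

    cfg = _Cfg()
    cfg.space, cfg.mortality, cfg.calibration, cfg.equations = (
        space, mortality, calibration, dict(equations),
    )
    age = profile.age + cycle_index / 12.0
    prof = rq.CohortProfile(**{**profile.__dict__, "age": age})
    _, hb, q_base = _cycle_inputs(cfg, prof, 1)
    q_eff = _effective_event_probs(q_base, space, effect if arm == "treated" else None)
    T, _ = _build_stack(
        space, hb, q_eff, mortality,
        excess_factor=mortality.excess_age_factor(np.array([age])),
    )
    return T[0]


# ---------------------------------------------------------------------------
# cohort propagation


@dataclass
class CycleTrace:
    """State occupancy and incident-event flows over a cohort run."""

    occupancy: np.ndarray          # (C+1, S) cohort fractions
    events: np.ndarray             # (C, E) incident events per cycle
    ages: np.ndarray               # (C+1,) attained age at cycle start
    space: HealthStateSpace
    arm: str
    sex: str

    @property
    def n_cycles(self) -> int:
        return self.events.shape[0]

    def dead_fraction(self, kind: str | None = None) -> np.ndarray:
        if kind == "cv":
            return self.occupancy[:, self.space.cv_idx]
        if kind == "noncv":
            return self.occupancy[:, self.space.ncv_idx]
        return (self.occupancy[:, self.space.cv_idx]
                + self.occupancy[:, self.space.ncv_idx])

    def alive_fraction(self) -> np.ndarray:
        return 1.0 - self.dead_fraction()

    def to_frame(self) -> pd.DataFrame:
        """Tidy (cycle, state, occupancy) export."""
        C1, S = self.occupancy.shape
        return pd.DataFrame({
            "cycle": np.repeat(np.arange(C1), S),
            "state": [s.name for s in self.space.states] * C1,
            "occupancy": self.occupancy.ravel(),
        })


def _propagate(T: np.ndarray, Q: np.ndarray, start: np.ndarray):
    C = T.shape[0]
    S = T.shape[1]
    occ = np.empty((C + 1, S))
    occ[0] = start
    x = start
    for c in range(C):
        x = x @ T[c]
        occ[c + 1] = x
    s = occ.sum(axis=1)
    dev = np.abs(s - 1.0)
    if dev.max() > _CONS_TOL * max(1, C // 1000 + 1):
        c = int(np.argmax(dev))
        raise NumericalError(f"occupancy not conserved at cycle {c}: sum {s[c]!r}")
    events = np.einsum("cs,sec->ce", occ[:-1], Q)
    return occ, events


def run_cohort(
    config,
    arm: str = "control",
    sex: str | None = None,
    horizon_cycles: int | None = None,
    start_occupancy: np.ndarray | None = None,
) -> CycleTrace:
    """Run one arm of the cohort model for one sex stratum.

    ``sex`` of None uses the profile's own (possibly fractional) sex mix in
    the risk equations and the majority sex's lifetable; production runs go
    through :func:`run_model`, which stratifies by sex and mixes.
    """
    if arm not in ARMS:
        raise ConfigurationError(f"arm must be one of {ARMS}")
    profile = config.cohort
    if sex == "male":
        profile = rq.CohortProfile(**{**profile.__dict__, "female_fraction": 0.0})
    elif sex == "female":
        profile = rq.CohortProfile(**{**profile.__dict__, "female_fraction": 1.0})
    elif sex is not None:
        raise ConfigurationError(f"unknown sex {sex!r}")

    n_default = int(round((config.horizon_age - profile.age) * 12))
    C = n_default if horizon_cycles is None else int(horizon_cycles)
    if C < 0:
        raise ConfigurationError("horizon_cycles must be >= 0")
    _, hb, q_base = _cycle_inputs(config, profile, C)
    label = sex or ("female" if profile.female_fraction >= 0.5 else "male")
    return _run_from_inputs(
        config, profile, arm, hb, q_base, C, start_occupancy, label
    )


def _run_from_inputs(
    config, profile, arm, hb, q_base, C, start_occupancy, sex_label
) -> CycleTrace:
    q_eff = _effective_event_probs(
        q_base, config.space, config.effect if arm == "treated" else None
    )
    cycle_ages = profile.age + np.arange(C) / 12.0
    T, Q = _build_stack(
        config.space, hb, q_eff, config.mortality,
        excess_factor=config.mortality.excess_age_factor(cycle_ages),
    )

    S = config.space.n_states
    if start_occupancy is None:
        start = np.zeros(S)
        start[config.space.index["htn"]] = 1.0
    else:
        start = np.asarray(start_occupancy, dtype=float)
        if start.shape != (S,) or abs(start.sum() - 1.0) > 1e-9:
            raise ConfigurationError("start_occupancy must sum to 1 over all states")
    occ, events = _propagate(T, Q, start)
    ages = profile.age + np.arange(C + 1) / 12.0
    return CycleTrace(occ, events, ages, config.space, arm, sex_label)


@dataclass
class ModelRun:
    """Both arms, both sex strata, plus the mixing weights."""

    traces: dict[tuple[str, str], CycleTrace]
    weights: dict[str, float]

    @property
    def sexes(self) -> list[str]:
        return list(self.weights)

    def trace(self, arm: str, sex: str) -> CycleTrace:
        return self.traces[(arm, sex)]

    def cumulative_incidence(
        self, arm: str, endpoint: str, horizon_cycles: int | None = None
    ) -> float:
        return sum(
            self.weights[sex]
            * cumulative_incidence(self.traces[(arm, sex)], endpoint, horizon_cycles)
            for sex in self.weights
        )

    def death_incidence(
        self, arm: str, kind: str | None, horizon_cycles: int | None = None
    ) -> float:
        """Cumulative death (%) by the horizon; ``kind`` 'cv', 'noncv' or None."""
        out = 0.0
        for sex, w in self.weights.items():
            tr = self.traces[(arm, sex)]
            h = tr.n_cycles if horizon_cycles is None else int(horizon_cycles)
            out += w * 100.0 * tr.dead_fraction(kind)[h]
        return out

    def event_rr(self, endpoint: str, horizon_cycles: int | None = None) -> float:
        ctrl = self.cumulative_incidence("control", endpoint, horizon_cycles)
        trt = self.cumulative_incidence("treated", endpoint, horizon_cycles)
        if ctrl == 0.0:
            raise ZeroDivisionError(
                f"control-arm incidence for {endpoint!r} is zero; RR undefined"
            )
        return trt / ctrl


def run_model(config, horizon_cycles: int | None = None) -> ModelRun:
    """Run both arms, stratified by sex and mixed by the cohort's sex split."""
    strata = rq.sex_stratified(config.cohort)
    traces: dict[tuple[str, str], CycleTrace] = {}
    weights: dict[str, float] = {}
    for sex, w, prof in strata:
        weights[sex] = w
        n_default = int(round((config.horizon_age - prof.age) * 12))
        C = n_default if horizon_cycles is None else int(horizon_cycles)
        _, hb, q_base = _cycle_inputs(config, prof, C)
        for arm in ARMS:
            traces[(arm, sex)] = _run_from_inputs(
                config, prof, arm, hb, q_base, C, None, sex
            )
    return ModelRun(traces=traces, weights=weights)


# ---------------------------------------------------------------------------
# summaries


def cumulative_incidence(
    trace: CycleTrace, endpoint: str, horizon_cycles: int | None = None
) -> float:
    """First-event cumulative incidence (% of starting cohort)."""
    if endpoint not in trace.space.endpoints:
        raise ConfigurationError(f"endpoint {endpoint!r} not tracked")
    h = trace.n_cycles if horizon_cycles is None else int(horizon_cycles)
    if h > trace.n_cycles:
        raise ConfigurationError(
            f"horizon {h} beyond trace length {trace.n_cycles}"
        )
    j = trace.space.endpoints.index(endpoint)
    return 100.0 * float(trace.events[:h, j].sum())


def event_rr(
    trace_treated: CycleTrace,
    trace_control: CycleTrace,
    endpoint: str,
    horizon_cycles: int | None = None,
) -> float:
    """Ratio of cumulative incidences, treated vs. control."""
    ctrl = cumulative_incidence(trace_control, endpoint, horizon_cycles)
    trt = cumulative_incidence(trace_treated, endpoint, horizon_cycles)
    if ctrl == 0.0:
        raise ZeroDivisionError(
            f"control-arm incidence for {endpoint!r} is zero; RR undefined"
        )
    return trt / ctrl
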
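"""Markov engine: structure, transition building, propagation, incidence."""

import numpy as np
import pytest

from rdncea.errors import ConfigurationError
from rdncea.markov_engine import (
    build_transition_matrix,
    cumulative_incidence,
    default_space,
    event_rr,
    run_cohort,
    run_model,
)
from conftest import toy_config
from oracles import microsimulate


class TestStateSpace:
    def test_default_space_has_33_states(self):
        space = default_space()
        assert space.n_states == 33

    def test_exactly_one_absorbing_partition(self):
        space = default_space()
        deaths = [s for s in space.states if s.is_death]
        assert sorted(s.death for s in deaths) == ["cv", "noncv"]

    def test_every_alive_state_reaches_death(self, base_config):
        """Graph check: death is reachable from every non-absorbing state."""
        space = base_config.space
        T = build_transition_matrix(
            space, base_config.cohort, base_config.effect, base_config.calibration,
            base_config.mortality, base_config.equations, cycle_index=0,
        )
        # reachability via powers of the adjacency structure
        reach = (T > 0).astype(int)
        for _ in range(space.n_states):
            reach = np.clip(reach + reach @ reach, 0, 1)
        death_cols = [space.cv_idx, space.ncv_idx]
        for i, st in enumerate(space.states):
            if not st.is_death:
                assert reach[i, death_cols].sum() > 0, st.name

    def test_no_repeat_events(self):
        """A state's own condition is never an admissible incident event."""
        space = default_space()
        for st in space.states:
            for e in space.admissible_events(st):
                assert e not in st.conditions

    def test_serialization_round_trip(self):
        space = default_space(unstable_chd_fraction=0.4)
        rebuilt = type(space).from_dict(space.to_dict())
        assert [s.name for s in rebuilt.states] == [s.name for s in space.states]
        assert rebuilt.targets == space.targets
        assert rebuilt.unstable_chd_fraction == pytest.approx(0.4)


class TestTransitionMatrix:
    def test_row_stochastic_and_nonnegative(self, base_config):
        for cycle in (0, 120, 600):
            for arm in ("control", "treated"):
                T = build_transition_matrix(
                    base_config.space, base_config.cohort, base_config.effect,
                    base_config.calibration, base_config.mortality,
                    base_config.equations, cycle_index=cycle, arm=arm,
                )
                assert np.all(T >= 0)
                np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-10)

    def test_zero_risk_zero_mortality_is_identity(self):
        cfg = toy_config(q_event_annual=1e-300, q_death_annual=0.0)
        T = build_transition_matrix(
            cfg.space, cfg.cohort, cfg.effect, cfg.calibration,
            cfg.mortality, cfg.equations,
        )
        np.testing.assert_allclose(T, np.eye(cfg.space.n_states), atol=1e-12)

    def test_treated_event_entries_dominated_by_control(self, base_config):
        """With all RRs <= 1 the treated arm never has larger event entries."""
        space = base_config.space
        Tc = build_transition_matrix(
            space, base_config.cohort, base_config.effect, base_config.calibration,
            base_config.mortality, base_config.equations, arm="control",
        )
        Tt = build_transition_matrix(
            space, base_config.cohort, base_config.effect, base_config.calibration,
            base_config.mortality, base_config.equations, arm="treated",
        )
        i = space.index["htn"]
        entry_cols = [space.index[n] for n in
                      ("stroke_acute", "mi_acute", "sap", "uap_acute",
                       "hf_acute", "esrd")]
        assert np.all(Tt[i, entry_cols] <= Tc[i, entry_cols] + 1e-15)

    def test_three_state_toy_matches_hand_calculation(self):
        """well->sick->dead with printed rates: two hand-multiplied cycles."""
        h_event = 0.06   # annual event hazard
        q_death = 0.02   # annual background mortality
        cfg = toy_config(q_event_annual=h_event, q_death_annual=q_death)
        tr = run_cohort(cfg, arm="control", sex="male", horizon_cycles=2)
        q_e = 1.0 - np.exp(-h_event / 12.0)
        q_d = 1.0 - np.exp(np.log(1.0 - q_death) / 12.0)
        # hand-multiplied occupancy: death first, events among survivors
        well, sick, dead = 1.0, 0.0, 0.0
        for _ in range(2):
            new_dead = dead + (well + sick) * q_d
            new_sick = sick * (1 - q_d) + well * (1 - q_d) * q_e
            new_well = well * (1 - q_d) * (1 - q_e)
            well, sick, dead = new_well, new_sick, new_dead
        i_well = cfg.space.index["htn"]
        i_sick = cfg.space.index["hf_post"]
        assert tr.occupancy[2, i_well] == pytest.approx(well, abs=1e-12)
        assert tr.occupancy[2, i_sick] == pytest.approx(sick, abs=1e-12)
        assert tr.dead_fraction()[2] == pytest.approx(dead, abs=1e-12)


class TestRunCohort:
    def test_identical_arms_give_bitwise_equal_traces(self, base_config):
        cfg = base_config.copy()
        cfg.effect.anchors = {e: (1.0, 10.0) for e in cfg.space.endpoints}
        run = run_model(cfg)
        for sex in run.weights:
            np.testing.assert_array_equal(
                run.trace("control", sex).occupancy,
                run.trace("treated", sex).occupancy,
            )

    def test_conservation_over_long_horizon(self, base_config):
        tr = run_cohort(base_config, arm="control", sex="male")
        assert tr.n_cycles == 660
        np.testing.assert_allclose(tr.occupancy.sum(axis=1), 1.0, atol=1e-9)

    def test_death_occupancy_monotone(self, base_config):
        tr = run_cohort(base_config, arm="treated", sex="female")
        assert np.all(np.diff(tr.dead_fraction()) >= -1e-15)

    def test_terminal_absorption_at_age_110(self, base_config):
        for sex in ("male", "female"):
            tr = run_cohort(base_config, arm="control", sex=sex)
            assert tr.dead_fraction()[-1] >= 0.999

    def test_lifetable_only_mortality_matches_survival_product(self):
        """120 cycles of pure background mortality equal the closed form."""
        q_annual = 0.03
        cfg = toy_config(q_event_annual=1e-300, q_death_annual=q_annual)
        tr = run_cohort(cfg, arm="control", sex="male", horizon_cycles=120)
        expected_dead = 1.0 - (1.0 - q_annual) ** 10
        assert tr.dead_fraction()[120] == pytest.approx(expected_dead, abs=1e-9)

    def test_bad_start_occupancy_rejected(self, base_config):
        start = np.zeros(base_config.space.n_states)
        start[0] = 0.5
        with pytest.raises(ConfigurationError):
            run_cohort(base_config, start_occupancy=start)


class TestCumulativeIncidence:
    def test_zero_horizon_is_zero(self, base_config):
        tr = run_cohort(base_config, arm="control", sex="male")
        assert cumulative_incidence(tr, "stroke", 0) == 0.0

    def test_geometric_closed_form_without_competing_risks(self):
        """Constant monthly event probability q gives 1-(1-q)^n."""
        h = 0.06
        cfg = toy_config(q_event_annual=h, q_death_annual=0.0)
        tr = run_cohort(cfg, arm="control", sex="male", horizon_cycles=24)
        q_m = 1.0 - np.exp(-h / 12.0)
        expected = 100.0 * (1.0 - (1.0 - q_m) ** 24)
        assert cumulative_incidence(tr, "hf", 24) == pytest.approx(expected, abs=1e-9)

    def test_non_decreasing_in_horizon(self, base_config):
        tr = run_cohort(base_config, arm="control", sex="male")
        incs = [cumulative_incidence(tr, "mi", h) for h in (12, 60, 120, 360, 660)]
        assert np.all(np.diff(incs) >= 0)

    def test_horizon_beyond_trace_rejected(self, base_config):
        tr = run_cohort(base_config, arm="control", sex="male", horizon_cycles=12)
        with pytest.raises(ConfigurationError):
            cumulative_incidence(tr, "stroke", 13)

    def test_unknown_endpoint_rejected(self, base_config):
        tr = run_cohort(base_config, arm="control", sex="male", horizon_cycles=1)
        with pytest.raises(ConfigurationError):
            cumulative_incidence(tr, "gout", 1)


class TestEventRR:
    def test_null_effect_gives_unity(self):
        cfg = toy_config(delta_osbp=0.0)
        t = run_cohort(cfg, arm="treated", sex="male", horizon_cycles=120)
        c = run_cohort(cfg, arm="control", sex="male", horizon_cycles=120)
        assert event_rr(t, c, "hf", 120) == pytest.approx(1.0, abs=1e-12)

    def test_zero_control_incidence_flagged(self):
        cfg = toy_config(q_event_annual=1e-300)
        t = run_cohort(cfg, arm="treated", sex="male", horizon_cycles=12)
        c = run_cohort(cfg, arm="control", sex="male", horizon_cycles=12)
        with pytest.raises(ZeroDivisionError):
            event_rr(t, c, "hf", 12)

    def test_ten_year_rr_close_to_per_cycle_hazard_ratio(self):
        """At low incidence the cumulative RR approaches the per-cycle RR."""
        cfg = toy_config(q_event_annual=0.005, delta_osbp=4.9, rr10=0.64)
        t = run_cohort(cfg, arm="treated", sex="male", horizon_cycles=120)
        c = run_cohort(cfg, arm="control", sex="male", horizon_cycles=120)
        rr_cycle = 0.64 ** (4.9 / 10.0)
        assert event_rr(t, c, "hf", 120) == pytest.approx(rr_cycle, abs=0.01)


class TestMicrosimulationOracle:
    def test_matrix_trace_matches_individual_simulation(self):
        """Cohort propagation equals microsimulation within 3 MC standard errors."""
        from rdncea.markov_engine import _build_stack, _cycle_inputs

        cfg = toy_config(q_event_annual=0.10, q_death_annual=0.03,
                         case_fatality=0.1, excess_annual=0.08)
        C = 24
        n_sim = 1_000_000
        tr = run_cohort(cfg, arm="control", sex="male", horizon_cycles=C)
        _, hb, q_base = _cycle_inputs(cfg, tr_profile(cfg), C)
        T, _ = _build_stack(cfg.space, hb, q_base, cfg.mortality)
        occ_mc = microsimulate(T, cfg.space.index["htn"], n_sim, seed=7)
        for c in (6, 12, 24):
            for i in range(cfg.space.n_states):
                p = tr.occupancy[c, i]
                se = np.sqrt(max(p * (1 - p), 1e-12) / n_sim)
                assert abs(occ_mc[c, i] - p) <= 3 * se + 1e-9, (c, i)


def tr_profile(cfg):
    from rdncea.risk_equations import CohortProfile
    return CohortProfile(**{**cfg.cohort.__dict__, "female_fraction": 0.0})
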
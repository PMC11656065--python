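"""Risk equations: links, conversions, calibration, covariate handling."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rdncea.errors import ConfigurationError
from rdncea.risk_equations import (
    CalibrationSet,
    CohortProfile,
    RiskEquationSpec,
    calibrate,
    native_risk,
    sex_stratified,
    to_cycle_probability,
)
from rdncea.synthetic_data import make_equations


@pytest.fixture
def profile():
    return CohortProfile(age=55.0, female_fraction=0.199, baseline_osbp=163.0,
                         smoking_fraction=0.15, diabetes_fraction=0.08)


class TestNativeRisk:
    def test_probability_bounds_over_grid(self, profile):
        """All equations return probabilities in [0,1] across an age/SBP grid."""
        for spec in make_equations().values():
            for age in np.linspace(30, 100, 8):
                for sbp in np.linspace(100, 240, 8):
                    p = native_risk(
                        spec,
                        CohortProfile(age=age, baseline_osbp=sbp,
                                      female_fraction=profile.female_fraction),
                    )
                    assert 0.0 <= p <= 1.0

    def test_monotone_in_sbp(self, profile):
        """Raising office SBP by 20 mmHg strictly raises every event risk."""
        for spec in make_equations().values():
            lo = native_risk(spec, profile)
            hi = native_risk(
                spec,
                CohortProfile(**{**profile.__dict__,
                                 "baseline_osbp": profile.baseline_osbp + 20}),
            )
            assert hi > lo

    def test_monotone_in_age(self):
        """Stroke/MI/HF risks rise with age over the whole validity range;
        angina and ESRD onset (which peak in late mid-life) rise up to 60."""
        eqs = make_equations()
        for endpoint, lo, hi in [("stroke", 40.0, None), ("mi", 45.0, None),
                                 ("hf", 40.0, None), ("chd", 40.0, 60.0),
                                 ("esrd", 40.0, 60.0)]:
            spec = eqs[endpoint]
            lo_a, hi_a = spec.age_range
            ages = np.linspace(max(lo_a, lo), hi or hi_a, 10)
            risks = [native_risk(spec, CohortProfile(age=a)) for a in ages]
            assert np.all(np.diff(risks) >= -1e-12), endpoint

    def test_null_coefficients_give_baseline_hazard_only(self):
        """With all covariate slopes zero the risk is the baseline survival term."""
        spec = RiskEquationSpec(endpoint="stroke", intercept=np.log(0.01),
                                coefficients={}, centers={}, native_horizon=10.0)
        p = native_risk(spec, CohortProfile(age=40.0))
        assert p == pytest.approx(1.0 - np.exp(-10 * 0.01), abs=1e-12)

    def test_missing_covariate_raises_named_error(self):
        spec = RiskEquationSpec(endpoint="stroke", intercept=-5.0,
                                coefficients={"serum_unobtainium": 1.0})
        with pytest.raises(ConfigurationError, match="serum_unobtainium"):
            native_risk(spec, CohortProfile())

    def test_age_outside_validity_clamped_with_warning(self, caplog):
        spec = RiskEquationSpec(endpoint="hf", intercept=np.log(0.01),
                                coefficients={"age": 0.1}, centers={"age": 55.0},
                                age_range=(30.0, 74.0))
        import rdncea.risk_equations as rq
        rq._CLAMP_WARNED.clear()
        with caplog.at_level(logging.WARNING, logger="rdncea.risk_equations"):
            p_hi = native_risk(spec, CohortProfile(age=95.0))
        assert "clamping" in caplog.text
        assert p_hi == pytest.approx(native_risk(spec, CohortProfile(age=74.0)))

    def test_fractional_binary_covariates_mix_strata(self):
        """A 50% smoking cohort's risk is the mean of the two indicator strata."""
        spec = RiskEquationSpec(endpoint="mi", intercept=np.log(0.02),
                                coefficients={"smoking": 0.7})
        p_mix = native_risk(spec, CohortProfile(smoking_fraction=0.5))
        p0 = native_risk(spec, CohortProfile(smoking_fraction=0.0))
        p1 = native_risk(spec, CohortProfile(smoking_fraction=1.0))
        assert p_mix == pytest.approx(0.5 * (p0 + p1), rel=1e-12)

    def test_sex_stratification_weights(self, profile):
        strata = sex_stratified(profile)
        assert [s[0] for s in strata] == ["male", "female"]
        assert sum(w for _, w, _ in strata) == pytest.approx(1.0)
        assert dict((s, w) for s, w, _ in strata)["female"] == pytest.approx(0.199)


class TestCycleConversion:
    @pytest.mark.parametrize(
        "p, horizon, months, expected",
        [
            (0.0, 10.0, 1.0, 0.0),
            (0.12, 1.0, 1.0, 1.0 - 0.88 ** (1.0 / 12.0)),  # ~0.010596
            (0.5, 10.0, 12.0, 1.0 - 0.5 ** 0.1),
        ],
    )
    def test_closed_forms(self, p, horizon, months, expected):
        assert to_cycle_probability(p, horizon, months) == pytest.approx(
            expected, abs=1e-12
        )

    def test_absorbing_risk_passes_through(self):
        assert to_cycle_probability(1.0, 10.0, 1.0) == 1.0

    @given(st.floats(min_value=1e-6, max_value=0.999))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_recovers_native_risk(self, p):
        """Compounding the monthly probability over the horizon returns p."""
        monthly = to_cycle_probability(p, 10.0, 1.0)
        recovered = 1.0 - (1.0 - monthly) ** 120
        assert recovered == pytest.approx(p, abs=1e-12)

    def test_out_of_range_input_rejected(self):
        with pytest.raises(ConfigurationError):
            to_cycle_probability(1.2, 10.0)


class TestCalibrate:
    @pytest.mark.parametrize(
        "p, hr, expected",
        [
            (0.037, 1.0, 0.037),
            (0.01, 2.0, 1.0 - 0.99 ** 2),        # 0.0199
            (0.01, 0.6, 1.0 - 0.99 ** 0.6),      # ~0.006012
        ],
    )
    def test_closed_forms(self, p, hr, expected):
        assert calibrate(p, hr) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(min_value=1e-6, max_value=0.99))
    @settings(max_examples=50, deadline=None)
    def test_double_then_halve_is_identity(self, p):
        assert calibrate(calibrate(p, 2.0), 0.5) == pytest.approx(p, abs=1e-12)

    def test_nonpositive_hazard_ratio_rejected(self):
        with pytest.raises(ConfigurationError):
            calibrate(0.01, 0.0)

    def test_calibration_set_scaling(self):
        cs = CalibrationSet(hazard_ratios={"stroke": 1.5})
        scaled = cs.scaled(2.0)
        assert scaled.ratio("stroke") == pytest.approx(3.0)
        assert scaled.ratio("hf") == pytest.approx(2.0)


class TestProfileValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"age": 17.0},
            {"age": 111.0},
            {"baseline_osbp": 80.0},
            {"baseline_osbp": 260.0},
            {"female_fraction": 1.2},
            {"smoking_fraction": -0.1},
        ],
    )
    def test_invariants_enforced(self, kwargs):
        with pytest.raises(ConfigurationError):
            CohortProfile(**kwargs)
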
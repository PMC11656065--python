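"""Calibrate the synthetic risk-equation coefficients of the base fixture.

The shipped fixture's risk equations are stand-ins for the source
publications' coefficient sets.  This script fits, per endpoint, the
log-hazard intercept (to the comparator arm's published 10-year cumulative
incidence) and the age slope (to the published lifetime incidence), with all
endpoints iterated jointly so competing risks are accounted for.  The
resulting coefficients are printed in the exact form of
``rdncea.synthetic_data.CALIBRATED_EQUATIONS`` and are frozen there.

Run from the repository root:  python scripts/calibrate_fixture.py
"""

from __future__ import annotations

import math

import numpy as np

from rdncea.markov_engine import run_cohort, cumulative_incidence
from rdncea.risk_equations import sex_stratified
from rdncea.synthetic_data import make_base_fixture, make_lifetable

# comparator-arm cumulative incidences (%), 10-year and lifetime, plus
# 10-year CV and all-cause death, all from the published base-case table
TARGETS_10Y = {"stroke": 9.0, "mi": 7.5, "chd": 14.5, "hf": 5.0, "esrd": 0.40}
TARGETS_LT = {"stroke": 33.8, "mi": 38.0, "chd": 28.0, "hf": 20.9, "esrd": 1.03}
TARGET_CVD10 = 4.9
TARGET_ACD10 = 11.1

AGE_SQ_STEP = 1 / 700.0   # damped update for the quadratic age term
MORT_STEP = 0.5           # damping for the two mortality scales


def comparator_incidences(config):
    inc10, inclt, acd10, cvd10 = {}, {}, 0.0, 0.0
    for sex, w, _prof in sex_stratified(config.cohort):
        tr = run_cohort(config, arm="control", sex=sex)
        for e in config.space.endpoints:
            inc10[e] = inc10.get(e, 0.0) + w * cumulative_incidence(tr, e, 120)
            inclt[e] = inclt.get(e, 0.0) + w * cumulative_incidence(tr, e, None)
        acd10 += w * 100.0 * tr.dead_fraction()[120]
        cvd10 += w * 100.0 * tr.dead_fraction("cv")[120]
    return inc10, inclt, acd10, cvd10


def main() -> None:
    config = make_base_fixture()
    cv_scale = 1.0
    bg_scale = 1.0
    base_excess = dict(config.mortality.excess)
    base_cf = dict(config.mortality.case_fatality)
    base_params = {s: (p.a, p.b, p.makeham)
                   for s, p in make_lifetable().params.items()}

    for it in range(60):
        inc10, inclt, acd10, cvd10 = comparator_incidences(config)
        err = 0.0
        for e, spec in config.equations.items():
            r10 = TARGETS_10Y[e] / inc10[e]
            ratio_model = inclt[e] / inc10[e]
            ratio_target = TARGETS_LT[e] / TARGETS_10Y[e]
            ra = ratio_target / ratio_model
            spec.intercept += math.log(r10)
            # linear age slope is held at its literature value; the
            # quadratic term absorbs the lifetime/10-year incidence ratio
            spec.coefficients["age_sq"] += AGE_SQ_STEP * math.log(ra)
            err = max(err, abs(math.log(r10)), abs(math.log(ra)))

        # scale case fatality + excess toward the CV-death target, and the
        # background hazard toward the residual all-cause target
        r_cv = TARGET_CVD10 / cvd10
        cv_scale *= r_cv ** MORT_STEP
        bd_model = acd10 - cvd10
        r_bg = (TARGET_ACD10 - TARGET_CVD10) / bd_model
        bg_scale *= r_bg ** MORT_STEP
        err = max(err, abs(math.log(r_cv)), abs(math.log(r_bg)))

        config.mortality.excess = {k: min(0.95, v * cv_scale)
                                   for k, v in base_excess.items()}
        config.mortality.case_fatality = {k: min(0.95, v * cv_scale)
                                          for k, v in base_cf.items()}
        from rdncea.synthetic_data import GompertzMakehamParams
        params = {
            s: GompertzMakehamParams(a=a * bg_scale, b=b, makeham=m * bg_scale)
            for s, (a, b, m) in base_params.items()
        }
        config.mortality.lifetable = make_lifetable(params).table

        print(f"iter {it:2d}  max |log err| = {err:.5f}  "
              f"ACD10 {acd10:.2f}%  CVD10 {cvd10:.2f}%  "
              f"cv_scale {cv_scale:.4f}  bg_scale {bg_scale:.4f}")
        if err < 2e-4:
            break

    inc10, inclt, acd10, cvd10 = comparator_incidences(config)
    print("\nfinal comparator incidences:")
    for e in config.space.endpoints:
        print(f"  {e:7s} 10y {inc10[e]:6.2f}% (target {TARGETS_10Y[e]:5.2f})   "
              f"lifetime {inclt[e]:6.2f}% (target {TARGETS_LT[e]:5.2f})")
    print(f"  ACD 10y {acd10:.2f}%   CVD 10y {cvd10:.2f}%")

    print("\nCALIBRATED_EQUATIONS = {")
    for e, spec in config.equations.items():
        c = spec.coefficients
        print(f'    "{e}": {{')
        print(f'        "intercept": {spec.intercept:.6f},')
        print(f'        "age": {c["age"]:.6f},')
        print(f'        "age_sq": {c["age_sq"]:.7f},')
        for k in ("male", "sbp", "smoking", "diabetes"):
            print(f'        "{k}": {c[k]:.6f},')
        print("    },")
    print("}")
    print(f"\ncv_scale = {cv_scale:.6f}  (apply to EXCESS_MORTALITY & CASE_FATALITY)")
    print("EXCESS_MORTALITY =", {k: round(v, 6)
                                 for k, v in config.mortality.excess.items()})
    print("CASE_FATALITY =", {k: round(v, 6)
                              for k, v in config.mortality.case_fatality.items()})
    print(f"bg_scale = {bg_scale:.6f}  (apply to lifetable a & makeham)")
    lt = make_lifetable()
    for s, p in lt.params.items():
        print(f"  {s}: a={p.a * bg_scale:.6e} b={p.b} makeham={p.makeham * bg_scale:.6e}")


if __name__ == "__main__":
    main()
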
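# rdncea

Lifetime cost-effectiveness modelling of catheter-based radiofrequency renal
denervation (RF RDN) for uncontrolled hypertension, from a UK NHS payer
perspective.

Health economists and HTA analysts use models like this to ask: if a one-off
procedure lowers office systolic blood pressure (oSBP) by a few mmHg, do the
strokes, infarctions, heart-failure admissions and renal failure it prevents
over a patient's remaining lifetime justify its upfront cost? `rdncea`
answers this with a monthly-cycle, 33-state Markov cohort model: baseline
transition probabilities come from multivariate risk equations evaluated at
the cohort's attained age each cycle; the treatment arm's oSBP reduction Δ
maps to endpoint-specific relative risks through a meta-regression,

    RR_e(Δ) = exp( ln(RR_e,10) · Δ / 10 ),

applied as hazard ratios to the monthly event probabilities; costs and
QALYs accrue with half-cycle correction and 3.5% p.a. discounting; and the
incremental cost-effectiveness ratio ICER = ΔC/ΔQ is judged against the NICE
£20 000–30 000 per QALY bands. One-way (tornado), scenario, and
probabilistic sensitivity analysis (10 000-draw second-order Monte Carlo
with a cost-effectiveness acceptability curve) are built in.

All inputs ship as a synthetic, self-contained fixture: a Gompertz–Makeham
lifetable emulating an English national lifetable, and risk equations
calibrated so the comparator arm reproduces published 10-year and lifetime
event incidences for a trial-like cohort (age 55, 19.9% female, oSBP
163 mmHg, 4.9 mmHg effect vs. sham). The fixture's provenance and its
limits are documented in `docs/methods.md`; the calibration is reproducible
via `scripts/calibrate_fixture.py`.

## Worked example

```bash
rdncea fixtures --out fx                       # write the synthetic config
rdncea base --config fx/base_fixture.yaml --out res
```

prints `ICER: 12636 GBP per QALY` and writes `res/base_case.csv`:

```
quantity  soc_10y_pct  rdn_10y_pct   rr_10y
  stroke     9.000011     7.313666 0.812629
      mi     7.500089     6.662307 0.888297
     chd    14.500065    12.910333 0.890364
      hf     4.999999     3.629978 0.725996
    esrd     0.400000     0.385400 0.963501
cv_death     4.900000     4.031136 0.822681

delta_cost        4757.11
delta_qalys          0.376
icer             12636.20
verdict        cost-effective
```

Reading this: over ten years the comparator ("soc", standard of care) cohort
experiences a 9.0% cumulative stroke incidence; the treated cohort 7.3%, a
relative risk of 0.81. Over the lifetime horizon the procedure adds £4 757
of discounted cost (the £6 862 procedure minus ~£2 100 of avoided event
costs) and buys 0.376 discounted QALYs, i.e. £12 636 per QALY — below the
£20 000 threshold, hence cost-effective. The same library calls are
available in Python:

```python
from rdncea import synthetic_data, evaluate
bundle = evaluate(synthetic_data.make_base_fixture())
print(bundle.ce.icer, bundle.ce.verdict)   # 12636.20... 'cost-effective'
```

Other subcommands: `rdncea scenario` (the published scenario battery:
ages 45/70, 100% male/female, 140/180 mmHg baselines, cost/utility scaling,
event-risk adjustment, repeat procedure, alternative effect sizes),
`rdncea tornado`, and `rdncea psa --seed 1 --n-draws 10000` (scatter CSV,
CEAC CSV, summary JSON). Every command writes a manifest with the config
hash; outputs are byte-identical across reruns at a fixed seed.

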
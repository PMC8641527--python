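# afscreen

Health-economic evaluation of **one-time population screening for atrial
fibrillation (AF)** with subsequent oral anticoagulation, built as a tested,
configurable pipeline.  The base case is Nigeria: the national cohort aged 55+
is offered a single screening session with a single-lead ECG device, and newly
detected AF patients start stroke prevention with a NOAC and/or warfarin.  The
package is aimed at health-economics and epidemiological-modelling researchers
who want a transparent, scriptable re-implementation of this class of
screening evaluations rather than a spreadsheet.

## What it computes

1. **Screening cascade** (decision tree): attendees → prevalent AF → newly
   detected cases, plus the one-time session cost
   (devices + contacts + diagnostic confirmations).
2. **Lifetime Markov cohort model** in 6-month cycles over eight states —
   AF, acute stroke (tunnel), post-stroke, acute major bleed (tunnel) and four
   absorbing death states — comparing *screening* (anticoagulation from
   detection) against *no screening* (anticoagulation only after a stroke).
   Treatment multiplies per-cycle risks (stroke ×0.38, major bleed ×2.40,
   background mortality ×0.74) for the on-treatment fraction (persistence
   70% → 60%).
3. **Cost-effectiveness**: discounted (4%/yr) QALYs, life years and costs per
   arm; ΔQALY, ΔCost, ICER = ΔC/ΔE, and net monetary benefit
   NMB = λ·ΔE − ΔC at a willingness-to-pay λ = $2,000/QALY.
4. **Uncertainty**: probabilistic sensitivity analysis (10,000 beta-distributed
   parameter draws → CE plane and acceptability curve), one-way/scenario
   analyses, and a NOAC price-threshold search.

Background mortality comes from a user life table (`age,q_annual` CSV) or, by
default, a synthetic Gompertz–Makeham table calibrated so the untreated
no-screening cohort has 10-year median survival from age 55 (the published
survival level; the original national table is unpublished).  See
`docs/methods.md` for model details and the known divergences from the
published headline numbers.

## Worked example

```python
import afscreen as afs

params = afs.default_parameters()                 # published base-case inputs
lifetable = afs.synthetic_life_table(params=params)  # calibrated to 10 y median

cascade = afs.run_cascade(params.screening)
print(cascade.new_af_detected)                    # 31687 newly detected patients

res = afs.evaluate_screening(params, lifetable)   # 100% NOAC by default
print(res.summary().round(1).to_string(index=False))
```

```
 mix        panel          row    qalys      lys       costs   icer
noac   discounted on_treatment 250141.1 299581.4 174399108.1    NaN
noac   discounted no_treatment 224617.0 270527.6  11231373.7    NaN
noac   discounted        delta  25524.2  29053.7 163167734.4 6392.7
noac undiscounted on_treatment 338644.4 405840.1 233170590.1    NaN
noac undiscounted no_treatment 294906.8 355560.0  15450256.7    NaN
noac undiscounted        delta  43737.6  50280.1 217720333.4 4977.9
```

The discounted block reads: screening the cohort of 31,687 newly detected
patients yields 25,524 extra QALYs at $163.2M extra cost (2018 US$), an ICER
of $6,393 per QALY gained — per patient, 0.81 QALY at $5,149.  Against the
$2,000/QALY threshold the per-patient NMB is −$3,538, so 100% NOAC screening
is **not** cost-effective at the current $448/6-months drug price, while the
same run with `mix=afs.TreatmentMix(frac_noac=0.0)` (warfarin) gives an ICER
of $886/QALY — cost-effective.  The undiscounted ICER is lower than the
discounted one because the health gains arrive later than the drug costs.

The same pipeline is scriptable from the shell:

```bash
afscreen dump-defaults config.yaml        # the base case as editable YAML
afscreen make-lifetable lt.csv            # the calibrated synthetic life table
afscreen run --mix warfarin               # Table-style report + ICER + NMB
afscreen psa --n 10000 --seed 1 --plot    # CE plane, CEAC, reproducible
afscreen scenarios                        # one-way sensitivity sweep
afscreen threshold --criterion wtp        # NOAC price turning point
```

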
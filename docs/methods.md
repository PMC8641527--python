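# Methods

`afscreen` evaluates whether one-time, population-wide screening for
non-valvular atrial fibrillation (AF), followed by oral anticoagulation of the
newly detected cases, is good value for money in a low-resource setting
(Nigeria is the base case).  It couples three parts: a decision-tree screening
cascade, a lifetime Markov cohort model of AF natural history under stroke
prevention, and standard cost-effectiveness machinery (ICER, net monetary
benefit, probabilistic and one-way sensitivity analysis, drug-price threshold
search).

## Screening cascade

A national cohort aged 55+ (9,053,294 people) is offered a single screening
session in 1,000 community clinics using a single-lead ECG device
(sensitivity 100%, specificity 95.9%).  With 50% attendance, 1% AF prevalence
and 70% of AF previously unknown, the expected number of newly detected
patients is 9,053,294 x 0.5 x 0.01 x 0.7 = 31,686.5, rounded half-up to
31,687.  Intermediate counts stay fractional (they are expectations); only the
final detected count is rounded.

Session costs are devices (one per clinic, $275 for one year's use of a €700
device amortised over three years), a contact cost per attendee (one third of
an int$5.20 clinic visit for the device; a full visit for pulse palpation) and
a confirmation cost per screen-positive (cardiologist ECG review, including
false positives).  Costs flagged as international dollars are converted to
US$ with a single factor (default 0.893).  This factor was derived by solving
the published totals of both screening modes for it — the $7.3M device session
implies 0.895, the $21.0M pulse-palpation session implies 0.892 — since the
exchange conventions themselves are only in the source's supplement.  With it
the device session costs $7.6M total ($1.68 per person screened) including
the confirmation component.

False positives incur confirmation costs but never enter the modelled cohort;
with the device's high specificity their cost share is marginal.

## Markov cohort model

Eight states in 6-month cycles: stable AF; acute stroke (one-cycle tunnel);
post-stroke (chronic); acute major bleed (one-cycle tunnel, survivors return
to AF); and four absorbing death states (acute stroke death, post-stroke
death, fatal bleed, age-related death).  The cohort enters 100% in AF at age
55 and is propagated until extinction (or an age cap of 110, with a warning if
mass remains).

Per-cycle untreated probabilities: stroke 0.0108 (pooling ischemic stroke and
intracranial haemorrhage; the 6-month transform of an annual 2.15% under a
constant hazard), of which 0.0023 immediately fatal; major extracranial bleed
0.0013, of which 0.0001 fatal; post-stroke death 0.1751 per cycle, lifelong,
from both the tunnel and the chronic state.  Background (age-related) death
comes from the life table, converted to a 6-month probability, and multiplies
the residual after event probabilities (competing risks without within-cycle
sequencing; over-subscribed rows raise an error rather than renormalise).

Anticoagulation multiplies risks: stroke x0.38, major bleed x2.40, background
mortality x0.74.  The source's effect table prints the triplet (stroke 0.38,
bleeding 0.74, mortality 2.40), which is clinically impossible as written —
anticoagulation increases extracranial bleeding and reduces mortality — so the
default `clinically_coherent` mapping assigns the printed values to the
clinically matching rows; a `literal_table` mode preserves the printed order
for anyone who wants it.  The stroke multiplier scales both the stroke
probability and its fatal subset; post-stroke death is governed separately and
is unaffected by treatment.

Treatment enters as the on-treatment fraction `f` of a state's occupants, with
per-cycle rows blended `f * treated + (1 - f) * untreated`.  Therapy
persistence is 70% in the first cycle on therapy and 60% thereafter.  In the
screening arm the whole cohort starts therapy at entry; in the no-screening
arm AF is undetected and untreated, and therapy begins only after a stroke —
conveniently, the acute-stroke tunnel is exactly the first post-onset cycle
(70%) and the post-stroke state every later one (60%), so no extra time
bookkeeping is needed.  Post-stroke treatment is identical in both arms, so
arm differences stem solely from AF-state treatment plus the screening cost.
Bleed-tunnel occupants follow their arm's AF schedule.

Valuation: each cycle contributes half a year of life, weighted by state
utilities (AF 0.843, acute stroke 0.328, post-stroke 0.549, bleed cycle 0.814
= AF utility minus a 0.029 six-month disutility, applied subtractively).
Event costs attach to state entries (acute stroke $938, fatal stroke $1,126 =
1.2x, bleed $195, fatal bleed $778 = 4x), post-stroke upkeep $6 per cycle of
occupancy, and drug costs per on-treatment cycle (NOAC $448; warfarin $17 +
$30 INR monitoring).  All flows are discounted at 4% per year,
`(1.04)^(-t/2)` at cycle `t`; no half-cycle correction by default (accrual
uses each row's occupancy at its own discount factor), with a trapezoid
half-cycle correction available behind `cycle.half_cycle_correction`.  The
acute-death inputs are absolute per-cycle probabilities by default; a
conditional-on-event reading is available via
`events.acute_death_conditional`.  Costs are 2018 US$/int$.

## Background mortality and calibration

The national life table behind the source evaluation is not published, so the
default is a synthetic Gompertz–Makeham table, `q(x) = 1 - exp(-(c + a e^{bx}))`
annually, with senescence rate `b = 0.085` and Makeham constant `c = 0.005`
fixed at typical adult-mortality values and the level `a` calibrated by
deterministic (geometric) bisection so the untreated no-screening cohort —
run through the full Markov model — has a 10-year median survival from age 55,
matching the published base case.  Median survival interpolates linearly
within the crossing cycle (deaths uniform within a cycle).  The calibrated
table reproduces the survival level, not the national age pattern; analyses
that hinge on the exact shape of old-age mortality (notably the size of the
treated background-mortality benefit) inherit that approximation.  Age is
advanced by half a year per cycle and the annual `q` looked up at the floored
age; event-specific deaths are not decremented from the background table,
following the source.

## Cost-effectiveness analysis

Cohort totals are per-patient outcomes x 31,687; the one-time screening cost
is added to the intervention arm at t = 0 (by default inside the ICER).
Increments use discounted totals; the ICER is dCost/dQALY with quadrant-based
dominance labels, and NMB = WTP x dQALY - dCost at a willingness-to-pay of
$2,000/QALY (≈ Nigeria's 2018 GDP per capita).  Per-patient values divide by
the detected cohort size.

## Probabilistic sensitivity analysis

Each of 10,000 iterations independently redraws every varied parameter from a
method-of-moments beta: probabilities, utilities and persistence on [0, 1];
risk multipliers and event costs on [0, 2 x mean] so the default ±20% range
(read as a 95% interval, sd = range/3.92) fits a bounded support.  Treatment
costs and the total screening cost are fixed.  Draws violating joint
invariants are excluded, not resampled, and counted.  A single pair of cohort
traces per draw serves all three treatment mixes (NOAC / 50:50 / warfarin),
because the mix changes only drug costs, never transitions.  Outputs are the
per-patient CE-plane clouds, the acceptability curve (fraction of draws with
NMB ≥ 0 per WTP), and the probability cost-effective at $2,000/QALY.
Everything is reproducible from the seed.

## Scenarios and price threshold

One-way analyses rerun the full pipeline under 100% NOAC with: stroke
probability x0.5/x1.5 (fatal subset scaled along), start age 45/65 (using the
same calibrated hazard extended to the new entry age), stroke utilities and
stroke costs x0.5/x1.5 (each group changed simultaneously), AF prevalence
0.5%–4%, screening costs x0.5/x1.5, a NOAC efficacy advantage (stroke
multiplier x0.81, mortality x0.90, bleed x1.25) and pulse palpation.  The
pulse scenario drops sensitivity to 92% — the missed 8% stay in the diagnosed
cohort but behave like no-screening patients, so the screening arm is the
0.92/0.08 mixture of the two traces — and prices a full clinic visit per
attendee plus confirmatory ECGs for the much larger false-positive pool
(specificity 82%).

The NOAC price threshold bisects the 6-month price to the largest value at
which screening remains cost-effective at the WTP (or remains cost-saving),
tolerance $0.5, after a sweep verifies the incremental cost is monotone in
price.  The search range is $0 to 150% of the base price; the lower bound is
extended below the source's 1% because the cost-saving turning point can sit
there.

## Numerical and design choices

- Extinction tolerance 1e-8 of cohort mass; age cap 110.
- Validation collects all invariant violations into one error; soft
  relationships (fatal-cost mark-ups, declining persistence, clinic capacity
  within 1% of attendees) warn instead of raising.
- "Stroke acute death 0.0023" is read as an absolute per-cycle probability
  (≈21% acute case fatality of strokes), not conditional on stroke.
- Recurrent stroke, TTR-dependent warfarin efficacy, stroke-severity-specific
  utilities, repeated screening and risk-score stratification are out of
  scope; stroke-severity shares are carried as metadata only.

## What the synthetic inputs do and do not show

The generator-based life table is the only synthetic input; every other
default is a published table value.  Tests passing against the calibrated
table show the pipeline reproduces the source's survival level, orderings and
qualitative conclusions (warfarin-based screening cost-effective at
$2,000/QALY, NOAC-based not, at current prices).  They do not certify the
absolute ICERs: those depend on the unpublished mortality table, the
supplement's currency conversions, and the source's internally inconsistent
stroke-risk and treatment-effect statements.  Under the defaults here the
100% NOAC ICER is ≈ $6,400/QALY — lower than the published $12,587 —
essentially because the clinically coherent mortality benefit (x0.74 on
treated background mortality) yields a larger survival gain than the
published model exhibits; the `literal_table` mode and the configurable
multipliers let users explore the alternatives.  Deterministic totals,
orderings, conservation properties and the microsimulation cross-check are
exact statements about this implementation, not about the source spreadsheet.
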
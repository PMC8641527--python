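"""One-way / scenario sensitivity analyses and the NOAC price-threshold search.

All scenarios rerun the full cascade-cohort-CEA pipeline under 100% NOAC use
(unless a mix is supplied) with one input or input group changed:

* stroke event probability x0.5 / x1.5 (the acute-fatal subset scales along);
* screening start age 45 / 65;
* stroke utilities x0.5 / x1.5 (acute and post-stroke together, capped at 1);
* stroke costs x0.5 / x1.5 (acute, post-event and fatal together);
* AF prevalence 0.5% / 4%;
* screening-session costs x0.5 / x1.5;
* a NOAC efficacy advantage over warfarin;
* pulse palpation instead of the single-lead ECG device.

The price-threshold search bisects the NOAC 6-month price to the largest
value at which screening is still cost-effective at the willingness-to-pay
threshold (or still cost-saving), after verifying by sweep that the ICER is
monotone in the price.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import pandas as pd

from .cea import EvaluationResult, evaluate_screening
from .lifetables import LifeTable
from .parameters import ModelParameters, ParameterError, with_overrides

__all__ = [
    "ScenarioSpec",
    "ThresholdResult",
    "run_scenario",
    "scale_overrides",
    "noac_efficacy_scenario",
    "pulse_palpation_scenario",
    "noac_price_threshold",
    "table6_scenarios",
    "run_table6",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """A named pair of parameter variations (lower / upper) around the base case.

    Each entry maps dotted parameter paths to absolute override values; an
    entry may instead be a callable ``params -> params`` for structural
    scenarios (NOAC efficacy, pulse palpation).
    """

    name: str
    lower: Mapping[str, float] | Callable[[ModelParameters], ModelParameters] | None = None
    upper: Mapping[str, float] | Callable[[ModelParameters], ModelParameters] | None = None


def scale_overrides(params: ModelParameters, paths: tuple[str, ...],
                    factor: float) -> dict[str, float]:
    """Multiplicative overrides for a group of parameters, capped for utilities."""
    if factor <= 0:
        raise ParameterError("multiplicative scenario factors must be > 0")
    out = {}
    for path in paths:
        obj = params
        for part in path.split("."):
            obj = getattr(obj, part)
        value = obj * factor
        if path.startswith("utilities."):
            value = min(value, 1.0)
        out[path] = value
    return out


def _apply(params: ModelParameters, variation) -> ModelParameters:
    if variation is None:
        return params
    if callable(variation):
        return variation(params)
    return with_overrides(params, variation)


def run_scenario(base: ModelParameters, lifetable: LifeTable,
                 spec: ScenarioSpec) -> tuple[EvaluationResult | None,
                                              EvaluationResult | None]:
    """Evaluate the lower and upper variation of one scenario (None if absent)."""
    lo = evaluate_screening(_apply(base, spec.lower), lifetable) if spec.lower is not None else None
    hi = evaluate_screening(_apply(base, spec.upper), lifetable) if spec.upper is not None else None
    return lo, hi


def noac_efficacy_scenario(base: ModelParameters) -> ModelParameters:
    """NOAC efficacy advantage: 19% more stroke reduction, 10% lower all-cause
    mortality, 25% more bleeding, relative to the base anticoagulation effect."""
    if base.effect.mapping_mode != "clinically_coherent":
        raise ParameterError("NOAC efficacy scenario requires the clinically_coherent "
                             "effect mapping")
    eff = base.effect
    return base.replace(effect=replace(
        eff,
        rr_stroke=eff.rr_stroke * (1.0 - 0.19),
        rr_mortality=eff.rr_mortality * (1.0 - 0.10),
        rr_bleed=eff.rr_bleed * (1.0 + 0.25),
    ))


def pulse_palpation_scenario(base: ModelParameters) -> ModelParameters:
    """Screening by pulse palpation instead of the single-lead ECG device.

    Sensitivity falls to 92% — the missed 8% remain in the newly-diagnosed
    cohort but go untreated from entry — and specificity to 82%.  Every
    attendee needs a full clinic visit (palpation is slower) and every
    screen-positive, including the much larger false-positive pool, needs a
    confirmatory ECG read.
    """
    if base.screening.sensitivity < 1.0:
        raise ParameterError("pulse-palpation scenario assumes the device base case")
    sp = base.screening
    return base.replace(screening=replace(
        sp,
        sensitivity=0.92,
        specificity=0.82,
        contact_cost=5.20,           # full health-centre visit, int$
        device_cost_year=0.0,        # no devices to buy
        cohort_includes_missed=True,
    ))


#: scenario sweep mirroring the published one-way analyses (100% NOAC)
def table6_scenarios(base: ModelParameters) -> list[ScenarioSpec]:
    stroke_p = ("events.p_stroke", "events.p_stroke_acute_death")
    stroke_u = ("utilities.u_acute_stroke", "utilities.u_post_stroke")
    stroke_c = ("costs.c_acute_stroke", "costs.c_post_stroke", "costs.c_stroke_death")
    screen_c = ("screening.device_cost_year", "screening.contact_cost",
                "screening.confirmation_cost")
    return [
        ScenarioSpec("stroke_probability_50_150",
                     scale_overrides(base, stroke_p, 0.5),
                     scale_overrides(base, stroke_p, 1.5)),
        ScenarioSpec("start_age_45_65",
                     {"cycle.start_age": 45.0}, {"cycle.start_age": 65.0}),
        ScenarioSpec("stroke_utility_50_150",
                     scale_overrides(base, stroke_u, 0.5),
                     scale_overrides(base, stroke_u, 1.5)),
        ScenarioSpec("pulse_palpation", None, pulse_palpation_scenario),
        ScenarioSpec("noac_efficacy", None, noac_efficacy_scenario),
        ScenarioSpec("stroke_costs_50_150",
                     scale_overrides(base, stroke_c, 0.5),
                     scale_overrides(base, stroke_c, 1.5)),
        ScenarioSpec("af_prevalence_05_4",
                     {"screening.prevalence": 0.005}, {"screening.prevalence": 0.04}),
        ScenarioSpec("screening_costs_50_150",
                     scale_overrides(base, screen_c, 0.5),
                     scale_overrides(base, screen_c, 1.5)),
    ]


def run_table6(base: ModelParameters, lifetable: LifeTable,
               lifetable_by_age: Mapping[int, LifeTable] | None = None) -> pd.DataFrame:
    """Run every scenario; returns one row per scenario with lower/upper ICERs.

    ``lifetable_by_age`` supplies tables covering the alternative start ages
    of the age scenario (the default table starts at the base-case age).
    """
    rows = []
    for spec in table6_scenarios(base):
        def evaluate(variation):
            if variation is None:
                return None
            p = _apply(base, variation)
            lt = lifetable
            if lifetable_by_age and int(p.cycle.start_age) in lifetable_by_age:
                lt = lifetable_by_age[int(p.cycle.start_age)]
            return evaluate_screening(p, lt)

        lo, hi = evaluate(spec.lower), evaluate(spec.upper)
        rows.append({
            "scenario": spec.name,
            "icer_lower": lo.ce.icer if lo is not None else float("nan"),
            "icer_upper": hi.ce.icer if hi is not None else float("nan"),
            "dqaly_pp_lower": lo.ce.delta_qaly_per_patient if lo is not None else float("nan"),
            "dqaly_pp_upper": hi.ce.delta_qaly_per_patient if hi is not None else float("nan"),
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of the NOAC price-threshold search."""

    threshold_price: float       # US$ per 6 months
    criterion: str               # "cost_effective_at_wtp" | "cost_saving"
    wtp: float | None
    at_boundary: bool            # criterion (un)satisfiable across the whole range
    sweep: pd.DataFrame = field(repr=False)
    trace: list[tuple[float, float]] = field(default_factory=list, repr=False)


def _satisfies(res: EvaluationResult, criterion: str, wtp: float | None) -> bool:
    if criterion == "cost_effective_at_wtp":
        return res.ce.nmb(wtp) >= 0.0
    if criterion == "cost_saving":
        return res.ce.delta_cost <= 0.0
    raise ValueError(f"unknown criterion {criterion!r}")


def noac_price_threshold(
    base: ModelParameters,
    lifetable: LifeTable,
    criterion: str = "cost_effective_at_wtp",
    wtp: float | None = None,
    price_range: tuple[float, float] | None = None,
    tol: float = 0.5,
    n_sweep: int = 7,
) -> ThresholdResult:
    """Largest 6-month NOAC price at which the criterion still holds (100% NOAC).

    Sweeps the range first to confirm the ICER (equivalently, incremental cost)
    rises monotonically with price, then bisects to ``tol`` dollars.  The
    search range spans $0 to 150% of the base price: the published range starts
    at 1% of the base price, but the cost-saving turning point can sit below
    that, so the lower bound is extended to zero.  If the criterion holds (or
    fails) across the whole range the boundary is returned and flagged.
    """
    if criterion == "cost_effective_at_wtp" and wtp is None:
        wtp = base.wtp
    base = base.replace(mix=type(base.mix)(frac_noac=1.0))
    if price_range is None:
        price_range = (0.0, 1.5 * base.costs.c_noac)
    lo, hi = price_range

    def result_at(price: float) -> EvaluationResult:
        return evaluate_screening(
            with_overrides(base, {"costs.c_noac": price}), lifetable)

    sweep_prices = [lo + (hi - lo) * i / (n_sweep - 1) for i in range(n_sweep)]
    sweep_rows = []
    for p in sweep_prices:
        r = result_at(p)
        sweep_rows.append({"price": p, "delta_cost": r.ce.delta_cost,
                           "delta_qaly": r.ce.delta_qaly, "icer": r.ce.icer,
                           "satisfies": _satisfies(r, criterion, wtp)})
    sweep = pd.DataFrame(sweep_rows)
    dcosts = sweep["delta_cost"].to_numpy()
    if not (dcosts[1:] >= dcosts[:-1] - 1e-6).all():
        raise RuntimeError("incremental cost is not monotone in NOAC price; "
                           "bisection precondition violated")

    ok_lo = bool(sweep["satisfies"].iloc[0])
    ok_hi = bool(sweep["satisfies"].iloc[-1])
    trace: list[tuple[float, float]] = []
    if ok_hi:  # criterion holds everywhere: threshold at the upper boundary
        return ThresholdResult(hi, criterion, wtp, True, sweep, trace)
    if not ok_lo:  # criterion fails even at zero price
        return ThresholdResult(lo, criterion, wtp, True, sweep, trace)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        r = result_at(mid)
        trace.append((mid, r.ce.delta_cost))
        if _satisfies(r, criterion, wtp):
            lo = mid
        else:
            hi = mid
    return ThresholdResult(0.5 * (lo + hi), criterion, wtp, False, sweep, trace)
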
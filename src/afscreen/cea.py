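"""Cost-effectiveness aggregation: arm totals, increments, ICER, NMB.

Cohort totals scale the per-patient Markov outcomes by the number of newly
detected AF patients from the screening cascade; the one-time screening cost
is added to the intervention arm at t = 0 (undiscounted == discounted).  The
incremental cost-effectiveness ratio is computed on discounted totals, with
quadrant-based dominance classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import cascade as _cascade
from . import markov as _markov
from .lifetables import LifeTable
from .parameters import ModelParameters, TreatmentMix

__all__ = ["ArmResult", "CEResult", "EvaluationResult", "arm_totals", "icer",
           "nmb", "table5_report", "evaluate_screening"]

#: |dQALY| below this is treated as zero when forming the ratio
_DQALY_EPS = 1e-9


@dataclass(frozen=True)
class ArmResult:
    """Lifetime totals for one arm and one cohort size."""

    n_patients: int
    qaly_disc: float
    qaly_undisc: float
    ly_disc: float
    ly_undisc: float
    cost_disc: float
    cost_undisc: float
    components_disc: dict[str, float] = field(default_factory=dict)
    components_undisc: dict[str, float] = field(default_factory=dict)

    def per_patient(self, attr: str) -> float:
        if self.n_patients == 0:
            raise ValueError("empty cohort: per-patient results undefined")
        return getattr(self, attr) / self.n_patients


def arm_totals(outcomes: _markov.CycleOutcomes, n_patients: int,
               screening_cost: float = 0.0) -> ArmResult:
    """Scale per-patient cycle outcomes to the cohort and add screening costs.

    ``screening_cost`` is the total one-time session cost, incurred at t = 0
    and therefore not discounted.
    """
    if n_patients <= 0:
        raise ValueError("empty cohort: arm totals undefined")
    n = n_patients
    comp_d = {k: v * n for k, v in outcomes.cost_components(True).items()}
    comp_u = {k: v * n for k, v in outcomes.cost_components(False).items()}
    comp_d["screening"] = screening_cost
    comp_u["screening"] = screening_cost
    return ArmResult(
        n_patients=n,
        qaly_disc=outcomes.total_qaly(True) * n,
        qaly_undisc=outcomes.total_qaly(False) * n,
        ly_disc=outcomes.total_ly(True) * n,
        ly_undisc=outcomes.total_ly(False) * n,
        cost_disc=outcomes.total_cost(True) * n + screening_cost,
        cost_undisc=outcomes.total_cost(False) * n + screening_cost,
        components_disc=comp_d,
        components_undisc=comp_u,
    )


@dataclass(frozen=True)
class CEResult:
    """Incremental result of intervention vs comparator (discounted)."""

    delta_qaly: float
    delta_ly: float
    delta_cost: float
    icer: float | None            # None when dominance applies or dQALY ~ 0
    dominance: str                # "none" | "dominant" | "dominated" | "undefined"
    n_patients: int

    @property
    def delta_qaly_per_patient(self) -> float:
        return self.delta_qaly / self.n_patients

    @property
    def delta_cost_per_patient(self) -> float:
        return self.delta_cost / self.n_patients

    def nmb(self, wtp: float) -> float:
        """Net monetary benefit, cohort total: wtp x dQALY - dCost."""
        return wtp * self.delta_qaly - self.delta_cost

    def cost_effective(self, wtp: float) -> bool:
        return self.nmb(wtp) >= 0.0


def icer(case: ArmResult, base: ArmResult) -> CEResult:
    """Incremental cost-effectiveness of ``case`` over ``base`` on discounted totals."""
    if case.n_patients != base.n_patients:
        raise ValueError(
            f"mismatched cohorts: {case.n_patients} vs {base.n_patients} patients")
    dq = case.qaly_disc - base.qaly_disc
    dl = case.ly_disc - base.ly_disc
    dc = case.cost_disc - base.cost_disc
    if abs(dq) < _DQALY_EPS:
        dominance, ratio = "undefined", None
    elif dq > 0 and dc <= 0:
        dominance, ratio = "dominant", None
    elif dq < 0 and dc >= 0:
        dominance, ratio = "dominated", None
    elif dq < 0:
        dominance, ratio = "undefined", None  # SW quadrant: ratio not meaningful alone
    else:
        dominance, ratio = "none", dc / dq
    return CEResult(delta_qaly=dq, delta_ly=dl, delta_cost=dc, icer=ratio,
                    dominance=dominance, n_patients=case.n_patients)


def nmb(ce: CEResult, wtp: float) -> float:
    """Net monetary benefit at a willingness-to-pay threshold (cohort total)."""
    if wtp <= 0:
        raise ValueError("wtp must be > 0")
    return ce.nmb(wtp)


@dataclass(frozen=True)
class EvaluationResult:
    """Everything one full screening-vs-no-screening evaluation produces."""

    params: ModelParameters
    cascade: _cascade.CascadeResult
    screening_costs: _cascade.ScreeningCostBreakdown
    case: ArmResult
    base: ArmResult
    ce: CEResult
    case_trace: _markov.CohortTrace
    base_trace: _markov.CohortTrace

    def summary(self) -> pd.DataFrame:
        return table5_report({self._mix_label(): self})

    def _mix_label(self) -> str:
        f = self.params.mix.frac_noac
        return {1.0: "noac", 0.0: "warfarin", 0.5: "mix5050"}.get(f, f"noac{f:g}")


def evaluate_screening(params: ModelParameters, lifetable: LifeTable,
                       mix: TreatmentMix | None = None) -> EvaluationResult:
    """Run cascade + both cohort arms + CEA for one parameter set.

    The modelled cohort is the newly detected patients; with
    ``screening.cohort_includes_missed`` (pulse palpation) the cohort is all
    previously unknown AF attendees and the screening arm is the
    sensitivity-weighted mixture of treated-from-entry and never-detected
    (i.e. no-screening-behaving) patients.
    """
    if mix is not None:
        params = params.replace(mix=mix)
    cr = _cascade.run_cascade(params.screening)
    costs = _cascade.screening_cost_total(params.screening, cr)

    if params.screening.cohort_includes_missed:
        n_patients = _cascade.round_half_up(cr.new_af_true)
    else:
        n_patients = cr.new_af_detected
    if n_patients <= 0:
        raise ValueError("cascade produced an empty cohort")

    case_arm = _markov.screening_arm(params.mix)
    base_arm = _markov.no_screening_arm(params.mix)
    case_trace = _markov.run_cohort(params, case_arm, lifetable)
    base_trace = _markov.run_cohort(params, base_arm, lifetable)
    case_out = _markov.trace_outcomes(case_trace, params, case_arm)
    base_out = _markov.trace_outcomes(base_trace, params, base_arm)

    screening_cost = costs.total if params.include_screening_cost_in_icer else 0.0

    if params.screening.cohort_includes_missed and params.screening.sensitivity < 1.0:
        # detected fraction follows the screening arm, the missed remainder the
        # no-screening arm; outcomes are linear in the cohort split
        w = params.screening.sensitivity
        case_out = _blend_outcomes(case_out, base_out, w)

    case_res = arm_totals(case_out, n_patients, screening_cost)
    base_res = arm_totals(base_out, n_patients, 0.0)
    ce = icer(case_res, base_res)
    return EvaluationResult(params=params, cascade=cr, screening_costs=costs,
                            case=case_res, base=base_res, ce=ce,
                            case_trace=case_trace, base_trace=base_trace)


def _blend_outcomes(case_out: _markov.CycleOutcomes, base_out: _markov.CycleOutcomes,
                    w: float) -> _markov.CycleOutcomes:
    import numpy as np

    n = max(case_out.ly.size, base_out.ly.size)

    def pad(a):
        return np.pad(a, (0, n - a.size))

    disc = pad(case_out.discount)
    disc_b = pad(base_out.discount)
    disc = np.where(disc > 0, disc, disc_b)
    return _markov.CycleOutcomes(
        ly=w * pad(case_out.ly) + (1 - w) * pad(base_out.ly),
        qaly=w * pad(case_out.qaly) + (1 - w) * pad(base_out.qaly),
        cost_treatment=(w * pad(case_out.cost_treatment)
                        + (1 - w) * pad(base_out.cost_treatment)),
        cost_events=w * pad(case_out.cost_events) + (1 - w) * pad(base_out.cost_events),
        cost_post_stroke=(w * pad(case_out.cost_post_stroke)
                          + (1 - w) * pad(base_out.cost_post_stroke)),
        discount=disc,
    )


def table5_report(results: dict[str, EvaluationResult]) -> pd.DataFrame:
    """Headline report: totals, increments and ICER per treatment mix.

    One block of rows per mix ("on treatment", "no treatment", "delta") for
    discounted and undiscounted panels, mirroring the published layout.
    """
    rows = []
    for label, res in results.items():
        for panel, suffix in (("discounted", "disc"), ("undiscounted", "undisc")):
            case_q = getattr(res.case, f"qaly_{suffix}")
            base_q = getattr(res.base, f"qaly_{suffix}")
            case_l = getattr(res.case, f"ly_{suffix}")
            base_l = getattr(res.base, f"ly_{suffix}")
            case_c = getattr(res.case, f"cost_{suffix}")
            base_c = getattr(res.base, f"cost_{suffix}")
            dq, dl, dc = case_q - base_q, case_l - base_l, case_c - base_c
            ratio = dc / dq if abs(dq) > _DQALY_EPS else float("nan")
            rows += [
                {"mix": label, "panel": panel, "row": "on_treatment",
                 "qalys": case_q, "lys": case_l, "costs": case_c, "icer": float("nan")},
                {"mix": label, "panel": panel, "row": "no_treatment",
                 "qalys": base_q, "lys": base_l, "costs": base_c, "icer": float("nan")},
                {"mix": label, "panel": panel, "row": "delta",
                 "qalys": dq, "lys": dl, "costs": dc, "icer": ratio},
            ]
    return pd.DataFrame(rows)
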
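"""Lifetime Markov cohort model over the AF health-state space.

The cohort enters in stable AF at the start age and is propagated in 6-month
cycles until extinction.  Acute stroke and acute major bleeding are
single-cycle tunnel states; stroke survivors move to a lifelong post-stroke
state, bleed survivors return to AF.  Four absorbing death states separate
acute stroke death, post-stroke death, fatal bleeding and age-related death.

Treatment enters through the on-treatment fraction of each state's occupants:
per-cycle probabilities are blended as ``f * p_treated + (1 - f) * p_untreated``
where the treated probabilities carry the anticoagulation multipliers.  In the
screening arm the whole cohort initiates therapy at entry (persistence 70% in
the first cycle, 60% thereafter); in the no-screening arm AF goes untreated
and therapy starts only after a stroke, with the same persistence schedule
measured from stroke onset — the acute-stroke tunnel is by construction the
first post-onset cycle, the post-stroke state every later one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd

from .lifetables import LifeTable, cycle_mortality
from .parameters import (ModelParameters, PersistenceSchedule, TreatmentMix,
                         treated_probabilities)

__all__ = [
    "State",
    "LIVING_STATES",
    "ABSORBING_STATES",
    "ArmSpec",
    "screening_arm",
    "no_screening_arm",
    "CohortTrace",
    "ModelConsistencyError",
    "on_treatment_fraction",
    "build_transition_row",
    "transition_matrix",
    "run_cohort",
    "trace_outcomes",
    "CycleOutcomes",
    "median_survival",
    "microsimulate",
]


class State(IntEnum):
    AF = 0
    ACUTE_STROKE = 1
    POST_STROKE = 2
    ACUTE_BLEED = 3
    DEAD_STROKE_ACUTE = 4
    DEAD_POST_STROKE = 5
    DEAD_BLEED = 6
    DEAD_AGE = 7


LIVING_STATES = (State.AF, State.ACUTE_STROKE, State.POST_STROKE, State.ACUTE_BLEED)
ABSORBING_STATES = (State.DEAD_STROKE_ACUTE, State.DEAD_POST_STROKE,
                    State.DEAD_BLEED, State.DEAD_AGE)
N_STATES = len(State)

#: utilities per state, in state-space order (filled from a UtilitySet)
_UTILITY_FIELDS = ("u_af", "u_acute_stroke", "u_post_stroke", "u_major_bleed")


class ModelConsistencyError(RuntimeError):
    """Per-cycle probabilities over-subscribe a transition row."""


@dataclass(frozen=True)
class ArmSpec:
    """One comparator arm of the evaluation."""

    arm: str                              # "screening" | "no_screening"
    mix: TreatmentMix | None = None       # None -> use ModelParameters.mix
    treat_from_start: bool = True
    treat_after_stroke: bool = True

    def __post_init__(self):
        if self.arm not in ("screening", "no_screening"):
            raise ValueError(f"unknown arm {self.arm!r}")
        if self.arm == "screening" and not self.treat_from_start:
            raise ValueError("screening arm must treat from start")
        if self.arm == "no_screening" and self.treat_from_start:
            raise ValueError("no-screening arm cannot treat from start")


def screening_arm(mix: TreatmentMix | None = None) -> ArmSpec:
    """Screening-detected cohort: anticoagulation from entry."""
    return ArmSpec(arm="screening", mix=mix, treat_from_start=True,
                   treat_after_stroke=True)


def no_screening_arm(mix: TreatmentMix | None = None) -> ArmSpec:
    """Undetected cohort: anticoagulation initiated only after a stroke."""
    return ArmSpec(arm="no_screening", mix=mix, treat_from_start=False,
                   treat_after_stroke=True)


def on_treatment_fraction(cycle_index: int, arm: ArmSpec,
                          persistence: PersistenceSchedule,
                          state: State = State.AF) -> float:
    """On-treatment fraction of a state's occupants during 1-based ``cycle_index``.

    AF (and the bleed tunnel, whose occupants are AF patients mid-bleed)
    follows the arm's from-entry schedule; the stroke states follow the
    from-onset schedule whenever the arm treats after stroke.
    """
    if cycle_index < 1:
        raise ValueError("cycle_index is 1-based")
    if state in (State.AF, State.ACUTE_BLEED):
        if not arm.treat_from_start:
            return 0.0
        return (persistence.persist_first_cycle if cycle_index == 1
                else persistence.persist_later)
    if state == State.ACUTE_STROKE:
        return persistence.persist_first_cycle if arm.treat_after_stroke else 0.0
    if state == State.POST_STROKE:
        return persistence.persist_later if arm.treat_after_stroke else 0.0
    return 0.0


def _state_row(state: State, e, q: float) -> np.ndarray:
    """Transition row for occupants with event probabilities ``e`` and background
    mortality ``q`` (competing risks: background death multiplies the residual)."""
    row = np.zeros(N_STATES)
    if state == State.AF:
        p_events = e.p_stroke + e.p_major_bleed
        residual = 1.0 - p_events
        if residual < 0:
            raise ModelConsistencyError(
                f"AF row over-subscribed: p_stroke + p_major_bleed = {p_events:g} > 1")
        p_fatal_stroke = e.fatal_stroke_probability()
        p_fatal_bleed = e.fatal_bleed_probability()
        row[State.DEAD_STROKE_ACUTE] = p_fatal_stroke
        row[State.ACUTE_STROKE] = e.p_stroke - p_fatal_stroke
        row[State.DEAD_BLEED] = p_fatal_bleed
        row[State.ACUTE_BLEED] = e.p_major_bleed - p_fatal_bleed
        row[State.DEAD_AGE] = residual * q
        row[State.AF] = residual * (1.0 - q)
    elif state in (State.ACUTE_STROKE, State.POST_STROKE):
        p_psd = e.p_post_stroke_death
        if p_psd > 1.0:
            raise ModelConsistencyError(f"{state.name} row over-subscribed")
        survivor = State.POST_STROKE  # tunnel exits to post-stroke; post-stroke stays
        row[State.DEAD_POST_STROKE] = p_psd
        row[State.DEAD_AGE] = (1.0 - p_psd) * q
        row[survivor] = (1.0 - p_psd) * (1.0 - q)
    elif state == State.ACUTE_BLEED:
        row[State.DEAD_AGE] = q
        row[State.AF] = 1.0 - q
    else:  # absorbing
        row[state] = 1.0
    return row


def build_transition_row(state: State, params: ModelParameters, age: float,
                         treated_fraction: float, lifetable: LifeTable) -> np.ndarray:
    """Per-cycle transition probabilities out of ``state`` at ``age``.

    The row is the treated-fraction blend of the untreated row and the row
    under anticoagulation (event multipliers on events, mortality multiplier
    on background death).
    """
    q = cycle_mortality(lifetable, age, params.cycle.cycle_length)
    row_untr = _state_row(state, params.events, q)
    f = treated_fraction
    if f == 0.0:
        return row_untr
    ev_tr, q_tr = treated_probabilities(params.events, params.effect, q)
    row_tr = _state_row(state, ev_tr, q_tr)
    return f * row_tr + (1.0 - f) * row_untr


def transition_matrix(params: ModelParameters, arm: ArmSpec, cycle_index: int,
                      age: float, lifetable: LifeTable) -> np.ndarray:
    """Full 8x8 matrix for 1-based ``cycle_index`` starting at ``age``."""
    P = np.empty((N_STATES, N_STATES))
    for s in State:
        f = on_treatment_fraction(cycle_index, arm, params.persistence, s)
        P[s] = build_transition_row(s, params, age, f, lifetable)
    return P


@dataclass
class CohortTrace:
    """State occupancy and event flows of one arm, per 6-month cycle.

    Row ``t`` of ``occupancy`` is the cohort distribution during the cycle
    spanning years ``[t/2, (t+1)/2)`` after entry; row 0 is the entry
    distribution.  ``entries[name][t]`` is the inflow into an event state
    during the transition into row ``t``.
    """

    occupancy: np.ndarray            # (T+1, 8) cohort fractions
    age_at_cycle: np.ndarray         # (T+1,) age at the start of each row's cycle
    on_treatment: np.ndarray         # (T+1,) treated cohort fraction during the cycle
    entries: dict[str, np.ndarray] = field(default_factory=dict)
    truncated: bool = False
    residual: float = 0.0

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def living(self) -> np.ndarray:
        return self.occupancy[:, [int(s) for s in LIVING_STATES]].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=[s.name for s in State])
        df.insert(0, "age", self.age_at_cycle)
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        df["on_treatment"] = self.on_treatment
        for name, arr in self.entries.items():
            df[name] = arr
        return df


def run_cohort(params: ModelParameters, arm: ArmSpec,
               lifetable: LifeTable, extinction_tol: float = 1e-8) -> CohortTrace:
    """Propagate the cohort from 100% AF at the start age until extinction.

    Stops when living occupancy falls below ``extinction_tol`` or the maximum
    age is reached (with a truncation warning reporting the residual mass).
    """
    cyc = params.cycle
    t_max = cyc.n_cycles_max
    occ = [np.zeros(N_STATES)]
    occ[0][State.AF] = 1.0
    ages = [cyc.start_age]
    living_idx = [int(s) for s in LIVING_STATES]

    on_tx = []
    entries = {name: [0.0] for name in
               ("new_strokes", "new_bleeds", "deaths_stroke_acute",
                "deaths_post_stroke", "deaths_bleed", "deaths_age")}

    t = 0
    while True:
        cycle_index = t + 1
        age = cyc.start_age + t * cyc.cycle_length
        fracs = np.array([on_treatment_fraction(cycle_index, arm, params.persistence, s)
                          for s in State])
        on_tx.append(float(occ[t] @ fracs))
        living = occ[t][living_idx].sum()
        if living < extinction_tol or t >= t_max:
            break
        P = transition_matrix(params, arm, cycle_index, age, lifetable)
        nxt = occ[t] @ P
        occ.append(nxt)
        ages.append(age + cyc.cycle_length)
        prev = occ[t]
        inflow = lambda s: float(prev @ P[:, s]) - (prev[s] if s >= State.DEAD_STROKE_ACUTE else 0.0)
        entries["new_strokes"].append(float(prev @ P[:, State.ACUTE_STROKE]))
        entries["new_bleeds"].append(float(prev @ P[:, State.ACUTE_BLEED]))
        entries["deaths_stroke_acute"].append(inflow(State.DEAD_STROKE_ACUTE))
        entries["deaths_post_stroke"].append(inflow(State.DEAD_POST_STROKE))
        entries["deaths_bleed"].append(inflow(State.DEAD_BLEED))
        entries["deaths_age"].append(inflow(State.DEAD_AGE))
        t += 1

    occupancy = np.vstack(occ)
    residual = float(occupancy[-1, living_idx].sum())
    truncated = residual >= extinction_tol
    if truncated:
        warnings.warn(
            f"cohort not extinct at max_age {cyc.max_age}: residual living mass "
            f"{residual:.3g}", stacklevel=2)
    return CohortTrace(
        occupancy=occupancy,
        age_at_cycle=np.array(ages),
        on_treatment=np.array(on_tx),
        entries={k: np.array(v) for k, v in entries.items()},
        truncated=truncated,
        residual=residual,
    )


@dataclass
class CycleOutcomes:
    """Per-cycle and total (un)discounted life years, QALYs and costs of one arm."""

    ly: np.ndarray
    qaly: np.ndarray
    cost_treatment: np.ndarray
    cost_events: np.ndarray
    cost_post_stroke: np.ndarray
    discount: np.ndarray

    @property
    def cost(self) -> np.ndarray:
        return self.cost_treatment + self.cost_events + self.cost_post_stroke

    def _tot(self, arr: np.ndarray, discounted: bool) -> float:
        return float((arr * self.discount).sum() if discounted else arr.sum())

    def total_ly(self, discounted: bool = True) -> float:
        return self._tot(self.ly, discounted)

    def total_qaly(self, discounted: bool = True) -> float:
        return self._tot(self.qaly, discounted)

    def total_cost(self, discounted: bool = True) -> float:
        return self._tot(self.cost, discounted)

    def cost_components(self, discounted: bool = True) -> dict[str, float]:
        return {
            "treatment": self._tot(self.cost_treatment, discounted),
            "events": self._tot(self.cost_events, discounted),
            "post_stroke": self._tot(self.cost_post_stroke, discounted),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cycle": np.arange(self.ly.size),
            "discount": self.discount,
            "ly": self.ly, "qaly": self.qaly,
            "cost_treatment": self.cost_treatment,
            "cost_events": self.cost_events,
            "cost_post_stroke": self.cost_post_stroke,
            "ly_disc": self.ly * self.discount,
            "qaly_disc": self.qaly * self.discount,
            "cost_disc": self.cost * self.discount,
        })


def trace_outcomes(trace: CohortTrace, params: ModelParameters,
                   arm: ArmSpec) -> CycleOutcomes:
    """Value a cohort trace: half-year life years and QALYs per cycle, event
    costs on state entry, post-stroke upkeep per cycle of occupancy, treatment
    costs on the on-treatment fraction, all discounted at the annual rate.

    No half-cycle correction: each row accrues a full half-year at the row's
    discount factor.
    """
    cyc = params.cycle
    u, c = params.utilities, params.costs
    mix = arm.mix if arm.mix is not None else params.mix
    occ = trace.occupancy
    n = occ.shape[0]
    discount = np.array([cyc.discount_factor(t) for t in range(n)])

    utility_vec = np.zeros(N_STATES)
    for s, fname in zip(LIVING_STATES, _UTILITY_FIELDS):
        utility_vec[s] = getattr(u, fname)

    weights = np.ones(n)
    if cyc.half_cycle_correction:
        weights[0] = weights[-1] = 0.5
    ly = occ[:, [int(s) for s in LIVING_STATES]].sum(axis=1) * cyc.cycle_length * weights
    qaly = (occ @ utility_vec) * cyc.cycle_length * weights

    cost_events = (trace.entries["new_strokes"] * c.c_acute_stroke
                   + trace.entries["deaths_stroke_acute"] * c.c_stroke_death
                   + trace.entries["new_bleeds"] * c.c_major_bleed
                   + trace.entries["deaths_bleed"] * c.c_bleed_death)
    cost_post_stroke = occ[:, State.POST_STROKE] * c.c_post_stroke * weights
    cost_treatment = (trace.on_treatment * c.per_cycle_treatment_cost(mix.frac_noac)
                      * weights)

    return CycleOutcomes(ly=ly, qaly=qaly, cost_treatment=cost_treatment,
                         cost_events=cost_events, cost_post_stroke=cost_post_stroke,
                         discount=discount)


def median_survival(trace: CohortTrace) -> float:
    """Years from entry at which living occupancy crosses 50% (linear interpolation)."""
    living = trace.living()
    below = np.nonzero(living <= 0.5)[0]
    if below.size == 0:
        raise ValueError("cohort never reaches 50% cumulative death; median undefined")
    t = int(below[0])
    if t == 0:
        return 0.0
    frac = (living[t - 1] - 0.5) / (living[t - 1] - living[t])
    return (t - 1 + frac) * 0.5


def microsimulate(params: ModelParameters, arm: ArmSpec, lifetable: LifeTable,
                  n: int, rng: np.random.Generator,
                  n_cycles: int | None = None) -> np.ndarray:
    """Individual-level simulation with the same transition rows as the cohort.

    Returns the (n_cycles+1, 8) matrix of state-occupancy fractions, the
    Monte-Carlo analogue of :func:`run_cohort`'s trace; used as an independent
    oracle for the deterministic propagation.
    """
    cyc = params.cycle
    if n_cycles is None:
        n_cycles = cyc.n_cycles_max
    states = np.full(n, int(State.AF))
    occ = np.zeros((n_cycles + 1, N_STATES))
    occ[0] = np.bincount(states, minlength=N_STATES) / n
    for t in range(n_cycles):
        age = cyc.start_age + t * cyc.cycle_length
        P = transition_matrix(params, arm, t + 1, age, lifetable)
        cum = np.cumsum(P, axis=1)
        cum[:, -1] = 1.0  # guard against floating-point shortfall
        unif = rng.random(n)
        states = (unif[:, None] <= cum[states]).argmax(axis=1)
        occ[t + 1] = np.bincount(states, minlength=N_STATES) / n
    return occ
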
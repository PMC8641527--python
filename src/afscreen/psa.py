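"""Probabilistic sensitivity analysis.

Each iteration draws every varied parameter from its distribution (betas on
a bounded support; treatment costs and the total screening cost stay fixed),
reruns the cascade-cohort-CEA pipeline and records the per-patient increments.
Because the NOAC/warfarin mix affects only treatment costs — never the
transition dynamics — one pair of cohort traces per draw serves every
requested mix.

Outputs are the cost-effectiveness plane point clouds and the acceptability
curve (fraction of draws with non-negative net monetary benefit per
willingness-to-pay value).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cascade as _cascade
from . import markov as _markov
from .lifetables import LifeTable
from .parameters import (DistributionSpec, ModelParameters, TreatmentMix,
                         ValidationError, with_overrides)

__all__ = ["PSAConfig", "PSAResult", "sample_parameters", "run_psa", "ceac",
           "MIX_FRACS"]

#: canonical treatment-mix labels
MIX_FRACS = {"noac": 1.0, "mix5050": 0.5, "warfarin": 0.0}


@dataclass(frozen=True)
class PSAConfig:
    n_iterations: int = 10_000
    seed: int = 0
    wtp_grid: tuple[float, ...] = (0.0, 500.0, 1000.0, 2000.0, 5000.0, 10_000.0,
                                   20_000.0, 50_000.0)

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if 2000.0 not in self.wtp_grid:
            object.__setattr__(self, "wtp_grid", tuple(sorted({*self.wtp_grid, 2000.0})))


def sample_parameters(params: ModelParameters, rng: np.random.Generator) -> ModelParameters:
    """One independent draw of every varied parameter.

    Parameters whose spec is ``fixed`` (treatment costs) keep their mean; the
    screening inputs are not in the distribution map at all, so total
    screening costs stay at the base value.  Raises
    :class:`~afscreen.parameters.ValidationError` when a draw lands outside
    the joint parameter invariants (the caller records and excludes it).
    """
    if not params.psa_distributions:
        raise ValidationError("no PSA distributions configured")
    overrides = {}
    for name, spec in params.psa_distributions.items():
        overrides[name] = spec.sample(rng)
    import warnings

    with warnings.catch_warnings():
        # independent draws routinely break the soft cost-ratio/persistence
        # flags; hard invariant violations still raise and are excluded
        warnings.simplefilter("ignore", UserWarning)
        return with_overrides(params, overrides)


@dataclass
class PSAResult:
    """Point clouds and summaries of one PSA run."""

    config: PSAConfig
    points: dict[str, pd.DataFrame]      # mix label -> (iteration, delta_qaly, delta_cost)
    n_excluded: int
    base_ce: dict[str, object] = field(default_factory=dict)

    def ceac(self, mix: str, wtp_grid=None) -> pd.DataFrame:
        grid = self.config.wtp_grid if wtp_grid is None else wtp_grid
        return ceac(self.points[mix], grid)

    def prob_cost_effective(self, mix: str, wtp: float) -> float:
        pts = self.points[mix]
        return float((wtp * pts["delta_qaly"] - pts["delta_cost"] >= 0).mean())

    def summary(self) -> pd.DataFrame:
        rows = []
        for mix, pts in self.points.items():
            rows.append({
                "mix": mix,
                "n": len(pts),
                "n_excluded": self.n_excluded,
                "mean_delta_qaly": pts["delta_qaly"].mean(),
                "mean_delta_cost": pts["delta_cost"].mean(),
                "prob_ce_at_2000": self.prob_cost_effective(mix, 2000.0),
            })
        return pd.DataFrame(rows)


def run_psa(params: ModelParameters, lifetable: LifeTable, config: PSAConfig,
            mixes: tuple[str, ...] = ("noac", "mix5050", "warfarin")) -> PSAResult:
    """Monte-Carlo rerun of the full pipeline, per-patient increments per mix.

    Fully reproducible from ``config.seed``.  Draws that violate parameter
    invariants are excluded (not resampled) and counted.
    """
    rng = np.random.default_rng(config.seed)
    cr = _cascade.run_cascade(params.screening)
    sc = _cascade.screening_cost_total(params.screening, cr)
    n_patients = cr.new_af_detected
    if n_patients <= 0:
        raise ValueError("cascade produced an empty cohort")
    screening_per_patient = (sc.total / n_patients
                             if params.include_screening_cost_in_icer else 0.0)

    records: dict[str, list[tuple[int, float, float]]] = {m: [] for m in mixes}
    n_excluded = 0
    for it in range(config.n_iterations):
        try:
            draw = sample_parameters(params, rng)
        except ValidationError:
            n_excluded += 1
            continue
        try:
            case_arm = _markov.screening_arm()
            base_arm = _markov.no_screening_arm()
            case_trace = _markov.run_cohort(draw, case_arm, lifetable)
            base_trace = _markov.run_cohort(draw, base_arm, lifetable)
        except _markov.ModelConsistencyError:
            n_excluded += 1
            continue
        for mix in mixes:
            tm = TreatmentMix(frac_noac=MIX_FRACS[mix])
            arm_c = _markov.screening_arm(tm)
            arm_b = _markov.no_screening_arm(tm)
            out_c = _markov.trace_outcomes(case_trace, draw, arm_c)
            out_b = _markov.trace_outcomes(base_trace, draw, arm_b)
            dq = out_c.total_qaly(True) - out_b.total_qaly(True)
            dc = (out_c.total_cost(True) - out_b.total_cost(True)
                  + screening_per_patient)
            records[mix].append((it, dq, dc))

    points = {
        mix: pd.DataFrame(recs, columns=["iteration", "delta_qaly", "delta_cost"])
        for mix, recs in records.items()
    }
    return PSAResult(config=config, points=points, n_excluded=n_excluded)


def ceac(points: pd.DataFrame, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve from per-patient plane points."""
    if len(points) == 0:
        raise ValueError("no plane points")
    rows = []
    for wtp in wtp_grid:
        prob = float((wtp * points["delta_qaly"] - points["delta_cost"] >= 0).mean())
        rows.append({"wtp": wtp, "prob_cost_effective": prob})
    return pd.DataFrame(rows)
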
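"""Age-specific background mortality.

The cohort model needs an annual death probability for every age from cohort
entry to extinction.  The national life table the evaluation was built on is
not distributed with this package, so two sources are supported:

* :func:`load_life_table` — a user-supplied delimited text file
  (``age,q_annual``);
* :func:`gompertz_life_table` + :func:`calibrate_median_survival` — a
  synthetic Gompertz–Makeham table whose level parameter is calibrated so the
  untreated no-screening cohort entering at the base-case age reaches a target
  median survival (10 years at age 55 in the base case).

The synthetic table is a stand-in: it reproduces the survival behaviour the
published base case reports, not the exact national age pattern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "GompertzParams",
    "LifeTableError",
    "CalibrationError",
    "load_life_table",
    "gompertz_life_table",
    "cycle_mortality",
    "calibrate_median_survival",
    "synthetic_life_table",
]


class LifeTableError(ValueError):
    """Malformed or invalid life-table input."""


class CalibrationError(RuntimeError):
    """Median-survival calibration could not reach the target."""


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz–Makeham hazard mu(x) = c + a * exp(b * x) at age x (per year).

    ``a`` sets the level of senescent mortality, ``b`` its exponential rise
    with age, and ``c`` an age-independent background hazard.
    """

    a: float = 5e-4
    b: float = 0.085
    c: float = 0.005

    def __post_init__(self):
        if not (self.a > 0 and self.b > 0 and self.c >= 0):
            raise LifeTableError(
                f"require a > 0, b > 0, c >= 0; got a={self.a}, b={self.b}, c={self.c}")


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities over a contiguous span of integer ages."""

    ages: np.ndarray        # contiguous, ascending integer years
    q_annual: np.ndarray    # annual death probability per age
    terminal_age: int       # q == 1 from this age on

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=int)
        q = np.asarray(self.q_annual, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "q_annual", q)
        if ages.ndim != 1 or ages.size == 0 or ages.size != q.size:
            raise LifeTableError("ages and q_annual must be matching 1-D arrays")
        if not np.all(np.diff(ages) == 1):
            gaps = ages[:-1][np.diff(ages) != 1]
            raise LifeTableError(f"ages must be contiguous; gap after age(s) {gaps.tolist()}")
        if np.any((q < 0) | (q > 1)):
            bad = ages[(q < 0) | (q > 1)]
            raise LifeTableError(
                f"q_annual outside [0, 1] at age(s) {bad.tolist()}")
        if self.terminal_age != ages[-1] or q[-1] != 1.0:
            raise LifeTableError("table must end at terminal_age with q_annual == 1")

    def q_at(self, age: float) -> float:
        """Annual death probability at ``floor(age)``; 1 beyond the terminal age."""
        a = int(math.floor(age))
        if a >= self.terminal_age:
            return 1.0
        if a < self.ages[0]:
            raise LifeTableError(f"age {age} below table start {self.ages[0]}")
        return float(self.q_annual[a - self.ages[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "q_annual": self.q_annual})

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)


def load_life_table(path: str) -> LifeTable:
    """Read an ``age,q_annual`` delimited text file into a validated table.

    The final row must carry ``q_annual = 1`` (the terminal age); gaps and
    out-of-range probabilities are errors, never silently repaired.
    """
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    if cols[:2] != ["age", "q_annual"]:
        raise LifeTableError(
            f"{path}: expected header 'age,q_annual', got {list(df.columns)}")
    ages = df.iloc[:, 0].to_numpy()
    if not np.allclose(ages, np.round(ages)):
        raise LifeTableError(f"{path}: ages must be integers")
    ages = ages.astype(int)
    q = df.iloc[:, 1].astype(float).to_numpy()
    if np.any(np.diff(ages) != 1):
        i = int(np.nonzero(np.diff(ages) != 1)[0][0])
        raise LifeTableError(
            f"{path}: missing age(s) between {ages[i]} and {ages[i + 1]}")
    if q[-1] != 1.0:
        raise LifeTableError(f"{path}: last row must have q_annual = 1 (terminal age)")
    return LifeTable(ages=ages, q_annual=q, terminal_age=int(ages[-1]))


def gompertz_life_table(params: GompertzParams, start_age: int = 55,
                        terminal_age: int = 110) -> LifeTable:
    """Tabulate q_annual(x) = 1 - exp(-(c + a e^{bx})) over [start_age, terminal_age]."""
    if start_age >= terminal_age:
        raise LifeTableError("start_age must be below terminal_age")
    ages = np.arange(start_age, terminal_age + 1)
    exponent = params.b * ages.astype(float)
    if np.max(exponent) > 700:
        raise LifeTableError("b too large: hazard overflows; use a smaller senescence rate")
    hazard = params.c + params.a * np.exp(exponent)
    q = 1.0 - np.exp(-hazard)
    q[-1] = 1.0
    return LifeTable(ages=ages, q_annual=q, terminal_age=int(ages[-1]))


def cycle_mortality(lt: LifeTable, age: float, cycle_length: float) -> float:
    """Per-cycle background death probability at ``age`` (constant-hazard conversion)."""
    from .parameters import to_cycle_probability

    return to_cycle_probability(lt.q_at(age), 1.0, cycle_length)


def _no_screening_median(lt: LifeTable, params) -> float:
    import warnings

    from .markov import median_survival, no_screening_arm, run_cohort

    with warnings.catch_warnings():
        # candidate tables far from the solution leave residual mass at the
        # age cap; the truncation warning is irrelevant mid-bisection
        warnings.simplefilter("ignore")
        trace = run_cohort(params, no_screening_arm(params.mix), lt)
    return median_survival(trace)


def calibrate_median_survival(
    start_age: int = 55,
    target_median: float = 10.0,
    b: float = 0.085,
    c: float = 0.005,
    params=None,
    terminal_age: int = 110,
    a_bracket: tuple[float, float] = (1e-6, 0.2),
    tol_years: float = 0.05,
    max_iter: int = 100,
) -> GompertzParams:
    """Find the Gompertz level ``a`` giving the target no-screening median survival.

    Runs the full Markov cohort (untreated-until-stroke arm, all event
    probabilities active) on candidate tables and bisects on ``a``, which is a
    monotone dial on mortality.  Deterministic; raises
    :class:`CalibrationError` if the bracket cannot straddle the target.
    """
    from .parameters import default_parameters

    if params is None:
        params = default_parameters()
    if int(params.cycle.start_age) != start_age:
        params = params.replace(cycle=type(params.cycle)(
            cycle_length=params.cycle.cycle_length,
            discount_rate=params.cycle.discount_rate,
            start_age=float(start_age),
            max_age=params.cycle.max_age,
        ))

    def median_for(a: float) -> float:
        lt = gompertz_life_table(GompertzParams(a=a, b=b, c=c), start_age, terminal_age)
        try:
            return _no_screening_median(lt, params)
        except ValueError:  # cohort never crosses 50% before the age cap
            return math.inf

    lo, hi = a_bracket
    m_lo, m_hi = median_for(lo), median_for(hi)  # median decreases as a grows
    if not (m_hi <= target_median <= m_lo):
        raise CalibrationError(
            f"target median {target_median} y outside achievable range "
            f"[{m_hi:.2f}, {m_lo:.2f}] y for a in {a_bracket}")
    for _ in range(max_iter):
        mid = math.sqrt(lo * hi)  # geometric bisection: a spans orders of magnitude
        m_mid = median_for(mid)
        if abs(m_mid - target_median) <= tol_years:
            return GompertzParams(a=mid, b=b, c=c)
        if m_mid > target_median:
            lo = mid
        else:
            hi = mid
    achieved = median_for(math.sqrt(lo * hi))
    raise CalibrationError(
        f"bisection exhausted after {max_iter} iterations; achieved median "
        f"{achieved:.3f} y vs target {target_median} y")


def synthetic_life_table(start_age: int = 55, target_median: float = 10.0,
                         b: float = 0.085, c: float = 0.005,
                         params=None, terminal_age: int = 110) -> LifeTable:
    """Calibrated synthetic background-mortality table (the default model input)."""
    gp = calibrate_median_survival(start_age=start_age, target_median=target_median,
                                   b=b, c=c, params=params, terminal_age=terminal_age)
    return gompertz_life_table(gp, start_age, terminal_age)
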
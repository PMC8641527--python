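"""Decision-tree screening cascade: population -> newly detected AF cases.

One-time systematic screening of the national 55+ population: attendees are
screened with a single-lead ECG device; among attendees with AF, the fraction
whose AF was previously unknown are the potential new diagnoses; device
sensitivity determines how many are actually detected.  Screen-positives are
confirmed by a cardiologist; imperfect specificity generates false positives
that incur confirmation costs but do not enter the modelled cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .parameters import ScreeningParams

__all__ = ["CascadeResult", "ScreeningCostBreakdown", "run_cascade",
           "screening_cost_total", "round_half_up"]


def round_half_up(x: float) -> int:
    """Round to the nearest integer with exact halves rounding up (31,686.5 -> 31,687)."""
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CascadeResult:
    """Person flows through the screening decision tree.

    Intermediate counts are kept fractional (expected values); only the final
    detected count is rounded, half-up.
    """

    attended: float
    prevalent_af_attending: float
    known_af: float
    new_af_true: float
    new_af_detected: int
    false_positives: float

    def __post_init__(self):
        if not (0 <= self.new_af_detected <= self.new_af_true + 0.5
                and self.new_af_true <= self.prevalent_af_attending + 1e-9
                and self.prevalent_af_attending <= self.attended + 1e-9):
            raise ValueError("cascade counts violate detected <= new <= prevalent <= attended")


@dataclass(frozen=True)
class ScreeningCostBreakdown:
    """Cost components of the one-time screening session (US$)."""

    devices: float
    contacts: float
    confirmations: float
    total: float
    per_screened: float | None  # None when nobody attended


def run_cascade(sp: ScreeningParams) -> CascadeResult:
    """Run the decision tree for a single screening session.

    attended = population x attendance; prevalent AF among attendees =
    attended x prevalence; previously unknown AF = prevalent x unknown_af;
    detected = unknown x sensitivity (rounded half-up); false positives =
    non-AF attendees x (1 - specificity).
    """
    attended = sp.population * sp.attendance
    prevalent = attended * sp.prevalence
    known = prevalent * (1.0 - sp.unknown_af)
    new_true = prevalent * sp.unknown_af
    detected = round_half_up(new_true * sp.sensitivity)
    false_pos = (attended - prevalent) * (1.0 - sp.specificity)
    return CascadeResult(
        attended=attended,
        prevalent_af_attending=prevalent,
        known_af=known,
        new_af_true=new_true,
        new_af_detected=detected,
        false_positives=false_pos,
    )


def screening_cost_total(sp: ScreeningParams, cr: CascadeResult) -> ScreeningCostBreakdown:
    """Cost of the screening session: devices + contacts + confirmations.

    Device costs are US$ (one device per clinic, one-year use share); contact
    and confirmation costs are int$ per person and are converted to US$ with
    ``sp.intdollar_to_usd``.  Confirmations cover true detections plus false
    positives.
    """
    f = sp.intdollar_to_usd
    devices = sp.n_clinics * sp.device_cost_year
    contacts = cr.attended * sp.contact_cost * f
    confirmations = (cr.new_af_detected + cr.false_positives) * sp.confirmation_cost * f
    total = devices + contacts + confirmations
    per_screened = total / cr.attended if cr.attended > 0 else None
    return ScreeningCostBreakdown(
        devices=devices, contacts=contacts, confirmations=confirmations,
        total=total, per_screened=per_screened,
    )
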
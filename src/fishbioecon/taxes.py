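"""Pigouvian tax instruments that steer an open-access fleet to a target regime.

Under open access, boats enter until revenue equals cost.  A regulator can
relocate that zero-rent equilibrium onto a chosen target point (MSY, MEY or
a discounted OSY optimum) with either instrument:

* landing tax T per tonne:   (p - T) H_target = c E_target
  =>  T = p - c E_target / H_target
* effort tax T per boat-year:  p H_target = (c + T) E_target
  =>  T = p H_target / E_target - c

Both are static equilibrium identities; no phase-in dynamics are modelled.
A target beyond the open-access effort would need a subsidy — the negative
tax is returned flagged rather than clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

from .control import discounted_optimum
from .economics import (
    EconomicParams,
    ReferencePoint,
    mey_point,
    msy_point,
)
from .production import BiologicalParams

__all__ = ["TaxSchedule", "landing_tax", "effort_tax", "tax_table"]


@dataclass(frozen=True)
class TaxSchedule:
    """Landing and effort tax levels that make one regime the open-access outcome."""

    regime: str  # MSY | MEY | OSY
    landing_tax: float  # OMR per tonne
    effort_tax: float  # OMR per boat-year
    target_effort: float  # boats
    target_harvest: float  # tonnes/year
    subsidy: bool = False  # True when a negative tax (subsidy) is required


def landing_tax(econ: EconomicParams, target: ReferencePoint) -> float:
    """Per-tonne tax T = p - c·E/H placing open access at ``target``.

    After the tax, (p - T)·H equals c·E at the target exactly.
    """
    if target.harvest <= 0:
        raise ValueError(f"target harvest must be positive, got {target.harvest}")
    return econ.price - econ.unit_cost * target.effort / target.harvest


def effort_tax(econ: EconomicParams, target: ReferencePoint) -> float:
    """Per-boat tax T = p·H/E - c placing open access at ``target``.

    After the tax, p·H equals (c + T)·E at the target exactly.
    """
    if target.effort <= 0:
        raise ValueError(f"target effort must be positive, got {target.effort}")
    return econ.price * target.harvest / target.effort - econ.unit_cost


def _schedule(regime: str, econ: EconomicParams, target: ReferencePoint) -> TaxSchedule:
    lt = landing_tax(econ, target)
    et = effort_tax(econ, target)
    return TaxSchedule(
        regime=regime,
        landing_tax=lt,
        effort_tax=et,
        target_effort=target.effort,
        target_harvest=target.harvest,
        subsidy=lt < 0 or et < 0,
    )


def tax_table(
    bio: BiologicalParams, econ: EconomicParams, osy_delta: float = 0.10
) -> list[TaxSchedule]:
    """Tax schedules targeting MSY, MEY and the OSY optimum at ``osy_delta``."""
    schedules = [
        _schedule("MSY", econ, msy_point(bio, econ)),
        _schedule("MEY", econ, mey_point(bio, econ)),
    ]
    osy = discounted_optimum(bio, econ, osy_delta)
    osy_ref = ReferencePoint(
        regime="OSY",
        effort=osy.e_star,
        harvest=osy.h_star,
        biomass=osy.x_star,
        total_revenue=econ.price * osy.h_star,
        total_cost=econ.unit_cost * osy.e_star,
        rent=osy.profit,
    )
    schedules.append(_schedule("OSY", econ, osy_ref))
    return schedules
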
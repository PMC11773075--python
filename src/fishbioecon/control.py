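"""Discounted optimal sustainable yield (OSY).

Maximizing the present value of the rent stream

    PV = ∫ exp(-δt) [p - c/(q x)] H dt

subject to logistic dynamics leads, along the singular (interior) path, to
the golden-rule marginal condition

    F'(x) + c F(x) / (q x^2 (p - c/(q x))) = δ,      F(x) = r x (1 - x/K),

whose positive root has the closed form (theta = c/(p q K), s = δ/r)

    x* = (K/4) [ (1 + theta - s) + sqrt((1 + theta - s)^2 + 8 theta s) ].

Limiting cases anchor the formula: δ = 0 gives the MEY stock K/2 + c/(2pq)
(rent maximization), δ → ∞ gives the open-access stock c/(pq) (a myopic
owner dissipates the rent).  Equilibrium harvest, effort, sustained profit
and PV = profit/δ follow from x*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .economics import EconomicParams, cost_price_ratio
from .production import BiologicalParams

__all__ = [
    "DiscountedOptimum",
    "optimal_stock",
    "discounted_optimum",
    "discount_sweep",
    "match_delta_to_taxes",
]


@dataclass(frozen=True)
class DiscountedOptimum:
    """Singular-path optimum at one discount rate.

    ``present_value`` is ``math.inf`` (with ``pv_infinite`` set) at delta = 0,
    where the sustained rent stream is undiscounted.
    """

    delta: float  # discount rate, 1/year
    x_star: float  # optimal stock, tonnes
    h_star: float  # optimal sustained harvest, tonnes/year
    e_star: float  # optimal effort, boats
    profit: float  # sustained rent, OMR/year
    present_value: float  # OMR
    pv_infinite: bool = False
    collapsed: bool = False  # x* pinned at the open-access floor


def optimal_stock(
    bio: BiologicalParams, econ: EconomicParams, delta: float
) -> float:
    """Optimal stock x* for discount rate delta (Clark singular solution).

    Continuous and non-increasing in delta, with x*(0) = X_MEY and
    x*(inf) = c/(pq).
    """
    if delta < 0:
        raise ValueError(f"discount rate must be >= 0, got {delta}")
    if bio.r == 0:
        raise ValueError("optimal stock undefined for r = 0 (no growth to harvest)")
    theta = cost_price_ratio(bio, econ)
    if theta >= 1.0:
        raise ValueError(
            f"fishing is never profitable (c/(pqK) = {theta:.3g} >= 1)"
        )
    s = delta / bio.r
    base = 1.0 + theta - s
    return (bio.K / 4.0) * (base + math.sqrt(base * base + 8.0 * theta * s))


def discounted_optimum(
    bio: BiologicalParams, econ: EconomicParams, delta: float
) -> DiscountedOptimum:
    """Full OSY point: stock, harvest H* = F(x*), effort E* = H*/(q x*),
    sustained profit [p - c/(q x*)] H*, and present value profit/delta."""
    x = optimal_stock(bio, econ, delta)
    h = bio.r * x * (1.0 - x / bio.K)
    e = h / (bio.q * x) if x > 0 else 0.0
    margin = econ.price - econ.unit_cost / (bio.q * x) if x > 0 else 0.0
    profit = margin * h
    if delta > 0:
        pv, pv_inf = profit / delta, False
    else:
        pv, pv_inf = math.inf, True
    theta = cost_price_ratio(bio, econ)
    collapsed = x <= theta * bio.K * (1.0 + 1e-12)
    return DiscountedOptimum(
        delta=delta,
        x_star=x,
        h_star=h,
        e_star=e,
        profit=profit,
        present_value=pv,
        pv_infinite=pv_inf,
        collapsed=collapsed,
    )


def discount_sweep(
    bio: BiologicalParams,
    econ: EconomicParams,
    deltas: Iterable[float],
) -> list[DiscountedOptimum]:
    """One :class:`DiscountedOptimum` per discount rate, in input order."""
    return [discounted_optimum(bio, econ, d) for d in deltas]


def match_delta_to_taxes(
    bio: BiologicalParams,
    econ: EconomicParams,
    landing_tax_target: float,
    effort_tax_target: float,
    deltas: Sequence[float] | None = None,
) -> float:
    """Grid-scan the discount rate whose OSY taxes best match a given pair.

    Diagnostic helper for reconciling an OSY tax column whose underlying
    discount rate is not reported: returns the delta minimizing the summed
    relative discrepancy of the landing and effort taxes.
    """
    from .taxes import effort_tax, landing_tax

    if deltas is None:
        deltas = [i / 1000.0 for i in range(1, 1001)]
    best_d, best_err = None, math.inf
    for d in deltas:
        opt = discounted_optimum(bio, econ, d)
        if opt.h_star <= 0 or opt.e_star <= 0:
            continue
        from .economics import ReferencePoint

        target = ReferencePoint(
            regime="OSY",
            effort=opt.e_star,
            harvest=opt.h_star,
            biomass=opt.x_star,
            total_revenue=econ.price * opt.h_star,
            total_cost=econ.unit_cost * opt.e_star,
            rent=opt.profit,
        )
        lt = landing_tax(econ, target)
        et = effort_tax(econ, target)
        err = abs(lt - landing_tax_target) / max(abs(landing_tax_target), 1e-12)
        err += abs(et - effort_tax_target) / max(abs(effort_tax_target), 1e-12)
        if err < best_err:
            best_d, best_err = d, err
    if best_d is None:
        raise ValueError("no feasible discount rate in the scanned grid")
    return best_d
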
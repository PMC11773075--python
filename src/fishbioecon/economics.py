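"""Static bioeconomic reference points: MSY, MEY and open-access equilibrium.

With sustainable revenue TR(E) = p·H(E) on the Schaefer yield parabola and
linear cost TC(E) = c·E, the three classical regimes have closed forms in
the dimensionless cost-price ratio ``theta = c/(p q K)`` (the open-access
biomass as a fraction of K):

====== ======================= =========================== ==================
regime effort                  harvest                     biomass
====== ======================= =========================== ==================
MSY    r/(2q)                  rK/4                        K/2
MEY    (r/2q)(1 - theta)       (rK/4)(1 - theta^2)         K/2 + c/(2pq)
OAE    (r/q)(1 - theta)        (rc/(pq))(1 - theta)        c/(pq)
====== ======================= =========================== ==================

MEY maximizes the sustainable rent pi(E) = TR - TC; open access dissipates
it (TR = TC exactly); E_OAE = 2 E_MEY always.  theta >= 1 means fishing is
never profitable: the closed forms go negative, so those regimes are
returned as flagged zero-effort points rather than nonsense.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .production import BiologicalParams, equilibrium_yield

__all__ = [
    "EconomicParams",
    "ReferencePoint",
    "cost_price_ratio",
    "msy_point",
    "mey_point",
    "oae_point",
    "derive_price_cost",
    "economics_at_effort",
    "reference_table",
]


@dataclass(frozen=True)
class EconomicParams:
    """Ex-vessel price p (OMR/tonne, > 0) and unit effort cost c (OMR/boat-year, >= 0)."""

    price: float
    unit_cost: float

    def __post_init__(self) -> None:
        if not self.price > 0:
            raise ValueError(f"price must be positive, got {self.price}")
        if self.unit_cost < 0:
            raise ValueError(f"unit cost must be >= 0, got {self.unit_cost}")


@dataclass(frozen=True)
class ReferencePoint:
    """A management regime with its effort, harvest, biomass and economics."""

    regime: str  # MSY | MEY | OAE | OSY
    effort: float  # boats
    harvest: float  # tonnes/year
    biomass: float  # tonnes
    total_revenue: float  # OMR/year
    total_cost: float  # OMR/year
    rent: float  # OMR/year
    feasible: bool = True  # False when theta >= 1 forced a zero-effort point


def cost_price_ratio(bio: BiologicalParams, econ: EconomicParams) -> float:
    """theta = c/(p q K), the open-access biomass depletion fraction."""
    return econ.unit_cost / (econ.price * bio.q * bio.K)


def _economics(regime, effort, harvest, biomass, econ, feasible=True):
    tr = econ.price * harvest
    tc = econ.unit_cost * effort
    return ReferencePoint(
        regime=regime,
        effort=effort,
        harvest=harvest,
        biomass=biomass,
        total_revenue=tr,
        total_cost=tc,
        rent=tr - tc,
        feasible=feasible,
    )


def msy_point(bio: BiologicalParams, econ: EconomicParams) -> ReferencePoint:
    """Maximum-sustainable-yield regime: E = r/(2q), H = rK/4, X = K/2."""
    effort = 0.0 if bio.r == 0 else bio.e_msy
    return _economics("MSY", effort, bio.msy, bio.K / 2.0, econ)


def mey_point(bio: BiologicalParams, econ: EconomicParams) -> ReferencePoint:
    """Maximum-economic-yield (rent-maximizing) regime.

    E = (r/2q)(1 - theta), H = (rK/4)(1 - theta^2), X = K/2 + c/(2pq).
    For theta >= 1 the fishery is never profitable and a flagged zero-effort
    point at the unfished stock is returned.
    """
    theta = cost_price_ratio(bio, econ)
    if theta >= 1.0:
        return _economics("MEY", 0.0, 0.0, bio.K, econ, feasible=False)
    effort = 0.0 if bio.r == 0 else bio.e_msy * (1.0 - theta)
    harvest = bio.msy * (1.0 - theta**2)
    biomass = bio.K / 2.0 + econ.unit_cost / (2.0 * econ.price * bio.q)
    return _economics("MEY", effort, harvest, biomass, econ)


def oae_point(bio: BiologicalParams, econ: EconomicParams) -> ReferencePoint:
    """Open-access equilibrium: entry until rent is fully dissipated.

    E = (r/q)(1 - theta), H = (rc/(pq))(1 - theta), X = c/(pq); TR = TC by
    construction.  theta >= 1 means no entry ever pays: zero-effort point.
    """
    theta = cost_price_ratio(bio, econ)
    if theta >= 1.0:
        return _economics("OAE", 0.0, 0.0, bio.K, econ, feasible=False)
    effort = 0.0 if bio.r == 0 else bio.e_extinction * (1.0 - theta)
    biomass = theta * bio.K  # = c/(pq)
    harvest = bio.r * biomass * (1.0 - theta)
    point = _economics("OAE", effort, harvest, biomass, econ)
    # rent is zero exactly in exact arithmetic; pin it against rounding noise
    return ReferencePoint(
        regime=point.regime,
        effort=point.effort,
        harvest=point.harvest,
        biomass=point.biomass,
        total_revenue=point.total_revenue,
        total_cost=point.total_cost,
        rent=0.0,
        feasible=point.feasible,
    )


def derive_price_cost(ref: ReferencePoint) -> EconomicParams:
    """Back out (p, c) from a reference point: p = TR/H, c = TC/E.

    Useful when only a published regime table (revenue, cost, harvest,
    effort) is available rather than the underlying market survey.
    """
    if ref.harvest <= 0 or ref.effort <= 0:
        raise ValueError(
            "price/cost derivation needs positive harvest and effort "
            f"(got H={ref.harvest}, E={ref.effort})"
        )
    return EconomicParams(
        price=ref.total_revenue / ref.harvest,
        unit_cost=ref.total_cost / ref.effort,
    )


def economics_at_effort(
    effort: float, bio: BiologicalParams, econ: EconomicParams
) -> tuple[float, float, float]:
    """(TR, TC, rent) at a sustained effort level on the equilibrium yield curve.

    Warns (via ValueError-free return) only inside [0, r/q]; outside that
    range the yield parabola is negative and a ValueError is raised.
    """
    if effort < 0 or (bio.r > 0 and effort > bio.e_extinction):
        raise ValueError(
            f"effort {effort} outside sustainable range [0, {bio.e_extinction:.6g}]"
        )
    tr = econ.price * equilibrium_yield(effort, bio)
    tc = econ.unit_cost * effort
    return tr, tc, tr - tc


def reference_table(
    bio: BiologicalParams, econ: EconomicParams
) -> list[ReferencePoint]:
    """The three static regimes (MSY, MEY, OAE) with full economics.

    A discounted OSY row can be appended from
    :func:`fishbioecon.control.discounted_optimum`.
    """
    return [msy_point(bio, econ), mey_point(bio, econ), oae_point(bio, econ)]
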
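"""Published parameter sets for four commercially important Omani stocks.

Surplus-production parameters (K, q, r) and initial-proportion values as
estimated from the 1990–2020 national catch–effort statistics for Indian
mackerel (*Rastrelliger kanagurta*), yellowfin tuna (*Thunnus albacares*),
kingfish (*Scomberomorus commerson*) and Indian oil sardine (*Sardinella
longiceps*), together with each stock's MSY-regime economics (effort,
harvest, revenue, cost in Omani rial).  The ex-vessel price and unit effort
cost implied by an MSY row are recovered with
:func:`fishbioecon.economics.derive_price_cost`, which keeps the whole
reference-point/tax pipeline runnable without the underlying market survey.
"""

from __future__ import annotations

from dataclasses import dataclass

from .economics import EconomicParams, ReferencePoint, derive_price_cost
from .production import BiologicalParams

__all__ = ["SpeciesPreset", "SPECIES", "species_names", "get_preset"]


@dataclass(frozen=True)
class SpeciesPreset:
    """Fitted biology plus the published MSY-regime economics for one stock."""

    name: str
    label: str
    params: BiologicalParams
    ip: float  # initial proportion: first-year catch / maximum catch
    replacement_yield: float  # tonnes/year, surplus production at final biomass
    final_biomass: float  # tonnes, last assessed year
    msy_row: ReferencePoint  # published MSY-regime effort/harvest/economics

    @property
    def econ(self) -> EconomicParams:
        """Price and unit cost implied by the MSY-row revenue and cost."""
        return derive_price_cost(self.msy_row)


def _msy_row(effort, harvest, biomass, tr, tc):
    return ReferencePoint(
        regime="MSY",
        effort=effort,
        harvest=harvest,
        biomass=biomass,
        total_revenue=tr,
        total_cost=tc,
        rent=tr - tc,
    )


SPECIES: dict[str, SpeciesPreset] = {
    "R_kanagurta": SpeciesPreset(
        name="R_kanagurta",
        label="Rastrelliger kanagurta",
        params=BiologicalParams(K=163745.5, r=0.260469, q=2.177e-05),
        ip=0.05,
        replacement_yield=7570.42,
        final_biomass=37782.5,
        msy_row=_msy_row(5982, 10662.65, 81872.75, 102357373.5, 51516277.33),
    ),
    "T_albacares": SpeciesPreset(
        name="T_albacares",
        label="Thunnus albacares",
        params=BiologicalParams(K=463266.9, r=0.11217, q=8.48e-06),
        ip=0.42,
        replacement_yield=5170.44,
        final_biomass=51911.62,
        msy_row=_msy_row(6614, 12991.16, 231633.45, 321452570.5, 44553193.84),
    ),
    "S_commerson": SpeciesPreset(
        name="S_commerson",
        label="Scomberomorus commerson",
        params=BiologicalParams(K=79007.23, r=0.130359, q=2.93e-05),
        ip=1.0,
        replacement_yield=214.865,
        final_biomass=23323.35,
        msy_row=_msy_row(2222, 2574.83, 39503.62, 3814143.989, 2634359.44),
    ),
    "S_longiceps": SpeciesPreset(
        name="S_longiceps",
        label="Sardinella longiceps",
        params=BiologicalParams(K=4675602.0, r=0.116227, q=8.41e-06),
        ip=0.095,
        replacement_yield=81545.8,
        final_biomass=859669.6,
        msy_row=_msy_row(6913, 135857.80, 2337801.00, 839138246.4, 87286012.84),
    ),
}


def species_names() -> list[str]:
    return list(SPECIES)


def get_preset(name: str) -> SpeciesPreset:
    """Look up a preset by key or by full species label (case-insensitive)."""
    if name in SPECIES:
        return SPECIES[name]
    for preset in SPECIES.values():
        if preset.label.lower() == name.lower():
            return preset
    raise KeyError(
        f"unknown species {name!r}; available: {', '.join(SPECIES)}"
    )
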
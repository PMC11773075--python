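"""Reference points and rent accounting against published regime tables."""

import numpy as np
import pytest

from fishbioecon import (
    BiologicalParams,
    EconomicParams,
    ReferencePoint,
    cost_price_ratio,
    derive_price_cost,
    economics_at_effort,
    equilibrium_yield,
    mey_point,
    msy_point,
    oae_point,
    reference_table,
)
from conftest import random_parameter_draw


class TestDerivePriceCost:
    def test_mackerel_msy_row(self, mackerel):
        econ = derive_price_cost(mackerel.msy_row)
        assert econ.price == pytest.approx(9599.6, rel=1e-4)
        assert econ.unit_cost == pytest.approx(8611.9, rel=1e-4)

    def test_kingfish_msy_row(self):
        from fishbioecon import SPECIES

        econ = derive_price_cost(SPECIES["S_commerson"].msy_row)
        assert econ.price == pytest.approx(1481.3, rel=1e-4)
        assert econ.unit_cost == pytest.approx(1185.6, rel=1e-4)

    def test_round_trip_identity(self):
        ref = ReferencePoint(
            regime="MSY", effort=100.0, harvest=50.0, biomass=1.0,
            total_revenue=123.0 * 50.0, total_cost=7.0 * 100.0,
            rent=123.0 * 50.0 - 700.0,
        )
        econ = derive_price_cost(ref)
        assert econ.price == 123.0
        assert econ.unit_cost == 7.0

    def test_degenerate_rows_rejected(self):
        bad = ReferencePoint("MSY", 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            derive_price_cost(bad)


class TestMsyPoint:
    def test_published_msy_row(self, mackerel_bio, mackerel_econ):
        pt = msy_point(mackerel_bio, mackerel_econ)
        assert pt.effort == pytest.approx(5982, rel=5e-3)
        assert pt.harvest == pytest.approx(10662.65, rel=5e-3)
        assert pt.biomass == pytest.approx(81872.75, rel=5e-3)

    def test_no_growth_limit(self):
        bio = BiologicalParams(K=1e4, r=0.0, q=1e-4)
        pt = msy_point(bio, EconomicParams(price=10.0, unit_cost=1.0))
        assert pt.effort == 0.0
        assert pt.harvest == 0.0
        assert pt.biomass == 5e3

    def test_harvest_is_parabola_maximum(self, mackerel_bio, mackerel_econ):
        grid = np.linspace(0, mackerel_bio.e_extinction, 50001)
        assert msy_point(mackerel_bio, mackerel_econ).harvest == pytest.approx(
            float(np.max(equilibrium_yield(grid, mackerel_bio))), rel=1e-8
        )


class TestMeyPoint:
    def test_published_mey_row(self, mackerel_bio, mackerel_econ):
        pt = mey_point(mackerel_bio, mackerel_econ)
        assert pt.effort == pytest.approx(4476.32, rel=5e-3)
        assert pt.harvest == pytest.approx(9987.41, rel=5e-3)
        assert pt.biomass == pytest.approx(102475.95, rel=5e-3)
        assert pt.rent == pytest.approx(57323108.04, rel=5e-3)

    def test_costless_limit_is_msy(self, mackerel_bio):
        econ = EconomicParams(price=100.0, unit_cost=0.0)
        mey = mey_point(mackerel_bio, econ)
        msy = msy_point(mackerel_bio, econ)
        assert mey.effort == pytest.approx(msy.effort)
        assert mey.harvest == pytest.approx(msy.harvest)
        assert mey.biomass == pytest.approx(msy.biomass)

    def test_rent_maximizes_over_effort_grid(self, mackerel_bio, mackerel_econ):
        mey = mey_point(mackerel_bio, mackerel_econ)
        grid = np.linspace(0, mackerel_bio.e_extinction, 20001)
        rents = (
            mackerel_econ.price * equilibrium_yield(grid, mackerel_bio)
            - mackerel_econ.unit_cost * grid
        )
        assert mey.rent >= float(np.max(rents)) - 1e-6 * abs(mey.rent)

    def test_never_profitable_fishery_flagged(self, mackerel_bio):
        econ = EconomicParams(price=1.0, unit_cost=1e9)
        pt = mey_point(mackerel_bio, econ)
        assert not pt.feasible
        assert pt.effort == 0.0


class TestOaePoint:
    def test_published_oae_rows(self, mackerel_bio, mackerel_econ):
        pt = oae_point(mackerel_bio, mackerel_econ)
        assert pt.effort == pytest.approx(8952.63, rel=5e-3)
        assert pt.harvest == pytest.approx(8032.04, rel=5e-3)
        assert pt.rent == 0.0

    def test_yellowfin_oae_harvest(self):
        from fishbioecon import SPECIES

        p = SPECIES["T_albacares"]
        pt = oae_point(p.params, p.econ)
        assert pt.harvest == pytest.approx(3351.58, rel=5e-3)

    def test_costless_open_access_collapses_stock(self, mackerel_bio):
        econ = EconomicParams(price=100.0, unit_cost=0.0)
        pt = oae_point(mackerel_bio, econ)
        assert pt.effort == pytest.approx(mackerel_bio.e_extinction)
        assert pt.harvest == 0.0
        assert pt.biomass == 0.0

    def test_revenue_equals_cost(self, all_presets):
        for preset in all_presets:
            pt = oae_point(preset.params, preset.econ)
            assert pt.total_revenue == pytest.approx(pt.total_cost, rel=1e-9)


class TestAlgebraicStructure:
    def test_open_access_effort_twice_mey_effort(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            K, r, q, price, c = random_parameter_draw(rng)
            bio = BiologicalParams(K=K, r=r, q=q)
            econ = EconomicParams(price=price, unit_cost=c)
            mey, oae = mey_point(bio, econ), oae_point(bio, econ)
            assert oae.effort == pytest.approx(2 * mey.effort, rel=1e-12)
            # X_OAE = c/(pq) = 2 X_MEY - K
            assert oae.biomass == pytest.approx(c / (price * q), rel=1e-9)
            assert oae.biomass == pytest.approx(2 * mey.biomass - K, rel=1e-9)

    def test_harvests_bounded_by_msy(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            K, r, q, price, c = random_parameter_draw(rng)
            bio = BiologicalParams(K=K, r=r, q=q)
            econ = EconomicParams(price=price, unit_cost=c)
            for pt in reference_table(bio, econ):
                assert -1e-9 <= pt.harvest <= bio.msy * (1 + 1e-12)

    def test_rising_cost_lowers_effort_raises_biomass(self, mackerel_bio):
        price = 9599.6
        efforts_mey, biomasses_mey, efforts_oae = [], [], []
        for c in (1000.0, 4000.0, 8000.0, 16000.0):
            econ = EconomicParams(price=price, unit_cost=c)
            mey, oae = mey_point(mackerel_bio, econ), oae_point(mackerel_bio, econ)
            efforts_mey.append(mey.effort)
            biomasses_mey.append(mey.biomass)
            efforts_oae.append(oae.effort)
        assert np.all(np.diff(efforts_mey) < 0)
        assert np.all(np.diff(efforts_oae) < 0)
        assert np.all(np.diff(biomasses_mey) > 0)


class TestEconomicsAtEffort:
    def test_zero_effort(self, mackerel_bio, mackerel_econ):
        assert economics_at_effort(0.0, mackerel_bio, mackerel_econ) == (0.0, 0.0, 0.0)

    def test_rent_zero_at_open_access(self, mackerel_bio, mackerel_econ):
        oae = oae_point(mackerel_bio, mackerel_econ)
        _, _, rent = economics_at_effort(oae.effort, mackerel_bio, mackerel_econ)
        assert rent == pytest.approx(0.0, abs=1e-6 * oae.total_revenue)

    def test_published_mey_rent(self, mackerel_bio, mackerel_econ):
        mey = mey_point(mackerel_bio, mackerel_econ)
        _, _, rent = economics_at_effort(mey.effort, mackerel_bio, mackerel_econ)
        assert rent == pytest.approx(57323108, rel=5e-3)

    def test_effort_beyond_extinction_rejected(self, mackerel_bio, mackerel_econ):
        with pytest.raises(ValueError):
            economics_at_effort(
                1.1 * mackerel_bio.e_extinction, mackerel_bio, mackerel_econ
            )


class TestReferenceTable:
    def test_rent_accounting_consistent(self, all_presets):
        for preset in all_presets:
            for pt in reference_table(preset.params, preset.econ):
                assert pt.rent == pytest.approx(
                    pt.total_revenue - pt.total_cost, rel=1e-9, abs=1e-6
                )

    def test_mey_rent_exceeds_msy_rent(self, all_presets):
        # rent maximization beats yield maximization for every stock
        for preset in all_presets:
            pts = {p.regime: p for p in reference_table(preset.params, preset.econ)}
            assert pts["MEY"].rent >= pts["MSY"].rent

    def test_theta_below_one_for_all_presets(self, all_presets):
        for preset in all_presets:
            assert 0 < cost_price_ratio(preset.params, preset.econ) < 1
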
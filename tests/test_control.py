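"""Discounted optimal yield: closed form vs golden-rule oracle and limits."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from fishbioecon import (
    BiologicalParams,
    EconomicParams,
    cost_price_ratio,
    discount_sweep,
    discounted_optimum,
    mey_point,
    optimal_stock,
)
from conftest import random_parameter_draw


def golden_rule_root(bio, econ, delta):
    """Independent numerical solution of the marginal condition
    F'(x) + c F(x) / (q x^2 (p - c/(qx))) = delta."""
    K, r, q = bio.K, bio.r, bio.q
    p, c = econ.price, econ.unit_cost

    def g(x):
        growth = r * x * (1 - x / K)
        return r * (1 - 2 * x / K) + c * growth / (q * x * x * (p - c / (q * x))) - delta

    theta = cost_price_ratio(bio, econ)
    lo = theta * K * (1 + 1e-7)  # just above the zero-margin stock
    hi = K / 2 * (1 + theta) * 1.000001  # just above the MEY stock
    return brentq(g, lo, hi, xtol=1e-12 * K)


class TestOptimalStock:
    def test_zero_discount_gives_mey_stock(self, mackerel_bio, mackerel_econ):
        mey = mey_point(mackerel_bio, mackerel_econ)
        assert optimal_stock(mackerel_bio, mackerel_econ, 0.0) == pytest.approx(
            mey.biomass, rel=1e-12
        )

    def test_myopic_limit_is_open_access_stock(self, mackerel_bio, mackerel_econ):
        theta = cost_price_ratio(mackerel_bio, mackerel_econ)
        x_inf = optimal_stock(mackerel_bio, mackerel_econ, 1e6 * mackerel_bio.r)
        assert x_inf == pytest.approx(theta * mackerel_bio.K, rel=1e-3)

    def test_matches_golden_rule_oracle(self, mackerel_bio, mackerel_econ):
        for delta in (0.01, 0.05, 0.1, 0.2, 0.5, 1.0):
            assert optimal_stock(mackerel_bio, mackerel_econ, delta) == pytest.approx(
                golden_rule_root(mackerel_bio, mackerel_econ, delta), rel=1e-6
            )

    def test_oracle_agreement_over_random_draws(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            K, r, q, price, c = random_parameter_draw(rng)
            bio = BiologicalParams(K=K, r=r, q=q)
            econ = EconomicParams(price=price, unit_cost=c)
            delta = rng.uniform(1e-3, 1.0)
            assert optimal_stock(bio, econ, delta) == pytest.approx(
                golden_rule_root(bio, econ, delta), rel=1e-6
            )

    def test_invalid_inputs(self, mackerel_bio, mackerel_econ):
        with pytest.raises(ValueError):
            optimal_stock(mackerel_bio, mackerel_econ, -0.1)
        flat = BiologicalParams(K=1e4, r=0.0, q=1e-4)
        with pytest.raises(ValueError):
            optimal_stock(flat, mackerel_econ, 0.1)
        with pytest.raises(ValueError):
            optimal_stock(
                mackerel_bio, EconomicParams(price=1.0, unit_cost=1e12), 0.1
            )


class TestDiscountedOptimum:
    def test_zero_discount_recovers_mey_triple(self, mackerel_bio, mackerel_econ):
        mey = mey_point(mackerel_bio, mackerel_econ)
        opt = discounted_optimum(mackerel_bio, mackerel_econ, 0.0)
        assert opt.x_star == pytest.approx(mey.biomass, rel=1e-12)
        assert opt.h_star == pytest.approx(mey.harvest, rel=1e-9)
        assert opt.e_star == pytest.approx(mey.effort, rel=1e-9)
        assert opt.profit == pytest.approx(mey.rent, rel=1e-9)
        assert opt.profit == pytest.approx(57323108, rel=5e-3)
        assert opt.pv_infinite and math.isinf(opt.present_value)

    def test_present_value_identity(self, mackerel_bio, mackerel_econ):
        for delta in (0.05, 0.1, 0.3):
            opt = discounted_optimum(mackerel_bio, mackerel_econ, delta)
            assert opt.present_value * delta == pytest.approx(opt.profit, rel=1e-12)

    def test_profit_ten_at_ten_percent_gives_pv_hundred(self):
        # PV = profit / delta on a contrived fishery scaled to profit 10
        bio = BiologicalParams(K=1e4, r=0.5, q=1e-4)
        econ = EconomicParams(price=1.0, unit_cost=0.1)
        opt = discounted_optimum(bio, econ, 0.1)
        scale = 10.0 / opt.profit
        assert opt.present_value * scale == pytest.approx(100.0, rel=1e-9)

    def test_stock_strictly_between_clark_bounds_at_delta_r(
        self, mackerel_bio, mackerel_econ
    ):
        theta = cost_price_ratio(mackerel_bio, mackerel_econ)
        mey = mey_point(mackerel_bio, mackerel_econ)
        opt = discounted_optimum(mackerel_bio, mackerel_econ, mackerel_bio.r)
        assert theta * mackerel_bio.K < opt.x_star < mey.biomass
        assert not opt.collapsed

    def test_harvest_effort_consistency(self, mackerel_bio, mackerel_econ):
        opt = discounted_optimum(mackerel_bio, mackerel_econ, 0.1)
        expected_h = mackerel_bio.r * opt.x_star * (1 - opt.x_star / mackerel_bio.K)
        assert opt.h_star == pytest.approx(expected_h, rel=1e-12)
        assert opt.e_star == pytest.approx(
            opt.h_star / (mackerel_bio.q * opt.x_star), rel=1e-12
        )


class TestDiscountSweep:
    def test_comparative_statics(self, all_presets):
        deltas = np.linspace(0.0, 1.0, 21)
        for preset in all_presets:
            sweep = discount_sweep(preset.params, preset.econ, deltas)
            x = [s.x_star for s in sweep]
            e = [s.e_star for s in sweep]
            profit = [s.profit for s in sweep]
            assert np.all(np.diff(x) <= 1e-9 * preset.params.K)
            assert np.all(np.diff(e) >= -1e-9 * max(e))
            assert np.all(np.diff(profit) <= 1e-9 * max(profit))
            assert all(p >= -1e-9 * max(profit) for p in profit)
            assert all(p <= profit[0] * (1 + 1e-12) for p in profit)

    def test_clark_bounds_hold_along_sweep(self, mackerel_bio, mackerel_econ):
        theta = cost_price_ratio(mackerel_bio, mackerel_econ)
        mey_stock = mey_point(mackerel_bio, mackerel_econ).biomass
        for s in discount_sweep(mackerel_bio, mackerel_econ, np.linspace(0, 1, 11)):
            assert theta * mackerel_bio.K <= s.x_star * (1 + 1e-12)
            assert s.x_star <= mey_stock * (1 + 1e-12)

    def test_singleton_zero_grid_is_mey(self, mackerel_bio, mackerel_econ):
        sweep = discount_sweep(mackerel_bio, mackerel_econ, [0.0])
        assert len(sweep) == 1
        assert sweep[0].x_star == pytest.approx(
            mey_point(mackerel_bio, mackerel_econ).biomass, rel=1e-12
        )

    def test_preserves_input_order(self, mackerel_bio, mackerel_econ):
        deltas = [0.5, 0.1, 0.9]
        sweep = discount_sweep(mackerel_bio, mackerel_econ, deltas)
        assert [s.delta for s in sweep] == deltas


class TestMatchDeltaToTaxes:
    def test_recovers_generating_discount_rate(self, mackerel_bio, mackerel_econ):
        # build OSY taxes at a known delta and scan it back
        from fishbioecon.control import match_delta_to_taxes
        from fishbioecon.economics import ReferencePoint
        from fishbioecon.taxes import effort_tax, landing_tax

        true_delta = 0.17
        opt = discounted_optimum(mackerel_bio, mackerel_econ, true_delta)
        target = ReferencePoint(
            regime="OSY", effort=opt.e_star, harvest=opt.h_star, biomass=opt.x_star,
            total_revenue=mackerel_econ.price * opt.h_star,
            total_cost=mackerel_econ.unit_cost * opt.e_star, rent=opt.profit,
        )
        matched = match_delta_to_taxes(
            mackerel_bio,
            mackerel_econ,
            landing_tax(mackerel_econ, target),
            effort_tax(mackerel_econ, target),
            deltas=[i / 100 for i in range(1, 101)],
        )
        assert matched == pytest.approx(true_delta, abs=1e-9)
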
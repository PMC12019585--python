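"""Network indices against hand arithmetic and brute-force oracles."""

import numpy as np
import pytest

import cryoweb as cw
from conftest import make_toy_ledger, random_toy_ledger

CATS5 = {
    "nut": "nutrient", "phyto": "producer", "zoo": "consumer",
    "det": "detritus", "benthos": "consumer",
}
COMPS5 = tuple(CATS5)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def tl_power_iteration(ledger, iters=20000, tol=1e-14):
    """Fixed-point iteration of TL = 1 + p^T TL with anchored baselines."""
    T = ledger.T
    n = len(ledger.comps)
    inflow = T.sum(axis=0)
    p = np.divide(T, inflow, out=np.zeros_like(T), where=inflow > 0)
    consumer = ledger.living & ~ledger.producers_mask
    tl = np.ones(n)
    for _ in range(iters):
        new = np.where(consumer & (inflow > 0), 1.0 + p.T @ tl, 1.0)
        if np.max(np.abs(new - tl)) < tol:
            return new
        tl = new
    return tl


def dominance_series(ledger, k_max=500):
    """Truncated path-sum oracle: sum_{k>=2} G^k over sum G."""
    T = ledger.T
    inflow = T.sum(axis=0) + ledger.imports
    G = np.divide(T, inflow, out=np.zeros_like(T), where=inflow > 0)
    term = G @ G
    acc = np.zeros_like(G)
    for _ in range(k_max):
        acc += term
        term = term @ G
        if term.sum() < 1e-16:
            break
    return acc.sum() / G.sum()


def ascendancy_direct(ledger):
    """Element-by-element evaluation of the information sums."""
    T = ledger.T
    tot = T.sum()
    A = C = 0.0
    for i in range(T.shape[0]):
        for j in range(T.shape[1]):
            t = T[i, j]
            if t <= 0:
                continue
            A += t * np.log2(t * tot / (T[i].sum() * T[:, j].sum()))
            C -= t * np.log2(t / tot)
    return A, C


# ---------------------------------------------------------------------------
# nutrition shares
# ---------------------------------------------------------------------------

class TestNutritionShares:
    def test_hand_classification(self):
        led = make_toy_ledger(
            COMPS5, CATS5,
            {("nut", "phyto"): 10.0, ("phyto", "zoo"): 5.0, ("det", "benthos"): 5.0},
        )
        shares = cw.nutrition_shares(led)
        assert shares["primary_production"] == pytest.approx(50.0)
        assert shares["consumption"] == pytest.approx(25.0)
        assert shares["recycling"] == pytest.approx(25.0)

    def test_pure_primary_production(self):
        led = make_toy_ledger(COMPS5, CATS5, {("nut", "phyto"): 3.0})
        assert cw.nutrition_shares(led)["primary_production"] == 100.0

    def test_shares_sum_to_100(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            led = random_toy_ledger(rng)
            assert sum(cw.nutrition_shares(led).values()) == pytest.approx(100.0)

    def test_dead_web_flagged(self):
        led = make_toy_ledger(COMPS5, CATS5, {})
        with pytest.raises(ValueError, match="undefined"):
            cw.nutrition_shares(led)


class TestMassShares:
    def test_mixed_feeder_ratio_split(self):
        led = make_toy_ledger(
            COMPS5, CATS5,
            {("det", "benthos"): 3.0, ("zoo", "benthos"): 1.0,
             ("nut", "phyto"): 1.0},
            masses={"benthos": 40.0},
        )
        shares = cw.mass_shares_by_mode(
            [0, 0, 0, 0, 40.0], led
        )
        assert shares["recycling"] == pytest.approx(100 * 30 / 40)
        assert shares["consumption"] == pytest.approx(100 * 10 / 40)

    def test_category_totals_without_mixed_feeders(self):
        led = make_toy_ledger(
            COMPS5, CATS5,
            {("nut", "phyto"): 1.0, ("phyto", "zoo"): 1.0, ("det", "benthos"): 1.0},
            masses={"phyto": 10.0, "zoo": 5.0, "benthos": 5.0},
        )
        shares = cw.mass_shares_by_mode([0, 10.0, 5.0, 0, 5.0], led)
        assert shares["primary_production"] == pytest.approx(50.0)
        assert shares["consumption"] == pytest.approx(25.0)
        assert shares["recycling"] == pytest.approx(25.0)

    def test_zero_flow_fallback_warns(self):
        led = make_toy_ledger(COMPS5, CATS5, {("nut", "phyto"): 1.0})
        with pytest.warns(UserWarning, match="no inbound flow"):
            shares = cw.mass_shares_by_mode([0, 1.0, 1.0, 0, 0], led)
        assert shares["consumption"] == pytest.approx(50.0)


class TestTrophicLevels:
    def test_single_food_source(self):
        led = make_toy_ledger(
            COMPS5, CATS5, {("nut", "phyto"): 1.0, ("phyto", "zoo"): 1.0}
        )
        tl = cw.trophic_levels(led)
        assert tl["phyto"] == 1.0
        assert tl["zoo"] == pytest.approx(2.0)

    def test_weighted_average_diet(self):
        led = make_toy_ledger(
            COMPS5, CATS5,
            {("nut", "phyto"): 2.0, ("phyto", "zoo"): 1.0,
             ("phyto", "benthos"): 1.0, ("zoo", "benthos"): 1.0},
        )
        tl = cw.trophic_levels(led)
        # benthos: 50% on TL1, 50% on TL2 -> 2.5
        assert tl["benthos"] == pytest.approx(2.5)

    def test_cycle_with_anchor_matches_iterative_oracle(self):
        led = make_toy_ledger(
            COMPS5, CATS5,
            {("nut", "phyto"): 5.0, ("phyto", "zoo"): 2.0,
             ("benthos", "zoo"): 0.5, ("zoo", "benthos"): 1.0},
        )
        tl = cw.trophic_levels(led)
        oracle = tl_power_iteration(led)
        for i, c in enumerate(led.comps):
            assert tl[c] == pytest.approx(oracle[i], abs=1e-10)

    def test_random_ledgers_match_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            led = random_toy_ledger(rng)
            tl = cw.trophic_levels(led)
            oracle = tl_power_iteration(led)
            got = np.array([tl[c] for c in led.comps])
            np.testing.assert_allclose(got, oracle, rtol=0, atol=1e-9)


class TestOmnivory:
    def test_single_prey_zero(self):
        led = make_toy_ledger(
            COMPS5, CATS5, {("nut", "phyto"): 1.0, ("phyto", "zoo"): 1.0}
        )
        oi = cw.omnivory_indices(led, cw.trophic_levels(led))
        assert oi["zoo"] == pytest.approx(0.0)

    def test_even_two_level_diet(self):
        led = make_toy_ledger(
            COMPS5, CATS5,
            {("nut", "phyto"): 2.0, ("phyto", "zoo"): 1.0,
             ("phyto", "benthos"): 1.0, ("zoo", "benthos"): 1.0},
        )
        oi = cw.omnivory_indices(led, cw.trophic_levels(led))
        assert oi["benthos"] == pytest.approx(0.25)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        led = random_toy_ledger(rng)
        tl = cw.trophic_levels(led)
        oi1 = cw.omnivory_indices(led, tl)
        led2 = cw.FlowLedger(
            comps=led.comps, T=7.5 * led.T, imports=7.5 * led.imports,
            exports=7.5 * led.exports, annual_mean_mass=led.annual_mean_mass,
            categories=led.categories,
        )
        oi2 = cw.omnivory_indices(led2, cw.trophic_levels(led2))
        for c in oi1:
            assert oi1[c] == pytest.approx(oi2[c], abs=1e-12)


class TestInformationIndices:
    def test_single_flow_degenerate(self):
        led = make_toy_ledger(COMPS5, CATS5, {("nut", "phyto"): 4.0})
        A, C, ratio = cw.ascendancy_capacity(led)
        assert A == pytest.approx(0.0)
        assert C == pytest.approx(0.0)
        assert np.isnan(ratio)

    def test_two_disjoint_unit_flows(self):
        led = make_toy_ledger(
            COMPS5, CATS5, {("nut", "phyto"): 1.0, ("det", "benthos"): 1.0}
        )
        A, C, ratio = cw.ascendancy_capacity(led)
        assert A == pytest.approx(2.0)
        assert C == pytest.approx(2.0)
        assert ratio == pytest.approx(1.0)

    def test_random_ledgers_bound_and_match_direct_sum(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            led = random_toy_ledger(rng)
            A, C, _ = cw.ascendancy_capacity(led)
            Ad, Cd = ascendancy_direct(led)
            assert A == pytest.approx(Ad, abs=1e-9)
            assert C == pytest.approx(Cd, abs=1e-9)
            assert -1e-9 <= A <= C + 1e-9

    def test_linear_scaling(self):
        rng = np.random.default_rng(11)
        led = random_toy_ledger(rng)
        A1, C1, r1 = cw.ascendancy_capacity(led)
        led2 = cw.FlowLedger(
            comps=led.comps, T=3.0 * led.T, categories=led.categories
        )
        A2, C2, r2 = cw.ascendancy_capacity(led2)
        assert A2 == pytest.approx(3 * A1, rel=1e-9)
        assert C2 == pytest.approx(3 * C1, rel=1e-9)
        assert r2 == pytest.approx(r1, rel=1e-9)


class TestIndirectDominance:
    def test_single_link_no_indirect_paths(self):
        led = make_toy_ledger(COMPS5, CATS5, {("nut", "phyto"): 2.0})
        assert cw.indirect_effects_dominance(led) == pytest.approx(0.0)

    def test_unit_chain(self):
        led = make_toy_ledger(
            COMPS5, CATS5, {("nut", "phyto"): 1.0, ("phyto", "zoo"): 1.0}
        )
        # one length-2 path over two direct links
        assert cw.indirect_effects_dominance(led) == pytest.approx(0.5)

    def test_random_ledgers_match_series_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            led = random_toy_ledger(rng)
            got = cw.indirect_effects_dominance(led)
            assert got == pytest.approx(dominance_series(led), abs=1e-9)

    def test_non_dissipative_rejected(self):
        # closed 2-cycle with no imports: spectral radius 1
        led = make_toy_ledger(
            COMPS5, CATS5, {("zoo", "benthos"): 1.0, ("benthos", "zoo"): 1.0}
        )
        with pytest.raises(ValueError, match="non-dissipative"):
            cw.indirect_effects_dominance(led)


class TestProduction:
    def test_f_ratio_cases(self):
        cats = {"nit_pool": "nutrient", "amm_pool": "nutrient", "phyto": "producer"}
        led = make_toy_ledger(
            tuple(cats), cats,
            {("nit_pool", "phyto"): 19.0, ("amm_pool", "phyto"): 1.0},
        )
        # substrate masks key on compartment names
        led2 = cw.FlowLedger(
            comps=("nitrate_x", "ammonia_x", "phyto"),
            T=led.T, categories={"nitrate_x": "nutrient", "ammonia_x": "nutrient",
                                 "phyto": "producer"},
        )
        assert cw.f_ratio(led2) == pytest.approx(0.95)

    def test_f_ratio_pure_and_even(self):
        def build(nit, amm):
            return cw.FlowLedger(
                comps=("nitrate_x", "ammonia_x", "phyto"),
                T=np.array([[0, 0, nit], [0, 0, amm], [0, 0, 0.0]]),
                categories={"nitrate_x": "nutrient", "ammonia_x": "nutrient",
                            "phyto": "producer"},
            )
        assert cw.f_ratio(build(2.0, 0.0)) == 1.0
        assert cw.f_ratio(build(2.0, 2.0)) == 0.5
        with pytest.raises(ValueError):
            cw.f_ratio(build(0.0, 0.0))

    def test_secondary_production_budget(self):
        cats = {"nitrate_x": "nutrient", "phyto": "producer", "zoo": "consumer"}
        led = make_toy_ledger(
            tuple(cats), cats,
            {("nitrate_x", "phyto"): 12.0, ("phyto", "zoo"): 10.0},
        )
        npp, sec = cw.production_metrics(led, {"zoo": (0.7, 0.2)})
        assert sec == pytest.approx(10 * 0.7 * (1 - 0.2))
        assert npp == pytest.approx(12.0)  # no respiration flows in this toy

    def test_no_consumers_no_secondary(self):
        cats = {"nitrate_x": "nutrient", "phyto": "producer"}
        led = make_toy_ledger(tuple(cats), cats, {("nitrate_x", "phyto"): 5.0})
        npp, sec = cw.production_metrics(led, {})
        assert sec == 0.0

    def test_npp_zero_when_uptake_equals_losses(self):
        cats = {"nitrate_x": "nutrient", "ammonia_x": "nutrient",
                "phyto": "producer"}
        led = make_toy_ledger(
            tuple(cats), cats,
            {("nitrate_x", "phyto"): 5.0, ("phyto", "ammonia_x"): 5.0},
        )
        npp, _ = cw.production_metrics(led, {})
        assert npp == pytest.approx(0.0)


class TestSummary:
    def test_mass_weighted_top_predator_level(self):
        # cetaceans eat zoo (TL 3); pinnipeds eat zoo and cetaceans evenly
        cats = {"nitrate_x": "nutrient", "phyto": "producer", "zoo": "consumer",
                "cetaceans": "consumer", "pinnipeds": "consumer"}
        comps = tuple(cats)
        led = make_toy_ledger(
            comps, cats,
            {("nitrate_x", "phyto"): 10.0, ("phyto", "zoo"): 5.0,
             ("zoo", "cetaceans"): 2.0,
             ("zoo", "pinnipeds"): 1.0, ("cetaceans", "pinnipeds"): 1.0},
            masses={"zoo": 1.0, "cetaceans": 1.0, "pinnipeds": 1.0},
        )
        ix = cw.summary_indices(led, params={"zoo": (0.6, 0.3),
                                             "cetaceans": (0.8, 0.4),
                                             "pinnipeds": (0.8, 0.4)})
        # TL: zoo 2, cetaceans 3, pinnipeds 1 + (2 + 3)/2 = 3.5 -> mean 3.25
        assert ix.TL["cetaceans"] == pytest.approx(3.0)
        assert ix.TL["pinnipeds"] == pytest.approx(3.5)
        assert ix.mean_TL_top_predators == pytest.approx((3.0 + 3.5) / 2)

    def test_equal_masses_reduce_to_arithmetic_mean(self):
        rng = np.random.default_rng(5)
        led = random_toy_ledger(rng)
        masses = np.ones(len(led.comps))
        params = {c: (0.6, 0.3) for c in led.comps}
        ix = cw.summary_indices(led, masses, params=params)
        assert ix.mean_OI_consumers == pytest.approx(np.mean(list(ix.OI.values())))
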
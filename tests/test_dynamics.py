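"""Process kernels and the assembled mass-balance derivative."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cryoweb as cw
from cryoweb.guilds import guild
from cryoweb.params import ProducerParams


class TestLightTransmission:
    def test_open_water_transmits_fully(self, params):
        assert cw.light_transmission(0.0, 3.0, 1.0, params) == 1.0

    def test_transparent_ice_transmits_fully(self, params):
        p = params.copy()
        p.k_ice = p.k_snow = p.albedo = 0.0
        assert cw.light_transmission(1.0, 2.0, 0.5, p) == pytest.approx(1.0)

    def test_attenuation_formula(self, params):
        p = params.copy()
        p.k_ice, p.k_snow, p.albedo = 1.5, 10.0, 0.0
        got = cw.light_transmission(1.0, 2.0, 0.0, p)
        assert got == pytest.approx(np.exp(-3.0), rel=1e-12)

    @given(
        c=st.floats(0, 1), hi=st.floats(0, 5), hs=st.floats(0, 2),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounded_fraction(self, c, hi, hs):
        t = cw.light_transmission(c, hi, hs, cw.default_params())
        assert 0.0 <= t <= 1.0


class TestQ10:
    def test_identity_at_reference(self):
        assert cw.q10_scale(0.3, 10.0, 2.0, 10.0) == 0.3

    def test_doubles_over_ten_degrees(self):
        assert cw.q10_scale(0.3, 20.0, 2.0, 10.0) == pytest.approx(0.6)

    def test_cooling_slows(self):
        got = cw.q10_scale(1.0, 5.0, 2.0, 10.0)
        assert got == pytest.approx(2 ** -0.5, rel=1e-12)


class TestDinUptake:
    P = ProducerParams(
        u_max_nitrate=0.8, u_max_ammonia=0.8, k_nitrate=1.0, k_ammonia=1.0,
        k_light=5.0, k_inhib=np.inf, resp_frac=0.1, mort=0.01,
    )

    def test_no_substrate_no_uptake(self):
        un, ua = cw.din_uptake(0.0, 2.0, 10.0, 0.0, self.P)
        assert un == 0.0 and ua > 0.0

    def test_pure_nitrate_regime(self):
        un, ua = cw.din_uptake(100.0, 0.0, 1e6, 0.0, self.P)
        assert ua == 0.0
        assert un / (un + ua) == 1.0

    def test_half_saturation_product(self):
        # S = k_S and I = k_I halve each factor: u = u_max / 4
        un, ua = cw.din_uptake(1.0, 1.0, 5.0, 0.0, self.P)
        assert un == pytest.approx(0.8 / 4)
        assert ua == pytest.approx(0.8 / 4)

    def test_ammonia_inhibits_nitrate(self):
        p = ProducerParams(0.8, 0.8, 1.0, 1.0, 5.0, 0.5, 0.1, 0.01)
        un_lo, _ = cw.din_uptake(1.0, 0.1, 5.0, 0.0, p)
        un_hi, _ = cw.din_uptake(1.0, 5.0, 5.0, 0.0, p)
        assert un_hi < un_lo


class TestFeeding:
    C = cw.ConsumerParams(
        u_max=0.5, k_food=2.0, assim_eff=0.7, excr_frac=0.2, mort=0.01, mort_dd=0.0
    )

    def test_no_prey_no_flux(self):
        f = cw.preference_weighted_feeding(3.0, [0.0, 0.0], [0.5, 0.5], self.C, 0.0)
        assert np.all(f == 0.0)

    def test_saturation_limit(self):
        f = cw.preference_weighted_feeding(3.0, [1e9, 1e9], [0.5, 0.5], self.C, 0.0)
        assert f.sum() == pytest.approx(3.0 * 0.5, rel=1e-6)

    def test_preference_ratio(self):
        f = cw.preference_weighted_feeding(1.0, [4.0, 4.0], [0.8, 0.2], self.C, 0.0)
        assert f[0] / f[1] == pytest.approx(4.0, rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            cw.preference_weighted_feeding(1.0, [1.0], [0.5, 0.5], self.C, 0.0)

    @given(st.floats(0.1, 100), st.floats(0.1, 100))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_fluxes_nonnegative_and_bounded(self, a, b):
        f = cw.preference_weighted_feeding(2.0, [a, b], [0.6, 0.4], self.C, 0.0)
        assert np.all(f >= 0.0)
        assert f.sum() <= 2.0 * self.C.u_max + 1e-9


class TestHabitat:
    def test_ice_hunter_loses_all_habitat(self):
        assert cw.habitat_accessibility(0.0, 0.0, guild("maritime_mammals")) == 0.0

    def test_open_water_forager_gains(self):
        assert cw.habitat_accessibility(0.0, 0.0, guild("cetaceans")) == 1.0

    def test_linear_rule_equal_cover(self):
        g = guild("maritime_mammals")
        assert cw.habitat_accessibility(0.5, 0.5, g, 0.5, 0.5) == pytest.approx(0.5)

    def test_indifferent_guild_unaffected(self):
        assert cw.habitat_accessibility(0.9, 0.9, guild("omniv_zoo")) == 1.0


class TestStateDerivative:
    def test_closed_boundaries_conserve(self, baseline_drivers, params, initial_state):
        d, _ = cw.state_derivative(
            100.0, initial_state, baseline_drivers, params, closed_boundaries=True
        )
        assert abs(d.sum()) < 1e-10 * np.abs(d).sum()

    def test_polar_night_stops_uptake(self, baseline_drivers, params, initial_state):
        # day 355: no sunlight at 76N
        _, snap = cw.state_derivative(355.0, initial_state, baseline_drivers, params)
        dissolved = [c for c in cw.COMPARTMENTS if "nitrate" in c or "ammonia" in c]
        for prod in cw.PRODUCERS:
            uptake = sum(
                v for (a, b), v in snap.flows.items() if b == prod and a in dissolved
            )
            assert uptake == pytest.approx(0.0, abs=1e-12)

    def test_melt_season_releases_cryosphere_pools(
        self, baseline_drivers, params, initial_state
    ):
        # day 210 sits in the melt season of the baseline climatology
        _, snap = cw.state_derivative(210.0, initial_state, baseline_drivers, params)
        assert snap.flow("ice_nitrate", "surface_nitrate") > 0.0
        assert snap.flow("ice_ammonia", "surface_ammonia") > 0.0
        assert snap.flow("snow_nitrate", "surface_nitrate") > 0.0

    def test_freeze_up_entrains_surface_nutrients(
        self, baseline_drivers, params, initial_state
    ):
        # late autumn: ice volume grows
        _, snap = cw.state_derivative(320.0, initial_state, baseline_drivers, params)
        assert snap.flow("surface_nitrate", "ice_nitrate") > 0.0

    def test_invalid_states_rejected(self, baseline_drivers, params, initial_state):
        bad = initial_state.copy()
        bad[3] = -1.0
        with pytest.raises(ValueError, match="negative"):
            cw.state_derivative(0.0, bad, baseline_drivers, params)
        bad[3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            cw.state_derivative(0.0, bad, baseline_drivers, params)

    def test_fishing_terms_vanish_at_zero_activity(
        self, baseline_drivers, params, initial_state
    ):
        p2 = params.copy()
        p2.harvest = {k: 0.0 for k in p2.harvest}
        d1, s1 = cw.state_derivative(100.0, initial_state, baseline_drivers, params)
        d2, s2 = cw.state_derivative(100.0, initial_state, baseline_drivers, p2)
        np.testing.assert_array_equal(d1, d2)
        assert s1.exports == s2.exports

    def test_more_light_never_reduces_producer_uptake(
        self, baseline_drivers, params, initial_state
    ):
        clear = params.copy()
        clear.k_ice = clear.k_snow = clear.albedo = 0.0

        def total_uptake(p):
            tot = 0.0
            for day in (120.0, 180.0, 240.0):
                _, snap = cw.state_derivative(day, initial_state, baseline_drivers, p)
                tot += sum(
                    v for (a, b), v in snap.flows.items() if b in cw.PRODUCERS
                )
            return tot

        assert total_uptake(clear) >= total_uptake(params)

    def test_every_flow_once_and_budget_consistent(
        self, baseline_drivers, params, initial_state
    ):
        d, snap = cw.state_derivative(200.0, initial_state, baseline_drivers, params)
        idx = {c: i for i, c in enumerate(cw.COMPARTMENTS)}
        recon = np.zeros_like(d)
        for (a, b), v in list(snap.flows.items()) + list(snap.demographic.items()):
            recon[idx[a]] -= v
            recon[idx[b]] += v
        for c, v in snap.imports.items():
            recon[idx[c]] += v
        for c, v in snap.exports.items():
            recon[idx[c]] -= v
        np.testing.assert_allclose(recon, d, rtol=0, atol=1e-12)
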
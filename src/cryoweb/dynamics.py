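"""Nitrogen mass-balance derivative: uptake, feeding, cycling, cryosphere.

Every process is expressed as a donor -> recipient flow (or an explicit
boundary import/export channel), so nitrogen is conserved by construction:
with all boundary channels closed the state derivative sums to zero to
numerical round-off.

Functional forms are the standard ones for this model family: Michaelis-
Menten nutrient uptake with ammonia inhibition of nitrate uptake and a
saturating light response, Holling type II preference-weighted feeding, Q10
temperature scaling per process class, and quadratic (density-dependent)
closure mortality on the top predators, with an interference factor that
sharpens competition among ice-hunting mammals as their habitat shrinks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .drivers import DriverSet, interp_annual
from .guilds import (
    COMPARTMENTS,
    CONSUMERS,
    GUILDS,
    GuildSpec,
    index_of,
)
from .params import ConsumerParams, ModelParams, ProducerParams

__all__ = [
    "light_transmission",
    "q10_scale",
    "din_uptake",
    "preference_weighted_feeding",
    "habitat_accessibility",
    "state_derivative",
    "FlowSnapshot",
    "Engine",
]

N = len(COMPARTMENTS)
_I = {name: index_of(name) for name in COMPARTMENTS}


# ---------------------------------------------------------------------------
# elementary process kernels (public, scalar-friendly)
# ---------------------------------------------------------------------------

def light_transmission(
    ice_cover: float,
    ice_thickness: float,
    snow_thickness: float,
    params: ModelParams,
) -> float:
    """Fraction of surface irradiance reaching the water column.

    Open water transmits fully; the ice-covered fraction loses light to
    surface reflection and to exponential attenuation in snow and ice:
    ``T = (1 - C) + C (1 - albedo) exp(-k_ice h_ice - k_snow h_snow)``.
    """
    c = ice_cover
    under = (1.0 - params.albedo) * np.exp(
        -params.k_ice * ice_thickness - params.k_snow * snow_thickness
    )
    return (1.0 - c) + c * under


def q10_scale(rate_ref: float, temperature: float, q10: float, t_ref: float) -> float:
    """Q10 temperature scaling: ``rate_ref * q10 ** ((T - t_ref) / 10)``."""
    return rate_ref * q10 ** ((temperature - t_ref) / 10.0)


def din_uptake(
    nitrate: float,
    ammonia: float,
    irradiance_at_depth: float,
    temperature: float,
    producer_params: ProducerParams,
    q10: float = 1.0,
    t_ref: float = 10.0,
):
    """Specific nitrate and ammonia uptake rates (d^-1) of one producer.

    Ammonia is the preferred substrate: the nitrate term carries an
    ammonia-inhibition factor ``k_inh / (k_inh + ammonia)``.
    """
    p = producer_params
    light = irradiance_at_depth / (p.k_light + irradiance_at_depth)
    tfac = q10 ** ((temperature - t_ref) / 10.0)
    inhib = p.k_inhib / (p.k_inhib + ammonia) if np.isfinite(p.k_inhib) else 1.0
    u_nit = p.u_max_nitrate * nitrate / (p.k_nitrate + nitrate) * inhib * light * tfac
    u_amm = p.u_max_ammonia * ammonia / (p.k_ammonia + ammonia) * light * tfac
    return u_nit, u_amm


def preference_weighted_feeding(
    consumer_mass: float,
    prey_masses,
    preferences,
    consumer_params: ConsumerParams,
    temperature: float,
    q10: float = 1.0,
    t_ref: float = 10.0,
    habitat: float = 1.0,
) -> np.ndarray:
    """Per-prey ingestion fluxes (mmol N m^-2 d^-1), Holling type II on the
    preference-weighted food availability ``A = sum(pref_i * prey_i)``."""
    prey = np.asarray(prey_masses, dtype=float)
    pref = np.asarray(preferences, dtype=float)
    if prey.shape != pref.shape:
        raise ValueError("preference/prey length mismatch")
    weighted = pref * prey
    avail = weighted.sum()
    if avail <= 0.0:
        return np.zeros_like(prey)
    c = consumer_params
    tfac = q10 ** ((temperature - t_ref) / 10.0)
    total = consumer_mass * c.u_max * avail / (c.k_food + avail) * tfac * habitat
    return total * weighted / avail


def habitat_accessibility(
    ice_cover_inshore: float,
    ice_cover_offshore: float,
    guild: GuildSpec,
    area_inshore: float = 0.35,
    area_offshore: float = 0.65,
) -> float:
    """Feeding-rate multiplier from the area accessible to a guild.

    Ice-hunting guilds scale with the area-weighted mean ice cover; obligate
    open-water foragers with the open-water fraction; everything else is
    unaffected.
    """
    w = area_inshore + area_offshore
    mean_cover = (
        area_inshore * ice_cover_inshore + area_offshore * ice_cover_offshore
    ) / w
    if guild.ice_dependence == "requires_ice":
        return mean_cover
    if guild.ice_dependence == "requires_open_water":
        return 1.0 - mean_cover
    return 1.0


# ---------------------------------------------------------------------------
# the vectorised derivative engine
# ---------------------------------------------------------------------------

_CONS_IDX = np.array([index_of(c) for c in CONSUMERS])
_N_CONS = len(CONSUMERS)

# consumers whose metabolism follows the deep-layer temperature
_DEEP_DWELLERS = {"dem_fish", "benthos_susp", "benthos_carn"}
# destination of excreted ammonia
_EXCRETE_TO = {
    "benthos_susp": "porewater_ammonia",
    "benthos_carn": "porewater_ammonia",
    "dem_fish": "deep_ammonia",
}
# destination of unassimilated intake
_DEFECATE_TO = {
    "benthos_susp": "sediment_labile_detritus",
    "benthos_carn": "sediment_labile_detritus",
    "dem_fish": "deep_detritus",
    "plank_fish": "deep_detritus",
    "migratory_fish": "deep_detritus",
}
# guilds whose dead fall as carcasses rather than fine detritus
_MORT_TO_CORPSES = {
    "plank_fish", "dem_fish", "migratory_fish", "benthos_susp", "benthos_carn",
    "birds", "pinnipeds", "cetaceans", "maritime_mammals",
}

_PRODUCER_SOURCES = {
    # producer: (nitrate pool, ammonia pool, respiration sink, mortality sink)
    "surface_phyto": ("surface_nitrate", "surface_ammonia",
                      "surface_ammonia", "surface_detritus"),
    "deep_phyto": ("deep_nitrate", "deep_ammonia", "deep_ammonia", "deep_detritus"),
    "ice_algae": ("ice_nitrate", "ice_ammonia", "ice_ammonia", "ice_detritus"),
    "macrophytes": ("surface_nitrate", "surface_ammonia",
                    "surface_ammonia", "surface_detritus"),
}


@dataclass
class FlowSnapshot:
    """Instantaneous flows (mmol N m^-2 d^-1) for one derivative evaluation."""

    comps: tuple[str, ...]
    flows: dict[tuple[str, str], float] = field(default_factory=dict)
    imports: dict[str, float] = field(default_factory=dict)
    exports: dict[str, float] = field(default_factory=dict)
    demographic: dict[tuple[str, str], float] = field(default_factory=dict)

    def flow(self, donor: str, recipient: str) -> float:
        return self.flows.get((donor, recipient), 0.0)

    def total(self) -> float:
        return sum(self.flows.values())


class Engine:
    """Precompiled right-hand side for one (drivers, params) pair.

    All forcing-dependent quantities are evaluated once on a fixed grid of
    time points; the per-call work is restricted to state-dependent terms.
    """

    def __init__(
        self,
        drivers: DriverSet,
        params: ModelParams,
        times: np.ndarray,
        closed_boundaries: bool = False,
    ):
        self.drivers = drivers
        self.params = params
        self.times = np.asarray(times, dtype=float)
        self.closed = closed_boundaries
        self._build_topology()
        self._build_forcing()

    # -- static flow topology ------------------------------------------------
    def _build_topology(self) -> None:
        p = self.params
        donors: list[int] = []
        recips: list[int] = []
        self._sections: dict[str, slice] = {}

        def section(name: str, pairs: list[tuple[str, str]]) -> None:
            start = len(donors)
            for d, r in pairs:
                donors.append(_I[d])
                recips.append(_I[r])
            self._sections[name] = slice(start, len(donors))

        # producer uptake: (nitrate->producer, ammonia->producer) x 4
        up_pairs = []
        for prod, (nit, amm, _, _) in _PRODUCER_SOURCES.items():
            up_pairs += [(nit, prod), (amm, prod)]
        section("uptake", up_pairs)
        section(
            "resp",
            [(prod, s[2]) for prod, s in _PRODUCER_SOURCES.items()],
        )
        section(
            "prod_mort",
            [(prod, s[3]) for prod, s in _PRODUCER_SOURCES.items()],
        )
        section("phyto_sink", [("surface_phyto", "deep_phyto")])

        # feeding links in guild order
        feed_pairs = []
        link_cons: list[int] = []
        link_pref: list[float] = []
        for ci, cname in enumerate(CONSUMERS):
            g = GUILDS[index_of(cname)]
            for prey, w in g.prey:
                feed_pairs.append((prey, cname))
                link_cons.append(ci)
                link_pref.append(w)
        section("feeding", feed_pairs)
        self._link_cons = np.array(link_cons)
        self._link_pref = np.array(link_pref)
        self._link_prey_idx = np.array(
            [_I[d] for d, _ in feed_pairs]
        )

        section(
            "excrete",
            [(c, _EXCRETE_TO.get(c, "surface_ammonia")) for c in CONSUMERS],
        )
        section(
            "defecate",
            [(c, _DEFECATE_TO.get(c, "surface_detritus")) for c in CONSUMERS],
        )
        section(
            "mortality",
            [
                (c, "corpses" if c in _MORT_TO_CORPSES else "surface_detritus")
                for c in CONSUMERS
            ],
        )
        section(
            "corpse",
            [("corpses", "deep_detritus"), ("corpses", "deep_ammonia")],
        )
        section(
            "detritus",
            [
                ("surface_detritus", "deep_detritus"),
                ("surface_detritus", "surface_ammonia"),
                ("deep_detritus", "sediment_labile_detritus"),
                ("deep_detritus", "deep_ammonia"),
                ("sediment_labile_detritus", "porewater_ammonia"),
                ("sediment_labile_detritus", "sediment_refractory_detritus"),
                ("ice_detritus", "ice_ammonia"),
            ],
        )
        section(
            "nitrif",
            [
                ("surface_ammonia", "surface_nitrate"),
                ("deep_ammonia", "deep_nitrate"),
                ("porewater_ammonia", "porewater_nitrate"),
            ],
        )
        section(
            "mixing",
            [
                ("deep_nitrate", "surface_nitrate"),
                ("deep_ammonia", "surface_ammonia"),
                ("surface_nitrate", "deep_nitrate"),
                ("surface_ammonia", "deep_ammonia"),
            ],
        )
        section(
            "sediment",
            [
                ("porewater_nitrate", "deep_nitrate"),
                ("porewater_ammonia", "deep_ammonia"),
                ("deep_nitrate", "porewater_nitrate"),
                ("deep_ammonia", "porewater_ammonia"),
            ],
        )
        section(
            "cryo",
            [
                # freezing entrains surface material into the ice
                ("surface_nitrate", "ice_nitrate"),
                ("surface_ammonia", "ice_ammonia"),
                ("surface_detritus", "ice_detritus"),
                # melt releases the cryosphere pools back to the water column
                ("ice_nitrate", "surface_nitrate"),
                ("ice_ammonia", "surface_ammonia"),
                ("ice_detritus", "surface_detritus"),
                ("ice_algae", "surface_detritus"),
                ("snow_nitrate", "surface_nitrate"),
                ("snow_ammonia", "surface_ammonia"),
            ],
        )
        # demographic transfers (kept out of the trophic flow matrix)
        from .guilds import DEMOGRAPHIC_PAIRS

        demo_pairs = [(a, l) for a, l in DEMOGRAPHIC_PAIRS] + [
            (l, a) for a, l in DEMOGRAPHIC_PAIRS
        ]
        section("demographic", demo_pairs)

        self.donor = np.array(donors)
        self.recip = np.array(recips)
        self.n_flows = len(donors)
        demo = np.zeros(self.n_flows, dtype=bool)
        demo[self._sections["demographic"]] = True
        self.is_demographic = demo

        # per-consumer parameter vectors
        self._c_umax = np.array([p.consumers[c].u_max for c in CONSUMERS])
        self._c_k = np.array([p.consumers[c].k_food for c in CONSUMERS])
        self._c_ae = np.array([p.consumers[c].assim_eff for c in CONSUMERS])
        self._c_ex = np.array([p.consumers[c].excr_frac for c in CONSUMERS])
        self._c_mort = np.array([p.consumers[c].mort for c in CONSUMERS])
        self._c_dd = np.array([p.consumers[c].mort_dd for c in CONSUMERS])

    # -- forcing precomputation ------------------------------------------------
    def _build_forcing(self) -> None:
        p = self.params
        d = self.drivers
        t = self.times
        nt = len(t)
        f_in, f_off = p.area_inshore, p.area_offshore
        h_s = p.depth_surface
        h_d_eff = p.depth_deep * f_off

        def at(name):
            return interp_annual(d[name], t)

        surf_temp = f_in * at("SI_temp") + f_off * at("SO_temp")
        deep_temp = at("D_temp")
        slight = at("Slight")
        cov_si, cov_so = at("SI_IceCover"), at("SO_IceCover")
        thick_si, thick_so = at("SI_IceThickness"), at("SO_IceThickness")
        snow_si, snow_so = at("SI_SnowThickness"), at("SO_SnowThickness")
        cover = f_in * cov_si + f_off * cov_so
        self.cover = cover

        # transmission through open water + snow/ice (area weighted)
        def trans(c, hi, hs):
            return (1.0 - c) + c * (1.0 - p.albedo) * np.exp(
                -p.k_ice * hi - p.k_snow * hs
            )

        t_ice = f_in * trans(cov_si, thick_si, snow_si) + f_off * trans(
            cov_so, thick_so, snow_so
        )
        self.transmission = t_ice

        spm = f_in * at("SPM_inshore") + f_off * at("SPM_offshore_upper")
        k_w = p.k_water + p.k_spm * spm
        i_surf0 = slight * t_ice
        # layer means of exponentially attenuated light
        lay_s = (1.0 - np.exp(-k_w * h_s)) / np.maximum(k_w * h_s, 1e-12)
        i_surface = i_surf0 * lay_s
        i_deep0 = i_surf0 * np.exp(-k_w * h_s)
        k_deep = p.k_water
        lay_d = (1.0 - np.exp(-k_deep * p.depth_deep)) / (k_deep * p.depth_deep)
        i_deep = i_deep0 * lay_d
        i_mac = i_surf0 * np.exp(-k_w * p.depth_macrophyte)
        under = (1.0 - p.albedo) * slight * (
            f_in * cov_si * np.exp(-p.k_ice * thick_si - p.k_snow * snow_si)
            + f_off * cov_so * np.exp(-p.k_ice * thick_so - p.k_snow * snow_so)
        )
        i_ice = under / np.maximum(cover, 1e-6)  # per unit ice-covered area

        def q10arr(q10, temp):
            return q10 ** ((temp - p.t_ref) / 10.0)

        q10u_s = q10arr(p.q10_uptake, surf_temp)
        q10u_d = q10arr(p.q10_uptake, deep_temp)
        self.q10_min_surf = q10arr(p.q10_mineralisation, surf_temp)
        self.q10_min_deep = q10arr(p.q10_mineralisation, deep_temp)

        # producer light x temperature factors (growth multiplier per producer)
        pp = p.producers
        self.prod_lt = {
            "surface_phyto": i_surface
            / (pp["surface_phyto"].k_light + i_surface) * q10u_s,
            "deep_phyto": i_deep / (pp["deep_phyto"].k_light + i_deep) * q10u_d,
            "ice_algae": i_ice / (pp["ice_algae"].k_light + i_ice) * q10u_s * cover,
            "macrophytes": i_mac / (pp["macrophytes"].k_light + i_mac) * q10u_s,
        }

        # consumer feeding scale: u_max * Q10(zone temperature) * habitat
        q10f_s = q10arr(p.q10_feeding, surf_temp)
        q10f_d = q10arr(p.q10_feeding, deep_temp)
        feed_scale = np.empty((_N_CONS, nt))
        dd_arr = np.empty((_N_CONS, nt))
        for ci, cname in enumerate(CONSUMERS):
            g = GUILDS[index_of(cname)]
            tfac = q10f_d if cname in _DEEP_DWELLERS else q10f_s
            if g.ice_dependence == "requires_ice":
                hab = cover
            elif g.ice_dependence == "requires_open_water":
                hab = 1.0 - cover
            else:
                hab = 1.0
            feed_scale[ci] = self._c_umax[ci] * tfac * hab
            dd_arr[ci] = self._c_dd[ci]
            if cname == "maritime_mammals":
                dd_arr[ci] = self._c_dd[ci] * (
                    1.0 + p.interference * (1.0 - cover)
                )
        self.feed_scale = feed_scale
        self.dd_arr = dd_arr
        self.mac_mort = p.producers["macrophytes"].mort * (
            1.0 + p.wave_mort_coef * at("wave_height_inshore")
        )

        # cryosphere volume dynamics from the prescribed ice fields
        def vol(name_c, name_h, tt):
            return f_in * interp_annual(d[f"SI_{name_c}"], tt) * interp_annual(
                d[f"SI_{name_h}"], tt
            ) + f_off * interp_annual(d[f"SO_{name_c}"], tt) * interp_annual(
                d[f"SO_{name_h}"], tt
            )

        v_ice = vol("IceCover", "IceThickness", t)
        dv_ice = (
            vol("IceCover", "IceThickness", t + 0.5)
            - vol("IceCover", "IceThickness", t - 0.5)
        )
        w_snow = vol("IceCover", "SnowThickness", t)
        dw_snow = (
            vol("IceCover", "SnowThickness", t + 0.5)
            - vol("IceCover", "SnowThickness", t - 0.5)
        )
        melt_ice = np.maximum(-dv_ice, 0.0)
        self.freeze = p.entrain_eff * np.maximum(dv_ice, 0.0)
        self.rho_ice = p.release_eff * melt_ice / np.maximum(v_ice, 0.02) + np.where(
            v_ice < 0.01, p.ice_free_leak, 0.0
        )
        self.rho_snow = p.release_eff * np.maximum(-dw_snow, 0.0) / np.maximum(
            w_snow, 0.01
        ) + np.where(w_snow < 0.005, p.ice_free_leak, 0.0)
        self.melt_volume = melt_ice  # m of water per day (density ignored)

        # vertical mixing / sediment exchange coefficients
        kz = at("vertical_diffusivity")
        self.mix_coef = kz / p.mix_length * f_off
        self.h_s = h_s
        self.h_d_eff = h_d_eff
        self.sed_v = p.sediment_exchange * f_off

        # boundary channels
        imports = np.zeros((N, nt))
        exp_rate = np.zeros((N, nt))
        if not self.closed:
            r_so, r_si, r_d = at("SO_OceanIN"), at("SI_OceanIN"), at("D_OceanIN")
            riv = at("river_volume")
            melt_din = at("meltwater_DIN")
            dep_w, dep_d = at("atm_deposition_wet"), at("atm_deposition_dry")
            river_vol = riv * f_in * h_s  # m of water per day over the domain

            def ocean_surf(so_var, si_var):
                return (r_so * f_off * at(so_var) + r_si * f_in * at(si_var)) * h_s

            imports[_I["surface_nitrate"]] = (
                ocean_surf("SO_nitrate", "SI_nitrate")
                + 0.7 * (river_vol + self.melt_volume) * melt_din
                + dep_d * (1.0 - cover)
            )
            imports[_I["surface_ammonia"]] = (
                ocean_surf("SO_ammonia", "SI_ammonia")
                + 0.3 * (river_vol + self.melt_volume) * melt_din
                + dep_w * (1.0 - cover)
            )
            imports[_I["surface_phyto"]] = ocean_surf("SO_phyt", "SI_phyt")
            imports[_I["surface_detritus"]] = ocean_surf("SO_detritus", "SI_detritus")
            imports[_I["snow_nitrate"]] = dep_d * cover
            imports[_I["snow_ammonia"]] = dep_w * cover
            imports[_I["deep_nitrate"]] = r_d * h_d_eff * at("D_nitrate")
            imports[_I["deep_ammonia"]] = r_d * h_d_eff * at("D_ammonia")
            imports[_I["deep_phyto"]] = r_d * h_d_eff * at("D_phyt")
            imports[_I["deep_detritus"]] = r_d * h_d_eff * at("D_detritus")

            doy = np.mod(t, 360.0)
            entry = (doy >= p.migration_entry_day) & (
                doy < p.migration_entry_day + p.migration_entry_days
            )
            imports[_I["migratory_fish"]] = np.where(
                entry,
                p.migratory_stock * p.migratory_in_frac / p.migration_entry_days,
                0.0,
            )

            r_out_surf = (
                r_so * f_off + r_si * f_in + riv * f_in + self.melt_volume / h_s
            )
            for name in ("surface_nitrate", "surface_ammonia", "surface_phyto",
                         "surface_detritus"):
                exp_rate[_I[name]] = r_out_surf
            for name in ("deep_nitrate", "deep_ammonia", "deep_phyto",
                         "deep_detritus"):
                exp_rate[_I[name]] = r_d
            exp_rate[_I["migratory_fish"]] = np.where(
                doy >= p.migration_exit_day, p.migration_exit_rate, 0.0
            )
            for cname in CONSUMERS:
                exp_rate[_I[cname]] += p.fishing_activity * p.harvest.get(cname, 0.0)
        self.imports = imports
        self.export_rate = exp_rate

        # demographic windows
        doy = np.mod(t, 360.0)
        self.spawn_on = (
            (doy >= p.spawn_day) & (doy < p.spawn_day + p.spawn_days)
        ).astype(float)
        self.recruit_on = (
            (doy >= p.recruit_day) & (doy < p.recruit_day + p.recruit_days)
        ).astype(float)

        self.surf_temp = surf_temp
        self.deep_temp = deep_temp

    # -- right-hand side -------------------------------------------------------
    def rhs(self, i: int, state: np.ndarray, dt_cap: float | None = None):
        """Derivative at time-grid index ``i``.

        Returns ``(dstate, flows, imports, exports)`` where ``flows`` is the
        flow vector over the engine's edge list (demographic edges included;
        see :attr:`is_demographic`).
        """
        p = self.params
        f = np.zeros(self.n_flows)
        s = self._sections

        # producers ----------------------------------------------------------
        pos = s["uptake"].start
        resp = np.empty(4)
        prod_mort = np.empty(4)
        h_s, h_d = self.h_s, self.h_d_eff
        for k, (prod, (nit, amm, _, _)) in enumerate(_PRODUCER_SOURCES.items()):
            pp = p.producers[prod]
            m = state[_I[prod]] + p.seed_refuge
            if prod == "ice_algae":
                cn, ca = state[_I[nit]], state[_I[amm]]  # areal pools
            else:
                depth = h_d if prod == "deep_phyto" else h_s
                cn, ca = state[_I[nit]] / depth, state[_I[amm]] / depth
            lt = self.prod_lt[prod][i]
            inhib = pp.k_inhib / (pp.k_inhib + ca)
            u_nit = pp.u_max_nitrate * cn / (pp.k_nitrate + cn) * inhib * lt
            u_amm = pp.u_max_ammonia * ca / (pp.k_ammonia + ca) * lt
            f[pos + 2 * k] = u_nit * m
            f[pos + 2 * k + 1] = u_amm * m
            resp[k] = pp.resp_frac * (u_nit + u_amm) * m
            mort = self.mac_mort[i] if prod == "macrophytes" else pp.mort
            prod_mort[k] = (mort + pp.mort_dd * m) * m
        f[s["resp"]] = resp
        f[s["prod_mort"]] = prod_mort
        f[s["phyto_sink"]] = p.phyto_sink * state[_I["surface_phyto"]]

        # feeding ------------------------------------------------------------
        weighted = self._link_pref * state[self._link_prey_idx]
        avail = np.bincount(self._link_cons, weights=weighted, minlength=_N_CONS)
        cmass = state[_CONS_IDX]
        total = (cmass + p.seed_refuge) * self.feed_scale[:, i] * avail / (
            self._c_k + avail
        )
        share = np.divide(
            weighted, avail[self._link_cons],
            out=np.zeros_like(weighted),
            where=avail[self._link_cons] > 0.0,
        )
        f[s["feeding"]] = total[self._link_cons] * share

        # consumer physiology and mortality -----------------------------------
        f[s["excrete"]] = self._c_ae * self._c_ex * total
        f[s["defecate"]] = (1.0 - self._c_ae) * total
        f[s["mortality"]] = self._c_mort * cmass + self.dd_arr[:, i] * cmass * cmass

        # corpses and detritus cycling -----------------------------------------
        f[s["corpse"]] = [
            p.corpse_to_detritus * state[_I["corpses"]],
            p.corpse_miner * state[_I["corpses"]],
        ]
        qms, qmd = self.q10_min_surf[i], self.q10_min_deep[i]
        f[s["detritus"]] = [
            p.sink_surface_detritus * state[_I["surface_detritus"]],
            p.miner_surface * qms * state[_I["surface_detritus"]],
            p.sink_deep_detritus * state[_I["deep_detritus"]],
            p.miner_deep * qmd * state[_I["deep_detritus"]],
            p.miner_sediment * qmd * state[_I["sediment_labile_detritus"]],
            p.labile_to_refractory * state[_I["sediment_labile_detritus"]],
            p.miner_ice * state[_I["ice_detritus"]],
        ]
        f[s["nitrif"]] = [
            p.nitrif_surface * qms * state[_I["surface_ammonia"]],
            p.nitrif_deep * qmd * state[_I["deep_ammonia"]],
            p.nitrif_sediment * qmd * state[_I["porewater_ammonia"]],
        ]

        # physical exchanges ----------------------------------------------------
        mix = self.mix_coef[i]
        f[s["mixing"]] = [
            mix * state[_I["deep_nitrate"]] / h_d,
            mix * state[_I["deep_ammonia"]] / h_d,
            mix * state[_I["surface_nitrate"]] / h_s,
            mix * state[_I["surface_ammonia"]] / h_s,
        ]
        sv = self.sed_v
        pw = p.porewater_depth
        f[s["sediment"]] = [
            sv * state[_I["porewater_nitrate"]] / pw,
            sv * state[_I["porewater_ammonia"]] / pw,
            sv * state[_I["deep_nitrate"]] / h_d,
            sv * state[_I["deep_ammonia"]] / h_d,
        ]

        # cryosphere --------------------------------------------------------------
        fz, ri, rs = self.freeze[i], self.rho_ice[i], self.rho_snow[i]
        f[s["cryo"]] = [
            fz * state[_I["surface_nitrate"]] / h_s,
            fz * state[_I["surface_ammonia"]] / h_s,
            0.5 * fz * state[_I["surface_detritus"]] / h_s,
            ri * state[_I["ice_nitrate"]],
            ri * state[_I["ice_ammonia"]],
            ri * state[_I["ice_detritus"]],
            ri * state[_I["ice_algae"]],
            rs * state[_I["snow_nitrate"]],
            rs * state[_I["snow_ammonia"]],
        ]

        # demographic transfers ------------------------------------------------
        demo = np.empty(8)
        sp = self.spawn_on[i] * p.spawn_rate
        rc = self.recruit_on[i] * p.recruit_rate
        from .guilds import DEMOGRAPHIC_PAIRS

        for k, (adult, larva) in enumerate(DEMOGRAPHIC_PAIRS):
            demo[k] = sp * state[_I[adult]]
            demo[k + 4] = rc * state[_I[larva]]
        f[s["demographic"]] = demo

        exports = self.export_rate[:, i] * state
        imports = self.imports[:, i]

        # donor-limited capping keeps compartments non-negative at finite steps
        if dt_cap is not None:
            out_tot = np.bincount(self.donor, weights=f, minlength=N) + exports
            allowed = 0.8 * state / dt_cap
            scale = np.minimum(1.0, allowed / np.maximum(out_tot, 1e-300))
            f *= scale[self.donor]
            exports = exports * scale

        dstate = (
            np.bincount(self.recip, weights=f, minlength=N)
            - np.bincount(self.donor, weights=f, minlength=N)
            + imports
            - exports
        )
        return dstate, f, imports, exports


def state_derivative(
    t: float,
    state: np.ndarray,
    drivers: DriverSet,
    params: ModelParams,
    closed_boundaries: bool = False,
):
    """Assemble all process fluxes at day ``t`` and return ``(dstate, snapshot)``.

    Every flux appears exactly once as a donor loss and once as a recipient
    gain (or as a boundary channel), so with boundaries closed the derivative
    sums to zero to round-off.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (N,):
        raise ValueError(f"state must have {N} entries, got {state.shape}")
    if not np.all(np.isfinite(state)):
        bad = COMPARTMENTS[int(np.argmax(~np.isfinite(state)))]
        raise ValueError(f"non-finite state entry for {bad}")
    if state.min() < 0:
        bad = COMPARTMENTS[int(np.argmin(state))]
        raise ValueError(f"negative state entry for {bad}")
    eng = Engine(drivers, params, np.array([t]), closed_boundaries)
    dstate, f, imports, exports = eng.rhs(0, state)
    snap = FlowSnapshot(comps=COMPARTMENTS)
    for k in range(eng.n_flows):
        if f[k] == 0.0:
            continue
        key = (COMPARTMENTS[eng.donor[k]], COMPARTMENTS[eng.recip[k]])
        target = snap.demographic if eng.is_demographic[k] else snap.flows
        target[key] = target.get(key, 0.0) + f[k]
    snap.imports = {
        COMPARTMENTS[j]: imports[j] for j in range(N) if imports[j] != 0.0
    }
    snap.exports = {
        COMPARTMENTS[j]: exports[j] for j in range(N) if exports[j] != 0.0
    }
    return dstate, snap
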
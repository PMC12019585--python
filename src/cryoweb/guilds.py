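"""Compartment inventory and food-web topology.

The model tracks nitrogen through 35 compartments: dissolved pools (water
column, sediment porewater, snow and ice), detritus pools, corpses, four
primary-producer guilds and fifteen consumer guilds up to top predators.
Masses are expressed in mmol N per m^2 of the whole model domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "GuildSpec",
    "COMPARTMENTS",
    "GUILDS",
    "index_of",
    "CATEGORY",
    "PRODUCERS",
    "CONSUMERS",
    "TOP_PREDATORS",
    "DEMOGRAPHIC_PAIRS",
    "living_names",
    "detrital_names",
]


@dataclass(frozen=True)
class GuildSpec:
    """Static description of one model compartment.

    ``prey`` lists (prey name, preference weight); weights over a consumer's
    prey sum to 1.  ``ice_dependence`` controls the habitat-accessibility
    multiplier applied to the guild's feeding rate: guilds that hunt on ice
    lose habitat as cover shrinks, open-water foragers gain it.
    """

    name: str
    category: str  # producer | consumer | detritus | nutrient | cryosphere | corpse
    living: bool
    zones: tuple[str, ...]
    prey: tuple[tuple[str, float], ...] = ()
    demographic_pair: str | None = None
    ice_dependence: str = "indifferent"  # requires_ice | requires_open_water | indifferent

    def __post_init__(self) -> None:
        if self.category == "producer" and self.prey:
            raise ValueError(f"producer {self.name} cannot have prey")
        if self.prey:
            tot = sum(w for _, w in self.prey)
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(
                    f"preferences of {self.name} sum to {tot!r}, expected 1"
                )
            if any(w < 0 for _, w in self.prey):
                raise ValueError(f"negative preference weight for {self.name}")
        if not self.living and self.category in ("producer", "consumer"):
            raise ValueError(f"{self.name}: producers/consumers must be living")


def _g(name, category, living, zones, prey=(), pair=None, ice="indifferent"):
    return GuildSpec(name, category, living, tuple(zones), tuple(prey), pair, ice)


#: Canonical compartment ordering used by every state vector in the package.
GUILDS: tuple[GuildSpec, ...] = (
    # -- dissolved nutrients -------------------------------------------------
    _g("surface_nitrate", "nutrient", False, ("surface_inshore", "surface_offshore")),
    _g("surface_ammonia", "nutrient", False, ("surface_inshore", "surface_offshore")),
    _g("deep_nitrate", "nutrient", False, ("deep",)),
    _g("deep_ammonia", "nutrient", False, ("deep",)),
    _g("porewater_nitrate", "nutrient", False, ("seabed",)),
    _g("porewater_ammonia", "nutrient", False, ("seabed",)),
    # -- cryosphere dissolved pools ------------------------------------------
    _g("snow_nitrate", "cryosphere", False, ("ice",)),
    _g("snow_ammonia", "cryosphere", False, ("ice",)),
    _g("ice_nitrate", "cryosphere", False, ("ice",)),
    _g("ice_ammonia", "cryosphere", False, ("ice",)),
    # -- detritus ------------------------------------------------------------
    _g("surface_detritus", "detritus", False, ("surface_inshore", "surface_offshore")),
    _g("deep_detritus", "detritus", False, ("deep",)),
    _g("ice_detritus", "detritus", False, ("ice",)),
    _g("sediment_labile_detritus", "detritus", False, ("seabed",)),
    _g("sediment_refractory_detritus", "detritus", False, ("seabed",)),
    _g("corpses", "corpse", False, ("deep", "seabed")),
    # -- producers -------------------------------------------------------------
    _g("surface_phyto", "producer", True, ("surface_inshore", "surface_offshore")),
    _g("deep_phyto", "producer", True, ("deep",)),
    _g("ice_algae", "producer", True, ("ice",)),
    _g("macrophytes", "producer", True, ("surface_inshore",)),
    # -- consumers -------------------------------------------------------------
    _g(
        "omniv_zoo", "consumer", True, ("surface_inshore", "surface_offshore"),
        prey=(
            ("surface_phyto", 0.47),
            ("deep_phyto", 0.13),
            ("ice_algae", 0.05),
            ("surface_detritus", 0.30),
            ("ice_detritus", 0.05),
        ),
    ),
    _g(
        "carn_zoo", "consumer", True, ("surface_inshore", "surface_offshore"),
        prey=(
            ("omniv_zoo", 0.85),
            ("plank_fish_larvae", 0.07),
            ("dem_fish_larvae", 0.05),
            ("benthos_susp_larvae", 0.03),
        ),
    ),
    _g(
        "plank_fish", "consumer", True, ("surface_inshore", "surface_offshore"),
        prey=(
            ("omniv_zoo", 0.60),
            ("carn_zoo", 0.30),
            ("benthos_carn_larvae", 0.05),
            ("benthos_susp_larvae", 0.05),
        ),
        pair="plank_fish_larvae",
    ),
    _g(
        "plank_fish_larvae", "consumer", True, ("surface_inshore", "surface_offshore"),
        prey=(("omniv_zoo", 1.0),),
        pair="plank_fish",
    ),
    _g(
        "dem_fish", "consumer", True, ("deep", "seabed"),
        prey=(
            ("plank_fish", 0.35),
            ("benthos_susp", 0.25),
            ("benthos_carn", 0.20),
            ("carn_zoo", 0.10),
            ("corpses", 0.10),
        ),
        pair="dem_fish_larvae",
    ),
    _g(
        "dem_fish_larvae", "consumer", True, ("surface_inshore", "surface_offshore"),
        prey=(("omniv_zoo", 1.0),),
        pair="dem_fish",
    ),
    _g(
        "migratory_fish", "consumer", True, ("surface_inshore", "surface_offshore"),
        prey=(
            ("omniv_zoo", 0.50),
            ("carn_zoo", 0.30),
            ("plank_fish", 0.10),
            ("benthos_susp", 0.10),
        ),
    ),
    _g(
        "benthos_susp", "consumer", True, ("seabed",),
        prey=(
            ("surface_detritus", 0.30),
            ("deep_detritus", 0.30),
            ("sediment_labile_detritus", 0.25),
            ("surface_phyto", 0.15),
        ),
        pair="benthos_susp_larvae",
    ),
    _g(
        "benthos_susp_larvae", "consumer", True,
        ("surface_inshore", "surface_offshore"),
        prey=(("surface_phyto", 0.5), ("surface_detritus", 0.5)),
        pair="benthos_susp",
    ),
    _g(
        "benthos_carn", "consumer", True, ("seabed",),
        prey=(
            ("benthos_susp", 0.50),
            ("corpses", 0.25),
            ("deep_detritus", 0.15),
            ("macrophytes", 0.10),
        ),
        pair="benthos_carn_larvae",
    ),
    _g(
        "benthos_carn_larvae", "consumer", True,
        ("surface_inshore", "surface_offshore"),
        prey=(("surface_phyto", 0.6), ("surface_detritus", 0.4)),
        pair="benthos_carn",
    ),
    _g(
        "birds", "consumer", True, ("surface_inshore", "surface_offshore"),
        prey=(
            ("plank_fish", 0.45),
            ("carn_zoo", 0.15),
            ("omniv_zoo", 0.10),
            ("migratory_fish", 0.10),
            ("plank_fish_larvae", 0.05),
            ("benthos_carn", 0.05),
            ("corpses", 0.10),
        ),
    ),
    _g(
        "pinnipeds", "consumer", True, ("surface_inshore", "surface_offshore", "ice"),
        prey=(
            ("plank_fish", 0.45),
            ("dem_fish", 0.20),
            ("benthos_carn", 0.10),
            ("migratory_fish", 0.10),
            ("carn_zoo", 0.10),
            ("corpses", 0.05),
        ),
    ),
    _g(
        "cetaceans", "consumer", True, ("surface_inshore", "surface_offshore"),
        prey=(
            ("migratory_fish", 0.30),
            ("plank_fish", 0.28),
            ("carn_zoo", 0.20),
            ("omniv_zoo", 0.12),
            ("dem_fish", 0.05),
            ("benthos_carn", 0.05),
        ),
        ice="requires_open_water",
    ),
    _g(
        "maritime_mammals", "consumer", True, ("ice",),
        prey=(
            ("pinnipeds", 0.75),
            ("corpses", 0.20),
            ("cetaceans", 0.05),
        ),
        ice="requires_ice",
    ),
)

COMPARTMENTS: tuple[str, ...] = tuple(g.name for g in GUILDS)
CATEGORY: dict[str, str] = {g.name: g.category for g in GUILDS}
_INDEX = {name: i for i, name in enumerate(COMPARTMENTS)}

PRODUCERS = tuple(g.name for g in GUILDS if g.category == "producer")
CONSUMERS = tuple(g.name for g in GUILDS if g.category == "consumer")

#: The four top-predator guilds used for the mass-weighted mean trophic level.
TOP_PREDATORS = ("maritime_mammals", "pinnipeds", "cetaceans", "birds")

#: (adult, larva) spawning/recruitment links; these transfers are demographic
#: and are excluded from the trophic flow matrix.
DEMOGRAPHIC_PAIRS = (
    ("plank_fish", "plank_fish_larvae"),
    ("dem_fish", "dem_fish_larvae"),
    ("benthos_susp", "benthos_susp_larvae"),
    ("benthos_carn", "benthos_carn_larvae"),
)


def index_of(name: str) -> int:
    """Position of a compartment in the canonical state-vector ordering."""
    try:
        return _INDEX[name]
    except KeyError:
        raise KeyError(f"unknown compartment {name!r}") from None


def living_names() -> tuple[str, ...]:
    return tuple(g.name for g in GUILDS if g.living)


def detrital_names() -> tuple[str, ...]:
    """Compartments whose consumption counts as recycling (detritivory)."""
    return tuple(
        g.name for g in GUILDS if g.category in ("detritus", "corpse")
    )


def guild(name: str) -> GuildSpec:
    return GUILDS[index_of(name)]
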
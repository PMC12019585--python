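"""Model parameters: defaults, validation, YAML round-trip and flattening.

Units: specific rates d^-1, half-saturations mmol N m^-3 (water column) or
mmol N m^-2 (areal food availability, ice-algal nutrient pools), lengths m,
light E m^-2 d^-1, fractions dimensionless in [0, 1].
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .guilds import CONSUMERS, PRODUCERS

__all__ = ["ProducerParams", "ConsumerParams", "ModelParams", "default_params"]


@dataclass
class ProducerParams:
    u_max_nitrate: float  # d^-1 maximum specific nitrate uptake
    u_max_ammonia: float  # d^-1 maximum specific ammonia uptake
    k_nitrate: float      # half-saturation, mmol N m^-3 (areal for ice algae)
    k_ammonia: float
    k_light: float        # saturation light intensity, E m^-2 d^-1
    k_inhib: float        # ammonia inhibition of nitrate uptake, mmol N m^-3
    resp_frac: float      # fraction of uptake lost as metabolic ammonia
    mort: float           # d^-1 linear mortality to detritus
    mort_dd: float = 0.0  # m^2 (mmol N)^-1 d^-1 self-limitation (canopy shading)


@dataclass
class ConsumerParams:
    u_max: float       # d^-1 maximum specific ingestion
    k_food: float      # half-saturation on preference-weighted food, mmol N m^-2
    assim_eff: float   # assimilated fraction of intake
    excr_frac: float   # fraction of assimilate excreted as ammonia
    mort: float        # d^-1 linear mortality
    mort_dd: float     # m^2 (mmol N)^-1 d^-1 density-dependent closure


def _producer_defaults() -> dict[str, ProducerParams]:
    return {
        "surface_phyto": ProducerParams(0.85, 1.00, 0.8, 0.5, 6.0, 0.4, 0.08, 0.04),
        "deep_phyto": ProducerParams(0.85, 1.00, 0.8, 0.5, 6.0, 0.4, 0.08, 0.05),
        # ice algae are shade adapted; their nutrient half-saturations act on
        # the areal brine pools (mmol N m^-2)
        "ice_algae": ProducerParams(0.45, 0.50, 0.15, 0.10, 0.05, 0.05, 0.08, 0.02),
        "macrophytes": ProducerParams(0.035, 0.040, 1.5, 1.0, 1.5, 0.4, 0.10, 0.0010, 1.0e-4),
    }


def _consumer_defaults() -> dict[str, ConsumerParams]:
    return {
        "omniv_zoo": ConsumerParams(0.40, 4.0, 0.60, 0.35, 0.015, 2.0e-3),
        "carn_zoo": ConsumerParams(0.12, 6.0, 0.65, 0.30, 0.008, 1.5e-3),
        "plank_fish": ConsumerParams(0.040, 6.0, 0.70, 0.30, 0.0020, 8.0e-4),
        "plank_fish_larvae": ConsumerParams(0.060, 6.0, 0.60, 0.35, 0.010, 0.0),
        "dem_fish": ConsumerParams(0.018, 8.0, 0.70, 0.30, 0.0015, 5.0e-4),
        "dem_fish_larvae": ConsumerParams(0.060, 6.0, 0.60, 0.35, 0.010, 0.0),
        "migratory_fish": ConsumerParams(0.030, 6.0, 0.70, 0.30, 0.0020, 0.0),
        "benthos_susp": ConsumerParams(0.035, 15.0, 0.50, 0.30, 0.0020, 2.0e-4),
        "benthos_susp_larvae": ConsumerParams(0.10, 4.0, 0.50, 0.35, 0.010, 0.0),
        "benthos_carn": ConsumerParams(0.012, 10.0, 0.60, 0.30, 0.0010, 3.0e-4),
        "benthos_carn_larvae": ConsumerParams(0.10, 4.0, 0.50, 0.35, 0.010, 0.0),
        "birds": ConsumerParams(0.020, 4.0, 0.75, 0.40, 5.0e-4, 2.0e-2),
        "pinnipeds": ConsumerParams(0.015, 4.0, 0.80, 0.40, 4.0e-4, 1.5e-2),
        "cetaceans": ConsumerParams(0.040, 5.0, 0.80, 0.40, 3.0e-4, 1.5e-2),
        "maritime_mammals": ConsumerParams(0.010, 0.15, 0.85, 0.40, 2.0e-4, 5.0e-2),
    }


@dataclass
class ModelParams:
    """Full parameter set for the nitrogen mass-balance model."""

    producers: dict[str, ProducerParams] = field(default_factory=_producer_defaults)
    consumers: dict[str, ConsumerParams] = field(default_factory=_consumer_defaults)

    # temperature scaling per process class (Q10 with a reference temperature)
    q10_feeding: float = 1.8
    q10_uptake: float = 1.3
    q10_mineralisation: float = 2.0
    t_ref: float = 0.0

    # extra density-dependent pressure on maritime mammals as habitat shrinks
    interference: float = 1.0

    # detritus / nutrient cycling, d^-1
    sink_surface_detritus: float = 0.05
    sink_deep_detritus: float = 0.03
    phyto_sink: float = 0.02
    miner_surface: float = 0.030
    miner_deep: float = 0.020
    miner_sediment: float = 0.010
    miner_ice: float = 0.002
    labile_to_refractory: float = 2.0e-5
    corpse_to_detritus: float = 0.02
    corpse_miner: float = 0.01
    nitrif_surface: float = 0.020
    nitrif_deep: float = 0.020
    nitrif_sediment: float = 0.050
    sediment_exchange: float = 0.10  # m d^-1 piston velocity porewater <-> deep

    # optics of snow, ice and water
    k_ice: float = 1.5        # m^-1
    k_snow: float = 10.0      # m^-1
    albedo: float = 0.6       # snow/ice surface reflection
    k_water: float = 0.04     # m^-1 background attenuation
    k_spm: float = 0.03       # m^-1 per g m^-3 suspended matter

    # cryosphere nutrient coupling
    entrain_eff: float = 0.6   # fraction of surface concentration frozen in
    release_eff: float = 1.0   # melt-release scaling
    ice_free_leak: float = 0.2  # d^-1 drain of cryosphere pools with no ice

    # migratory fish boundary stock and seasonal presence window
    migratory_stock: float = 0.3      # mmol N m^-2 outside the domain
    migratory_in_frac: float = 0.4    # fraction entering each year
    migration_entry_day: float = 90.0
    migration_entry_days: float = 30.0
    migration_exit_day: float = 270.0
    migration_exit_rate: float = 0.15  # d^-1

    # spawning / recruitment (demographic transfers, not trophic flows)
    spawn_day: float = 60.0
    spawn_days: float = 60.0
    spawn_rate: float = 0.002   # d^-1 adult -> larvae
    recruit_day: float = 240.0
    recruit_days: float = 60.0
    recruit_rate: float = 0.08  # d^-1 larvae -> adult

    # physical configuration (whole-domain area = 1)
    area_inshore: float = 0.35
    area_offshore: float = 0.65
    depth_surface: float = 40.0     # m, both zones
    depth_deep: float = 160.0       # m, offshore only
    depth_macrophyte: float = 10.0  # m, effective depth of the macrophyte bed
    porewater_depth: float = 0.3    # m, effective porewater volume per area
    mix_length: float = 100.0       # m, surface <-> deep mixing length
    wave_mort_coef: float = 0.15    # macrophyte loss per m significant wave height

    # tiny refuge mass added to producer/consumer uptake terms so transient
    # collapses are not absorbing (recolonisation from unresolved refugia)
    seed_refuge: float = 1e-6

    # fishing: activity fixed at zero for the "natural" system; harvest ratios
    # are retained so that sensitivity screening can perturb them
    fishing_activity: float = 0.0
    harvest: dict[str, float] = field(
        default_factory=lambda: {name: 0.1 for name in CONSUMERS}
    )

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------------
    def validate(self) -> None:
        missing = set(PRODUCERS) - set(self.producers)
        if missing:
            raise ValueError(f"missing producer parameters: {sorted(missing)}")
        missing = set(CONSUMERS) - set(self.consumers)
        if missing:
            raise ValueError(f"missing consumer parameters: {sorted(missing)}")
        for q in (self.q10_feeding, self.q10_uptake, self.q10_mineralisation):
            if q < 1.0:
                raise ValueError("Q10 values must be >= 1")
        for name, p in self.producers.items():
            for f_ in ("resp_frac",):
                _check_frac(getattr(p, f_), f"{name}.{f_}")
            _check_nonneg_obj(p, name)
        for name, c in self.consumers.items():
            _check_frac(c.assim_eff, f"{name}.assim_eff")
            _check_frac(c.excr_frac, f"{name}.excr_frac")
            _check_nonneg_obj(c, name)
        _check_frac(self.albedo, "albedo")
        if not 0.999 <= self.area_inshore + self.area_offshore <= 1.001:
            raise ValueError("zone area fractions must sum to 1")

    # -- serialisation ----------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        d = dict(d)
        d["producers"] = {
            k: ProducerParams(**v) for k, v in d.get("producers", {}).items()
        }
        d["consumers"] = {
            k: ConsumerParams(**v) for k, v in d.get("consumers", {}).items()
        }
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter entries: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            "# cryoweb model parameters (rates d^-1, lengths m, light E m^-2 d^-1)\n"
            + yaml.safe_dump(self.to_dict(), sort_keys=True)
        )

    @classmethod
    def load(cls, path: str | Path) -> "ModelParams":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"parameter file {path} is not a mapping")
        return cls.from_dict(data)

    def copy(self) -> "ModelParams":
        return ModelParams.from_dict(self.to_dict())

    # -- flattening (used by the sensitivity module) ---------------------------
    def flatten(self) -> dict[str, float]:
        """Every scalar parameter as ``dotted.name -> value``."""
        out: dict[str, float] = {}
        for gname, p in self.producers.items():
            for f_ in fields(ProducerParams):
                out[f"producers.{gname}.{f_.name}"] = getattr(p, f_.name)
        for gname, c in self.consumers.items():
            for f_ in fields(ConsumerParams):
                out[f"consumers.{gname}.{f_.name}"] = getattr(c, f_.name)
        for f_ in fields(ModelParams):
            if f_.name in ("producers", "consumers", "harvest"):
                continue
            out[f_.name] = float(getattr(self, f_.name))
        for gname, v in self.harvest.items():
            out[f"harvest.{gname}"] = v
        return out

    def with_value(self, dotted: str, value: float) -> "ModelParams":
        """Return a copy with one flattened entry replaced."""
        new = self.copy()
        parts = dotted.split(".")
        if parts[0] == "producers":
            setattr(new.producers[parts[1]], parts[2], value)
        elif parts[0] == "consumers":
            setattr(new.consumers[parts[1]], parts[2], value)
        elif parts[0] == "harvest":
            new.harvest[parts[1]] = value
        elif len(parts) == 1 and hasattr(new, parts[0]):
            setattr(new, parts[0], value)
        else:
            raise KeyError(f"unknown parameter {dotted!r}")
        return new


def _check_frac(x: float, name: str) -> None:
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{name} must be a fraction in [0, 1], got {x}")


def _check_nonneg_obj(obj, name: str) -> None:
    for f_ in fields(obj):
        v = getattr(obj, f_.name)
        if v < 0:
            raise ValueError(f"{name}.{f_.name} must be >= 0, got {v}")


def default_params() -> ModelParams:
    """The shipped default parameterisation (ice-dominated, oligotrophic)."""
    return ModelParams()
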
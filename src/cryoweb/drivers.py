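"""Synthetic monthly climatological forcing for decadal scenarios.

Emulates the forcing a high-emissions ocean/biogeochemistry projection
supplies for an Arctic shelf: a cold, perennially ice-covered baseline decade
that warms linearly and becomes seasonally ice-free by the final decade,
with a polar-latitude daylight cycle and slowly declining boundary nitrate.

The native driver resolution is monthly (12 values per variable per decade);
inside the solver daily values are linear interpolations between month
midpoints, wrapping at year end (360-day year, 30-day months).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "VARIABLES",
    "DriverSet",
    "ScenarioConfig",
    "ExperimentSpec",
    "KNOCKOUT_SETS",
    "EXPERIMENT_NAMES",
    "generate_decadal_drivers",
    "apply_knockout",
    "write_drivers",
    "read_drivers",
    "roundtrip_drivers",
    "month_midpoints",
    "interp_annual",
]

#: Complete driver inventory.  SO/SI/D = surface offshore, surface inshore,
#: deep compartments.
VARIABLES: tuple[str, ...] = (
    "SO_temp", "D_temp", "SI_temp", "SO_AirTemp", "SI_AirTemp",
    "Slight",
    "SO_IceFree", "SI_IceFree", "SO_IceCover", "SI_IceCover",
    "SO_IceThickness", "SI_IceThickness", "SO_SnowThickness", "SI_SnowThickness",
    "SO_OceanIN", "D_OceanIN", "SI_OceanIN", "SI_OceanOUT", "SO_SI_flow",
    "SO_nitrate", "SO_ammonia", "SO_phyt", "SO_detritus",
    "D_nitrate", "D_ammonia", "D_phyt", "D_detritus",
    "SI_nitrate", "SI_ammonia", "SI_phyt", "SI_detritus",
    "river_volume", "meltwater_DIN",
    "atm_deposition_wet", "atm_deposition_dry",
    "SPM_inshore", "SPM_offshore_upper", "wave_height_inshore",
    "vertical_diffusivity",
)

_FRACTIONAL = {"SO_IceFree", "SI_IceFree", "SO_IceCover", "SI_IceCover"}
_SIGNED = {"SO_temp", "D_temp", "SI_temp", "SO_AirTemp", "SI_AirTemp"}

YEAR_DAYS = 360.0


def month_midpoints() -> np.ndarray:
    """Day-of-year of the centre of each 30-day month (15, 45, ..., 345)."""
    return 15.0 + 30.0 * np.arange(12)


@dataclass
class DriverSet:
    """Monthly climatology of every forcing variable for one decade/experiment."""

    decade_label: str
    data: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = {k: np.asarray(v, dtype=float) for k, v in self.data.items()}
        self.validate()

    def validate(self) -> None:
        missing = set(VARIABLES) - set(self.data)
        if missing:
            raise ValueError(f"missing driver variables: {sorted(missing)}")
        unknown = set(self.data) - set(VARIABLES)
        if unknown:
            raise ValueError(f"unknown driver variables: {sorted(unknown)}")
        for name, series in self.data.items():
            if series.shape != (12,):
                raise ValueError(
                    f"{name}: expected 12 monthly values, got shape {series.shape}"
                )
            if name in _FRACTIONAL and (
                series.min() < -1e-12 or series.max() > 1.0 + 1e-12
            ):
                raise ValueError(f"{name}: fractional values outside [0, 1]")
            if name not in _SIGNED and series.min() < -1e-12:
                raise ValueError(f"{name}: negative values not allowed")
        for zone in ("SO", "SI"):
            cover = self.data[f"{zone}_IceCover"]
            thick = self.data[f"{zone}_IceThickness"]
            if np.any((thick == 0.0) & (cover > 1e-12)):
                raise ValueError(f"{zone}: IceCover must be 0 wherever IceThickness is 0")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[name]

    def copy(self) -> "DriverSet":
        return DriverSet(self.decade_label, {k: v.copy() for k, v in self.data.items()})

    def equals(self, other: "DriverSet") -> bool:
        return self.decade_label == other.decade_label and all(
            np.array_equal(self.data[k], other.data[k]) for k in VARIABLES
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (var, m + 1, self.data[var][m]) for var in VARIABLES for m in range(12)
        ]
        return pd.DataFrame(rows, columns=["variable", "month", "value"])


def interp_annual(series: np.ndarray, t: np.ndarray | float) -> np.ndarray:
    """Linear interpolation of a 12-value monthly series at day-of-year ``t``,
    between month midpoints, wrapping at year end."""
    mids = month_midpoints()
    xp = np.concatenate(([mids[-1] - YEAR_DAYS], mids, [mids[0] + YEAR_DAYS]))
    fp = np.concatenate(([series[-1]], series, [series[0]]))
    return np.interp(np.mod(t, YEAR_DAYS), xp, fp)


@dataclass
class ScenarioConfig:
    """Decadal trend scenario controlling the synthetic drivers."""

    baseline_decade: int = 0
    n_decades: int = 5
    warming_per_decade: float = 0.5              # degC per decade, all water/air temps
    ice_season_shortening_per_decade: float = 12.0  # days added to the melt window
    ice_cover_decline_per_decade: float = 0.10      # winter-cover loss per decade
    thickness_decline_per_decade: float = 0.30      # m per decade
    boundary_nitrate_trend: float = 0.03            # fractional decline per decade
    latitude: float = 76.0                          # deg N, daylight cycle
    seed: int = 0
    noise_sd: float = 0.0  # optional multiplicative jitter; off by default

    def __post_init__(self) -> None:
        if self.n_decades < 1:
            raise ValueError("n_decades must be >= 1")
        if not 60.0 <= self.latitude <= 90.0:
            raise ValueError("latitude must lie in [60, 90]")
        for name in (
            "warming_per_decade",
            "ice_season_shortening_per_decade",
            "ice_cover_decline_per_decade",
            "thickness_decline_per_decade",
            "boundary_nitrate_trend",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name}: trend magnitudes must be >= 0")


# ---------------------------------------------------------------------------
# knock-out experiment definitions
# ---------------------------------------------------------------------------

#: Driver groups frozen at baseline values in each knock-out experiment.
KNOCKOUT_SETS: dict[str, tuple[str, ...]] = {
    "full_climate": (),
    "boundary": (
        "SO_nitrate", "SO_ammonia", "SO_phyt", "SO_detritus",
        "D_nitrate", "D_ammonia", "D_phyt", "D_detritus",
        "SI_nitrate", "SI_ammonia", "SI_phyt", "SI_detritus",
    ),
    "flows": ("SO_OceanIN", "D_OceanIN", "SI_OceanIN", "SI_OceanOUT", "SO_SI_flow"),
    "ice": (
        "SO_IceFree", "SI_IceFree", "SO_IceCover", "SI_IceCover",
        "SO_IceThickness", "SI_IceThickness", "SO_SnowThickness", "SI_SnowThickness",
    ),
    "light": ("Slight",),
    "temperature": ("SO_temp", "D_temp", "SI_temp", "SO_AirTemp", "SI_AirTemp"),
}
# the attenuation daughter experiment freezes the same drivers as the ice
# knock-out but additionally zeroes the snow/ice optics parameters
KNOCKOUT_SETS["attenuation"] = KNOCKOUT_SETS["ice"]

EXPERIMENT_NAMES = tuple(KNOCKOUT_SETS)


@dataclass
class ExperimentSpec:
    """One knock-out (or full-climate) run definition."""

    name: str
    decade: int = 0
    held_variables: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.name not in KNOCKOUT_SETS:
            raise ValueError(
                f"unknown experiment {self.name!r}; expected one of {EXPERIMENT_NAMES}"
            )
        if self.held_variables is None:
            self.held_variables = KNOCKOUT_SETS[self.name]
        self.held_variables = tuple(self.held_variables)
        unknown = set(self.held_variables) - set(VARIABLES)
        if unknown:
            raise ValueError(f"unknown driver variables in held set: {sorted(unknown)}")

    @property
    def overrides_attenuation(self) -> bool:
        return self.name == "attenuation"


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

_SOLAR_SCALE = 60.0  # E m^-2 d^-1 at overhead sun, clear Arctic atmosphere

# baseline seasonal-envelope constants (decade 0 = the 2010s analogue)
_WINTER_COVER = 0.96
_MELT_AMP0 = 0.38
_MELT_AMP_GROWTH = 0.33   # per decade, deepens the summer melt
_MELT_WIDTH0 = 40.0       # days
_MELT_PEAK = 225.0        # day of year of maximum melt
_THICKNESS0 = 1.8         # m
_SNOW0 = 0.35             # m


def _daylight_irradiance(lat_deg: float) -> np.ndarray:
    """Daily-mean surface irradiance from the astronomical daylight cycle."""
    phi = math.radians(lat_deg)
    days = month_midpoints()
    out = np.empty(12)
    for i, day in enumerate(days):
        decl = math.radians(-23.44 * math.cos(2 * math.pi * (day + 10.0) / YEAR_DAYS))
        cos_h0 = -math.tan(phi) * math.tan(decl)
        h0 = math.acos(min(1.0, max(-1.0, cos_h0)))
        mu = (
            h0 * math.sin(phi) * math.sin(decl)
            + math.cos(phi) * math.cos(decl) * math.sin(h0)
        ) / math.pi
        out[i] = _SOLAR_SCALE * max(mu, 0.0)
    return out


def _cosine(mean: float, amp: float, peak_day: float) -> np.ndarray:
    days = month_midpoints()
    return mean + amp * np.cos(2 * np.pi * (days - peak_day) / YEAR_DAYS)


def _melt_shape(width: float) -> np.ndarray:
    days = month_midpoints()
    return np.exp(-(((days - _MELT_PEAK) / width) ** 2))


def _ice_fields(config: ScenarioConfig, decade: int) -> dict[str, np.ndarray]:
    winter = _WINTER_COVER - config.ice_cover_decline_per_decade * decade
    amp = _MELT_AMP0 + _MELT_AMP_GROWTH * decade
    width = _MELT_WIDTH0 + config.ice_season_shortening_per_decade * decade
    base = np.clip(winter - amp * _melt_shape(width), 0.0, 1.0)
    thick_max = max(_THICKNESS0 - config.thickness_decline_per_decade * decade, 0.05)
    snow_max = max(_SNOW0 - 0.05 * decade, 0.0)
    out: dict[str, np.ndarray] = {}
    for zone, scale in (("SO", 0.97), ("SI", 1.04)):
        cover = np.clip(scale * base, 0.0, 1.0)
        out[f"{zone}_IceCover"] = cover
        out[f"{zone}_IceFree"] = 1.0 - cover
        out[f"{zone}_IceThickness"] = thick_max * cover
        # snow disappears before the ice does
        out[f"{zone}_SnowThickness"] = snow_max * np.clip(cover - 0.25, 0.0, None) / 0.75
    return out


def generate_decadal_drivers(config: ScenarioConfig, decade: int) -> DriverSet:
    """Build the monthly driver climatology for one decade of the scenario.

    Deterministic given ``(config, decade)``; the seed only matters when the
    optional noise is switched on (``config.noise_sd > 0``).
    """
    if not 0 <= decade < config.n_decades:
        raise IndexError(
            f"decade {decade} outside scenario range [0, {config.n_decades})"
        )
    d = decade
    warm = config.warming_per_decade * d
    ntrend = max(0.0, 1.0 - config.boundary_nitrate_trend * d)

    data: dict[str, np.ndarray] = {}
    data.update(_ice_fields(config, d))

    data["SO_temp"] = _cosine(-0.9, 1.0, _MELT_PEAK) + warm
    data["SI_temp"] = _cosine(-1.0, 1.0, _MELT_PEAK) + warm
    data["D_temp"] = _cosine(0.3, 0.15, _MELT_PEAK + 30) + 0.3 * warm
    data["SO_AirTemp"] = _cosine(-8.0, 11.0, 200.0) + 1.8 * warm
    data["SI_AirTemp"] = _cosine(-9.0, 11.0, 200.0) + 1.8 * warm

    data["Slight"] = _daylight_irradiance(config.latitude)

    data["SO_OceanIN"] = _cosine(0.0020, 0.0005, 30.0)
    data["D_OceanIN"] = np.full(12, 0.0010)
    data["SI_OceanIN"] = _cosine(0.0030, 0.0005, 30.0)
    data["SI_OceanOUT"] = _cosine(0.0030, 0.0005, 30.0)
    data["SO_SI_flow"] = np.full(12, 0.0020)

    days = month_midpoints()
    bloom = np.exp(-(((days - 200.0) / 50.0) ** 2))
    data["SO_nitrate"] = _cosine(11.0, 2.5, 20.0) * ntrend
    data["SO_ammonia"] = _cosine(0.6, 0.2, 250.0)
    data["SO_phyt"] = 0.05 + 1.2 * bloom
    data["SO_detritus"] = 0.4 + 0.3 * bloom
    data["D_nitrate"] = np.full(12, 13.5) * ntrend
    data["D_ammonia"] = np.full(12, 0.8)
    data["D_phyt"] = np.full(12, 0.05)
    data["D_detritus"] = np.full(12, 0.3)
    data["SI_nitrate"] = _cosine(10.0, 2.5, 20.0) * ntrend
    data["SI_ammonia"] = _cosine(0.7, 0.2, 250.0)
    data["SI_phyt"] = 0.05 + 1.0 * bloom
    data["SI_detritus"] = 0.5 + 0.3 * bloom

    data["river_volume"] = 0.0002 + 0.0006 * np.exp(-(((days - 210.0) / 40.0) ** 2))
    data["meltwater_DIN"] = np.full(12, 4.0)
    data["atm_deposition_wet"] = np.full(12, 0.0015)
    data["atm_deposition_dry"] = np.full(12, 0.0008)
    data["SPM_inshore"] = 1.5 + 0.5 * bloom
    data["SPM_offshore_upper"] = np.full(12, 0.35)
    data["wave_height_inshore"] = _cosine(1.1, 0.5, 30.0)
    data["vertical_diffusivity"] = _cosine(15.0, 13.0, 15.0)

    if config.noise_sd > 0.0:
        rng = np.random.default_rng(config.seed + 1000 * d)
        for name in VARIABLES:
            jitter = rng.lognormal(0.0, config.noise_sd, 12)
            if name in _SIGNED:
                data[name] = data[name] + rng.normal(0.0, config.noise_sd, 12)
            else:
                data[name] = data[name] * jitter
            if name in _FRACTIONAL:
                data[name] = np.clip(data[name], 0.0, 1.0)
        # restore the cover/thickness consistency invariant
        for zone in ("SO", "SI"):
            cover = data[f"{zone}_IceCover"]
            cover[data[f"{zone}_IceThickness"] == 0.0] = 0.0
            data[f"{zone}_IceFree"] = 1.0 - cover

    return DriverSet(decade_label=f"decade_{d}", data=data)


def apply_knockout(
    scenario_drivers: DriverSet,
    baseline_drivers: DriverSet,
    experiment: ExperimentSpec,
) -> DriverSet:
    """Freeze the experiment's driver group at baseline values.

    Returns a copy of ``scenario_drivers`` in which every held variable is
    copied verbatim from ``baseline_drivers``; all other series are untouched.
    """
    unknown = set(experiment.held_variables) - set(VARIABLES)
    if unknown:
        raise ValueError(f"unknown driver variables: {sorted(unknown)}")
    out = scenario_drivers.copy()
    for name in experiment.held_variables:
        out.data[name] = baseline_drivers.data[name].copy()
    out.validate()
    return out


# ---------------------------------------------------------------------------
# persistence (long-format delimited text)
# ---------------------------------------------------------------------------

def write_drivers(path: str | Path, driver_set: DriverSet) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# decade_label: {driver_set.decade_label}\n")
        driver_set.to_frame().to_csv(fh, index=False, float_format="%.17g")


def read_drivers(path: str | Path) -> DriverSet:
    path = Path(path)
    label = "unknown"
    with path.open() as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition(":")
            if key.strip() == "decade_label":
                label = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        frame = pd.read_csv(fh, float_precision="round_trip")
    expected = {"variable", "month", "value"}
    if set(frame.columns) != expected:
        raise ValueError(f"driver file columns {list(frame.columns)} != {sorted(expected)}")
    unknown = set(frame["variable"]) - set(VARIABLES)
    if unknown:
        raise ValueError(f"unknown driver variables in file: {sorted(unknown)}")
    data = {}
    for name, grp in frame.groupby("variable"):
        grp = grp.sort_values("month")
        if list(grp["month"]) != list(range(1, 13)):
            raise ValueError(f"{name}: expected months 1..12, got {list(grp['month'])}")
        data[name] = grp["value"].to_numpy()
    return DriverSet(decade_label=label, data=data)


def roundtrip_drivers(path: str | Path, driver_set: DriverSet) -> DriverSet:
    """Write then re-read a driver set (identity to full stored precision)."""
    write_drivers(path, driver_set)
    return read_drivers(path)
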
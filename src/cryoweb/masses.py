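"""Published guild nitrogen-mass inventory, packaged as a fixture.

Annual-average nitrogen masses (mmol N m^-2, whole model domain) for the
Greenland-shelf system in its baseline (2010s) and seasonally ice-free
(2050s) states, with the Barents Sea 2010s values as a sense check.  The
table is stored verbatim, ordered with the lowest concentrations first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .guilds import COMPARTMENTS

__all__ = ["MassTableFixture", "load_mass_fixture", "MASS_TABLE_COLUMNS"]

MASS_TABLE_COLUMNS = ("GL_2010s", "GL_2050s", "BS_2010s")

# (guild label, GL 2010s, GL 2050s, BS 2010s)
_ROWS: tuple[tuple[str, float, float, float], ...] = (
    ("Birds", 5.048656e-03, 1.490990e-02, 1.237110e-02),
    ("Pinnipeds", 1.062421e-02, 7.754153e-02, 7.148973e-02),
    ("Maritime mammals", 1.417246e-02, 4.774963e-03, 2.516999e-03),
    ("Migratory fish", 6.195191e-02, 6.233540e-02, 6.320373e-02),
    ("Ice algae", 6.258407e-02, 5.316104e-02, 6.388779e-02),
    ("Cetaceans", 8.885116e-02, 3.137842e-01, 4.532786e-01),
    ("Demersal fish larvae", 9.627418e-02, 2.675364e-01, 7.227460e-01),
    ("Planktivorous fish larvae", 9.637280e-02, 4.328851e-01, 2.331033e-01),
    ("Snow ammonia", 2.248572e-01, 8.568849e-02, 8.928734e-02),
    ("Snow nitrate", 3.265977e-01, 1.245446e-01, 7.936141e-02),
    ("Ice ammonia", 4.754215e-01, 5.340487e-02, 9.325340e-02),
    ("Benthos carn/scav feeders larvae", 5.484466e-01, 6.846217e-01, 7.100788e-01),
    ("Benthos susp/dep feeders larvae", 5.790206e-01, 9.411860e-01, 1.043274e+00),
    ("Ice nitrate", 7.150457e-01, 2.891845e-01, 1.922444e-02),
    ("Ice detritus", 7.873267e-01, 8.152309e-01, 1.119108e+00),
    ("Sediment porewater nitrate", 9.893880e-01, 7.307051e-01, 9.118393e-01),
    ("Deep layer phytoplankton", 1.092862e+00, 1.398580e+00, 9.070223e-01),
    ("Demersal fish", 1.338207e+00, 3.648652e+00, 7.296833e+00),
    ("Planktivorous fish", 1.387123e+00, 6.343029e+00, 3.368735e+00),
    ("Sediment porewater ammonia", 1.584903e+00, 2.063427e+00, 2.510188e+00),
    ("Corpses", 1.955949e+00, 2.898967e+00, 3.027624e+00),
    ("Carnivorous zooplankton", 4.978142e+00, 5.792072e+00, 9.320204e+00),
    ("Surface layer phytoplankton", 6.170512e+00, 7.422738e+00, 7.392445e+00),
    ("Deep layer detritus", 6.348369e+00, 6.665317e+00, 8.912465e+00),
    ("Benthos carn/scav feeders", 9.294691e+00, 1.036397e+01, 8.751406e+00),
    ("Surface layer detritus", 1.061713e+01, 1.126787e+01, 1.137937e+01),
    ("Benthos susp/dep feeders", 4.253288e+01, 5.231259e+01, 5.142915e+01),
    ("Omnivorous zooplankton", 4.822393e+01, 5.846732e+01, 9.471605e+01),
    ("Macrophyte nitrogen", 4.873217e+01, 4.722330e+01, 5.041410e+01),
    ("Surface layer ammonia", 5.800559e+01, 5.609282e+01, 1.930920e+02),
    ("Deep layer ammonia", 7.257979e+01, 7.652691e+01, 3.893234e+02),
    ("Surface layer nitrate", 6.658904e+02, 4.441402e+02, 2.946609e+02),
    ("Deep layer nitrate", 1.436946e+03, 1.216641e+03, 1.151911e+03),
    ("Sediment refractory detritus", 1.592244e+04, 1.592244e+04, 1.766065e+04),
    ("Sediment labile plus refractory detritus", 1.599796e+04, 1.602212e+04, 1.776644e+04),
)

#: published row label -> model compartment key.  The published table reports
#: labile-plus-refractory sediment detritus as one combined row; the model
#: carries the two pools separately, so the combined row maps to None and the
#: labile pool is recovered by subtraction.
LABEL_TO_COMPARTMENT: dict[str, str | None] = {
    "Birds": "birds",
    "Pinnipeds": "pinnipeds",
    "Maritime mammals": "maritime_mammals",
    "Migratory fish": "migratory_fish",
    "Ice algae": "ice_algae",
    "Cetaceans": "cetaceans",
    "Demersal fish larvae": "dem_fish_larvae",
    "Planktivorous fish larvae": "plank_fish_larvae",
    "Snow ammonia": "snow_ammonia",
    "Snow nitrate": "snow_nitrate",
    "Ice ammonia": "ice_ammonia",
    "Benthos carn/scav feeders larvae": "benthos_carn_larvae",
    "Benthos susp/dep feeders larvae": "benthos_susp_larvae",
    "Ice nitrate": "ice_nitrate",
    "Ice detritus": "ice_detritus",
    "Sediment porewater nitrate": "porewater_nitrate",
    "Deep layer phytoplankton": "deep_phyto",
    "Demersal fish": "dem_fish",
    "Planktivorous fish": "plank_fish",
    "Sediment porewater ammonia": "porewater_ammonia",
    "Corpses": "corpses",
    "Carnivorous zooplankton": "carn_zoo",
    "Surface layer phytoplankton": "surface_phyto",
    "Deep layer detritus": "deep_detritus",
    "Benthos carn/scav feeders": "benthos_carn",
    "Surface layer detritus": "surface_detritus",
    "Benthos susp/dep feeders": "benthos_susp",
    "Omnivorous zooplankton": "omniv_zoo",
    "Macrophyte nitrogen": "macrophytes",
    "Surface layer ammonia": "surface_ammonia",
    "Deep layer ammonia": "deep_ammonia",
    "Surface layer nitrate": "surface_nitrate",
    "Deep layer nitrate": "deep_nitrate",
    "Sediment refractory detritus": "sediment_refractory_detritus",
    "Sediment labile plus refractory detritus": None,
}

#: Consumer guild labels used in the published consumer change comparison.
CONSUMER_LABELS = (
    "Birds", "Pinnipeds", "Maritime mammals", "Migratory fish", "Cetaceans",
    "Demersal fish larvae", "Planktivorous fish larvae",
    "Benthos carn/scav feeders larvae", "Benthos susp/dep feeders larvae",
    "Demersal fish", "Planktivorous fish", "Carnivorous zooplankton",
    "Benthos carn/scav feeders", "Benthos susp/dep feeders",
    "Omnivorous zooplankton",
)


@dataclass(frozen=True)
class MassTableFixture:
    """The packaged mass inventory, verbatim."""

    frame: pd.DataFrame

    def lookup(self, guild: str, column: str) -> float:
        if column not in MASS_TABLE_COLUMNS:
            raise KeyError(f"unknown column {column!r}")
        sub = self.frame[self.frame["guild"] == guild]
        if sub.empty:
            raise KeyError(f"unknown guild {guild!r}")
        return float(sub[column].iloc[0])

    def state_vector(self, column: str = "GL_2010s") -> np.ndarray:
        """Map the table onto the model's compartment ordering.

        The labile sediment pool is the combined labile-plus-refractory row
        minus the refractory row.
        """
        values: dict[str, float] = {}
        for label, comp in LABEL_TO_COMPARTMENT.items():
            if comp is not None:
                values[comp] = self.lookup(label, column)
        combined = self.lookup("Sediment labile plus refractory detritus", column)
        refractory = self.lookup("Sediment refractory detritus", column)
        values["sediment_labile_detritus"] = combined - refractory
        return np.array([values[c] for c in COMPARTMENTS])


def load_mass_fixture() -> MassTableFixture:
    """Return the packaged mass inventory (35 rows, three systems)."""
    frame = pd.DataFrame(
        list(_ROWS), columns=["guild", *MASS_TABLE_COLUMNS]
    )
    if len(frame) != 35 or (frame[list(MASS_TABLE_COLUMNS)] <= 0).any().any():
        raise RuntimeError("packaged mass table is corrupted")
    return MassTableFixture(frame=frame)


def default_initial_state() -> np.ndarray:
    """Baseline inventory as a convenient integration start point."""
    return load_mass_fixture().state_vector("GL_2010s")
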
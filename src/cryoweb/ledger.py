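"""Annually integrated flow ledger: the input to all network statistics."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .guilds import CATEGORY, COMPARTMENTS

__all__ = ["FlowLedger", "save_ledger", "load_ledger"]


def _default_categories(comps) -> dict[str, str]:
    if tuple(comps) == COMPARTMENTS:
        return dict(CATEGORY)
    raise ValueError(
        "categories must be supplied for non-standard compartment lists"
    )


@dataclass
class FlowLedger:
    """Annually integrated donor -> recipient flows (mmol N m^-2 y^-1).

    ``T[i, j]`` is the annual flow from compartment i to j; demographic
    (spawning/recruitment) transfers are accumulated separately in
    ``demographic`` and never enter ``T``.  ``imports``/``exports`` are the
    per-compartment boundary totals, ``annual_mean_mass`` the time-averaged
    state over the ledger year.
    """

    comps: tuple[str, ...]
    T: np.ndarray
    imports: np.ndarray | None = None
    exports: np.ndarray | None = None
    annual_mean_mass: np.ndarray | None = None
    demographic: np.ndarray | None = None
    year_index: int = 0
    categories: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.comps = tuple(self.comps)
        n = len(self.comps)
        self.T = np.asarray(self.T, dtype=float)
        if self.T.shape != (n, n):
            raise ValueError(f"T must be {n}x{n}, got {self.T.shape}")
        if np.any(self.T < -1e-12):
            raise ValueError("flow matrix entries must be non-negative")
        if np.any(np.abs(np.diag(self.T)) > 0):
            raise ValueError("flow matrix diagonal must be zero")
        for name, default in (
            ("imports", 0.0), ("exports", 0.0), ("annual_mean_mass", 0.0)
        ):
            v = getattr(self, name)
            if v is None:
                setattr(self, name, np.full(n, default))
            else:
                setattr(self, name, np.asarray(v, dtype=float))
        if self.categories is None:
            self.categories = _default_categories(self.comps)

    # -- convenience -----------------------------------------------------------
    def index(self, name: str) -> int:
        return self.comps.index(name)

    def flow(self, donor: str, recipient: str) -> float:
        return float(self.T[self.index(donor), self.index(recipient)])

    def mask(self, *categories: str) -> np.ndarray:
        return np.array([self.categories[c] in categories for c in self.comps])

    @property
    def living(self) -> np.ndarray:
        return self.mask("producer", "consumer")

    @property
    def producers_mask(self) -> np.ndarray:
        return self.mask("producer")

    @property
    def detrital_mask(self) -> np.ndarray:
        return self.mask("detritus", "corpse")

    def mass_of(self, name: str) -> float:
        return float(self.annual_mean_mass[self.index(name)])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        n = len(self.comps)
        for i in range(n):
            for j in range(n):
                if self.T[i, j] != 0.0:
                    rows.append((self.comps[i], self.comps[j], self.T[i, j]))
        for j in range(n):
            if self.imports[j] != 0.0:
                rows.append(("IMPORT", self.comps[j], self.imports[j]))
            if self.exports[j] != 0.0:
                rows.append((self.comps[j], "EXPORT", self.exports[j]))
        return pd.DataFrame(rows, columns=["donor", "recipient", "annual_flow"])


def save_ledger(path: str | Path, ledger: FlowLedger) -> None:
    """Persist a ledger as two delimited tables (flows + masses)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# year_index: {ledger.year_index}\n")
        ledger.to_frame().to_csv(fh, index=False, float_format="%.17g")
    mass = pd.DataFrame(
        {"compartment": ledger.comps, "annual_mean_mass": ledger.annual_mean_mass}
    )
    mass.to_csv(path.with_suffix(".masses.csv"), index=False, float_format="%.17g")


def load_ledger(path: str | Path) -> FlowLedger:
    path = Path(path)
    year = 0
    with path.open() as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition(":")
            if key.strip() == "year_index":
                year = int(val)
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        frame = pd.read_csv(fh, float_precision="round_trip")
    n = len(COMPARTMENTS)
    idx = {c: i for i, c in enumerate(COMPARTMENTS)}
    T = np.zeros((n, n))
    imports = np.zeros(n)
    exports = np.zeros(n)
    for donor, recip, flow in frame.itertuples(index=False):
        if donor == "IMPORT":
            imports[idx[recip]] = flow
        elif recip == "EXPORT":
            exports[idx[donor]] = flow
        else:
            T[idx[donor], idx[recip]] = flow
    mass_path = path.with_suffix(".masses.csv")
    mass = None
    if mass_path.exists():
        mf = pd.read_csv(mass_path, float_precision="round_trip")
        mass = np.array([mf.set_index("compartment")["annual_mean_mass"][c]
                         for c in COMPARTMENTS])
    return FlowLedger(
        comps=COMPARTMENTS, T=T, imports=imports, exports=exports,
        annual_mean_mass=mass, year_index=year,
    )
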
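"""Delimited-text reports: mass inventory, change table, index summary."""

from __future__ import annotations

import datetime as _dt
import hashlib
from pathlib import Path

import pandas as pd

from .experiments import ExperimentResultTable, change_table
from .masses import (
    CONSUMER_LABELS,
    LABEL_TO_COMPARTMENT,
    MassTableFixture,
)

__all__ = ["render_reports"]

_VERSION = "0.1.0"


def _header(seed, config_hash) -> str:
    stamp = _dt.datetime.now().isoformat(timespec="seconds")
    return (
        f"# version: {_VERSION}\n"
        f"# seed: {seed}\n"
        f"# config_hash: {config_hash}\n"
        f"# created: {stamp}\n"
    )


def _write(path: Path, frame: pd.DataFrame, seed, config_hash) -> None:
    with path.open("w") as fh:
        fh.write(_header(seed, config_hash))
        frame.to_csv(fh, index=False, float_format="%.6g")


def render_reports(
    results: ExperimentResultTable,
    fixture: MassTableFixture,
    outdir: str | Path,
    seed: int | None = None,
    experiment: str = "full_climate",
) -> dict[str, Path]:
    """Write the three standard reports for one experiment of a grid.

    * ``mass_table.csv`` — annual mean masses per decade in the published
      inventory's layout, sorted ascending on the baseline-decade mass;
    * ``change_table.csv`` — per-consumer percent change (headline changes
      rounded to the nearest integer) and log10 ratio, first vs last decade;
    * ``indices.csv`` — flat key/value dump of the network indices per decade.

    Reports are deterministic apart from the ``# created`` timestamp line.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if results.masses.empty:
        raise ValueError("empty result table")
    decades = sorted(results.masses["decade"].unique())
    cfg_hash = hashlib.sha256(
        results.masses.to_csv(index=False).encode()
    ).hexdigest()[:12]

    wide = results.masses[results.masses["experiment"] == experiment].pivot_table(
        index="compartment", columns="decade", values="mass"
    )
    rows = []
    for label, comp in LABEL_TO_COMPARTMENT.items():
        if comp is None:
            vals = [
                wide.loc["sediment_labile_detritus", d]
                + wide.loc["sediment_refractory_detritus", d]
                for d in decades
            ]
        else:
            vals = [wide.loc[comp, d] for d in decades]
        rows.append([label, *vals])
    mass_frame = pd.DataFrame(
        rows, columns=["guild", *[f"decade_{d}" for d in decades]]
    ).sort_values(f"decade_{decades[0]}", kind="stable").reset_index(drop=True)

    first, last = decades[0], decades[-1]
    base = {
        label: wide.loc[LABEL_TO_COMPARTMENT[label], first]
        for label in CONSUMER_LABELS
    }
    scen = {
        label: wide.loc[LABEL_TO_COMPARTMENT[label], last]
        for label in CONSUMER_LABELS
    }
    changes = change_table(base, scen)
    changes["percent_change"] = changes["percent_change"].round(0)
    changes["log10_ratio"] = changes["log10_ratio"].round(4)

    idx_rows = []
    for d in decades:
        ix = results.indices[(experiment, d)]
        idx_rows += [
            (d, "mean_TL_top_predators", ix.mean_TL_top_predators),
            (d, "mean_OI_consumers", ix.mean_OI_consumers),
            (d, "A_internal", ix.A_internal),
            (d, "C_internal", ix.C_internal),
            (d, "AC_ratio", ix.AC_ratio),
            (d, "indirect_dominance", ix.indirect_dominance),
            (d, "f_ratio", ix.f_ratio),
            (d, "npp", ix.npp),
            (d, "secondary_production", ix.secondary_production),
            (d, "share_flow_primary_production", ix.shares_flow["primary_production"]),
            (d, "share_flow_recycling", ix.shares_flow["recycling"]),
            (d, "share_flow_consumption", ix.shares_flow["consumption"]),
            (d, "share_mass_primary_production", ix.shares_mass["primary_production"]),
            (d, "share_mass_recycling", ix.shares_mass["recycling"]),
            (d, "share_mass_consumption", ix.shares_mass["consumption"]),
            (d, "converged", float(results.converged[(experiment, d)])),
        ]
    idx_frame = pd.DataFrame(idx_rows, columns=["decade", "index", "value"])

    paths = {
        "mass_table": outdir / "mass_table.csv",
        "change_table": outdir / "change_table.csv",
        "indices": outdir / "indices.csv",
    }
    _write(paths["mass_table"], mass_frame, seed, cfg_hash)
    _write(paths["change_table"], changes, seed, cfg_hash)
    _write(paths["indices"], idx_frame, seed, cfg_hash)
    return paths
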
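"""Scenario grid orchestration: decadal runs, knock-outs, change tables, PCA.

Each knock-out freezes one driver group at the baseline decade's values while
every other driver follows the climate trajectory, isolating that group's
causal contribution to the decadal ecosystem change.  The attenuation
daughter experiment additionally zeroes the snow/ice optics (attenuation
coefficients and albedo), letting light through intact ice while the
entrained nutrients stay locked up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .drivers import (
    DriverSet,
    ExperimentSpec,
    ScenarioConfig,
    apply_knockout,
    generate_decadal_drivers,
)
from .guilds import COMPARTMENTS
from .indices import NetworkIndexSet, summary_indices
from .masses import default_initial_state
from .params import ModelParams
from .simulate import SteadyStateResult, run_to_steady_state

__all__ = [
    "ExperimentResultTable",
    "PCAResult",
    "run_experiment_grid",
    "change_table",
    "snow_ice_nutrient_change",
    "pca_states",
    "attenuation_overrides",
]

_CRYO_DIN = ("snow_nitrate", "snow_ammonia", "ice_nitrate", "ice_ammonia")


def attenuation_overrides(params: ModelParams) -> ModelParams:
    """Parameter overrides of the attenuation daughter experiment:
    no attenuation by ice or snow and no surface reflection."""
    new = params.copy()
    new.k_ice = 0.0
    new.k_snow = 0.0
    new.albedo = 0.0
    return new


@dataclass
class ExperimentResultTable:
    """Steady-state outcomes over an (experiment x decade) grid."""

    masses: pd.DataFrame  # columns: experiment, decade, compartment, mass
    indices: dict[tuple[str, int], NetworkIndexSet]
    results: dict[tuple[str, int], SteadyStateResult]
    converged: dict[tuple[str, int], bool]

    def mass_of(self, experiment: str, decade: int, compartment: str) -> float:
        sub = self.masses[
            (self.masses["experiment"] == experiment)
            & (self.masses["decade"] == decade)
            & (self.masses["compartment"] == compartment)
        ]
        return float(sub["mass"].iloc[0])

    def mass_series(self, experiment: str, compartment: str) -> pd.Series:
        sub = self.masses[
            (self.masses["experiment"] == experiment)
            & (self.masses["compartment"] == compartment)
        ].sort_values("decade")
        return sub.set_index("decade")["mass"]

    def secondary_production(self, experiment: str) -> pd.Series:
        decs = sorted(
            d for (e, d) in self.indices if e == experiment
        )
        return pd.Series(
            [self.indices[(experiment, d)].secondary_production for d in decs],
            index=decs,
            name=experiment,
        )


def run_experiment_grid(
    config: ScenarioConfig,
    params: ModelParams,
    experiments: list[ExperimentSpec] | list[str] | None = None,
    decades: list[int] | None = None,
    tol: float = 1e-4,
    max_years: int = 60,
    step: float = 0.5,
    state0: np.ndarray | None = None,
    warm_start: bool = True,
) -> ExperimentResultTable:
    """Run every (experiment, decade) pair to its steady state.

    Knock-out drivers are built against the scenario's baseline decade.  With
    ``warm_start`` each decade starts from the previous decade's end state
    (the first decade starts from ``state0``), which shortens relaxation
    without changing the attractor.  Non-converged runs are recorded with
    ``converged = False``, never dropped.
    """
    if experiments is None:
        experiments = ["full_climate", "boundary", "flows", "ice", "light",
                       "temperature"]
    if decades is None:
        decades = list(range(config.n_decades))
    if state0 is None:
        state0 = default_initial_state()
    baseline = generate_decadal_drivers(config, config.baseline_decade)

    rows = []
    indices: dict[tuple[str, int], NetworkIndexSet] = {}
    results: dict[tuple[str, int], SteadyStateResult] = {}
    converged: dict[tuple[str, int], bool] = {}
    for exp in experiments:
        if isinstance(exp, str):
            spec = ExperimentSpec(name=exp)
        else:
            spec = exp
        run_params = (
            attenuation_overrides(params) if spec.overrides_attenuation else params
        )
        state = np.asarray(state0, dtype=float).copy()
        for dec in decades:
            scen = generate_decadal_drivers(config, dec)
            drv = apply_knockout(scen, baseline, spec)
            res = run_to_steady_state(
                state, drv, run_params, tol=tol, max_years=max_years, step=step
            )
            key = (spec.name, dec)
            results[key] = res
            converged[key] = res.converged
            if not res.converged:
                warnings.warn(
                    f"run {key} did not converge "
                    f"(metric {res.convergence_metric:.3e})",
                    stacklevel=2,
                )
            indices[key] = summary_indices(
                res.ledger, res.annual_mean_mass, run_params
            )
            for comp, mass in zip(COMPARTMENTS, res.annual_mean_mass):
                rows.append((spec.name, dec, comp, mass))
            if warm_start:
                state = res.state_end.copy()
    masses = pd.DataFrame(
        rows, columns=["experiment", "decade", "compartment", "mass"]
    )
    return ExperimentResultTable(
        masses=masses, indices=indices, results=results, converged=converged
    )


def change_table(baseline_masses, scenario_masses) -> pd.DataFrame:
    """Per-guild change: percent and log10 proportional ratio.

    Accepts mappings ``guild -> mass``.  Guilds with zero baseline mass are
    flagged (``percent_change = inf`` or nan) and excluded from the log
    column.
    """
    rows = []
    for guild, base in baseline_masses.items():
        scen = scenario_masses[guild]
        if base > 0:
            pct = 100.0 * (scen / base - 1.0)
            lr = float(np.log10(scen / base)) if scen > 0 else float("-inf")
            flagged = False
        else:
            pct = float("inf") if scen > 0 else float("nan")
            lr = float("nan")
            flagged = True
        rows.append((guild, pct, lr, flagged))
    return pd.DataFrame(
        rows, columns=["guild", "percent_change", "log10_ratio", "zero_baseline"]
    )


def snow_ice_nutrient_change(masses_baseline, masses_future) -> float:
    """Percent change of the DIN mass locked in snow and ice.

    Accepts state vectors in compartment order or ``name -> mass`` mappings.
    """
    def total(m):
        if isinstance(m, dict):
            return sum(m[c] for c in _CRYO_DIN)
        m = np.asarray(m, dtype=float)
        return sum(m[COMPARTMENTS.index(c)] for c in _CRYO_DIN)

    base = total(masses_baseline)
    fut = total(masses_future)
    return 100.0 * (fut / base - 1.0)


@dataclass
class PCAResult:
    """Principal components of scaled steady-state masses across runs."""

    scores: pd.DataFrame           # runs x components
    loadings: pd.DataFrame         # compartments x components
    variance_fractions: np.ndarray
    dropped: tuple[str, ...] = ()

    def reconstruct_scaled(self) -> np.ndarray:
        return self.scores.to_numpy() @ self.loadings.to_numpy().T


def pca_states(table: ExperimentResultTable | pd.DataFrame) -> PCAResult:
    """PCA of standardised steady-state masses, one row per model run.

    Masses span several orders of magnitude, so each compartment is scaled
    to zero mean and unit variance across runs (correlation PCA).
    Zero-variance compartments are dropped with a warning.  Component signs
    follow a deterministic convention: the largest-magnitude loading of each
    component is positive.
    """
    frame = table.masses if isinstance(table, ExperimentResultTable) else table
    wide = frame.pivot_table(
        index=["experiment", "decade"], columns="compartment", values="mass",
        sort=False,
    )
    if len(wide) < 2:
        raise ValueError("PCA needs at least 2 runs")
    X = wide.to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0.0
    dropped = tuple(np.asarray(wide.columns)[~keep])
    if dropped:
        warnings.warn(
            f"dropping zero-variance compartments: {list(dropped)}", stacklevel=2
        )
    Z = (X[:, keep] - mean[keep]) / sd[keep]
    u, svals, vt = np.linalg.svd(Z, full_matrices=False)
    # deterministic sign: largest |loading| positive per component
    for k in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] = -vt[k]
            u[:, k] = -u[:, k]
    scores = u * svals
    var = svals**2
    var_frac = var / var.sum() if var.sum() > 0 else var
    comp_names = [f"PC{k + 1}" for k in range(len(svals))]
    run_index = pd.Index(
        [f"{e}:{d}" for e, d in wide.index], name="run"
    )
    return PCAResult(
        scores=pd.DataFrame(scores, index=run_index, columns=comp_names),
        loadings=pd.DataFrame(
            vt.T, index=np.asarray(wide.columns)[keep], columns=comp_names
        ),
        variance_fractions=var_frac,
        dropped=dropped,
    )
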
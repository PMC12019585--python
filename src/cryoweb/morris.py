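"""Morris elementary-effects screening of model parameters.

A Morris design perturbs one parameter at a time along r randomised
trajectories on a p-level grid of the unit hypercube (step
``delta = p / (2 (p - 1))``), mapped to per-parameter bounds.  Each
trajectory yields one elementary effect per parameter; their mean, absolute
mean and dispersion separate influential, interacting and inert parameters
at a cost of ``r * (k + 1)`` model runs.  A parameter is flagged significant
when a two-sided one-sample t test rejects a zero mean effect at alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .drivers import DriverSet
from .indices import f_ratio as _f_ratio
from .indices import production_metrics
from .masses import default_initial_state
from .params import ModelParams
from .simulate import run_to_steady_state

__all__ = [
    "ParamEntry",
    "ParamSpace",
    "MorrisPlan",
    "MorrisResult",
    "morris_design",
    "morris_effects",
    "run_sensitivity",
]

_FAMILY_RULES: tuple[tuple[str, str], ...] = (
    ("harvest.", "harvest_ratio"),
    ("spawn", "biological_event"),
    ("recruit", "biological_event"),
    ("migration", "biological_event"),
    ("migratory", "biological_event"),
    ("q10", "fixed_ecology"),
    ("t_ref", "fixed_ecology"),
    ("area_", "physical_configuration"),
    ("depth_", "physical_configuration"),
    ("porewater_depth", "physical_configuration"),
    ("mix_length", "physical_configuration"),
)


def _family(name: str) -> str:
    for prefix, fam in _FAMILY_RULES:
        if name.startswith(prefix) or f".{prefix}" in name:
            return fam
    if name.startswith(("producers.", "consumers.")):
        return "fitted_ecology"
    if name == "fishing_activity":
        return "harvest_ratio"
    return "fitted_ecology"


@dataclass(frozen=True)
class ParamEntry:
    name: str
    family: str
    nominal: float
    lower: float
    upper: float

    @property
    def fixed(self) -> bool:
        return self.upper <= self.lower


@dataclass
class ParamSpace:
    """Screening space: one entry per scalar model parameter."""

    entries: tuple[ParamEntry, ...]
    levels: int = 4

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names in space")
        for e in self.entries:
            if e.upper < e.lower:
                raise ValueError(f"{e.name}: lower must not exceed upper")
        if self.levels < 2 or self.levels % 2:
            raise ValueError("levels p must be an even count >= 2")

    @property
    def active(self) -> tuple[ParamEntry, ...]:
        return tuple(e for e in self.entries if not e.fixed)

    @classmethod
    def from_params(
        cls,
        params: ModelParams,
        rel_bound: float = 0.2,
        levels: int = 4,
        include: list[str] | None = None,
    ) -> "ParamSpace":
        """Build the space from a parameter set with +/-``rel_bound`` bounds.

        Parameters with a zero nominal value (e.g. the fishing activity in the
        unfished configuration) get degenerate bounds and are carried as
        fixed entries, never perturbed.  ``include`` restricts the space to a
        subset of dotted names.
        """
        flat = params.flatten()
        if include is not None:
            unknown = set(include) - set(flat)
            if unknown:
                raise KeyError(f"unknown parameters: {sorted(unknown)}")
            flat = {k: flat[k] for k in include}
        entries = []
        for name, val in flat.items():
            lo, hi = val * (1 - rel_bound), val * (1 + rel_bound)
            if val == 0.0:
                lo = hi = 0.0
            entries.append(ParamEntry(name, _family(name), val, lo, hi))
        return cls(entries=tuple(entries), levels=levels)

    def apply(self, params: ModelParams, x_unit: np.ndarray) -> ModelParams:
        """Map a unit-hypercube point over the active entries onto a copy of
        ``params``."""
        new = params
        for e, x in zip(self.active, x_unit):
            new = new.with_value(e.name, e.lower + x * (e.upper - e.lower))
        return new


@dataclass
class MorrisPlan:
    """Evaluation plan: r trajectories of k+1 points in unit coordinates."""

    space: ParamSpace
    X: np.ndarray          # (r * (k + 1), k) unit-hypercube coordinates
    changed: np.ndarray    # (r, k) parameter index changed at each step
    signed_delta: np.ndarray  # (r, k) signed step applied at each move
    delta: float
    r: int
    seed: int

    @property
    def n_evaluations(self) -> int:
        return self.X.shape[0]


def morris_design(space: ParamSpace, r: int, seed: int) -> MorrisPlan:
    """Randomised one-at-a-time trajectories on a p-level grid.

    Each trajectory starts from a random grid point and perturbs every active
    parameter exactly once by ``+/- delta`` with ``delta = p / (2 (p - 1))``,
    in a random order; the design is deterministic given the seed.
    """
    if r < 2:
        raise ValueError("r must be >= 2 (effect dispersion needs replicates)")
    k = len(space.active)
    if k == 0:
        raise ValueError("no active (non-degenerate) parameters to screen")
    p = space.levels
    delta = p / (2.0 * (p - 1.0))
    rng = np.random.default_rng(seed)
    base_levels = np.arange(p // 2) / (p - 1.0)  # grid points with room for +delta
    X = np.empty((r * (k + 1), k))
    changed = np.empty((r, k), dtype=int)
    signed = np.empty((r, k))
    for t in range(r):
        x = base_levels[rng.integers(0, len(base_levels), size=k)].astype(float)
        direction = rng.choice([-1.0, 1.0], size=k)
        # start opposite the move for parameters stepping downwards
        x = np.where(direction < 0, x + delta, x)
        order = rng.permutation(k)
        row = t * (k + 1)
        X[row] = x
        for s, j in enumerate(order):
            x = x.copy()
            x[j] += direction[j] * delta
            X[row + s + 1] = x
            changed[t, s] = j
            signed[t, s] = direction[j] * delta
    if X.min() < -1e-12 or X.max() > 1.0 + 1e-12:
        raise RuntimeError("trajectory left the unit hypercube")
    return MorrisPlan(
        space=space, X=X, changed=changed, signed_delta=signed,
        delta=delta, r=r, seed=seed,
    )


@dataclass
class MorrisResult:
    """Per-parameter elementary-effect statistics."""

    stats: pd.DataFrame  # name, family, mean, abs_mean, sd, se, significant
    r: int
    levels: int
    delta: float
    seed: int
    metric: str = ""
    n_missing: int = 0

    def fraction_significant(self) -> float:
        return float(self.stats["significant"].mean())

    def effect_of(self, name: str) -> float:
        return float(self.stats.set_index("name").loc[name, "mean"])


def morris_effects(
    plan: MorrisPlan, outputs, alpha: float = 0.05, metric: str = ""
) -> MorrisResult:
    """Elementary effects from the outputs of a Morris plan.

    ``outputs`` is aligned with the plan rows; NaN marks a failed
    evaluation, and effects touching it are dropped (counted as missing).
    """
    y = np.asarray(outputs, dtype=float)
    if y.shape != (plan.n_evaluations,):
        raise ValueError(
            f"expected {plan.n_evaluations} outputs, got {y.shape}"
        )
    k = len(plan.space.active)
    effects: list[list[float]] = [[] for _ in range(k)]
    missing = 0
    for t in range(plan.r):
        row = t * (k + 1)
        for s in range(k):
            j = plan.changed[t, s]
            y0, y1 = y[row + s], y[row + s + 1]
            if np.isnan(y0) or np.isnan(y1):
                missing += 1
                continue
            effects[j].append((y1 - y0) / plan.signed_delta[t, s])
    rows = []
    names = [e.name for e in plan.space.active]
    for j, e in enumerate(plan.space.active):
        ee = np.asarray(effects[j])
        if ee.size == 0:
            rows.append((e.name, e.family, np.nan, np.nan, np.nan, np.nan, False))
            continue
        mean = float(ee.mean())
        sd = float(ee.std(ddof=1)) if ee.size > 1 else np.nan
        se = sd / np.sqrt(ee.size) if ee.size > 1 else np.nan
        if ee.size > 1 and sd > 0.0:
            tstat = mean / se
            pval = 2.0 * stats.t.sf(abs(tstat), df=ee.size - 1)
            significant = bool(pval < alpha)
        else:
            # zero dispersion: the effect is exactly its mean
            significant = bool(mean != 0.0)
        rows.append(
            (e.name, e.family, mean, float(np.abs(ee).mean()), sd, se, significant)
        )
    # fixed entries are reported as inert
    for e in plan.space.entries:
        if e.fixed:
            rows.append((e.name, e.family, 0.0, 0.0, 0.0, 0.0, False))
    frame = pd.DataFrame(
        rows,
        columns=["name", "family", "mean", "abs_mean", "sd", "se", "significant"],
    )
    return MorrisResult(
        stats=frame, r=plan.r, levels=plan.space.levels, delta=plan.delta,
        seed=plan.seed, metric=metric, n_missing=missing,
    )


def run_sensitivity(
    params: ModelParams,
    drivers: DriverSet,
    metric: str = "f_ratio",
    r: int = 4,
    seed: int = 0,
    space: ParamSpace | None = None,
    tol: float = 1e-4,
    max_years: int = 10,
    step: float = 1.0,
    state0: np.ndarray | None = None,
    require_converged: bool = False,
) -> MorrisResult:
    """Morris screening of the steady-state F-ratio or net primary production.

    Every plan point rebuilds the parameter set, relaxes the model on the
    supplied (baseline) drivers (warm-started from the nominal attractor) and
    evaluates the metric on the final annual ledger.  Unstable evaluations —
    and, with ``require_converged``, runs that miss the tolerance within
    ``max_years`` — are recorded as missing and excluded from the effects.
    """
    if metric not in ("f_ratio", "npp"):
        raise ValueError("metric must be 'f_ratio' or 'npp'")
    if space is None:
        space = ParamSpace.from_params(params)
    plan = morris_design(space, r=r, seed=seed)
    if state0 is None:
        state0 = default_initial_state()
    # warm-start every evaluation from the nominal attractor
    base = run_to_steady_state(
        state0, drivers, params, tol=tol, max_years=max_years, step=step
    )
    start = base.state_end
    outputs = np.empty(plan.n_evaluations)
    for i in range(plan.n_evaluations):
        trial = space.apply(params, plan.X[i])
        try:
            res = run_to_steady_state(
                start, drivers, trial, tol=tol, max_years=max_years, step=step
            )
        except RuntimeError:
            outputs[i] = np.nan
            continue
        if require_converged and not res.converged:
            outputs[i] = np.nan
            continue
        ledger = res.ledger
        if metric == "f_ratio":
            outputs[i] = _f_ratio(ledger)
        else:
            outputs[i] = production_metrics(ledger, trial)[0]
    return morris_effects(plan, outputs, metric=metric)
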
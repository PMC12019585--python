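"""Flow-network statistics: nutrition shares, trophic structure, information
indices, indirect-effect dominance, F-ratio and production.

All statistics operate on an annually integrated :class:`~cryoweb.ledger.FlowLedger`
and are scale-aware: trophic levels, omnivory, share percentages, the
ascendancy/capacity ratio, indirect dominance and the F-ratio are invariant
under uniform rescaling of all flows; ascendancy and capacity themselves
scale linearly (they are measured in mmol N-bits m^-2 d^-1 when the ledger
is expressed per day).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .guilds import TOP_PREDATORS
from .ledger import FlowLedger
from .params import ModelParams

__all__ = [
    "NetworkIndexSet",
    "nutrition_shares",
    "mass_shares_by_mode",
    "trophic_levels",
    "omnivory_indices",
    "ascendancy_capacity",
    "indirect_effects_dominance",
    "f_ratio",
    "production_metrics",
    "summary_indices",
]


@dataclass
class NetworkIndexSet:
    """Bundle of the reported food-web indices for one steady state."""

    TL: dict[str, float]
    OI: dict[str, float]
    A_internal: float
    C_internal: float
    AC_ratio: float
    indirect_dominance: float
    shares_flow: dict[str, float]
    shares_mass: dict[str, float]
    mean_TL_top_predators: float
    mean_OI_consumers: float
    f_ratio: float
    npp: float
    secondary_production: float


# ---------------------------------------------------------------------------
# nutrition modes
# ---------------------------------------------------------------------------

def nutrition_shares(ledger: FlowLedger) -> dict[str, float]:
    """Percent shares of live activity: primary production, recycling
    (detritivory) and consumption; the three sum to exactly 100.
    """
    T = ledger.T
    prod = ledger.producers_mask
    living = ledger.living
    detr = ledger.detrital_mask
    pp = T[:, prod].sum()
    rec = T[np.ix_(detr, living & ~prod)].sum()
    con = T[np.ix_(living, living & ~prod)].sum()
    total = pp + rec + con
    if total <= 0.0:
        raise ValueError("no living activity in the ledger: shares undefined")
    return {
        "primary_production": 100.0 * pp / total,
        "recycling": 100.0 * rec / total,
        "consumption": 100.0 * con / total,
    }


def mass_shares_by_mode(masses, ledger: FlowLedger) -> dict[str, float]:
    """Standing living mass attributed to the three nutrition modes (%).

    Producer mass counts as primary production.  A consumer's mass is split
    between recycling and consumption in proportion to its inbound
    detritivory vs consumption flows (scavengers/omnivores are shared).
    """
    masses = np.asarray(masses, dtype=float)
    T = ledger.T
    prod = ledger.producers_mask
    living = ledger.living
    detr = ledger.detrital_mask
    pp = float(masses[prod].sum())
    rec = con = 0.0
    for j in np.flatnonzero(living & ~prod):
        m = masses[j]
        if m < 0:
            raise ValueError("living masses must be non-negative")
        d_in = T[detr, j].sum()
        c_in = T[living, j].sum()
        tot = d_in + c_in
        if tot > 0.0:
            rec += m * d_in / tot
            con += m * c_in / tot
        else:
            if m > 0.0:
                warnings.warn(
                    f"{ledger.comps[j]} has mass but no inbound flow; "
                    "assigned to consumption by category",
                    stacklevel=2,
                )
            con += m
    total = pp + rec + con
    if total <= 0.0:
        raise ValueError("no living mass: shares undefined")
    return {
        "primary_production": 100.0 * pp / total,
        "recycling": 100.0 * rec / total,
        "consumption": 100.0 * con / total,
    }


# ---------------------------------------------------------------------------
# trophic structure
# ---------------------------------------------------------------------------

def _diet_proportions(ledger: FlowLedger) -> np.ndarray:
    """p[i, j]: proportion of consumer j's food inflow supplied by i."""
    T = ledger.T
    inflow = T.sum(axis=0)
    p = np.zeros_like(T)
    cols = inflow > 0.0
    p[:, cols] = T[:, cols] / inflow[cols]
    return p

def trophic_levels(ledger: FlowLedger) -> dict[str, float]:
    """Flow-weighted trophic levels.

    Primary producers and non-living compartments are anchored at TL 1; a
    consumer sits one level above the diet-weighted mean of its food sources.
    Solved exactly as a linear system.
    """
    comps = ledger.comps
    n = len(comps)
    living = ledger.living
    prod = ledger.producers_mask
    consumer = living & ~prod
    p = _diet_proportions(ledger)
    tl = np.ones(n)
    idx = np.flatnonzero(consumer)
    if idx.size:
        # TL_j - sum_{i consumer} p_ij TL_i = 1 + sum_{i anchored} p_ij
        A = np.eye(idx.size) - p[np.ix_(idx, idx)].T
        b = 1.0 + p[np.ix_(~consumer, idx)].sum(axis=0)
        if abs(np.linalg.det(A)) < 1e-12:
            names = [comps[i] for i in idx]
            raise ValueError(
                f"diet cycle without external anchor among {names}: "
                "trophic levels are undefined"
            )
        tl[idx] = np.linalg.solve(A, b)
    return {comps[i]: float(tl[i]) for i in range(n)}


def omnivory_indices(ledger: FlowLedger, TL: dict[str, float]) -> dict[str, float]:
    """Diet-weighted variance of prey trophic levels around TL_j - 1."""
    comps = ledger.comps
    p = _diet_proportions(ledger)
    tl = np.array([TL[c] for c in comps])
    out: dict[str, float] = {}
    consumer = ledger.living & ~ledger.producers_mask
    for j in np.flatnonzero(consumer):
        pj = p[:, j]
        if pj.sum() <= 0.0:
            out[comps[j]] = 0.0
            continue
        out[comps[j]] = float(np.sum(pj * (tl - (tl[j] - 1.0)) ** 2))
    return out


# ---------------------------------------------------------------------------
# information indices
# ---------------------------------------------------------------------------

def ascendancy_capacity(ledger: FlowLedger):
    """Internal ascendancy A, capacity C (bits-weighted flow) and their ratio.

    Only internal flows enter the sums (boundary imports/exports ignored).
    Degenerate webs where C = 0 return ``AC_ratio = nan``.
    """
    T = ledger.T
    tot = T.sum()
    if tot <= 0.0:
        raise ValueError("empty internal flow matrix: indices undefined")
    ti = T.sum(axis=1)  # donor totals
    tj = T.sum(axis=0)  # recipient totals
    nz = T > 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        a_terms = np.where(
            nz, T * np.log2(np.where(nz, T * tot / np.outer(ti, tj), 1.0)), 0.0
        )
        c_terms = np.where(nz, -T * np.log2(np.where(nz, T / tot, 1.0)), 0.0)
    A = float(a_terms.sum())
    C = float(c_terms.sum())
    ratio = A / C if C > 0.0 else float("nan")
    return A, C, ratio


def indirect_effects_dominance(ledger: FlowLedger) -> float:
    """Indirect (path length > 1) mass contributions over direct intensity.

    G normalises each recipient's inflow column by its total inflow
    including imports, so G is substochastic; with N = (I - G)^-1 the
    statistic is sum(N - I - G) / sum(G).
    """
    T = ledger.T
    n = len(ledger.comps)
    inflow = T.sum(axis=0) + ledger.imports
    G = np.zeros_like(T)
    cols = inflow > 0.0
    G[:, cols] = T[:, cols] / inflow[cols]
    if G.sum() <= 0.0:
        raise ValueError("no direct flows: dominance undefined")
    rho = np.max(np.abs(np.linalg.eigvals(G)))
    if rho >= 1.0 - 1e-12:
        raise ValueError(
            f"flow network is non-dissipative (spectral radius {rho:.6f} >= 1)"
        )
    Nmat = np.linalg.inv(np.eye(n) - G)
    return float((Nmat - np.eye(n) - G).sum() / G.sum())


# ---------------------------------------------------------------------------
# production statistics
# ---------------------------------------------------------------------------

def _substrate_mask(ledger: FlowLedger, kind: str) -> np.ndarray:
    return np.array([kind in c for c in ledger.comps])


def f_ratio(ledger: FlowLedger) -> float:
    """Nitrate share of total producer DIN uptake (new production proxy)."""
    prod = ledger.producers_mask
    nit = ledger.T[np.ix_(_substrate_mask(ledger, "nitrate"), prod)].sum()
    amm = ledger.T[np.ix_(_substrate_mask(ledger, "ammonia"), prod)].sum()
    total = nit + amm
    if total <= 0.0:
        raise ValueError("no producer DIN uptake: F-ratio undefined")
    return float(nit / total)


def _ae_ex(params, name: str) -> tuple[float, float]:
    if isinstance(params, ModelParams):
        c = params.consumers[name]
        return c.assim_eff, c.excr_frac
    ae, ex = params[name]
    return ae, ex


def production_metrics(ledger: FlowLedger, params) -> tuple[float, float]:
    """(net primary production, secondary production), mmol N m^-2 y^-1.

    NPP is producer DIN uptake minus the producers' metabolic losses back to
    ammonia (positive when producers fix more nitrogen than they respire;
    grazing and mortality are transfers, not losses, under this convention).
    Secondary production sums assimilated intake net of excretion over all
    non-producer living guilds: ``ae * (1 - ex) * intake``.
    """
    prod = ledger.producers_mask
    living = ledger.living
    uptake = ledger.T[np.ix_(~living, prod)].sum()
    resp = ledger.T[np.ix_(prod, _substrate_mask(ledger, "ammonia"))].sum()
    npp = float(uptake - resp)
    secondary = 0.0
    for j in np.flatnonzero(living & ~prod):
        intake = ledger.T[:, j].sum()
        if intake <= 0.0:
            continue
        ae, ex = _ae_ex(params, ledger.comps[j])
        secondary += ae * (1.0 - ex) * intake
    return npp, float(secondary)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def summary_indices(
    ledger: FlowLedger,
    masses=None,
    params: ModelParams | None = None,
) -> NetworkIndexSet:
    """Compute the full index bundle for one steady-state ledger."""
    if masses is None:
        masses = ledger.annual_mean_mass
    masses = np.asarray(masses, dtype=float)
    if params is None:
        params = ModelParams()
    TL = trophic_levels(ledger)
    OI = omnivory_indices(ledger, TL)
    A, C, ratio = ascendancy_capacity(ledger)
    dom = indirect_effects_dominance(ledger)
    shares_f = nutrition_shares(ledger)
    shares_m = mass_shares_by_mode(masses, ledger)
    fr = f_ratio(ledger)
    npp, secondary = production_metrics(ledger, params)

    tops = [c for c in TOP_PREDATORS if c in ledger.comps]
    w = np.array([masses[ledger.index(c)] for c in tops])
    tlv = np.array([TL[c] for c in tops])
    mean_tl = float((w * tlv).sum() / w.sum()) if w.sum() > 0 else float("nan")

    cons = list(OI)
    wc = np.array([masses[ledger.index(c)] for c in cons])
    oiv = np.array([OI[c] for c in cons])
    mean_oi = float((wc * oiv).sum() / wc.sum()) if wc.sum() > 0 else float("nan")

    return NetworkIndexSet(
        TL=TL,
        OI=OI,
        A_internal=A,
        C_internal=C,
        AC_ratio=ratio,
        indirect_dominance=dom,
        shares_flow=shares_f,
        shares_mass=shares_m,
        mean_TL_top_predators=mean_tl,
        mean_OI_consumers=mean_oi,
        f_ratio=fr,
        npp=npp,
        secondary_production=secondary,
    )
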
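import numpy as np
import pytest

import cryoweb as cw


@pytest.fixture(scope="session")
def config() -> cw.ScenarioConfig:
    return cw.ScenarioConfig()


@pytest.fixture(scope="session")
def params() -> cw.ModelParams:
    return cw.default_params()


@pytest.fixture(scope="session")
def baseline_drivers(config) -> cw.DriverSet:
    return cw.generate_decadal_drivers(config, 0)


@pytest.fixture(scope="session")
def final_drivers(config) -> cw.DriverSet:
    return cw.generate_decadal_drivers(config, config.n_decades - 1)


@pytest.fixture(scope="session")
def initial_state() -> np.ndarray:
    return cw.default_initial_state()


def make_toy_ledger(comps, categories, flows, imports=None, masses=None):
    """Small hand-built ledger for index tests."""
    n = len(comps)
    T = np.zeros((n, n))
    idx = {c: i for i, c in enumerate(comps)}
    for (a, b), v in flows.items():
        T[idx[a], idx[b]] = v
    imp = np.zeros(n)
    if imports:
        for c, v in imports.items():
            imp[idx[c]] = v
    mass = np.zeros(n)
    if masses:
        for c, v in masses.items():
            mass[idx[c]] = v
    return cw.FlowLedger(
        comps=tuple(comps), T=T, imports=imp, annual_mean_mass=mass,
        categories=dict(categories),
    )


def random_toy_ledger(rng, n_max=6):
    """Random small flow web: one nutrient, one producer, consumers/detritus."""
    n = rng.integers(4, n_max + 1)
    comps = ["nitrate0"] + [f"c{i}" for i in range(1, n)]
    cats = {"nitrate0": "nutrient", "c1": "producer"}
    for i in range(2, n):
        cats[f"c{i}"] = rng.choice(["consumer", "consumer", "detritus"])
    T = np.zeros((n, n))
    T[0, 1] = rng.uniform(1.0, 10.0)  # uptake anchor (nitrate -> producer)
    for j in range(2, n):
        if cats[f"c{j}"] == "consumer":
            # always some producer diet, plus extra lower prey and rare cycles
            T[1, j] = rng.uniform(0.2, 2.0)
            for i in rng.choice(j, size=min(j, int(rng.integers(1, 4))), replace=False):
                if i == 0:
                    continue
                T[i, j] += rng.uniform(0.1, 5.0)
            if j + 1 < n and rng.random() < 0.3:
                T[j + 1, j] = rng.uniform(0.05, 0.5)
        else:
            T[1, j] = rng.uniform(0.1, 2.0)
    imports = np.zeros(n)
    imports[0] = rng.uniform(1.0, 5.0)
    # exports keep the web dissipative for the dominance statistic
    exports = 0.2 * T.sum(axis=0) + 0.1
    masses = rng.uniform(0.1, 10.0, size=n)
    return cw.FlowLedger(
        comps=tuple(comps), T=T, imports=imports, exports=exports,
        annual_mean_mass=masses, categories=cats,
    )
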
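# cryoweb

A guild-based nitrogen mass-balance model of an Arctic continental-shelf
ecosystem with explicit sea-ice coupling, for exploring how sea-ice retreat
propagates through a polar food web: who gains as light floods into the water
column, and who loses their hunting grounds.

It is written for marine ecosystem modellers who want a fast, fully
inspectable end-to-end box model — from dissolved nutrients, detritus and
snow/ice pools through phytoplankton, ice algae and kelp up to fish, birds,
seals, whales and polar bears — together with the analysis stack used in
ecosystem studies of this kind: steady-state (attractor) runs under decadal
climatological forcing, flow-matrix network indices, driver knock-out
experiments for causal attribution, and Morris elementary-effects screening.

## The model in brief

Nitrogen mass `B_i` in each of 35 compartments obeys a donor–recipient
bookkeeping of process flows,

```
dB_i/dt = Σ_j F_{j→i} − Σ_k F_{i→k} + imports_i − exports_i
```

with the standard kernels of this model family:

* uptake `u = u_max · S/(k_S+S) · I/(k_I+I) · Q10^{(T−T_ref)/10}`, ammonia
  preferred (nitrate inhibited by `k_inh/(k_inh+NH₄)`);
* Holling type II preference-weighted feeding
  `u_max · B · A/(k+A)`, `A = Σ pref_i·prey_i`, split across prey;
* light transmission through snow and ice
  `T = (1−C) + C(1−α)·e^{−k_ice h_ice − k_snow h_snow}`;
* habitat limitation: ice-hunting guilds feed ∝ ice cover, obligate
  open-water foragers ∝ open fraction;
* quadratic closure mortality on top predators, with an interference factor
  that tightens maritime-mammal competition as habitat shrinks;
* detritus sinking/mineralisation, nitrification, sediment–water exchange,
  and nutrient entrainment into (and melt release from) snow and ice.

The system is integrated with fixed-step RK4 over a 360-day year and relaxed
to its repeating annual cycle; the annually integrated flow matrix then feeds
the network statistics (trophic levels, omnivory, internal
ascendancy/capacity, dominance of indirect effects, nutrition shares,
F-ratio, production).

## Worked example

```python
import cryoweb as cw

config  = cw.ScenarioConfig()            # 5 decades, +0.5 degC/decade, ice loss
params  = cw.default_params()
drivers = cw.generate_decadal_drivers(config, 0)   # baseline decade

res = cw.run_to_steady_state(cw.default_initial_state(), drivers, params,
                             tol=1e-4, max_years=200, step=0.5)
ix = cw.summary_indices(res.ledger, params=params)
print(res.converged, res.years_run)
print(round(ix.mean_TL_top_predators, 2), round(ix.f_ratio, 3),
      round(ix.secondary_production, 1))
```

prints

```
True 127
3.33 0.726 258.6
```

— the baseline decade reaches its annual-cycle attractor after 127 simulated
years; top predators feed at mean trophic level 3.33, 72.6% of producer DIN
uptake is nitrate (new production), and secondary production is
258.6 mmol N m⁻² y⁻¹.

Running the decadal experiment grid shows the trophic cascade and its cause:

```python
grid = cw.run_experiment_grid(config, params,
                              experiments=["full_climate", "ice", "attenuation"],
                              tol=1e-4, max_years=250, step=0.5)
print(grid.secondary_production("full_climate").round(1).tolist())
print(grid.secondary_production("ice").round(1).tolist())
print(grid.mass_series("full_climate", "maritime_mammals").round(4).tolist())
```

```
[258.6, 337.2, 413.1, 502.8, 586.4]
[258.6, 259.9, 260.9, 261.7, 262.2]
[0.0586, 0.0406, 0.0246, 0.0143, 0.0071]
```

Secondary production more than doubles over five decades of ice retreat; with
the cryosphere drivers frozen at baseline (the ice knock-out) it barely moves
even though temperatures and boundary nutrients keep changing; and the
attenuation experiment (frozen ice made optically transparent) restores most
of the rise — the cascade is light-driven.  The one consumer that declines is
the ice-hunting maritime-mammal guild, which loses its habitat monotonically.

The `examples/` directory holds one short script per capability: driver
generation and persistence, a single audited annual cycle, steady-state
indices, the knock-out grid with PCA, Morris screening, and the packaged
guild-mass inventory (from which the headline published statistics — a 66%
maritime-mammal decline, a 357% planktivorous-fish increase and a 68.25% drop
in snow/ice DIN — are recomputed exactly).

## Layout

```
src/cryoweb/
  guilds.py       compartment inventory and food-web topology
  params.py       parameter set, validation, YAML round-trip, flattening
  drivers.py      synthetic decadal forcing, knock-outs, CSV persistence
  dynamics.py     process kernels and the mass-balance derivative engine
  simulate.py     RK4 annual cycles, flow ledger, steady-state relaxation
  ledger.py       annually integrated flow matrix container + persistence
  indices.py      trophic levels, omnivory, ascendancy/capacity, dominance,
                  nutrition shares, F-ratio, production
  experiments.py  experiment grid, change tables, snow/ice DIN change, PCA
  morris.py       Morris design, elementary effects, model screening
  masses.py       packaged guild-mass inventory (35 compartments)
  reporting.py    delimited-text reports
```

`docs/methods.md` documents the model equations, assumptions, parameter
choices, numerical details and the limits of the synthetic study design.
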
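# Methods

`cryoweb` is a guild-based nitrogen mass-balance model of an Arctic
continental-shelf ecosystem with explicit sea-ice coupling, plus the analysis
stack that turns its steady states into food-web statistics, causal knock-out
experiments and parameter-sensitivity screens.  This note records the model,
its assumptions, the numerical choices, and what the synthetic study design
can and cannot show.

## Model structure

Nitrogen is the single currency.  The domain is a coarse box geometry: an
inshore and an offshore surface zone (area fractions 0.35/0.65, 40 m deep), a
deep layer under the offshore zone (160 m), a sediment layer with porewater
nutrient pools, and a snow/ice compartment set on top.  All masses are
mmol N per m² of the whole domain; concentrations divide by the effective
layer volume per unit domain area.

The 35 compartments comprise dissolved nutrients (nitrate and ammonia in the
surface, deep, porewater, snow and ice pools), detritus (surface, deep, ice,
sediment labile and sediment refractory), corpses, four producers (surface
and deep phytoplankton, ice algae, macrophytes) and fifteen consumer guilds
from omnivorous zooplankton to maritime mammals (polar bears and arctic
foxes).  Four fish/benthos guilds carry separate larval compartments linked
by seasonal spawning and recruitment transfers; these demographic transfers
are mass-conserving but are accounted outside the trophic flow matrix.

Every process is written as a donor→recipient flow or an explicit boundary
channel, so the closed-boundary system conserves nitrogen by construction.

### Process kernels

* **Nutrient uptake** — Michaelis–Menten in each substrate with a saturating
  light factor `I/(k_I + I)`; ammonia is taken preferentially and inhibits
  nitrate uptake through `k_inh/(k_inh + NH4)`.  A fraction of uptake is
  respired straight back to ammonia; net primary production is reported as
  uptake minus this metabolic loss (positive under our sign convention,
  which is stated here because conventions differ between tools).
* **Light** — surface irradiance follows the astronomical daylight cycle at
  the configured latitude.  Transmission through the ice-covered fraction is
  `(1−C) + C(1−albedo)·exp(−k_ice·h_ice − k_snow·h_snow)`; the water column
  attenuates with a background coefficient plus an SPM-dependent term, and
  producers see the layer-mean irradiance.  Ice algae live at the ice bottom
  and see the under-ice irradiance, scaled by ice cover; they are strongly
  shade-adapted (k_I = 0.05 E m⁻² d⁻¹).
* **Feeding** — Holling type II on preference-weighted availability
  `A = Σ pref·prey`: total ingestion `B·u_max·A/(k+A)`, split across prey in
  proportion to `pref·prey`.  Assimilated intake is reduced by an excretion
  fraction (to ammonia); the unassimilated remainder is defecated to the
  zone-appropriate detritus pool.
* **Temperature** — Q10 scaling per process class (feeding 1.8, uptake 1.3,
  mineralisation/nitrification 2.0) referenced to 0 °C, the ambient
  temperature of the baseline system.  Mortality and closure terms are
  temperature-independent.  The low uptake Q10 encodes the weak temperature
  response of cold-adapted polar autotrophs; it is also what keeps warming
  alone (the ice knock-out condition) from masquerading as the light-driven
  production increase.
* **Habitat** — a feeding multiplier from the area-weighted mean ice cover:
  maritime mammals hunt on ice (multiplier = cover), cetaceans need open
  water (1 − cover), everything else is unaffected.  Pinnipeds are treated
  as indifferent: they haul out on ice but forage in open water, and the
  published inventory shows them gaining mass as ice retreats.
* **Closure** — linear plus quadratic (density-dependent) mortality.  Top
  predators carry the quadratic closure; for maritime mammals its
  coefficient is inflated by an interference factor `1 + i·(1 − cover)`
  representing intensified competition as hunting grounds shrink.  Dead
  large organisms become corpses (scavenged by benthos, birds and bears);
  small organisms go to fine detritus.
* **Recycling chain** — detritus sinks (surface→deep→sediment labile) and
  mineralises to the corresponding ammonia pool; ammonia is nitrified; the
  porewater pools exchange with the deep layer through a piston velocity; a
  small leak converts labile to refractory sediment detritus.
* **Cryosphere coupling** — ice growth (from the prescribed cover×thickness
  climatology) entrains surface nutrients and some suspended detritus into
  the ice pools; melt releases the snow/ice pools back to the surface layer
  at a rate proportional to the relative volume loss, and delivers meltwater
  DIN as a boundary input.  Atmospheric deposition lands on snow where there
  is ice cover and in the water elsewhere.  When no ice remains, residual
  cryosphere pools drain at a fixed leak rate.
* **Boundaries** — ocean exchange imports nutrients, phytoplankton and
  detritus at boundary concentrations and exports at domain concentrations
  using the prescribed volume-exchange rates; rivers deliver meltwater DIN.
  Migratory fish are a fixed outside stock of which a fraction enters over a
  30-day window each spring and leaves again in autumn — they are modelled
  only for their predation and recycling effects.  Fishing machinery exists
  (per-guild harvest ratios × an activity level) but activity is zero: the
  system is studied in its unfished state, and the harvest parameters exist
  so sensitivity screens can verify their inertness.

Driver channels that the reduced box physics does not consume (air
temperatures, the inshore–offshore exchange, the inshore outflow rate) are
still generated, persisted and honoured by the knock-out machinery, because
they are part of the forcing interface; their dynamical influence is already
embodied in the prescribed ice fields.

## Synthetic forcing

The driver generator emulates what a high-emissions ocean/biogeochemistry
projection supplies for this shelf, as monthly climatologies per decade:

* smooth truncated-sinusoid temperature cycles shifted linearly by
  +0.5 °C per decade (surface and air; the deep layer warms at 30% of that);
* a plateau-with-shoulders ice-cover envelope — perennial cover (minimum
  > 0.5) in the baseline decade, with the summer melt deepening and widening
  each decade so the final decade is ice-free for three-plus consecutive
  summer months; thickness and snow depth scale with cover so that cover and
  thickness vanish together;
* the astronomical daylight cycle at 76° N (zero irradiance in the polar
  night) with a fixed clear-sky scale;
* boundary nitrate declining 3% per decade, a summer phytoplankton bloom at
  the boundary, constant atmospheric deposition, a summer meltwater/river
  pulse, seasonal vertical diffusivity (winter convection) and wave climate.

Decadal trends are linear in the decade index — the simplest monotone
emulation.  Optional multiplicative noise (off by default, seed-controlled)
exists for robustness experiments; the default deterministic drivers keep the
steady-state attractors well defined.  Monthly values are interpolated
linearly between month midpoints inside the solver, wrapping at year end;
whether a daily-output model steps or interpolates its monthly climatology is
not observable from our sources, and interpolation was chosen for smoothness.

## Numerics

* 360-day year (12 × 30-day months) for clean month alignment.
* Fixed-step classical RK4, default 0.25 d (heavy grids in the tests and
  acceptance script use 0.5 d, which changes steady-state annual means by
  well under 1%).  Donor-limited capping inside every stage scales a
  compartment's total outflow so one step cannot remove more than 80% of its
  mass; this keeps the system non-negative without breaking the double-entry
  bookkeeping.
* The annual flow ledger accumulates the same RK4-weighted flow snapshots
  used to advance the state, so each compartment's inflow − outflow +
  boundary − Δmass budget closes to round-off.
* A tiny "refuge" mass (10⁻⁶ mmol N m⁻²) is added inside uptake and feeding
  terms so a transient collapse is not an absorbing state — recolonisation
  from unresolved refugia.  It is a parameter and can be set to zero.
* **Convergence.**  The reported metric is the maximum relative year-on-year
  change of annual mean masses (denominator floored at 10⁻⁴ mmol N m⁻²).
  Because slow modes decay geometrically — the habitat-suppressed cetacean
  guild relaxes at only a few percent per year — a small year-on-year change
  can still hide a ~25× larger remaining distance.  The run is therefore
  declared converged only when the extrapolated remaining distance
  (`metric·λ/(1−λ)`, λ estimated from successive metric ratios) is also
  within tolerance, or the metric has fallen two orders below it.  Default
  tolerance 10⁻⁶; the test suite and acceptance script use 10⁻⁴.
* The sediment refractory pool has no loss pathway: it is a permanent store
  whose mass remembers the initial condition.  It is excluded from the
  convergence metric and from attractor-independence comparisons.
* Steady states are fixed annual cycles (periodic attractors), not fixed
  points; all comparisons use annual means over the final year.

## Experiments and statistics

Knock-outs freeze a named driver group at the baseline decade's values while
all other drivers follow the scenario: boundary concentrations, water
exchanges, the eight cryosphere channels, surface irradiance, or all
temperatures.  The attenuation daughter experiment uses the ice knock-out's
drivers plus parameter overrides `k_ice = k_snow = albedo = 0`: light passes
as if the ice were gone while the nutrients stay entrained.  Grids chain
decades with warm starts (the attractor is independent of the start; warm
starts only shorten relaxation).

Flow statistics follow the ecological network analysis conventions: flows
into producers are primary production, detrital/corpse flows into living
compartments are recycling, living→living flows are consumption, scaled to
percent of live activity; standing mass is attributed to the same modes, with
mixed feeders split by their inbound flow ratio.  Trophic levels anchor
producers and non-living pools at TL 1 and solve the diet-weighted linear
system exactly; omnivory is the diet-weighted variance of prey trophic
levels.  Ascendancy and capacity are the internal (boundary-free)
information-weighted flow sums in bits (log₂, matching the mmolN-bits
convention).  The dominance of indirect effects normalises each column of the
flow matrix by total inflow including imports (making G substochastic) and
reports `Σ(N − I − G)/ΣG` with `N = (I − G)⁻¹`; inflow rather than outflow
normalisation was chosen and is flagged here because the source convention is
not stated.  The F-ratio is the nitrate share of producer DIN uptake;
secondary production sums `ae·(1−ex)·intake` over non-producer living guilds.

PCA of the experiment grid standardises each compartment across runs
(correlation PCA — masses span five orders of magnitude), drops zero-variance
compartments with a warning, and fixes component signs by making the
largest-magnitude loading positive.

Morris screening builds r randomised one-at-a-time trajectories on a p-level
grid (Δ = p/(2(p−1))), maps them to ±20% bounds around nominal values
(bounds are configurable; zero-valued parameters are carried as fixed,
unperturbed entries), and computes per-parameter elementary effects in
scaled coordinates.  Significance is a two-sided one-sample t test of the
mean effect at α = 0.05 — an explicit, configurable stand-in for the
graphical cut-off used in the source analyses, with no claim of equivalence.
Desk-scale screening uses r = 2–4 with shortened relaxations.

## Parameterisation and calibration

The shipped defaults are not a fitted parameter set.  They were chosen so
that the baseline decade is an ice-dominated, oligotrophic, light-limited
system in which every guild persists, the annual cycle is a stable attractor,
and the qualitative response structure of the study holds: production rises
as ice retreats because light (not melt nutrient) is limiting, and the
ice-hunting guild declines as its habitat disappears.  Reproducing the
published absolute masses, index values or percentage changes would require
the original calibrated parameter set and the real ocean-model forcing, and
is explicitly not attempted; the packaged inventory table ships so those
published statistics can be recomputed exactly from the printed numbers.

What the synthetic design shows: conservation, attractor independence,
correctness of the index kernels against brute-force oracles, and the causal
structure of the cascade (full climate vs ice knock-out vs attenuation).
What it cannot show: agreement with observations, realistic absolute
magnitudes, species-level turnover, or fishing-fleet dynamics (activity is
fixed at zero by design).

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the 35-compartment model at a
0.5-day step with tolerance 10⁻⁴ and up to 250–300 years per relaxation; the
experiment grid covers {full climate, ice, attenuation} × 5 decades with
warm-started decade chains; attractor independence uses three initial states;
index oracles run on 200 random ≤ 6-node webs; the model-level Morris screen
covers the fifteen harvest ratios plus a phytoplankton uptake parameter at
r = 2 with shortened (4-year, 1-day step) relaxations.  These sizes are the
package's default desk-scale study; all of them are parameters of the
respective functions.
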
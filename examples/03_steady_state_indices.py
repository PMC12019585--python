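"""Relax the baseline decade to its attractor and read the food-web indices.

Takes a few minutes: the model repeats the annual cycle until year-on-year
annual mean masses stop changing, then computes trophic levels, omnivory,
ascendancy/capacity, indirect-effect dominance, nutrition shares, the
F-ratio and production from the final annual flow ledger.
"""

import cryoweb as cw

config = cw.ScenarioConfig()
drivers = cw.generate_decadal_drivers(config, 0)
params = cw.default_params()

res = cw.run_to_steady_state(
    cw.default_initial_state(), drivers, params,
    tol=1e-4, max_years=200, step=0.5,
)
print(f"converged = {res.converged} after {res.years_run} years "
      f"(metric {res.convergence_metric:.1e})")

ix = cw.summary_indices(res.ledger, params=params)
print(f"\nmean trophic level of top predators: {ix.mean_TL_top_predators:.2f}")
print(f"mass-weighted consumer omnivory:     {ix.mean_OI_consumers:.3f}")
print(f"internal ascendancy / capacity:      {ix.AC_ratio:.3f}")
print(f"dominance of indirect effects:       {ix.indirect_dominance:.2f}")
print(f"phytoplankton F-ratio:               {ix.f_ratio:.3f}")
print(f"net primary production:              {ix.npp:8.1f} mmol N m^-2 y^-1")
print(f"secondary production:                {ix.secondary_production:8.1f}")
print("\nshares of live activity (%):")
for k, v in ix.shares_flow.items():
    print(f"  {k:20s} {v:6.1f}")

# Under the ice-covered baseline most light is reflected or absorbed by snow
# and ice, primary production is light limited, and recycling carries a large
# share of the live activity -- the signature of an immature, ice-dominated
# food web.
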
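"""Covariate balance: certified reference area vs quasi-experimental controls.

Compares both kinds of comparison area against the same synthetic project
with standardised mean differences. The biased-sited reference area lands
outside the +/-0.25 band on hazard-related covariates, while matched
controls do not — the mechanism behind inflated certified baselines.
"""

import pacteval as pe
from pacteval.matching import epoch_cover_rasters, greedy_match, sample_units, unit_table, candidate_pool

scenario = pe.make_scenario(
    grid=pe.GridSpec(450, 450, pixel_size=100.0), project_shape=(50, 50),
    siting_bias=0.25, seed=11,
)
stack = scenario.factual
cov = epoch_cover_rasters(stack, scenario.t0)

rows, cols = sample_units(scenario.project_polygon, stack.grid)
project = unit_table(stack, rows, cols, scenario.t0, cover_rasters=cov)
rrows, rcols = sample_units(scenario.reference_polygon, stack.grid)
reference = unit_table(stack, rrows, rcols, scenario.t0, cover_rasters=cov)
pool = candidate_pool(stack, scenario.project_polygon, project, scenario.t0,
                      pool_density=0.25, cover_rasters=cov)
matched = greedy_match(project.sample(120, random_state=0).reset_index(drop=True), pool, seed=0)
controls = pool.iloc[matched.pairs[:, 1]]

rep_ref = pe.balance_report(project, reference, area_kind="reference", project_id="SYN")
rep_ctl = pe.balance_report(project, controls, area_kind="control", project_id="SYN")

print("reference area vs project:")
print(rep_ref[["covariate", "smd", "flag"]].round(2).to_string(index=False))
print("\nmatched controls vs project:")
print(rep_ctl[["covariate", "smd", "flag"]].round(2).to_string(index=False))
print("\nValues beyond +/-0.25 mark a meaningful imbalance; the reference area"
      "\nis systematically more exposed to deforestation drivers than the"
      "\nproject, while the matched controls are statistically comparable.")
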
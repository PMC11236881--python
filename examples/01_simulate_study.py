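"""Generate a complete synthetic multi-environment trial.

Builds the four pipeline inputs at the study's scale: plot-level yields of
six row-column trials (100 genotypes, 2 replicates of 25 rows x 4 columns),
a breeding pedigree, and 65 correlated environmental covariates per
location, with all ground-truth effects recorded.
"""

import metpredict as mp

scenario = mp.fullscale_scenario(seed=42)

print(f"locations: {scenario.locations}")
print(f"trial plots per location: {len(scenario.trials[0].data)} "
      f"(layout {scenario.layout[0]}x{scenario.layout[1]}, "
      f"{scenario.layout[2]} replicates, unit {scenario.trials[0].unit})")
print(f"pedigree entries: {len(scenario.pedigree.entries)}")
print(f"EC table: {len(scenario.ec.locations)} locations x "
      f"{len(scenario.ec.covariate_names)} covariates")
print(f"true overall mean: {scenario.truth.mu} t/ha")
print(f"true fixed covariate slope: {scenario.truth.beta} t/ha per SD")
print("true genotype-by-location means (t/ha), first 3 genotypes:")
print(scenario.truth.true_means[:, :3].round(3))
# Each row is a location, each column a genotype; the spread across rows of
# one column is that genotype's environmental sensitivity plus interaction.
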
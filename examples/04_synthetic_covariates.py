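"""Extract synthetic covariates (SCs) from the environmental covariate panel.

Standardizes the 65 ECs and fits a multivariate PLS regression with each
genotype's location means as a separate response. The X-scores are the SCs:
one number per location per component summarizing the environment in the
direction most predictive of genotype performance. The per-EC coefficients
show which measured covariates dominate the first SC.
"""

import metpredict as mp

scenario = mp.fullscale_scenario(seed=42)
_, mean_sets = mp.fit_stage1(scenario.trials)

model, z = mp.extract_sc(mean_sets, scenario.ec, n_components=2)

for k in range(2):
    print(f"Comp{k + 1}: {model.x_variance_explained[k]:.2f}% of EC variance, "
          f"{model.y_variance_explained[k]:.2f}% of mean-yield variance")
print("\nSC values per location:")
print(model.scores_frame().round(3))
print("\ntop 5 ECs by absolute first-component coefficient:")
print(mp.coefficient_ranking(model, top_n=5).to_string(index=False))
# A held-out location's SC comes from projecting its standardized EC vector:
new_scores = mp.project_location(model, z.row(scenario.locations[0]))
print(f"\nprojected scores for {scenario.locations[0]}: {new_scores.round(3)}")
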
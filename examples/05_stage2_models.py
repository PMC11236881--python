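"""Stage II: fit across-location mixed models of increasing richness.

All models share random genotype and location effects and the fixed
residual covariance from the Stage I weights; they differ in the genotype
covariance (identity vs pedigree kinship) and the genotype-by-location
interaction structure (identity, per-location diagonal, factor-analytic).
The factor-analytic order is chosen by AIC over FA(1)-FA(3).
"""

import metpredict as mp
from metpredict.datatypes import ModelSpec, stack_means
from metpredict.stage2 import fit_fa_order_path, fit_model

scenario = mp.fullscale_scenario(seed=42)
_, mean_sets = mp.fit_stage1(scenario.trials)
A = mp.numerator_relationship(scenario.pedigree)
mean_sets, dropped = mp.drop_genotypes_without_pedigree(mean_sets, A)
print(f"dropped between stages (no pedigree): {dropped}")
stacked = stack_means(mean_sets, intersect=True)

model_sc, _ = mp.extract_sc(mean_sets, scenario.ec, n_components=1)
sc = model_sc.scores_frame()

for model_id, kw in [("M1", {}), ("M2", {"A": A}),
                     ("M7", {"sc": sc, "n_sc": 1})]:
    fit = fit_model(stacked, model_id, **kw)
    p = fit.params
    print(f"{model_id}: loglik={fit.reml_loglik:8.2f} AIC={fit.aic:8.2f} "
          f"sigma2_a={p.sigma2_a:.4f} sigma2_l={p.sigma2_l:.4f}")

best = fit_fa_order_path(stacked, ModelSpec(pi_structure="fa"))
print(f"FA order selected by AIC: {best.spec.fa_order} "
      f"(AIC {best.aic:.2f})")
# Lower AIC = better fit after penalizing extra variance parameters; the
# genotype variance sigma2_a is what selection acts on.
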
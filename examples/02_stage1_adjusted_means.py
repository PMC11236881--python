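"""Stage I: adjust one location's plot data for its row-column design.

Fits yield = mu + genotype + replicate + row + column + error by REML
(genotype fixed, design factors random) and forwards adjusted means with
precision weights to the across-location stage.
"""

import metpredict as mp

scenario = mp.fullscale_scenario(seed=42)
trial = scenario.trials[0]

fit = mp.fit_rowcol_model(trial)
ms = mp.stage2_weights(fit)

vc = fit.varcomps
print(f"location {fit.location}: REML log-likelihood {fit.loglik:.1f}, "
      f"{fit.n_iter} iterations")
print(f"variance components (kg^2/ha^2): replicate={vc.sigma2_h:.0f} "
      f"row={vc.sigma2_r:.0f} column={vc.sigma2_c:.0f} error={vc.sigma2_e:.0f}")
print("first five adjusted means forwarded to Stage II (t/ha):")
for g, m, w in list(zip(ms.genotypes, ms.means, ms.weights))[:5]:
    print(f"  {g}: mean={m:.3f}  weight={w:.1f}")
# The weight is the diagonal of the inverted mean covariance matrix: the
# effective information each adjusted mean carries into Stage II.
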
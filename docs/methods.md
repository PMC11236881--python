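# Methods

This note documents the statistical model, the estimation machinery, the
synthetic-data generator and the numerical/design choices behind
`metpredict`. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute.

## The two-stage model

Stage-wise MET analysis trades a small approximation (summarizing each
trial by adjusted means and a diagonal precision matrix) for large gains in
robustness and speed, and makes it trivial to combine trials with different
designs. Stage I fits each location's resolvable row–column model by REML
with the genotype as a fixed cell-means factor, so the adjusted mean of
genotype *i* is the GLS estimate of mu + a_i and its covariance matrix
Ω_m is the corresponding block of the inverted coefficient matrix. The
Stage II weights are the *diagonal of the full inverse* Ω_m⁻¹ — not the
reciprocal diagonal of Ω_m — which is the diagonal approximation with the
right marginal precision for each mean. Means are converted from kg/ha to
t/ha at the Stage I→II boundary (weights scale by 10⁶), so Stage II
variances and MSEPD are in t²/ha².

Stage II treats genotypes and locations as random. Writing
T = [1, t₁, …, t_q] for the (M × (1+q)) matrix of location-level
covariates, the marginal covariance of the stacked means (location-major,
genotype-within) collapses to

    V = (T G T′ + Π) ⊗ Γ + σ²_l I_M ⊗ J_I + Ω^(d)

where G is the (1+q)×(1+q) unstructured covariance of the per-genotype
random intercept and slopes, Π the among-location interaction structure,
Γ the genotype covariance (identity or the numerator relationship matrix),
J the all-ones matrix and Ω^(d) the fixed diagonal residual. This identity
is what both likelihood backends evaluate; the explicit design-matrix form
(including the genotype-major var(s) = Γ ⊗ Π stacking, equivalent under a
permutation) is verified against it in the tests.

Ω^(d) carries **no free residual scale**: the Stage I variances are taken
at face value (the fully-efficient stage-wise convention). For diagnostics,
`reml_fit(..., free_residual_scale=True)` adds one multiplicative
parameter on Ω^(d); an estimate far from 1 flags miscalibrated Stage I
weights. The scale is only identified when Ω^(d) is not proportional to a
covariance term already in the model (e.g. under the identity interaction
structure with equal weights everywhere it is confounded with σ²_s).

### Prediction for an untested location

A new location has no data, so its own effect BLUP is zero and the
prediction for genotype *i* is

    z_i = mu + a_i + Σ_q t_q (beta_q + b_iq)          (main_effect)

with the new location's SC values t_q. Under covariance structures that
allow location-specific genotype variance (diagonal, FA), part of the
genotype main effect is absorbed into the interaction; adding the average
of the genotype's interaction BLUPs over the training locations
(`main_plus_avg_interaction`) restores it and is the recommended mode for
FA models.

### Scores

MSEPD is evaluated exactly over all ordered pairs; per location the pair
sum reduces to 2(I·Σd² − (Σd)²) with d = observed − predicted, making the
statistic invariant to per-location additive shifts — deliberate, since
breeders act on differences, and an unpredictable location main effect
should not dominate the score. Spearman correlations use average ranks for
ties; the reported standard error is the between-location standard
deviation of rho divided by √M. Folds that fail to converge are excluded
from the aggregates and listed; a strict mode raises instead.

## Estimation

Both REML problems (Stage I: 4 variance components; Stage II: up to ~25
parameters for FA(3) with two covariates) are solved by direct maximization
of the REML log-likelihood with **analytic gradients** under an
unconstrained parameterization — log variances, a log-Cholesky factor for
G, free factor loadings — using L-BFGS-B. The line search guarantees a
monotone objective over accepted iterates (recorded in the fit trace), the
transform enforces nonnegativity and PSD-ness by construction, and bound
constraints keep the optimizer out of overflow territory. Defaults:
`ftol` 1e−12, projected-gradient tolerance 1e−6, at most 200 (Stage I) /
2000 (Stage II) iterations — Heywood-bound specific variances approach
their floor geometrically under the log parameterization and need the
larger budget. A fit that stops at the iteration cap with a clearly
nonzero gradient raises with its objective trace attached.

The gradient needs one projection matrix P per iteration; all parameter
derivatives then reduce to M × M contractions because every dV is either
dC ⊗ Γ or the location-block ones matrix. When Γ = I and the residual
weights are constant within each location (exactly the case for balanced
trials, whose adjusted means share a common precision), an orthogonal
rotation of genotype space whose first direction is the genotype average
block-diagonalizes V into I blocks of size M — one "average" block carrying
the fixed effects and the location variance, and I−1 identical "contrast"
blocks. Likelihood and gradient then cost O(I M³ + M² I) instead of
O((IM)³). The dense and factorized backends are checked for equality (to
1e−8, values and gradients) in the tests; BLUPs are always computed
densely at the optimum via u = Cov(u, y) V⁻¹ (y − X β̂), which the tests
verify against an independently assembled Henderson system.

FA identification uses the zero upper triangle Λ_{mk} = 0 for k > m;
the likelihood itself is rotation-invariant in Λ (tested), so this only
pins the reported representation. Specific variances are floored at
1e−8 · var(y) (flagged as Heywood cases when active). The FA order path
fits K = 1, 2, 3 with warm starts (order-K loadings seed order K+1) and
selects by AIC = −2·loglik + 2·(number of variance parameters), ties
toward the smaller order. Starting values: variance thirds of var(y) for
σ²_a, σ²_l, σ²_s; per-location sample variances for Φ; top-K eigenpairs of
the among-location covariance of the means for Λ.

## Synthetic covariates

ECs are standardized to mean zero and unit **sample (n−1)** variance over
the training locations only; a held-out location is standardized with
training statistics and never influences them. The multivariate PLS uses
the orthogonal-scores (NIPALS-family) algorithm via scikit-learn's
`PLSRegression` (centered X and Y, no Y scaling — the genotype responses
share units) run to a tight inner tolerance; the test suite pins it
against an independently coded textbook NIPALS to 1e−8. X-scores are the
SC values; projection of a new location applies the fitted
weight/deflation sequence (W(P′W)⁻¹). Variance-explained percentages are
per-deflation-step captured sums of squares over the total, for X and Y
separately; the biplot convention is the X share. The per-EC coefficient
ranking reduces the P × I coefficient matrix to one number per EC as the
first-component weight times the summed first-component response loadings
— the single linear combination that characterizes locations — an
interpretive choice, since several aggregations are defensible.

Inside cross-validation the PLS is refit on the M−1 training locations per
fold; leakage-freedom (mutating held-out means does not change the fold's
prediction) is asserted by a construction test.

## Synthetic data generator

The generator emulates a single-year dry-lowland sorghum MET at its actual
scale: M = 6 locations, I = 100 genotypes including one unpedigreed check
(dropped between stages, as such checks are in practice), two replicates
of a 25 × 4 row–column layout, and P = 65 ECs per location built as a
low-rank latent-factor structure (strength decaying per factor, Gaussian
measurement noise, default sd 0.3) to mimic blocks of correlated soil
properties. Defaults, chosen once as realistic for this crop and design
and expressed in t²/ha²: overall mean 3.0 t/ha; Stage I components
(replicate, row, column, error) = (0.05, 0.02, 0.02, 0.10); Stage II
(genotype, location, interaction) = (0.04, 0.09, 0.02); fixed covariate
slope 0.15 t/ha per SD of the first latent environmental factor with
genotype slope variance 0.01. Pedigrees come from a founder population
with random biparental crosses and optional selfing; genotype effects and
interactions are drawn with exactly the Γ ⊗ structure covariances the
models assume (matrix-normal sampling through Cholesky factors). A single
seed expands into independent substreams per component, so changing the
plot-error draw does not perturb the pedigree or the ECs.

What the generator does **not** emulate: spatial field trend beyond the
randomization-based row/column effects, year effects, genotype-specific
missingness patterns, non-Gaussian yields, or ECs whose relationship to
performance is nonlinear. Passing tests therefore demonstrate internal
correctness and the qualitative behavior of the method under its own
assumptions — not calibration to any particular real dataset.

## Problem sizes in the checks

The simulation-based checks run at deliberately chosen scales: Stage I
parameter recovery uses 200 replicate simulations of the full 100-genotype
trial (the replicate variance has a single degree of freedom at 2
replicates, so the tolerance is the larger of 10% of truth and three
Monte-Carlo standard errors of the simulation mean); FA order selection
uses 100 datasets at I = 50, M = 6; the end-to-end covariate-gain study
uses 100 paired datasets at I = 12, M = 6 with the interaction signal
flowing mainly through the environmental gradient (slope variance 0.02 vs
residual interaction 0.01). The acceptance script runs the complete
pipeline once at full scale.

## Known limitations

- Unstructured M × M interaction covariance, multi-year and multi-zone
  models, spatial (AR1×AR1) Stage I adjustments and marker-based
  relationship matrices are out of scope.
- The diagonal approximation of Ω_m⁻¹ is inherited from the stage-wise
  framework; with strongly unbalanced trials the full-matrix forwarding
  would differ.
- Founder inbreeding in the pedigree is assumed absent by default; a flag
  sets founders fully inbred (diagonal 2), the more realistic state for
  advanced selfing-crop lines — results depend on which convention the
  pedigree source used.
- With M = 6 locations, the location variance, fixed SC slopes and FA
  loadings rest on few effective observations; their estimates are noisy,
  and two SCs are near the edge of what the design supports.
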
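"""Synthetic multi-environment-trial data with known ground truth.

Generates the four pipeline inputs — plot-level phenotypes, pedigree,
environmental covariates, and (directly, for Stage II-level studies)
adjusted means — from the same generative structures the models assume, so
every stage can be tested without external data.

The default ``fullscale`` scenario mirrors a single-year dry-lowland sorghum
MET: 6 locations, 100 genotypes (one unpedigreed check among them), two
replicates in a resolvable 25-rows-by-4-columns row-column layout per
replicate, and 65 correlated environmental covariates per location built
from a low-dimensional latent factor structure. Default variance components
(t^2/ha^2): Stage I (replicate, row, column, plot error) =
(0.05, 0.02, 0.02, 0.10); Stage II (genotype, location, interaction) =
(0.04, 0.09, 0.02); overall mean 3.0 t/ha, a typical dry-lowland sorghum
yield level. The first latent environmental factor acts as the true
location covariate, with fixed slope 0.15 t/ha per SD and genotype slope
variance 0.01, so covariate-aware models have a real signal to find.

All generators are pure functions of (parameters, seed); the global seed is
expanded into independent substreams per component, so e.g. changing the
plot-error draw does not perturb the pedigree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    AMatrix,
    ECTable,
    MeanSet,
    ModelSpec,
    PedigreeTable,
    Stage1VarComps,
    TrialDataset,
    VarianceParams,
)
from .io import KG_PER_TONNE, build_pedigree
from .kinship import ensure_positive_definite, numerator_relationship


@dataclass
class SimulationTruth:
    """Ground truth behind one simulated dataset."""

    seed: int
    mu: float
    stage1_vc: Stage1VarComps
    vparams: VarianceParams
    beta: np.ndarray                  # fixed covariate slopes
    latent_scores: np.ndarray         # (M, q) true location covariates (SD units)
    genotype_effects: np.ndarray      # (I,) a
    genotype_slopes: np.ndarray       # (I, q) b
    location_effects: np.ndarray      # (M,)
    interaction: np.ndarray           # (M, I) s
    true_means: np.ndarray            # (M, I) genotype-by-location values, t/ha
    genotypes: list[str] = field(default_factory=list)
    locations: list[str] = field(default_factory=list)


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_pedigree(n_founders: int = 30, n_generations: int = 2,
                      crosses_per_gen: int = 60, selfing_prob: float = 0.2,
                      seed: int = 0) -> PedigreeTable:
    """Random breeding pedigree: founders, then generations of crosses.

    Each non-founder picks two parents from the previous generation pool
    (one parent twice with probability ``selfing_prob``, the selfing
    notation of a self-pollinated crop). Acyclic by construction.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    rng = _streams(seed, 1)[0]
    rows: list[tuple[str, Optional[str], Optional[str]]] = []
    founders = [f"F{k + 1:03d}" for k in range(n_founders)]
    rows += [(f, None, None) for f in founders]
    pool = founders
    for gen in range(1, n_generations + 1):
        new = []
        for k in range(crosses_per_gen):
            name = f"G{gen}-{k + 1:03d}"
            if rng.random() < selfing_prob:
                p = pool[rng.integers(len(pool))]
                rows.append((name, p, p))
            else:
                i, j = rng.choice(len(pool), size=2, replace=False)
                rows.append((name, pool[i], pool[j]))
            new.append(name)
        pool = new
    return build_pedigree(rows)


def final_generation(ped: PedigreeTable) -> list[str]:
    """Genotypes of the last simulated generation (sorted)."""
    names = [g for g in ped.genotypes if g.startswith("G")]
    if not names:
        return sorted(ped.genotypes)
    last = max(int(n[1:].split("-")[0]) for n in names)
    return sorted(n for n in names if n.startswith(f"G{last}-"))


def simulate_ecs(M: int = 6, P: int = 65, latent_dim: int = 3,
                 noise_sd: float = 0.3, seed: int = 0,
                 locations: Optional[Sequence[str]] = None
                 ) -> tuple[ECTable, np.ndarray]:
    """Correlated environmental covariates from a latent factor structure.

    EC = F S L' + noise with F the (M, latent_dim) standard-normal factor
    scores, L the (P, latent_dim) loadings and S a decaying strength per
    factor, mimicking blocks of correlated soil/weather variables. Returns
    the table and the factor scores (the first column is the "true"
    environmental gradient used by the phenotype generator).
    """
    if M < 2:
        raise ValueError("need at least 2 locations for an EC table")
    rng_f, rng_l, rng_e = _streams(seed, 3)
    if locations is None:
        locations = [f"LOC{m + 1}" for m in range(M)]
    F = rng_f.standard_normal((M, latent_dim))
    F = (F - F.mean(axis=0)) / F.std(axis=0, ddof=0)
    L = rng_l.standard_normal((P, latent_dim))
    strength = 1.0 / np.sqrt(np.arange(1, latent_dim + 1))
    values = F @ np.diag(strength) @ L.T + noise_sd * rng_e.standard_normal((M, P))
    names = [f"ec{j + 1:02d}" for j in range(P)]
    return ECTable(list(locations), names, values), F


def _draw_matrix_normal(rng, row_cov_chol, col_cov_chol, shape):
    Z = rng.standard_normal(shape)
    return row_cov_chol @ Z @ col_cov_chol.T


def simulate_genotype_location_effects(
    genotypes: Sequence[str], locations: Sequence[str], spec: ModelSpec,
    vparams: VarianceParams, beta: np.ndarray, latent_scores: np.ndarray,
    A: Optional[AMatrix], mu: float, seed: int,
) -> SimulationTruth:
    """Draw the Stage II random effects and assemble true G-by-L means.

    Genotype intercepts/slopes have covariance G x Gamma, interactions
    Pi x Gamma (location-major), locations are iid. ``latent_scores`` is the
    true per-location covariate multiplying the fixed and random slopes.
    """
    genotypes = sorted(genotypes)
    locations = sorted(locations)
    I, M = len(genotypes), len(locations)
    rng_c, rng_l, rng_s = _streams(seed, 3)
    if spec.uses_kinship:
        if A is None:
            raise ValueError("kinship spec needs an A matrix")
        Gam = A.submatrix(genotypes).values
    else:
        Gam = np.eye(I)
    Lg = np.linalg.cholesky(ensure_positive_definite(Gam))
    q = spec.n_sc
    G = vparams.g_matrix
    if G.shape[0] != 1 + q:
        raise ValueError(f"g_matrix must be {(1 + q, 1 + q)} for n_sc={q}")
    Lq = np.linalg.cholesky(ensure_positive_definite(G, 1e-10))
    coefs = _draw_matrix_normal(rng_c, Lq, Lg, (1 + q, I))
    a = coefs[0]
    b = coefs[1:].T  # (I, q)
    l = np.sqrt(vparams.sigma2_l) * rng_l.standard_normal(M)
    Pi = vparams.pi_matrix(M)
    Lp = np.linalg.cholesky(ensure_positive_definite(Pi, 1e-10))
    s = _draw_matrix_normal(rng_s, Lp, Lg, (M, I))
    t = np.asarray(latent_scores, dtype=float)
    if t.ndim == 1:
        t = t[:, None]
    t = t[:M, :q] if q else np.zeros((M, 0))
    beta = np.atleast_1d(np.asarray(beta, dtype=float))[:q]
    means = np.empty((M, I))
    for m in range(M):
        means[m] = mu + l[m] + a + s[m]
        for k in range(q):
            means[m] += t[m, k] * (beta[k] + b[:, k])
    return SimulationTruth(
        seed=seed, mu=mu, stage1_vc=Stage1VarComps(0, 0, 0, 0),
        vparams=vparams, beta=beta, latent_scores=t,
        genotype_effects=a, genotype_slopes=b, location_effects=l,
        interaction=s, true_means=means,
        genotypes=list(genotypes), locations=list(locations),
    )


def simulate_met(truth: SimulationTruth, stage1_vc: Stage1VarComps,
                 layout: tuple[int, int, int], seed: int,
                 unit: str = "kg/ha") -> list[TrialDataset]:
    """Plot-level trials around true genotype-by-location means.

    Each location is a resolvable row-column trial: every genotype appears
    once per replicate at a random cell of the rows x cols grid; plot yield
    adds replicate, row-within-replicate, column-within-replicate and
    residual effects with the Stage I variances (t^2/ha^2), then converts
    to the requested unit.
    """
    rows_n, cols_n, reps = layout
    I = len(truth.genotypes)
    if rows_n * cols_n != I:
        raise ValueError(f"layout {rows_n}x{cols_n} does not hold {I} genotypes")
    scale = KG_PER_TONNE if unit == "kg/ha" else 1.0
    streams = _streams(seed, len(truth.locations))
    trials = []
    for m, loc in enumerate(truth.locations):
        rng = streams[m]
        h = np.sqrt(stage1_vc.sigma2_h) * rng.standard_normal(reps)
        r_eff = np.sqrt(stage1_vc.sigma2_r) * rng.standard_normal((reps, rows_n))
        c_eff = np.sqrt(stage1_vc.sigma2_c) * rng.standard_normal((reps, cols_n))
        recs = []
        for j in range(reps):
            perm = rng.permutation(I)
            for cell, g_idx in enumerate(perm):
                k, lcol = divmod(cell, cols_n)
                value = (truth.true_means[m, g_idx] + h[j] + r_eff[j, k]
                         + c_eff[j, lcol]
                         + np.sqrt(stage1_vc.sigma2_e) * rng.standard_normal())
                recs.append((truth.genotypes[g_idx], j + 1, k + 1, lcol + 1,
                             value * scale))
        df = pd.DataFrame(recs, columns=["genotype", "replicate", "row",
                                         "column", "yield_value"])
        trials.append(TrialDataset(location=loc, data=df,
                                   layout=(rows_n, cols_n, reps), unit=unit))
    return trials


def simulate_single_trial(genotype_means: np.ndarray, stage1_vc: Stage1VarComps,
                          layout: tuple[int, int, int], seed: int,
                          location: str = "LOC1",
                          unit: str = "kg/ha") -> TrialDataset:
    """One row-column trial around given true genotype means (t/ha)."""
    genotype_means = np.asarray(genotype_means, dtype=float)
    I = genotype_means.size
    genotypes = [f"g{i + 1:03d}" for i in range(I)]
    truth = SimulationTruth(
        seed=seed, mu=float(genotype_means.mean()), stage1_vc=stage1_vc,
        vparams=VarianceParams(g_matrix=np.zeros((1, 1)), sigma2_l=0.0),
        beta=np.zeros(0), latent_scores=np.zeros((1, 0)),
        genotype_effects=genotype_means - genotype_means.mean(),
        genotype_slopes=np.zeros((I, 0)), location_effects=np.zeros(1),
        interaction=np.zeros((1, I)), true_means=genotype_means[None, :],
        genotypes=genotypes, locations=[location])
    return simulate_met(truth, stage1_vc, layout, seed=seed, unit=unit)[0]


def simulate_stacked_means(truth: SimulationTruth, residual_var: float | np.ndarray,
                           seed: int) -> list[MeanSet]:
    """Stage II-level data: true means plus heteroscedastic 'Stage I' noise.

    ``residual_var`` is a scalar or an (M,) / (M, I) array of mean variances;
    weights are their reciprocals (exactly the diagonal-approximation
    forwarding scheme with a diagonal Omega).
    """
    M, I = truth.true_means.shape
    rv = np.broadcast_to(np.asarray(residual_var, dtype=float).reshape(-1, 1)
                         if np.ndim(residual_var) == 1 else residual_var,
                         (M, I)).copy()
    rng = _streams(seed, 1)[0]
    noisy = truth.true_means + np.sqrt(rv) * rng.standard_normal((M, I))
    return [MeanSet(location=loc, genotypes=list(truth.genotypes),
                    means=noisy[m], weights=1.0 / rv[m])
            for m, loc in enumerate(truth.locations)]


# ---------------------------------------------------------------------------
# scenarios

_DEFAULT_STAGE1 = Stage1VarComps(0.05, 0.02, 0.02, 0.10)
_DEFAULT_MU = 3.0
_DEFAULT_BETA = 0.15


def _default_vparams(n_sc: int, pi_structure: str, M: int,
                     sigma2_a=0.04, sigma2_l=0.09, sigma2_s=0.02,
                     sigma2_b=0.01) -> VarianceParams:
    G = np.zeros((1 + n_sc, 1 + n_sc))
    G[0, 0] = sigma2_a
    for k in range(n_sc):
        G[1 + k, 1 + k] = sigma2_b
    if pi_structure == "identity":
        return VarianceParams(g_matrix=G, sigma2_l=sigma2_l, sigma2_s=sigma2_s)
    if pi_structure == "diagonal":
        phi = np.full(M, sigma2_s) * np.linspace(0.5, 1.5, M)
        return VarianceParams(g_matrix=G, sigma2_l=sigma2_l, phi=phi)
    lam = np.sqrt(sigma2_s) * np.linspace(0.6, 1.4, M)[:, None]
    phi = np.full(M, 0.5 * sigma2_s)
    return VarianceParams(g_matrix=G, sigma2_l=sigma2_l, phi=phi, loadings=lam)


@dataclass
class Scenario:
    """One complete simulated study: all four inputs plus the truth."""

    trials: list[TrialDataset]
    pedigree: PedigreeTable
    ec: ECTable
    truth: SimulationTruth
    layout: tuple[int, int, int]

    @property
    def locations(self) -> list[str]:
        return [t.location for t in self.trials]


def make_scenario(seed: int, M: int, I: int, layout: tuple[int, int, int],
                  P: int = 65, latent_dim: int = 3, ec_noise_sd: float = 0.3,
                  n_sc: int = 1, pi_structure: str = "identity",
                  gamma: str = "kinship", with_check: bool = True,
                  mu: float = _DEFAULT_MU, beta: float = _DEFAULT_BETA,
                  stage1_vc: Stage1VarComps = _DEFAULT_STAGE1,
                  vparams: Optional[VarianceParams] = None) -> Scenario:
    """Assemble a full scenario from independent seeded substreams."""
    s_ped, s_ec, s_eff, s_plot = [int(s.generate_state(1)[0] % (2**31))
                                  for s in np.random.SeedSequence(seed).spawn(4)]
    n_ped = I - 1 if with_check else I
    ped = simulate_pedigree(n_founders=max(4, n_ped // 3), n_generations=2,
                            crosses_per_gen=max(n_ped, 4), seed=s_ped)
    pool = final_generation(ped)
    genotypes = pool[:n_ped]
    if len(genotypes) < n_ped:
        raise ValueError("pedigree simulation produced too few genotypes")
    trial_genotypes = sorted(genotypes + (["CHECK-1"] if with_check else []))
    ec, F = simulate_ecs(M=M, P=P, latent_dim=latent_dim, noise_sd=ec_noise_sd,
                         seed=s_ec)
    spec = ModelSpec(gamma=gamma, pi_structure=pi_structure, n_sc=n_sc)
    A = numerator_relationship(ped) if gamma == "kinship" else None
    if A is not None and with_check:
        # the check has no pedigree: simulate its effects as unrelated
        vals = np.zeros((len(A.genotypes) + 1, len(A.genotypes) + 1))
        g2 = sorted(A.genotypes + ["CHECK-1"])
        idx = [g2.index(g) for g in A.genotypes]
        vals[np.ix_(idx, idx)] = A.values
        c = g2.index("CHECK-1")
        vals[c, c] = 1.0
        A_sim = AMatrix(g2, vals)
    else:
        A_sim = A
    vp = vparams if vparams is not None else _default_vparams(n_sc, pi_structure, M)
    truth = simulate_genotype_location_effects(
        trial_genotypes, ec.locations, spec, vp,
        beta=np.full(max(n_sc, 1), beta)[:n_sc] if n_sc else np.zeros(0),
        latent_scores=F[:, : max(n_sc, 1)], A=A_sim, mu=mu, seed=s_eff)
    truth.stage1_vc = stage1_vc
    trials = simulate_met(truth, stage1_vc, layout, seed=s_plot, unit="kg/ha")
    return Scenario(trials=trials, pedigree=ped, ec=ec, truth=truth, layout=layout)


def fullscale_scenario(seed: int = 0, **overrides) -> Scenario:
    """Six locations, 100 genotypes (one unpedigreed check), 2 replicates of
    a 25x4 row-column layout, 65 correlated ECs."""
    kw = dict(M=6, I=100, layout=(25, 4, 2), P=65, latent_dim=3)
    kw.update(overrides)
    return make_scenario(seed, **kw)


def tiny_scenario(seed: int = 0, **overrides) -> Scenario:
    """Fast smoke-test scale: 4 locations, 12 genotypes, 4x3 layout, 20 ECs."""
    kw = dict(M=4, I=12, layout=(4, 3, 2), P=20, latent_dim=2,
              with_check=False)
    kw.update(overrides)
    return make_scenario(seed, **kw)
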
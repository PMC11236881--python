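"""Stage II REML: likelihood correctness, BLUP oracle, structure properties."""

import numpy as np
import pytest
import scipy.linalg as sla

import metpredict as mp
from metpredict import stage2
from metpredict.datatypes import (
    MeanSet,
    ModelSpec,
    VarianceParams,
    stack_means,
)
from metpredict.stage1 import ConvergenceError

from _oracles import henderson_mme_blups
from conftest import identity_vparams

_LOG2PI = np.log(2.0 * np.pi)


def _reml_loglik_oracle(mm, params):
    """Independent REML log-likelihood from explicit design matrices.

    Builds V term by term with Z matrices, using the genotype-major
    interaction stacking var(s) = Gamma x Pi mapped to the location-major
    response order by an explicit permutation — the printed form of the
    model, not the collapsed one used by the implementation.
    """
    I, M = mm.n_genotypes, mm.n_locations
    N = I * M
    Gam = mm.gamma if mm.gamma is not None else np.eye(I)
    T = mm.T
    X = np.kron(T, np.ones((I, 1)))
    Zc = np.kron(T, np.eye(I))
    Z2 = np.kron(np.eye(M), np.ones((I, 1)))
    # permutation: s is genotype-major (i outer, m inner); y is location-major
    Pmat = np.zeros((N, N))
    for m in range(M):
        for i in range(I):
            Pmat[m * I + i, i * M + m] = 1.0
    Pi = params.pi_matrix(M)
    V = (Zc @ np.kron(params.g_matrix, Gam) @ Zc.T
         + params.sigma2_l * Z2 @ Z2.T
         + Pmat @ np.kron(Gam, Pi) @ Pmat.T
         + np.diag(mm.omega))
    p = X.shape[1]
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ mm.y)
    r = mm.y - X @ beta
    return -0.5 * ((N - p) * _LOG2PI + np.linalg.slogdet(V)[1]
                   + np.linalg.slogdet(XtViX)[1] + r @ Vi @ r)


@pytest.fixture(scope="module")
def tiny_stacked(tiny, tiny_means):
    return stack_means(tiny_means, intersect=True)


@pytest.fixture(scope="module")
def tiny_A(tiny):
    return mp.numerator_relationship(tiny.pedigree)


class TestBuildModel:
    def test_smallest_identity_case(self):
        sets = [MeanSet(f"L{m}", ["g1", "g2"], [1.0 + m, 2.0 + m], [4.0, 4.0])
                for m in range(2)]
        mm = stage2.build_model(stack_means(sets), ModelSpec())
        assert mm.X.shape == (4, 1)
        np.testing.assert_array_equal(mm.omega, np.full(4, 0.25))
        assert mm.gamma is None

    def test_sc_design_row_structure(self):
        sets = [MeanSet(f"L{m}", ["g1", "g2"], [1.0, 2.0], [1.0, 1.0])
                for m in range(3)]
        t = np.array([-1.0, 0.0, 1.0])
        mm = stage2.build_model(stack_means(sets),
                                ModelSpec(n_sc=1), sc=t)
        # fixed-design row for (genotype i, location m) is (1, t_m)
        np.testing.assert_array_equal(mm.X[:, 0], np.ones(6))
        np.testing.assert_array_equal(mm.X[:, 1], np.repeat(t, 2))

    def test_missing_sc_location_error(self):
        sets = [MeanSet(f"L{m}", ["g1", "g2"], [1.0, 2.0], [1.0, 1.0])
                for m in range(3)]
        with pytest.raises(ValueError, match="missing SC"):
            stage2.build_model(stack_means(sets), ModelSpec(n_sc=1),
                               sc={"L0": 1.0, "L1": 0.5})

    def test_single_location_rejected(self):
        sets = [MeanSet("L0", ["g1", "g2", "g3"], [1, 2, 3], [1, 1, 1])]
        with pytest.raises(ValueError, match="2 locations"):
            stage2.build_model(stack_means(sets), ModelSpec())


class TestLikelihood:
    @pytest.mark.parametrize("gamma,pi,n_sc", [
        ("identity", "identity", 0),
        ("kinship", "identity", 0),
        ("identity", "diagonal", 1),
        ("kinship", "fa", 1),
    ])
    def test_matches_printed_form_oracle(self, tiny, tiny_means, tiny_A,
                                         gamma, pi, n_sc):
        """The collapsed covariance equals the explicit Z-matrix model with
        genotype-major interaction stacking var(s) = Gamma x Pi."""
        stacked = stack_means(tiny_means, intersect=True)
        spec = ModelSpec(gamma=gamma, pi_structure=pi, fa_order=1, n_sc=n_sc)
        sc = tiny.truth.latent_scores[:, :1] if n_sc else None
        mm = stage2.build_model(stacked, spec, A=tiny_A, sc=sc)
        M = mm.n_locations
        rng = np.random.default_rng(7)
        G = np.array([[0.05]]) if n_sc == 0 else \
            np.array([[0.05, 0.01], [0.01, 0.02]])
        if pi == "identity":
            params = VarianceParams(g_matrix=G, sigma2_l=0.08, sigma2_s=0.03)
        elif pi == "diagonal":
            params = VarianceParams(g_matrix=G, sigma2_l=0.08,
                                    phi=0.01 + 0.02 * rng.random(M))
        else:
            params = VarianceParams(g_matrix=G, sigma2_l=0.08,
                                    phi=0.01 + 0.01 * rng.random(M),
                                    loadings=0.1 * rng.standard_normal((M, 1)))
        got = stage2.reml_loglik(mm, params)
        want = _reml_loglik_oracle(mm, params)
        assert abs(got - want) < 1e-8

    def test_dense_and_factorized_backends_agree(self, tiny):
        ms = mp.simulate_stacked_means(tiny.truth, residual_var=0.01, seed=2)
        stacked = stack_means(ms, intersect=True)
        for spec in [ModelSpec(), ModelSpec(pi_structure="diagonal"),
                     ModelSpec(pi_structure="fa", fa_order=2),
                     ModelSpec(n_sc=1)]:
            sc = tiny.truth.latent_scores[:, :1] if spec.n_sc else None
            mm = stage2.build_model(stacked, spec, sc=sc)
            assert mm.gamma is None and mm.homogeneous_weights
            par = stage2._Parameterization(mm, float(np.var(mm.y)))
            rng = np.random.default_rng(11)
            for _ in range(3):
                theta = rng.normal(-3.0, 0.7, par.n_params)
                nd, gd = stage2._dense_nll(mm, par, theta, True)
                nf, gf = stage2._factorized_nll(mm, par, theta, True)
                assert abs(nd - nf) < 1e-8 * max(1.0, abs(nd))
                np.testing.assert_allclose(gd, gf, atol=1e-8)

    def test_fa_rotation_invariance(self, tiny_means):
        stacked = stack_means(tiny_means, intersect=True)
        spec = ModelSpec(pi_structure="fa", fa_order=2)
        mm = stage2.build_model(stacked, spec)
        M = mm.n_locations
        rng = np.random.default_rng(5)
        lam = 0.15 * rng.standard_normal((M, 2))
        phi = 0.01 + 0.01 * rng.random(M)
        base = VarianceParams(g_matrix=np.array([[0.05]]), sigma2_l=0.08,
                              phi=phi, loadings=lam)
        theta = rng.uniform(0, 2 * np.pi)
        Q = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        rot = VarianceParams(g_matrix=base.g_matrix, sigma2_l=0.08,
                             phi=phi, loadings=lam @ Q)
        assert abs(stage2.reml_loglik(mm, base)
                   - stage2.reml_loglik(mm, rot)) < 1e-8

    def test_fa_with_zero_loadings_equals_identity_structure(self, tiny_means):
        stacked = stack_means(tiny_means, intersect=True)
        mm_id = stage2.build_model(stacked, ModelSpec())
        mm_fa = stage2.build_model(stacked, ModelSpec(pi_structure="fa"))
        M = mm_id.n_locations
        s2 = 0.025
        ll_id = stage2.reml_loglik(mm_id, identity_vparams(sigma2_s=s2))
        ll_fa = stage2.reml_loglik(
            mm_fa, VarianceParams(g_matrix=np.array([[0.04]]), sigma2_l=0.09,
                                  phi=np.full(M, s2), loadings=np.zeros((M, 1))))
        assert abs(ll_id - ll_fa) < 1e-6


class TestFitting:
    def test_blups_match_henderson_mme_at_frozen_params(self, tiny, tiny_means,
                                                        tiny_A):
        stacked = stack_means(tiny_means, intersect=True)
        spec = ModelSpec(gamma="kinship", pi_structure="diagonal", n_sc=1)
        mm = stage2.build_model(stacked, spec, A=tiny_A,
                                sc=tiny.truth.latent_scores[:, :1])
        I, M = mm.n_genotypes, mm.n_locations
        Gam = tiny_A.submatrix(stacked.genotypes).values
        params = VarianceParams(g_matrix=np.array([[0.04, 0.005],
                                                   [0.005, 0.01]]),
                                sigma2_l=0.09,
                                phi=np.linspace(0.01, 0.03, M))
        mu, beta, a, b, l, s = stage2.blups(mm, params)
        T = mm.T
        X = np.kron(T, np.ones((I, 1)))
        Z = np.hstack([np.kron(T, np.eye(I)),
                       np.kron(np.eye(M), np.ones((I, 1))),
                       np.eye(I * M)])
        G_full = sla.block_diag(np.kron(params.g_matrix, Gam),
                                params.sigma2_l * np.eye(M),
                                np.kron(np.diag(params.phi), Gam))
        beta_o, u_o = henderson_mme_blups(mm.y, X, Z, G_full, mm.omega)
        np.testing.assert_allclose([mu, beta[0]], beta_o, atol=1e-8)
        np.testing.assert_allclose(a, u_o[:I], atol=1e-8)
        np.testing.assert_allclose(b[:, 0], u_o[I:2 * I], atol=1e-8)
        np.testing.assert_allclose(l, u_o[2 * I:2 * I + M], atol=1e-8)
        np.testing.assert_allclose(s.ravel(), u_o[2 * I + M:], atol=1e-8)

    def test_loglik_trace_monotone(self, tiny_means):
        stacked = stack_means(tiny_means, intersect=True)
        for spec in [ModelSpec(), ModelSpec(pi_structure="diagonal"),
                     ModelSpec(pi_structure="fa")]:
            fit = stage2.reml_fit(stage2.build_model(stacked, spec))
            assert np.all(np.diff(fit.trace) >= -1e-9)

    def test_nesting_loglik_ordering(self, tiny_means):
        stacked = stack_means(tiny_means, intersect=True)
        ll_id = stage2.reml_fit(stage2.build_model(stacked, ModelSpec())).reml_loglik
        ll_diag = stage2.reml_fit(
            stage2.build_model(stacked, ModelSpec(pi_structure="diagonal"))).reml_loglik
        ll_fa = stage2.reml_fit(
            stage2.build_model(stacked, ModelSpec(pi_structure="fa"))).reml_loglik
        assert ll_diag >= ll_id - 1e-6
        assert ll_fa >= ll_diag - 1e-6

    def test_identity_and_kinship_coincide_with_A_identity(self, tiny_means):
        stacked = stack_means(tiny_means, intersect=True)
        fit1 = stage2.reml_fit(stage2.build_model(stacked, ModelSpec()))
        A_id = mp.identity_amatrix(stacked.genotypes)
        fit2 = stage2.reml_fit(stage2.build_model(
            stacked, ModelSpec(gamma="kinship"), A=A_id))
        assert abs(fit1.reml_loglik - fit2.reml_loglik) < 1e-5
        np.testing.assert_allclose(fit1.params.sigma2_a, fit2.params.sigma2_a,
                                   rtol=1e-3)

    def test_aic_counts_variance_parameters(self, tiny_means):
        stacked = stack_means(tiny_means, intersect=True)
        M = stacked.n_locations
        fit = stage2.reml_fit(stage2.build_model(stacked, ModelSpec()))
        assert fit.n_vparams == 3
        assert abs(fit.aic - (-2 * fit.reml_loglik + 2 * 3)) < 1e-10
        fit_fa = stage2.reml_fit(stage2.build_model(
            stacked, ModelSpec(pi_structure="fa", fa_order=1)))
        assert fit_fa.n_vparams == 2 + M + M

    def test_blup_sum_near_zero(self, tiny_means):
        stacked = stack_means(tiny_means, intersect=True)
        fit = stage2.reml_fit(stage2.build_model(stacked, ModelSpec()))
        scale = np.abs(fit.blup_a).max()
        assert abs(fit.blup_a.mean()) < 0.05 * scale + 1e-8

    def test_free_residual_scale_diagnostic(self, tiny):
        """With the diagnostic scale freed, inflating all weights by c is
        absorbed by the scale estimate and the loglik can only improve."""
        M = len(tiny.truth.locations)
        # heterogeneous weights: the scale is only identified when Omega^(d)
        # is not proportional to any covariance term already in the model
        rv = np.linspace(0.004, 0.03, M)
        ms = mp.simulate_stacked_means(tiny.truth, residual_var=rv, seed=61)
        stacked = stack_means(ms, intersect=True)
        mm = stage2.build_model(stacked, ModelSpec())
        fixed = stage2.reml_fit(mm)
        freed = stage2.reml_fit(mm, free_residual_scale=True)
        assert freed.reml_loglik >= fixed.reml_loglik - 1e-6
        assert freed.params.residual_scale > 0
        # misstate the weights by 4x: the freed model family is unchanged,
        # so the loglik matches and the scale estimate compensates
        inflated = [MeanSet(m.location, list(m.genotypes), m.means,
                            m.weights * 4.0) for m in ms]
        mm4 = stage2.build_model(stack_means(inflated, intersect=True),
                                 ModelSpec())
        freed4 = stage2.reml_fit(mm4, free_residual_scale=True)
        assert abs(freed4.reml_loglik - freed.reml_loglik) < 1e-4
        np.testing.assert_allclose(freed4.params.residual_scale,
                                   4.0 * freed.params.residual_scale,
                                   rtol=0.02)

    def test_ill_posed_model_rejected(self):
        sets = [MeanSet(f"L{m}", ["g1", "g2"], [1.0, 2.0], [1.0, 1.0])
                for m in range(2)]
        stacked = stack_means(sets)
        with pytest.raises(ValueError, match="ill-posed"):
            stage2.reml_fit(stage2.build_model(
                stacked, ModelSpec(pi_structure="fa", fa_order=2)))


class TestFAOrderPath:
    def test_fa2_sigma_is_psd_low_rank(self, tiny_means):
        stacked = stack_means(tiny_means, intersect=True)
        spec = ModelSpec(pi_structure="fa", fa_order=2)
        fit = stage2.reml_fit(stage2.build_model(stacked, spec))
        lam = fit.params.loadings
        Sigma = lam @ lam.T + np.diag(fit.params.phi)
        assert np.linalg.eigvalsh(Sigma).min() > 0
        assert np.linalg.matrix_rank(lam @ lam.T, tol=1e-10) <= 2
        # identification: zero upper triangle
        for m in range(lam.shape[0]):
            np.testing.assert_array_equal(lam[m, m + 1:], 0.0)

    def test_aic_path_monotone_under_strong_fa3_truth(self):
        M, I = 6, 60
        rng = np.random.default_rng(8)
        lam = 0.25 * rng.standard_normal((M, 3))
        vp = VarianceParams(g_matrix=np.array([[0.04]]), sigma2_l=0.09,
                            phi=np.full(M, 0.005), loadings=lam)
        truth = mp.simulate_genotype_location_effects(
            [f"g{i:03d}" for i in range(I)], [f"L{m}" for m in range(M)],
            ModelSpec(pi_structure="fa"), vp, beta=np.zeros(0),
            latent_scores=np.zeros((M, 0)), A=None, mu=3.0, seed=4)
        ms = mp.simulate_stacked_means(truth, residual_var=0.002, seed=5)
        stacked = stack_means(ms)
        spec = ModelSpec(pi_structure="fa")
        fits = stage2.fit_fa_order_path(stacked, spec, return_all=True)
        aics = [f.aic for f in sorted(fits, key=lambda f: f.spec.fa_order)]
        assert aics[1] < aics[0]
        assert aics[2] < aics[1]
        best = stage2.fit_fa_order_path(stacked, spec)
        assert best.spec.fa_order == 3

    def test_requires_fa_spec(self, tiny_means):
        stacked = stack_means(tiny_means, intersect=True)
        with pytest.raises(ValueError, match="fa spec"):
            stage2.fit_fa_order_path(stacked, ModelSpec())
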
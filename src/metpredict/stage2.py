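"""Stage II: weighted REML for the across-location model suite.

The response is the stacked vector of Stage I adjusted means (location-major,
genotype-within). The model is

    y = 1 mu + t beta + Z1 a + Z2 l + Z3 s + Z4 b + f

with genotype effects a ~ N(0, Gamma sigma2_a) (Gamma = I or the kinship
matrix A), location effects l ~ N(0, I sigma2_l), interaction effects
s ~ N(0, Gamma x Pi) where Pi is the among-location structure (identity
sigma2_s, diagonal Phi, or factor-analytic Sigma = Lambda Lambda' + Phi),
optional fixed slopes beta on synthetic covariates t with per-genotype
random slopes b jointly distributed with a as N(0, G x Gamma), and residual
f with *fixed* diagonal covariance Omega^(d) from the Stage I weights (no
extra residual scale parameter: the fully-efficient stage-wise convention).

Writing T = [1, t_1, ..., t_q] (M x (1+q)) for the location-level fixed
covariates, the marginal covariance collapses to

    V = (T G T' + Pi) (x) Gamma  +  sigma2_l I_M (x) J_I  +  diag(omega)

with (x) the Kronecker product and J the all-ones matrix, which is what the
likelihood code exploits. REML maximization runs on an unconstrained
parameterization (log variances, log-Cholesky for G, free loadings with the
zero-upper-triangle identification Lambda[m,k] = 0 for k > m) with analytic
gradients via L-BFGS-B; accepted iterates are monotone in the objective.

When Gamma = I and the residual weights are constant within each location, a
rotation of genotype space block-diagonalizes V into M x M blocks, reducing
each likelihood evaluation from O((IM)^3) to O(I M^3); the dense and
factorized paths are algebraically identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .datatypes import (
    AMatrix,
    FitResult,
    ModelSpec,
    StackedMeans,
    VarianceParams,
)
from .stage1 import ConvergenceError, FitControls

log = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# model assembly

@dataclass
class ModelMatrices:
    """Assembled inputs of one Stage II model fit."""

    spec: ModelSpec
    genotypes: list[str]
    locations: list[str]
    y: np.ndarray          # (N,) location-major
    T: np.ndarray          # (M, 1+q) location-level fixed covariates [1, t]
    gamma: Optional[np.ndarray]  # (I, I) kinship, or None for identity
    omega: np.ndarray      # (N,) fixed residual variances (diag of Omega^(d))
    sc: Optional[np.ndarray]     # (M, q) covariate values, None if q == 0

    @property
    def n_genotypes(self) -> int:
        return len(self.genotypes)

    @property
    def n_locations(self) -> int:
        return len(self.locations)

    @property
    def n_sc(self) -> int:
        return self.T.shape[1] - 1

    @property
    def X(self) -> np.ndarray:
        return np.kron(self.T, np.ones((self.n_genotypes, 1)))

    @property
    def homogeneous_weights(self) -> bool:
        W = self.omega.reshape(self.n_locations, self.n_genotypes)
        return bool(np.all(np.ptp(W, axis=1) <= 1e-12 * np.abs(W).max()))


def build_model(stacked: StackedMeans, spec: ModelSpec,
                A: Optional[AMatrix] = None,
                sc: Optional[np.ndarray | pd.DataFrame | dict] = None
                ) -> ModelMatrices:
    """Assemble design quantities for one model on stacked Stage I means.

    ``sc`` supplies the synthetic covariate values per location when
    ``spec.n_sc > 0``: an (M, n_sc) array in stacked-location order, a
    DataFrame indexed by location, or a mapping location -> vector.
    """
    I, M = stacked.n_genotypes, stacked.n_locations
    if M < 2:
        raise ValueError("Stage II needs at least 2 locations "
                         "(location variance inestimable otherwise)")
    gamma = None
    if spec.uses_kinship:
        if A is None:
            raise ValueError("spec requires kinship but no A matrix supplied")
        sub = A.submatrix(stacked.genotypes)
        gamma = sub.values
    t = None
    if spec.n_sc > 0:
        if sc is None:
            raise ValueError("spec requires synthetic covariates but sc is None")
        if isinstance(sc, pd.DataFrame):
            missing = [l for l in stacked.locations if l not in sc.index]
            if missing:
                raise ValueError(f"missing SC for location(s): {missing}")
            t = sc.loc[stacked.locations].to_numpy(dtype=float)
        elif isinstance(sc, dict):
            missing = [l for l in stacked.locations if l not in sc]
            if missing:
                raise ValueError(f"missing SC for location(s): {missing}")
            t = np.vstack([np.atleast_1d(sc[l]) for l in stacked.locations])
        else:
            t = np.asarray(sc, dtype=float)
            if t.ndim == 1:
                t = t[:, None]
            if t.shape[0] != M:
                raise ValueError(f"sc has {t.shape[0]} rows, expected {M}")
        if t.shape[1] < spec.n_sc:
            raise ValueError(f"spec.n_sc={spec.n_sc} but sc has {t.shape[1]} columns")
        t = t[:, : spec.n_sc]
    T = np.hstack([np.ones((M, 1))] + ([t] if t is not None else []))
    return ModelMatrices(spec=spec, genotypes=list(stacked.genotypes),
                         locations=list(stacked.locations), y=stacked.y.copy(),
                         T=T, gamma=gamma, omega=stacked.omega_d.copy(), sc=t)


# ---------------------------------------------------------------------------
# parameterization

class _Parameterization:
    """Maps the unconstrained optimizer vector to VarianceParams and back,
    and carries the chain rule for the analytic gradient."""

    def __init__(self, mm: ModelMatrices, vary: float,
                 free_residual_scale: bool = False):
        self.spec = mm.spec
        self.M = mm.n_locations
        self.q = mm.n_sc
        self.vary = vary
        self.free_scale = free_residual_scale
        self.dim_g = (1 + self.q) * (2 + self.q) // 2
        pi = self.spec.pi_structure
        if pi == "identity":
            self.dim_pi = 1
        elif pi == "diagonal":
            self.dim_pi = self.M
        else:
            K = self.spec.fa_order
            self.n_load = self.M * K - K * (K - 1) // 2
            self.dim_pi = self.n_load + self.M
        self.n_params = self.dim_g + 1 + self.dim_pi + int(free_residual_scale)
        # index pairs of the lower-triangular G Cholesky factor
        self.g_idx = [(i, j) for i in range(1 + self.q) for j in range(i + 1)]
        if pi == "fa":
            K = self.spec.fa_order
            self.load_idx = [(m, k) for k in range(K) for m in range(k, self.M)]
        lo, hi = np.log(vary) - 27.0, np.log(vary) + 6.0
        lam_bound = 10.0 * np.sqrt(vary)
        heywood = np.log(1e-8 * vary)
        bounds: list[tuple[float, float]] = []
        for (i, j) in self.g_idx:
            bounds.append((lo, hi) if i == j else (-lam_bound, lam_bound))
        bounds.append((lo, hi))  # log sigma2_l
        if pi == "identity":
            bounds.append((lo, hi))
        elif pi == "diagonal":
            bounds += [(lo, hi)] * self.M
        else:
            bounds += [(-lam_bound, lam_bound)] * self.n_load
            bounds += [(max(lo, heywood), hi)] * self.M
        if free_residual_scale:
            bounds.append((np.log(1e-2), np.log(1e2)))
        self.bounds = bounds
        self.heywood_floor = np.exp(heywood)

    def res_scale(self, theta) -> float:
        return float(np.exp(theta[-1])) if self.free_scale else 1.0

    # -- mapping ---------------------------------------------------------
    def _g_chol(self, theta) -> np.ndarray:
        L = np.zeros((1 + self.q, 1 + self.q))
        for t, (i, j) in zip(theta[: self.dim_g], self.g_idx):
            L[i, j] = np.exp(t) if i == j else t
        return L

    def unpack(self, theta: np.ndarray) -> tuple[np.ndarray, float, np.ndarray,
                                                 Optional[np.ndarray],
                                                 Optional[np.ndarray], float]:
        """Return (G, sigma2_l, C=TGT'+Pi ingredients): (G, sl, Pi, Lambda, phi, sigma2_s)."""
        L = self._g_chol(theta)
        G = L @ L.T
        sl = float(np.exp(theta[self.dim_g]))
        rest = theta[self.dim_g + 1: self.dim_g + 1 + self.dim_pi]
        pi = self.spec.pi_structure
        if pi == "identity":
            ss = float(np.exp(rest[0]))
            return G, sl, ss * np.eye(self.M), None, None, ss
        if pi == "diagonal":
            phi = np.exp(rest)
            return G, sl, np.diag(phi), None, phi, 0.0
        K = self.spec.fa_order
        lam = np.zeros((self.M, K))
        for t, (m, k) in zip(rest[: self.n_load], self.load_idx):
            lam[m, k] = t
        phi = np.exp(rest[self.n_load:])
        return G, sl, lam @ lam.T + np.diag(phi), lam, phi, 0.0

    def to_params(self, theta: np.ndarray) -> VarianceParams:
        G, sl, Pi, lam, phi, ss = self.unpack(theta)
        return VarianceParams(g_matrix=G, sigma2_l=sl, sigma2_s=ss,
                              phi=phi, loadings=lam,
                              residual_scale=self.res_scale(theta))

    def from_params(self, p: VarianceParams) -> np.ndarray:
        theta = np.empty(self.n_params)
        L = np.linalg.cholesky(p.g_matrix + 1e-12 * np.eye(1 + self.q))
        for n, (i, j) in enumerate(self.g_idx):
            theta[n] = np.log(max(L[i, j], 1e-12)) if i == j else L[i, j]
        theta[self.dim_g] = np.log(max(p.sigma2_l, 1e-12))
        if self.free_scale:
            theta[-1] = np.log(max(p.residual_scale, 1e-12))
        pi = self.spec.pi_structure
        rest = theta[self.dim_g + 1: self.dim_g + 1 + self.dim_pi]
        if pi == "identity":
            rest[0] = np.log(max(p.sigma2_s, 1e-12))
        elif pi == "diagonal":
            rest[:] = np.log(np.maximum(p.phi, 1e-12))
        else:
            for n, (m, k) in enumerate(self.load_idx):
                rest[n] = p.loadings[m, k]
            rest[self.n_load:] = np.log(np.maximum(p.phi, self.heywood_floor))
        return theta

    # -- gradient chain rule --------------------------------------------
    def grad_from_blocks(self, theta: np.ndarray, T: np.ndarray,
                         D: np.ndarray, d_sl: float,
                         d_scale: float = 0.0) -> np.ndarray:
        """Gradient of the negative REML log-likelihood.

        ``D = 0.5 * (S - K)`` where S and K are the M x M trace and
        quadratic-form blocks such that d(nll)/dC = D for the among-location
        matrix C = T G T' + Pi; ``d_sl`` is the ready-made derivative w.r.t.
        log sigma2_l.
        """
        grad = np.empty(self.n_params)
        L = self._g_chol(theta)
        Dt = T.T @ D @ T
        DtL2 = 2.0 * Dt @ L
        for n, (i, j) in enumerate(self.g_idx):
            g = DtL2[i, j]
            grad[n] = g * L[i, j] if i == j else g
        grad[self.dim_g] = d_sl
        rest_i = self.dim_g + 1
        rest_end = rest_i + self.dim_pi
        pi = self.spec.pi_structure
        if pi == "identity":
            ss = float(np.exp(theta[rest_i]))
            grad[rest_i] = float(np.trace(D)) * ss
        elif pi == "diagonal":
            phi = np.exp(theta[rest_i:rest_end])
            grad[rest_i:rest_end] = np.diag(D) * phi
        else:
            K = self.spec.fa_order
            lam = np.zeros((self.M, K))
            rest = theta[rest_i:rest_end]
            for t, (m, k) in zip(rest[: self.n_load], self.load_idx):
                lam[m, k] = t
            Dlam2 = 2.0 * D @ lam
            for n, (m, k) in enumerate(self.load_idx):
                grad[rest_i + n] = Dlam2[m, k]
            phi = np.exp(rest[self.n_load:])
            grad[rest_i + self.n_load:rest_end] = np.diag(D) * phi
        if self.free_scale:
            grad[-1] = d_scale
        return grad


# ---------------------------------------------------------------------------
# likelihood backends

def _dense_nll(mm: ModelMatrices, par: _Parameterization, theta,
               want_grad: bool, aux: Optional[dict] = None):
    I, M = mm.n_genotypes, mm.n_locations
    N = I * M
    G, sl, Pi, _, _, _ = par.unpack(theta)
    scale = par.res_scale(theta)
    C = mm.T @ G @ mm.T.T + Pi
    Gam = mm.gamma if mm.gamma is not None else np.eye(I)
    V = np.kron(C, Gam)
    V[np.arange(N), np.arange(N)] += scale * mm.omega
    JI = np.ones((I, I))
    V += sl * np.kron(np.eye(M), JI)
    X, y = mm.X, mm.y
    p = X.shape[1]
    Lv = np.linalg.cholesky(V)
    logdetV = 2.0 * np.sum(np.log(np.diag(Lv)))
    half = np.linalg.solve(Lv, np.hstack([X, y[:, None]]))
    ViX = np.linalg.solve(Lv.T, half[:, :p])
    XtViX = X.T @ ViX
    Lc = np.linalg.cholesky(XtViX)
    logdetC = 2.0 * np.sum(np.log(np.diag(Lc)))
    beta = np.linalg.solve(Lc.T, np.linalg.solve(Lc, ViX.T @ y))
    Viy = np.linalg.solve(Lv.T, half[:, p:]).ravel()
    r = Viy - ViX @ beta
    yPy = float(y @ r)
    nll = 0.5 * ((N - p) * _LOG2PI + logdetV + logdetC + yPy)
    if aux is not None:
        aux.update(beta=beta, r=r, XtViX=XtViX, C=C, G=G, sl=sl, Pi=Pi)
    if not want_grad:
        return nll, None
    Vinv = np.linalg.inv(V)
    W = np.linalg.solve(Lc, ViX.T)
    P = Vinv - W.T @ W
    P4 = P.reshape(M, I, M, I)
    R = r.reshape(M, I)
    if mm.gamma is None:
        S = np.einsum("aibi->ab", P4)
        Kq = R @ R.T
    else:
        S = np.einsum("aibj,ij->ab", P4, Gam)
        Kq = R @ Gam @ R.T
    D = 0.5 * (S - Kq)
    trPJ = float(np.einsum("aiaj->", P4))
    ysJ = float(np.sum(R.sum(axis=1) ** 2))
    d_sl = 0.5 * sl * (trPJ - ysJ)
    d_scale = 0.0
    if par.free_scale:
        d_scale = 0.5 * scale * (float(np.diag(P) @ mm.omega)
                                 - float((r * r) @ mm.omega))
    grad = par.grad_from_blocks(theta, mm.T, D, d_sl, d_scale)
    return nll, grad


def _factorized_nll(mm: ModelMatrices, par: _Parameterization, theta,
                    want_grad: bool, aux: Optional[dict] = None):
    """Fast path: Gamma = I and per-location-constant residual weights."""
    I, M = mm.n_genotypes, mm.n_locations
    N = I * M
    G, sl, Pi, _, _, _ = par.unpack(theta)
    scale = par.res_scale(theta)
    C = mm.T @ G @ mm.T.T + Pi
    d = scale * mm.omega.reshape(M, I)[:, 0]
    Y = mm.y.reshape(M, I)
    rowsum = Y.sum(axis=1)
    y1 = rowsum / np.sqrt(I)
    G2 = Y @ Y.T - np.outer(rowsum, rowsum) / I  # residual genotype-space blocks
    B0 = C + np.diag(d)
    B1 = B0 + (I * sl) * np.eye(M)
    X1 = np.sqrt(I) * mm.T
    p = X1.shape[1]
    L0 = np.linalg.cholesky(B0)
    L1 = np.linalg.cholesky(B1)
    logdetV = 2.0 * np.sum(np.log(np.diag(L1))) + \
        (I - 1) * 2.0 * np.sum(np.log(np.diag(L0)))
    half = np.linalg.solve(L1, np.hstack([X1, y1[:, None]]))
    ViX = np.linalg.solve(L1.T, half[:, :p])
    XtViX = X1.T @ ViX
    Lc = np.linalg.cholesky(XtViX)
    logdetC = 2.0 * np.sum(np.log(np.diag(Lc)))
    beta = np.linalg.solve(Lc.T, np.linalg.solve(Lc, ViX.T @ y1))
    Viy1 = np.linalg.solve(L1.T, half[:, p:]).ravel()
    r1 = Viy1 - ViX @ beta
    B0inv = np.linalg.inv(B0)
    yPy = float(y1 @ r1) + float(np.sum(B0inv * G2))
    nll = 0.5 * ((N - p) * _LOG2PI + logdetV + logdetC + yPy)
    if aux is not None:
        aux.update(beta=beta, XtViX=XtViX, C=C, G=G, sl=sl, Pi=Pi)
    if not want_grad:
        return nll, None
    B1inv = np.linalg.inv(B1)
    W = np.linalg.solve(Lc, ViX.T)
    P1 = B1inv - W.T @ W
    S = P1 + (I - 1) * B0inv
    Krest = B0inv @ G2 @ B0inv
    Kq = np.outer(r1, r1) + Krest
    D = 0.5 * (S - Kq)
    d_sl = 0.5 * (I * sl) * (float(np.trace(P1)) - float(r1 @ r1))
    d_scale = 0.0
    if par.free_scale:
        # diag(d) appears in every genotype-space block
        tr_part = float(np.diag(P1) @ d) + (I - 1) * float(np.diag(B0inv) @ d)
        ys_part = float((r1 * r1) @ d) + float(np.diag(Krest) @ d)
        d_scale = 0.5 * (tr_part - ys_part)
    grad = par.grad_from_blocks(theta, mm.T, D, d_sl, d_scale)
    return nll, grad


def _nll(mm, par, theta, want_grad=True, aux=None):
    if mm.gamma is None and mm.homogeneous_weights:
        return _factorized_nll(mm, par, theta, want_grad, aux)
    return _dense_nll(mm, par, theta, want_grad, aux)


def reml_loglik(mm: ModelMatrices, params: VarianceParams) -> float:
    """REML log-likelihood at fixed variance parameters.

    Evaluates directly from the given parameters (no identification
    constraint is imposed, so e.g. rotated factor loadings are honored).
    """
    I, M = mm.n_genotypes, mm.n_locations
    N = I * M
    C = mm.T @ params.g_matrix @ mm.T.T + params.pi_matrix(M)
    Gam = mm.gamma if mm.gamma is not None else np.eye(I)
    V = np.kron(C, Gam)
    V[np.arange(N), np.arange(N)] += params.residual_scale * mm.omega
    V += params.sigma2_l * np.kron(np.eye(M), np.ones((I, I)))
    X, y = mm.X, mm.y
    p = X.shape[1]
    Lv = np.linalg.cholesky(V)
    logdetV = 2.0 * np.sum(np.log(np.diag(Lv)))
    half = np.linalg.solve(Lv, np.hstack([X, y[:, None]]))
    ViX = np.linalg.solve(Lv.T, half[:, :p])
    XtViX = X.T @ ViX
    Lc = np.linalg.cholesky(XtViX)
    logdetC = 2.0 * np.sum(np.log(np.diag(Lc)))
    beta = np.linalg.solve(Lc.T, np.linalg.solve(Lc, ViX.T @ y))
    Viy = np.linalg.solve(Lv.T, half[:, p:]).ravel()
    yPy = float(y @ (Viy - ViX @ beta))
    return -0.5 * ((N - p) * _LOG2PI + logdetV + logdetC + yPy)


# ---------------------------------------------------------------------------
# BLUPs

def blups(mm: ModelMatrices, params: VarianceParams
          ) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fixed-effect GLS estimates and BLUPs at the given variance parameters.

    Returns (mu_hat, beta_hat, a_hat, b_hat (I x q), l_hat, s_hat (M x I)).
    Uses the closed form u_hat = Cov(u, y) V^{-1} (y - X beta_hat).
    """
    I, M = mm.n_genotypes, mm.n_locations
    N = I * M
    G = params.g_matrix
    sl = params.sigma2_l
    Pi = params.pi_matrix(M)
    Gam = mm.gamma if mm.gamma is not None else np.eye(I)
    C = mm.T @ G @ mm.T.T + Pi
    V = np.kron(C, Gam)
    V[np.arange(N), np.arange(N)] += params.residual_scale * mm.omega
    V += sl * np.kron(np.eye(M), np.ones((I, I)))
    X, y = mm.X, mm.y
    Lv = np.linalg.cholesky(V)
    half = np.linalg.solve(Lv, np.hstack([X, y[:, None]]))
    ViX = np.linalg.solve(Lv.T, half[:, : X.shape[1]])
    XtViX = X.T @ ViX
    beta_full = np.linalg.solve(XtViX, ViX.T @ y)
    resid = y - X @ beta_full
    rt = np.linalg.solve(Lv.T, np.linalg.solve(Lv, resid))
    R = rt.reshape(M, I)
    H = mm.T.T @ R                      # (1+q, I)
    Chat = G @ H @ Gam                  # coefficient BLUPs, component-major
    a_hat = Chat[0]
    b_hat = Chat[1:].T if Chat.shape[0] > 1 else np.zeros((I, 0))
    l_hat = sl * R.sum(axis=1)
    s_hat = Pi @ R @ Gam                # (M, I)
    mu_hat = float(beta_full[0])
    beta_hat = np.asarray(beta_full[1:], dtype=float)
    return mu_hat, beta_hat, a_hat, b_hat, l_hat, s_hat


# ---------------------------------------------------------------------------
# fitting

def _starting_params(mm: ModelMatrices) -> VarianceParams:
    I, M = mm.n_genotypes, mm.n_locations
    Y = mm.y.reshape(M, I)
    vy = float(np.var(mm.y)) or 1.0
    third = vy / 3.0
    q = mm.n_sc
    G = np.zeros((1 + q, 1 + q))
    G[0, 0] = third
    for k in range(q):
        vt = float(np.var(mm.T[:, 1 + k])) or 1.0
        G[1 + k, 1 + k] = 0.1 * vy / vt
    spec = mm.spec
    if spec.pi_structure == "identity":
        return VarianceParams(g_matrix=G, sigma2_l=third, sigma2_s=third)
    loc_var = np.maximum(Y.var(axis=1), 0.05 * vy)
    if spec.pi_structure == "diagonal":
        return VarianceParams(g_matrix=G, sigma2_l=third, phi=loc_var)
    K = spec.fa_order
    Cov = np.cov(Y)  # among-location covariance over genotypes
    w, U = np.linalg.eigh(Cov)
    lam = np.zeros((M, K))
    for k in range(K):
        lam[:, k] = np.sqrt(max(w[-1 - k], 0.01 * vy)) * U[:, -1 - k]
        if lam[k, k] < 0:
            lam[:, k] *= -1.0
    for m in range(M):
        lam[m, m + 1:] = 0.0  # identification: zero upper triangle
    phi = np.maximum(np.diag(Cov) - np.sum(lam**2, axis=1), 0.05 * vy)
    return VarianceParams(g_matrix=G, sigma2_l=third, phi=phi, loadings=lam)


def reml_fit(mm: ModelMatrices, controls: Optional[FitControls] = None,
             start: Optional[VarianceParams] = None,
             free_residual_scale: bool = False) -> FitResult:
    """Maximize the REML log-likelihood and return estimates and BLUPs.

    The residual covariance is held fixed at Omega^(d) throughout; only the
    genotype/location/interaction variance parameters are free.
    ``free_residual_scale=True`` adds one multiplicative parameter on
    Omega^(d) as a diagnostic for the fixed-weight convention. Raises
    :class:`ConvergenceError` when the optimizer stops without success and
    the gradient is clearly nonzero; boundary (Heywood) specific variances
    are floored and flagged in ``messages``.
    """
    controls = controls or FitControls(max_iter=2000)
    I, M = mm.n_genotypes, mm.n_locations
    par = _Parameterization(mm, float(np.var(mm.y)) or 1.0,
                            free_residual_scale=free_residual_scale)
    if I * M <= par.n_params:
        raise ValueError(f"ill-posed model: {I * M} observations for "
                         f"{par.n_params} variance parameters")
    theta0 = par.from_params(start if start is not None else _starting_params(mm))
    theta0 = np.clip(theta0, [b[0] for b in par.bounds], [b[1] for b in par.bounds])
    cache: dict[bytes, float] = {}
    trace: list[float] = []

    def fun(theta):
        nll, grad = _nll(mm, par, theta, want_grad=True)
        if len(cache) > 8:
            cache.clear()
        cache[theta.tobytes()] = nll
        return nll, grad

    def cb(xk):
        key = xk.tobytes()
        if key in cache:
            trace.append(cache[key])
        else:
            trace.append(_nll(mm, par, xk, want_grad=False)[0])

    res = optimize.minimize(
        fun, theta0, jac=True, method="L-BFGS-B", bounds=par.bounds,
        callback=cb,
        options={"maxiter": controls.max_iter, "ftol": controls.ftol,
                 "gtol": controls.gtol},
    )
    if not res.success and np.linalg.norm(res.jac, np.inf) > 1e-2:
        raise ConvergenceError(f"Stage II REML did not converge: {res.message}",
                               [-t for t in trace])
    params = par.to_params(res.x)
    messages = []
    if params.phi is not None:
        hey = np.flatnonzero(params.phi <= par.heywood_floor * (1 + 1e-9))
        for m in hey:
            messages.append(f"Heywood case: specific variance of location "
                            f"{mm.locations[m]!r} at floor")
    mu_hat, beta_hat, a_hat, b_hat, l_hat, s_hat = blups(mm, params)
    loglik = -float(res.fun)
    aic = -2.0 * loglik + 2.0 * par.n_params
    return FitResult(
        spec=mm.spec, genotypes=list(mm.genotypes), locations=list(mm.locations),
        params=params, mu_hat=mu_hat, beta_hat=beta_hat,
        blup_a=a_hat, blup_b=b_hat, blup_l=l_hat, blup_s=s_hat,
        sc=mm.sc, reml_loglik=loglik, aic=aic, n_vparams=par.n_params,
        converged=bool(res.success), n_iter=int(res.nit),
        trace=[-t for t in trace], messages=messages,
    )


def fit_fa_order_path(stacked: StackedMeans, spec: ModelSpec,
                      A: Optional[AMatrix] = None,
                      sc: Optional[np.ndarray | pd.DataFrame | dict] = None,
                      orders: Sequence[int] = (1, 2, 3),
                      controls: Optional[FitControls] = None,
                      return_all: bool = False):
    """Fit FA(K) for each order and return the AIC-minimal fit.

    Fits are warm-started: the loadings of order K seed order K+1 (new column
    initialized near zero). Ties in AIC break toward the smaller order. If
    every order fails, the convergence errors are aggregated. With
    ``return_all=True`` the list of per-order fits is returned instead.
    """
    if spec.pi_structure != "fa":
        raise ValueError("fit_fa_order_path requires an fa spec")
    results: list[FitResult] = []
    errors: list[str] = []
    prev: Optional[FitResult] = None
    for K in sorted(orders):
        spec_k = ModelSpec(gamma=spec.gamma, pi_structure="fa", fa_order=K,
                           n_sc=spec.n_sc, prediction_mode=spec.prediction_mode)
        mm = build_model(stacked, spec_k, A=A, sc=sc)
        start = None
        if prev is not None:
            lam_prev = prev.params.loadings
            M = mm.n_locations
            lam = np.zeros((M, K))
            kprev = lam_prev.shape[1]
            lam[:, :kprev] = lam_prev
            for k in range(kprev, K):
                lam[k:, k] = 0.01 * np.sqrt(float(np.var(mm.y)) or 1.0)
            for m in range(M):
                lam[m, m + 1:] = 0.0
            start = VarianceParams(g_matrix=prev.params.g_matrix.copy(),
                                   sigma2_l=prev.params.sigma2_l,
                                   phi=prev.params.phi.copy(), loadings=lam)
        try:
            fit = reml_fit(mm, controls=controls, start=start)
        except (ConvergenceError, np.linalg.LinAlgError, ValueError) as e:
            errors.append(f"FA({K}): {e}")
            continue
        results.append(fit)
        prev = fit
    if not results:
        raise ConvergenceError("all FA orders failed: " + "; ".join(errors), [])
    if return_all:
        return results
    best = min(results, key=lambda f: (round(f.aic, 10), f.spec.fa_order))
    return best


def fit_model(stacked: StackedMeans, model_id: str,
              A: Optional[AMatrix] = None,
              sc: Optional[np.ndarray | pd.DataFrame | dict] = None,
              n_sc: int = 1, fa_order: Optional[int] = None,
              prediction_mode: str = "main_effect",
              controls: Optional[FitControls] = None) -> FitResult:
    """Fit one catalogue model (M1-M12) on stacked means.

    For factor-analytic models, ``fa_order=None`` runs the AIC order path
    over FA(1)-FA(3); an explicit order fits only that order.
    """
    spec = ModelSpec.from_id(model_id, n_sc=n_sc,
                             fa_order=fa_order if fa_order else 1,
                             prediction_mode=prediction_mode)
    if spec.pi_structure == "fa" and fa_order is None:
        return fit_fa_order_path(stacked, spec, A=A, sc=sc, controls=controls)
    mm = build_model(stacked, spec, A=A, sc=sc)
    return reml_fit(mm, controls=controls)
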
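"""Stage I: per-location row-column analysis of plot data.

Each location's trial is analyzed with the linear mixed model

    y = mu + genotype_i + rep_j + row_{jk} + col_{jl} + error

with genotype fixed (cell-means parameterization, one mean per genotype)
and replicate, row-within-replicate and column-within-replicate random.
Variance components are estimated by REML; the adjusted genotype means are
the generalized-least-squares estimates at the REML variances, and their
variance-covariance matrix Omega is read from the inverse of the
generalized-least-squares coefficient matrix.

For the stage-wise analysis, the inverse of Omega is approximated by the
diagonal of its full inverse; those diagonal elements are forwarded to
Stage II as per-genotype weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .datatypes import MeanSet, Stage1Fit, Stage1VarComps, TrialDataset
from .io import KG_PER_TONNE

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class FitControls:
    """Convergence controls for the REML optimizers."""

    max_iter: int = 200
    gtol: float = 1e-6
    ftol: float = 1e-12
    #: variances below boundary_frac * var(y) are flagged as boundary estimates
    boundary_frac: float = 1e-6


class ConvergenceError(RuntimeError):
    """REML failed to converge; carries the accepted-objective trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


def _incidence(codes: np.ndarray, n_levels: int) -> np.ndarray:
    Z = np.zeros((codes.size, n_levels))
    Z[np.arange(codes.size), codes] = 1.0
    return Z


def _reml_neg_loglik_and_grad(theta, y, X, BB, r_proj):
    """Negative REML log-likelihood and gradient w.r.t. log-variances.

    BB holds the relationship matrices Z_k Z_k' of each variance component
    (the last one the identity for the residual). Returns (nll, grad) and,
    via r_proj, exposes intermediate solves for reuse.
    """
    n, p = X.shape
    sig = np.exp(theta)
    V = sig[-1] * np.eye(n)
    for s, B in zip(sig[:-1], BB[:-1]):
        V += s * B
    L = np.linalg.cholesky(V)
    logdetV = 2.0 * np.sum(np.log(np.diag(L)))
    Xi = np.linalg.solve(L, np.hstack([X, y[:, None]]))  # L^{-1}[X y]
    ViX = np.linalg.solve(L.T, Xi[:, :p])
    Viy = np.linalg.solve(L.T, Xi[:, p:]).ravel()
    XtViX = X.T @ ViX
    Lc = np.linalg.cholesky(XtViX)
    logdetC = 2.0 * np.sum(np.log(np.diag(Lc)))
    beta = np.linalg.solve(Lc.T, np.linalg.solve(Lc, ViX.T @ y))
    r = Viy - ViX @ beta  # P y
    yPy = float(y @ r)
    nll = 0.5 * ((n - p) * _LOG2PI + logdetV + logdetC + yPy)
    # P = V^{-1} - ViX (X'V^{-1}X)^{-1} ViX'
    Vinv = np.linalg.inv(V)
    W = np.linalg.solve(Lc, ViX.T)  # so P = Vinv - W'W
    P = Vinv - W.T @ W
    grad = np.empty_like(theta)
    for k, B in enumerate(BB):
        trPB = float(np.sum(P * B))
        rBr = float(r @ B @ r)
        grad[k] = 0.5 * sig[k] * (trPB - rBr)
    if r_proj is not None:
        r_proj["V"] = V
        r_proj["beta"] = beta
        r_proj["XtViX"] = XtViX
    return nll, grad


def fit_rowcol_model(trial: TrialDataset,
                     controls: FitControls | None = None) -> Stage1Fit:
    """Fit the row-column model for one location by REML.

    Rows with missing yield are dropped; genotypes never observed at the
    location are excluded from the returned means. Variance estimates pinned
    near zero are flagged (not fatal); failure to converge raises
    :class:`ConvergenceError` with the objective trace.
    """
    controls = controls or FitControls()
    df = trial.data.dropna(subset=["yield_value"]).reset_index(drop=True)
    if len(df) == 0:
        raise ValueError(f"location {trial.location!r}: no non-missing plots")
    genotypes = sorted(df["genotype"].unique())
    g_idx = pd.Categorical(df["genotype"], categories=genotypes).codes
    rep = pd.Categorical(df["replicate"]).codes
    row = pd.Categorical(list(zip(df["replicate"], df["row"]))).codes
    col = pd.Categorical(list(zip(df["replicate"], df["column"]))).codes
    y = df["yield_value"].to_numpy(dtype=float)
    n, I = len(df), len(genotypes)
    if n <= I:
        raise ValueError(f"location {trial.location!r}: fewer plots than genotypes")
    X = _incidence(np.asarray(g_idx), I)
    BB = []
    for codes in (rep, row, col):
        Z = _incidence(np.asarray(codes), int(codes.max()) + 1)
        BB.append(Z @ Z.T)
    BB.append(np.eye(n))

    vary = float(np.var(y)) or 1.0
    theta0 = np.log(np.array([0.05, 0.05, 0.05, 0.5]) * vary)
    lb, ub = np.log(vary) - 27.0, np.log(vary) + 6.0
    trace: list[float] = []

    aux: dict = {}
    cache: dict[bytes, float] = {}

    def fun(theta):
        nll, grad = _reml_neg_loglik_and_grad(theta, y, X, BB, None)
        if len(cache) > 8:
            cache.clear()
        cache[theta.tobytes()] = float(nll)
        return nll, grad

    def cb(xk):
        v = cache.get(xk.tobytes())
        if v is None:
            v = float(_reml_neg_loglik_and_grad(xk, y, X, BB, None)[0])
        trace.append(v)

    res = optimize.minimize(
        fun, theta0, jac=True, method="L-BFGS-B",
        bounds=[(lb, ub)] * 4,
        callback=cb,
        options={"maxiter": controls.max_iter, "ftol": controls.ftol,
                 "gtol": controls.gtol},
    )
    if not res.success and np.linalg.norm(res.jac, np.inf) > 1e-2:
        raise ConvergenceError(
            f"Stage I REML did not converge for location {trial.location!r}: "
            f"{res.message}", trace)
    nll, _ = _reml_neg_loglik_and_grad(res.x, y, X, BB, aux)
    sig = np.exp(res.x)
    flags = []
    for name, v in zip(("sigma2_h", "sigma2_r", "sigma2_c", "sigma2_e"), sig):
        if v < controls.boundary_frac * vary:
            flags.append(f"{name} at boundary (~0)")
    omega = np.linalg.inv(aux["XtViX"])
    means = np.asarray(aux["beta"], dtype=float)
    return Stage1Fit(
        location=trial.location,
        genotypes=genotypes,
        mu_hat=float(np.mean(means)),
        genotype_means=means,
        varcomps=Stage1VarComps(*[float(v) for v in sig]),
        omega=omega,
        loglik=-float(nll),
        converged=bool(res.success),
        n_iter=int(res.nit),
        unit=trial.unit,
        boundary_flags=flags,
        trace=[-t for t in trace],
    )


def stage2_weights(fit: Stage1Fit) -> MeanSet:
    """Turn a Stage I fit into the Stage II input for its location.

    Weights are the diagonal elements of the full inverse of Omega (not the
    reciprocal diagonal of Omega). Means are converted to t/ha at this
    boundary; weights are rescaled accordingly (variances in t^2/ha^2).
    """
    try:
        omega_inv = np.linalg.inv(fit.omega)
    except np.linalg.LinAlgError:
        raise ValueError(
            f"Omega for location {fit.location!r} is singular; drop aliased "
            "genotype means or add a ridge before weighting") from None
    weights = np.diag(omega_inv).copy()
    if np.any(weights <= 0):
        raise ValueError(f"non-positive weight for location {fit.location!r}")
    means = fit.genotype_means
    if fit.unit == "kg/ha":
        means = means / KG_PER_TONNE
        weights = weights * KG_PER_TONNE**2
    elif fit.unit != "t/ha":
        raise ValueError(f"unknown yield unit {fit.unit!r}")
    return MeanSet(location=fit.location, genotypes=list(fit.genotypes),
                   means=means, weights=weights)


def fit_stage1(trials, controls: FitControls | None = None
               ) -> tuple[list[Stage1Fit], list[MeanSet]]:
    """Run Stage I over all locations; returns fits and t/ha mean sets."""
    fits = [fit_rowcol_model(t, controls) for t in trials]
    return fits, [stage2_weights(f) for f in fits]
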
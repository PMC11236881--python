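"""Synthetic environmental covariates via multivariate partial least squares.

A large panel of environmental covariates (ECs: soil properties by layer,
temperature, rainfall) is reduced to a handful of synthetic covariates (SCs)
that best predict the genotype-by-location mean responses. The ECs are
standardized to zero mean and unit variance over the training locations, and
a multivariate PLS regression is fitted with the standardized EC matrix as
predictors and the locations-by-genotypes mean matrix as the multivariate
response (each genotype's response is a separate variate). The X-scores of
the fitted components are the SC values of the training locations; a new
location's SCs are obtained by standardizing its EC vector with the training
statistics and projecting it through the fitted weight/deflation sequence.

The orthogonal-scores (NIPALS) algorithm is used, as implemented in
scikit-learn's ``PLSRegression`` (the same family as R's ``pls::mvr``),
run to a tight inner tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .datatypes import ECTable, MeanSet


@dataclass
class StandardizedECs:
    """ECs standardized with statistics from a reference location set."""

    base: ECTable
    reference_locations: list[str]
    column_means: np.ndarray
    column_sds: np.ndarray
    z: np.ndarray  # (M, P) standardized values for *all* locations

    @property
    def covariate_names(self) -> list[str]:
        return self.base.covariate_names

    def row(self, location: str) -> np.ndarray:
        m = self.base.locations.index(location)
        return self.z[m]

    def reference_matrix(self) -> np.ndarray:
        idx = [self.base.locations.index(l) for l in self.reference_locations]
        return self.z[idx]


@dataclass
class PLSModel:
    """Fitted multivariate PLS model and derived SC quantities."""

    n_components: int
    locations: list[str]           # training locations, fit order
    covariate_names: list[str]
    genotypes: list[str]
    x_weights: np.ndarray          # (P, K)
    x_scores: np.ndarray           # (M, K) -- the SC values per location
    x_loadings: np.ndarray         # (P, K)
    y_loadings: np.ndarray         # (I, K)
    x_rotations: np.ndarray        # (P, K) weights mapped through deflation
    coefficients: np.ndarray       # (P, I) regression coefficients
    x_variance_explained: np.ndarray  # (K,) percent of standardized-X SS
    y_variance_explained: np.ndarray  # (K,) percent of centered-Y SS
    x_mean: np.ndarray             # (P,) centering applied to z by the fit

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"SC{k + 1}" for k in range(self.n_components)]
        return pd.DataFrame(self.x_scores, index=self.locations, columns=cols)


def standardize(ec: ECTable,
                reference_locations: Optional[Sequence[str]] = None) -> StandardizedECs:
    """Standardize EC columns to mean 0, unit variance over the reference set.

    Statistics are computed on ``reference_locations`` only (default: all
    locations); z-values are produced for every location in the table, so a
    held-out location is standardized with training statistics and never
    influences them. Sample (n-1) standard deviations are used.
    """
    ref = list(reference_locations) if reference_locations is not None else list(ec.locations)
    if len(ref) < 2:
        raise ValueError("need at least 2 reference locations to standardize")
    refmat = ec.subset(ref).values
    mu = refmat.mean(axis=0)
    sd = refmat.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [ec.covariate_names[j] for j in zero[:10]]
        raise ValueError(f"zero variance over reference locations for EC(s): {names}")
    z = (ec.values - mu) / sd
    return StandardizedECs(base=ec, reference_locations=ref,
                           column_means=mu, column_sds=sd, z=z)


def fit_pls(z: StandardizedECs, y_matrix: np.ndarray, n_components: int,
            genotypes: Optional[Sequence[str]] = None) -> PLSModel:
    """Fit multivariate PLS of genotype means on standardized ECs.

    ``y_matrix`` is (M_ref, I): one row per reference location (in
    ``z.reference_locations`` order), one column per genotype. Y columns are
    centered on the training locations; no Y scaling (all responses share
    units). The X-scores are the synthetic covariates.
    """
    X = z.reference_matrix()
    Y = np.asarray(y_matrix, dtype=float)
    M, P = X.shape
    if Y.shape[0] != M:
        raise ValueError(f"y_matrix has {Y.shape[0]} rows, expected {M}")
    kmax = min(M - 1, P)
    if not 1 <= n_components <= kmax:
        raise ValueError(f"n_components must be in [1, {kmax}], got {n_components}")
    # sklearn's tol is on the squared inner-iteration weight change
    reg = PLSRegression(n_components=n_components, scale=False,
                        tol=1e-22, max_iter=50_000)
    reg.fit(X, Y)
    T = reg.x_scores_
    Pl = reg.x_loadings_
    Q = reg.y_loadings_
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    ssx, ssy = np.sum(Xc**2), np.sum(Yc**2)
    t2 = np.sum(T**2, axis=0)
    xve = 100.0 * t2 * np.sum(Pl**2, axis=0) / ssx
    yve = 100.0 * t2 * np.sum(Q**2, axis=0) / (ssy if ssy > 0 else np.inf)
    coef = np.asarray(reg.coef_)
    if coef.shape == (Y.shape[1], P):  # sklearn >=1.1 returns (n_targets, P)
        coef = coef.T
    return PLSModel(
        n_components=n_components,
        locations=list(z.reference_locations),
        covariate_names=list(z.covariate_names),
        genotypes=list(genotypes) if genotypes is not None else
                  [f"g{i}" for i in range(Y.shape[1])],
        x_weights=reg.x_weights_,
        x_scores=T,
        x_loadings=Pl,
        y_loadings=Q,
        x_rotations=reg.x_rotations_,
        coefficients=coef,
        x_variance_explained=xve,
        y_variance_explained=yve,
        x_mean=np.asarray(reg._x_mean),
    )


def project_location(model: PLSModel, z_row: np.ndarray) -> np.ndarray:
    """SC scores of a new location from its standardized EC vector.

    Equivalent to running the fitted deflation sequence on the new row:
    scores = (z - x_mean) @ W (P'W)^{-1}.
    """
    z_row = np.asarray(z_row, dtype=float).ravel()
    if z_row.size != len(model.covariate_names):
        raise ValueError(f"expected {len(model.covariate_names)} covariates, "
                         f"got {z_row.size}")
    return (z_row - model.x_mean) @ model.x_rotations


def coefficient_ranking(model: PLSModel, top_n: int = 15) -> pd.DataFrame:
    """Rank ECs by the magnitude of their first-component contribution.

    The (P x I) coefficient matrix is reduced to a single coefficient per EC
    as the first-component weight times the sum of first-component response
    loadings (one linear combination of ECs characterizes each location, so
    one coefficient per EC summarizes its pull on the first SC). Returns the
    ``top_n`` rows sorted by absolute coefficient, ranks starting at 1.
    """
    coef = model.x_weights[:, 0] * float(np.sum(model.y_loadings[:, 0]))
    order = np.argsort(-np.abs(coef), kind="stable")
    top = order[: min(top_n, coef.size)]
    return pd.DataFrame({
        "rank": np.arange(1, top.size + 1),
        "covariate": [model.covariate_names[j] for j in top],
        "coefficient": coef[top],
    })


def extract_sc(mean_sets: Sequence[MeanSet], ec: ECTable, n_components: int,
               reference_locations: Optional[Sequence[str]] = None
               ) -> tuple[PLSModel, StandardizedECs]:
    """Convenience wrapper: standardize ECs and fit PLS on location means.

    The Y matrix rows follow the reference locations; its columns the sorted
    common genotype set of the mean sets.
    """
    from .datatypes import stack_means

    stacked = stack_means(mean_sets, intersect=True)
    ref = list(reference_locations) if reference_locations is not None \
        else list(stacked.locations)
    missing = [l for l in ref if l not in ec.locations]
    if missing:
        raise ValueError(f"locations missing from EC table: {missing}")
    z = standardize(ec, ref)
    by_loc = {m.location: m.means for m in stacked.mean_sets}
    Y = np.vstack([by_loc[l] for l in ref])
    model = fit_pls(z, Y, n_components, genotypes=stacked.genotypes)
    return model, z
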
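"""Core data containers for two-stage multi-environment-trial analysis.

The pipeline moves through a fixed sequence of containers:

``TrialDataset`` (plot-level yields of one location)
    -> ``Stage1Fit`` (adjusted genotype means and their precision)
    -> ``MeanSet`` / ``StackedMeans`` (Stage II input: means + diagonal weights)
    -> ``FitResult`` (REML estimates and BLUPs of one Stage II model)
    -> ``CVResult`` (leave-one-location-out scores).

All genotype-indexed arrays use a single canonical ordering: lexicographic
over genotype identifiers. Locations are likewise sorted lexicographically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: sentinel used for unknown parents in pedigrees
UNKNOWN_PARENT = None

#: tokens in CSV input that denote an unknown parent
_MISSING_TOKENS = {"", "na", "nan", "none", "null", "0", "unknown", "?", "-"}


@dataclass
class TrialDataset:
    """Plot-level records of a single location's resolvable row-column trial.

    Parameters
    ----------
    location:
        Trial/location identifier.
    data:
        One row per plot with columns ``genotype, replicate, row, column,
        yield_value``. ``yield_value`` may contain NaN for missing plots.
    layout:
        ``(rows_per_replicate, cols_per_replicate, n_replicates)``.
    unit:
        Unit of ``yield_value`` (``"kg/ha"`` or ``"t/ha"``).
    """

    location: str
    data: pd.DataFrame
    layout: tuple[int, int, int]
    unit: str = "kg/ha"

    def __post_init__(self) -> None:
        required = {"genotype", "replicate", "row", "column", "yield_value"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"TrialDataset missing columns: {sorted(missing)}")
        cells = self.data[["replicate", "row", "column"]]
        dup = cells.duplicated()
        if dup.any():
            bad = cells[dup].iloc[0]
            raise ValueError(
                f"duplicate field cell in location {self.location!r}: "
                f"replicate={bad['replicate']}, row={bad['row']}, column={bad['column']}"
            )
        if (cells <= 0).any().any():
            raise ValueError("replicate/row/column indices must be positive")

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.data["genotype"].unique())


@dataclass
class PedigreeTable:
    """Pedigree records: one entry per genotype with up to two parents.

    ``entries`` is a DataFrame with columns ``genotype, parent1, parent2``;
    unknown parents are ``None``. Selfing is encoded as parent1 == parent2.
    """

    entries: pd.DataFrame
    no_pedigree: list[str] = field(default_factory=list)

    @property
    def genotypes(self) -> list[str]:
        return list(self.entries["genotype"])


@dataclass
class ECTable:
    """Environmental covariates: locations x covariates matrix."""

    locations: list[str]
    covariate_names: list[str]
    values: np.ndarray  # (M, P)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.locations), len(self.covariate_names)):
            raise ValueError("EC value matrix shape does not match labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("EC table contains missing/non-finite cells")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.locations, columns=self.covariate_names)

    def row(self, location: str) -> np.ndarray:
        try:
            m = self.locations.index(location)
        except ValueError:
            raise KeyError(f"location {location!r} not in EC table") from None
        return self.values[m]

    def subset(self, locations: Sequence[str]) -> "ECTable":
        rows = [self.row(loc) for loc in locations]
        return ECTable(list(locations), list(self.covariate_names), np.array(rows))


@dataclass
class MeanSet:
    """Adjusted genotype means of one location with Stage II weights.

    ``weights`` are the diagonal elements of the inverse of the Stage I
    variance-covariance matrix of the means (the diagonal approximation of
    the stage-wise weighting scheme); the Stage II residual variance for
    genotype i at this location is 1/weights[i].
    """

    location: str
    genotypes: list[str]
    means: np.ndarray  # t/ha
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if not (len(self.genotypes) == self.means.size == self.weights.size):
            raise ValueError("MeanSet fields have inconsistent lengths")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be strictly positive")
        order = np.argsort(np.asarray(self.genotypes, dtype=object))
        if not np.all(order == np.arange(len(self.genotypes))):
            self.genotypes = [self.genotypes[k] for k in order]
            self.means = self.means[order]
            self.weights = self.weights[order]

    def subset(self, genotypes: Sequence[str]) -> "MeanSet":
        idx = {g: k for k, g in enumerate(self.genotypes)}
        missing = [g for g in genotypes if g not in idx]
        if missing:
            raise KeyError(f"genotypes not in MeanSet {self.location!r}: {missing[:5]}")
        sel = [idx[g] for g in sorted(genotypes)]
        return MeanSet(self.location, [self.genotypes[k] for k in sel],
                       self.means[sel], self.weights[sel])


@dataclass
class StackedMeans:
    """Concatenated Stage II response: location-major, genotype-within.

    ``omega_d`` holds the diagonal of the fixed residual covariance
    (inverse weights), stored as a vector of length I*M.
    """

    mean_sets: list[MeanSet]
    genotypes: list[str]
    locations: list[str]
    y: np.ndarray
    omega_d: np.ndarray

    @property
    def n_genotypes(self) -> int:
        return len(self.genotypes)

    @property
    def n_locations(self) -> int:
        return len(self.locations)


def stack_means(mean_sets: Sequence[MeanSet], intersect: bool = False) -> StackedMeans:
    """Stack per-location mean sets into the Stage II response vector.

    Locations are sorted lexicographically; within each location genotypes
    follow the single canonical (sorted) order. By default the genotype sets
    must agree across locations; with ``intersect=True`` the common subset
    (sorted) is used instead.
    """
    if len(mean_sets) == 0:
        raise ValueError("no mean sets supplied")
    ms = sorted(mean_sets, key=lambda m: m.location)
    sets = [set(m.genotypes) for m in ms]
    common = set.intersection(*sets)
    union = set.union(*sets)
    if common != union and not intersect:
        raise ValueError(
            "genotype sets differ across locations; pass intersect=True to use "
            f"the common subset ({len(common)} of {len(union)} genotypes)"
        )
    genotypes = sorted(common)
    if not genotypes:
        raise ValueError("no genotype common to all locations")
    ms = [m.subset(genotypes) for m in ms]
    y = np.concatenate([m.means for m in ms])
    omega = np.concatenate([1.0 / m.weights for m in ms])
    return StackedMeans(ms, genotypes, [m.location for m in ms], y, omega)


@dataclass
class AMatrix:
    """Numerator relationship matrix over an ordered genotype list."""

    genotypes: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genotypes)
        if self.values.shape != (n, n):
            raise ValueError("A matrix shape does not match genotype list")

    def submatrix(self, genotypes: Sequence[str]) -> "AMatrix":
        idx = {g: k for k, g in enumerate(self.genotypes)}
        missing = [g for g in genotypes if g not in idx]
        if missing:
            raise KeyError(f"genotypes not in A matrix: {missing[:5]}")
        order = sorted(genotypes)
        sel = np.array([idx[g] for g in order])
        return AMatrix(order, self.values[np.ix_(sel, sel)])


_PI_STRUCTURES = ("identity", "diagonal", "fa")
_GAMMA_STRUCTURES = ("identity", "kinship")

#: Stage II model catalogue: model id -> (genotype covariance, GxL structure,
#: whether the model regresses on synthetic covariates)
MODEL_CATALOGUE: dict[str, tuple[str, str, bool]] = {
    "M1": ("identity", "identity", False),
    "M2": ("kinship", "identity", False),
    "M3": ("identity", "identity", True),
    "M4": ("kinship", "identity", True),
    "M5": ("identity", "diagonal", False),
    "M6": ("kinship", "diagonal", False),
    "M7": ("identity", "diagonal", True),
    "M8": ("kinship", "diagonal", True),
    "M9": ("identity", "fa", False),
    "M10": ("kinship", "fa", False),
    "M11": ("identity", "fa", True),
    "M12": ("kinship", "fa", True),
}


@dataclass
class ModelSpec:
    """Specification of one Stage II model.

    ``gamma`` selects the genotype covariance (identity or pedigree kinship),
    ``pi_structure`` the genotype-by-location covariance (identity, diagonal
    or factor-analytic of order ``fa_order``), ``n_sc`` the number of
    synthetic environmental covariates entering as fixed slopes plus random
    per-genotype slopes.
    """

    gamma: str = "identity"
    pi_structure: str = "identity"
    fa_order: int = 1
    n_sc: int = 0
    prediction_mode: str = "main_effect"

    def __post_init__(self) -> None:
        if self.gamma not in _GAMMA_STRUCTURES:
            raise ValueError(f"unknown gamma structure {self.gamma!r}")
        if self.pi_structure not in _PI_STRUCTURES:
            raise ValueError(f"unknown pi structure {self.pi_structure!r}")
        if self.pi_structure == "fa" and self.fa_order not in (1, 2, 3):
            raise ValueError("fa_order must be 1, 2 or 3")
        if self.n_sc not in (0, 1, 2):
            raise ValueError("n_sc must be 0, 1 or 2")
        if self.prediction_mode not in ("main_effect", "main_plus_avg_interaction"):
            raise ValueError(f"unknown prediction mode {self.prediction_mode!r}")

    @classmethod
    def from_id(cls, model_id: str, n_sc: int = 1, fa_order: int = 1,
                prediction_mode: str = "main_effect") -> "ModelSpec":
        """Build the spec for one of the catalogue models M1-M12."""
        try:
            gamma, pi, uses_sc = MODEL_CATALOGUE[model_id]
        except KeyError:
            raise ValueError(f"unknown model id {model_id!r}") from None
        return cls(gamma=gamma, pi_structure=pi, fa_order=fa_order,
                   n_sc=n_sc if uses_sc else 0, prediction_mode=prediction_mode)

    @property
    def uses_kinship(self) -> bool:
        return self.gamma == "kinship"


@dataclass
class Stage1VarComps:
    """Variance components of the per-location row-column model."""

    sigma2_h: float  # replicate
    sigma2_r: float  # row within replicate
    sigma2_c: float  # column within replicate
    sigma2_e: float  # plot residual

    def as_array(self) -> np.ndarray:
        return np.array([self.sigma2_h, self.sigma2_r, self.sigma2_c, self.sigma2_e])


@dataclass
class Stage1Fit:
    """REML fit of one location's row-column model.

    ``genotype_means`` are the generalized-least-squares estimates of
    mu + a_i (cell-means parameterization); ``omega`` their estimated
    variance-covariance matrix.
    """

    location: str
    genotypes: list[str]
    mu_hat: float
    genotype_means: np.ndarray
    varcomps: Stage1VarComps
    omega: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    unit: str = "kg/ha"
    boundary_flags: list[str] = field(default_factory=list)
    trace: list[float] = field(default_factory=list)

    @property
    def genotype_effects(self) -> np.ndarray:
        return self.genotype_means - self.mu_hat


@dataclass
class VarianceParams:
    """Stage II variance parameters on the natural scale.

    For models without synthetic covariates ``g_matrix`` is the 1x1 matrix
    [sigma2_a]; with q covariates it is the (1+q)x(1+q) unstructured
    covariance of (intercept, slope_1, ..., slope_q) per genotype.
    """

    g_matrix: np.ndarray            # (1+q, 1+q)
    sigma2_l: float
    sigma2_s: float = 0.0           # identity Pi
    phi: Optional[np.ndarray] = None       # (M,) diagonal/fa specific variances
    loadings: Optional[np.ndarray] = None  # (M, K) fa loadings
    #: multiplier on the fixed residual Omega^(d); 1 unless the diagnostic
    #: free-scale option is enabled
    residual_scale: float = 1.0

    @property
    def sigma2_a(self) -> float:
        return float(self.g_matrix[0, 0])

    def pi_matrix(self, n_locations: int) -> np.ndarray:
        """GxL covariance among locations (the M x M structure matrix)."""
        if self.loadings is not None:
            return self.loadings @ self.loadings.T + np.diag(self.phi)
        if self.phi is not None:
            return np.diag(self.phi)
        return self.sigma2_s * np.eye(n_locations)


@dataclass
class FitResult:
    """Stage II REML fit: estimates, BLUPs and fit statistics."""

    spec: ModelSpec
    genotypes: list[str]
    locations: list[str]
    params: VarianceParams
    mu_hat: float
    beta_hat: np.ndarray           # (n_sc,) fixed SC slopes
    blup_a: np.ndarray             # (I,)
    blup_b: np.ndarray             # (I, n_sc)
    blup_l: np.ndarray             # (M,)
    blup_s: np.ndarray             # (M, I) interaction BLUPs, location-major
    sc: Optional[np.ndarray]       # (M, n_sc) covariate values used
    reml_loglik: float
    aic: float
    n_vparams: int
    converged: bool
    n_iter: int
    trace: list[float] = field(default_factory=list)
    messages: list[str] = field(default_factory=list)


@dataclass
class PredictionSet:
    """Predicted genotype values for one (held-out) location."""

    location: str
    genotypes: list[str]
    z: np.ndarray
    mode: str


@dataclass
class CVResult:
    """Leave-one-location-out cross-validation summary for one model."""

    model_id: str
    spec: ModelSpec
    per_location_rho: list[tuple[str, float]]
    msepd: float
    mean_rho: float
    se_rho: float
    predictions: list[PredictionSet]
    failed_folds: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model": self.model_id,
            "n_sc": self.spec.n_sc,
            "prediction_mode": self.spec.prediction_mode,
            "msepd": self.msepd,
            "mean_rho": self.mean_rho,
            "se_rho": self.se_rho,
            "per_location_rho": {loc: rho for loc, rho in self.per_location_rho},
            "failed_folds": list(self.failed_folds),
        }
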
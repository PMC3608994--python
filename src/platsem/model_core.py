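"""Domain types and plumbing shared by every stage of the platform-comparison model.

The model treats the true (logit-scale) relative frequency of a taxon as a
latent variable measured by ``m`` platforms, optionally regressed on ``k``
observed covariates.  All fitting operates on second moments, so the central
type here is :class:`MomentSummary` — a covariance (or correlation) matrix
plus the sample size, the sufficient statistic for maximum-likelihood
estimation of the model.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger("platsem")

SYMMETRY_TOL = 1e-12


class PlatsemError(Exception):
    """Base class for errors raised by this package."""


class DegenerateInputError(PlatsemError):
    """Input data cannot support the requested computation (too few rows,
    zero-variance column, non-finite entries, ...)."""


class IdentificationError(PlatsemError):
    """The requested model is not identified from the supplied moments."""


class NotPositiveDefiniteError(PlatsemError):
    """A matrix that must be positive definite is not."""


class ConvergenceError(PlatsemError):
    """The optimizer failed to converge; carries the best value found."""

    def __init__(self, message: str, best_f: float | None = None,
                 grad_norm: float | None = None):
        super().__init__(message)
        self.best_f = best_f
        self.grad_norm = grad_norm


class ConstraintMode(enum.Enum):
    """Constraint pattern imposed on the measurement model.

    FREE
        One-factor model with only the reference loading fixed at 1; the
        general latent-variable measurement model.
    EQUAL_LOADINGS
        All loadings fixed at 1; equivalent to the multivariate
        repeated-measures ANOVA (per-platform error variances free).
    EQUAL_LOADINGS_EQUAL_ERRORS
        All loadings fixed at 1 and a single common error variance;
        equivalent to the univariate repeated-measures ANOVA, implying a
        compound-symmetric covariance matrix.
    """

    FREE = "free"
    EQUAL_LOADINGS = "equal_loadings"
    EQUAL_LOADINGS_EQUAL_ERRORS = "equal_loadings_equal_errors"


def _as_2d(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise DegenerateInputError(f"expected a 2-D array, got shape {arr.shape}")
    return arr


@dataclass
class PlatformMatrix:
    """Samples × platforms table of logit-scale measurements.

    Parameters
    ----------
    values
        ``n_samples × m_platforms`` real matrix on the logit scale.
    platform_names
        ``m`` unique platform identifiers.
    covariates
        Optional ``n_samples × k`` matrix of covariates (binary phenotype
        indicators or continuous), with ``covariate_names``.
    """

    values: np.ndarray
    platform_names: list[str]
    covariates: Optional[np.ndarray] = None
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = _as_2d(self.values)
        n, m = self.values.shape
        if m < 2:
            raise DegenerateInputError(f"need at least 2 platforms, got {m}")
        if len(self.platform_names) != m:
            raise DegenerateInputError("platform_names length does not match columns")
        if len(set(self.platform_names)) != m:
            raise DegenerateInputError("platform names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise DegenerateInputError("non-finite entries in platform matrix")
        k = 0
        if self.covariates is not None:
            self.covariates = _as_2d(self.covariates)
            if self.covariates.shape[0] != n:
                raise DegenerateInputError("covariate rows do not match sample rows")
            if not np.all(np.isfinite(self.covariates)):
                raise DegenerateInputError("non-finite entries in covariates")
            k = self.covariates.shape[1]
            if len(self.covariate_names) != k:
                raise DegenerateInputError("covariate_names length does not match columns")
        if n < m + k + 2:
            raise DegenerateInputError(
                f"need at least m + k + 2 = {m + k + 2} samples, got {n}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_platforms(self) -> int:
        return self.values.shape[1]

    @property
    def n_covariates(self) -> int:
        return 0 if self.covariates is None else self.covariates.shape[1]

    def all_names(self) -> list[str]:
        return list(self.platform_names) + list(self.covariate_names)

    def stacked(self) -> np.ndarray:
        """Platforms followed by covariates, as one n × (m+k) matrix."""
        if self.covariates is None:
            return self.values
        return np.hstack([self.values, self.covariates])


@dataclass
class MomentSummary:
    """Symmetric moment matrix plus sample size — the sufficient statistic.

    ``S`` covers platforms first, then covariates, in ``names`` order.
    """

    S: np.ndarray
    N: int
    names: list[str]
    is_correlation: bool = False

    def __post_init__(self):
        self.S = _as_2d(self.S)
        p = self.S.shape[0]
        if self.S.shape[1] != p:
            raise DegenerateInputError("moment matrix must be square")
        if len(self.names) != p:
            raise DegenerateInputError("names length does not match matrix")
        asym = np.max(np.abs(self.S - self.S.T)) if p else 0.0
        if asym > max(SYMMETRY_TOL, 1e-8 * np.max(np.abs(self.S))):
            raise DegenerateInputError(f"moment matrix asymmetric (max |S-S'| = {asym:g})")
        self.S = 0.5 * (self.S + self.S.T)
        if np.any(np.diag(self.S) <= 0):
            raise DegenerateInputError("moment matrix diagonal must be positive")
        if self.is_correlation and not np.allclose(np.diag(self.S), 1.0, atol=1e-8):
            raise DegenerateInputError("correlation matrix must have unit diagonal")
        if self.N < p + 2:
            raise DegenerateInputError(f"sample size N={self.N} too small for {p} variables")

    @property
    def n_variables(self) -> int:
        return self.S.shape[0]

    def submatrix(self, names: Sequence[str]) -> "MomentSummary":
        idx = [self.names.index(n) for n in names]
        return MomentSummary(self.S[np.ix_(idx, idx)], self.N, list(names),
                             self.is_correlation)

    def to_correlation(self) -> "MomentSummary":
        d = np.sqrt(np.diag(self.S))
        R = self.S / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
        return MomentSummary(R, self.N, list(self.names), True)


@dataclass
class ModelSpec:
    """Declarative description of the model to fit.

    ``reference`` names the indicator whose loading is fixed at 1 (the scale
    anchor of the latent variable); defaults to the first indicator.
    """

    indicator_names: list[str]
    reference: Optional[str] = None
    constraint_mode: ConstraintMode = ConstraintMode.FREE
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        if isinstance(self.constraint_mode, str):
            self.constraint_mode = ConstraintMode(self.constraint_mode)
        m = len(self.indicator_names)
        if m < 2:
            raise IdentificationError("need at least two indicators")
        if len(set(self.indicator_names)) != m:
            raise DegenerateInputError("indicator names must be unique")
        if self.reference is None:
            self.reference = self.indicator_names[0]
        if self.reference not in self.indicator_names:
            raise DegenerateInputError(
                f"reference indicator {self.reference!r} not among indicators")

    @property
    def m(self) -> int:
        return len(self.indicator_names)

    @property
    def k(self) -> int:
        return len(self.covariate_names)

    @property
    def reference_index(self) -> int:
        return self.indicator_names.index(self.reference)


def n_free_parameters(m: int, k: int, mode: ConstraintMode) -> int:
    """Count of free parameters, including the saturated covariate block."""
    cov_block = k + k * (k + 1) // 2  # gamma plus cov(X)
    if mode is ConstraintMode.FREE:
        return (m - 1) + 1 + m + cov_block
    if mode is ConstraintMode.EQUAL_LOADINGS:
        return 1 + m + cov_block
    return 1 + 1 + cov_block


def degrees_of_freedom(m: int, k: int, mode: ConstraintMode) -> int:
    p = m + k
    return p * (p + 1) // 2 - n_free_parameters(m, k, mode)


@dataclass
class CheckedSpec:
    """A ModelSpec resolved against a MomentSummary: indices, df, counts."""

    spec: ModelSpec
    indicator_idx: list[int]
    covariate_idx: list[int]
    df: int
    n_free_params: int

    @property
    def m(self) -> int:
        return self.spec.m

    @property
    def k(self) -> int:
        return self.spec.k

    @property
    def reference_index(self) -> int:
        return self.spec.reference_index

    @property
    def constraint_mode(self) -> ConstraintMode:
        return self.spec.constraint_mode


def validate_spec(spec: ModelSpec, moments: MomentSummary) -> CheckedSpec:
    """Resolve a model spec against a moment summary.

    Checks identification (FREE mode needs m >= 3 indicators), resolves
    variable names to indices, and computes the model degrees of freedom.
    """
    missing = [n for n in spec.indicator_names + spec.covariate_names
               if n not in moments.names]
    if missing:
        raise DegenerateInputError(f"names not found in moments: {missing}")
    if spec.constraint_mode is ConstraintMode.FREE and spec.m < 3:
        raise IdentificationError(
            "the free one-factor model needs at least 3 indicators for identification")
    df = degrees_of_freedom(spec.m, spec.k, spec.constraint_mode)
    if df < 0:
        raise IdentificationError(f"negative degrees of freedom ({df})")
    if moments.N < spec.m + spec.k + 2:
        raise DegenerateInputError("sample size too small for this model")
    return CheckedSpec(
        spec=spec,
        indicator_idx=[moments.names.index(n) for n in spec.indicator_names],
        covariate_idx=[moments.names.index(n) for n in spec.covariate_names],
        df=df,
        n_free_params=n_free_parameters(spec.m, spec.k, spec.constraint_mode),
    )


def moments_from_data(data: PlatformMatrix) -> MomentSummary:
    """Sample covariance (denominator N−1) of the centered columns.

    Platforms first, covariates after, matching the block layout of the
    model-implied covariance. Rows with missing values must have been removed
    upstream; a zero-variance column is a degenerate input.
    """
    Z = data.stacked()
    n = Z.shape[0]
    Zc = Z - Z.mean(axis=0)
    if np.any(np.isclose(np.einsum("ij,ij->j", Zc, Zc), 0.0)):
        raise DegenerateInputError("constant column: zero variance")
    S = (Zc.T @ Zc) / (n - 1)
    return MomentSummary(S, n, data.all_names(), is_correlation=False)


@dataclass
class ParameterEstimates:
    """Point estimates of the measurement (and optional covariate) model.

    ``loadings`` are on the raw scale with the reference loading fixed at 1;
    ``standardized_loadings`` are on the correlation metric and equal the
    indicator–latent correlations.  Error variances may be negative only on
    the closed-form path (Heywood case, flagged by the caller).
    """

    loadings: np.ndarray
    latent_variance: float
    error_variances: np.ndarray
    covariate_coefficients: np.ndarray = field(default_factory=lambda: np.zeros(0))
    covariate_cov: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    standardized_loadings: Optional[np.ndarray] = None

    def __post_init__(self):
        self.loadings = np.atleast_1d(np.asarray(self.loadings, dtype=float))
        self.error_variances = np.atleast_1d(np.asarray(self.error_variances, dtype=float))
        self.covariate_coefficients = np.atleast_1d(
            np.asarray(self.covariate_coefficients, dtype=float))
        self.covariate_cov = np.asarray(self.covariate_cov, dtype=float).reshape(
            len(self.covariate_coefficients), len(self.covariate_coefficients))
        if self.latent_variance <= 0:
            raise DegenerateInputError("latent variance must be positive")

    @property
    def total_latent_variance(self) -> float:
        """Var(xi) = Gamma' cov(X) Gamma + Var(zeta)."""
        g = self.covariate_coefficients
        if g.size == 0:
            return float(self.latent_variance)
        return float(g @ self.covariate_cov @ g + self.latent_variance)


@dataclass
class FitResult:
    """Everything a fit produces: estimates, discrepancy, fit indices."""

    estimates: ParameterEstimates
    f_ml: float
    chi_square: float
    df: int
    p_value: float
    rmsea: float
    cfi: float
    converged: bool
    n_used: int
    spec: ModelSpec
    heywood: bool = False
    standard_errors: Optional[dict] = None
    implied: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.f_ml < -1e-10:
            raise PlatsemError(f"negative fit function value {self.f_ml}")
        self.f_ml = max(self.f_ml, 0.0)


@dataclass
class ReliabilityReport:
    """Per-platform reliability R² and latent correlation, with optional CIs.

    The identity R² = (latent correlation)² holds by construction; CI
    endpoints, when present, are clamped to [0, 1].
    """

    platform_names: list[str]
    reliability: np.ndarray
    latent_correlation: np.ndarray
    ci_lower: Optional[np.ndarray] = None
    ci_upper: Optional[np.ndarray] = None
    heywood: bool = False

    def __post_init__(self):
        self.reliability = np.atleast_1d(np.asarray(self.reliability, dtype=float))
        self.latent_correlation = np.atleast_1d(
            np.asarray(self.latent_correlation, dtype=float))
        if not np.allclose(self.latent_correlation ** 2, self.reliability, atol=1e-10):
            raise PlatsemError("latent_correlation² must equal reliability")
        for name in ("ci_lower", "ci_upper"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.clip(np.asarray(v, dtype=float), 0.0, 1.0))


@dataclass
class EffectSummary:
    """A covariate's effect on the latent variable, with the implied shift in
    the underlying proportion for that covariate pattern vs. the zero baseline."""

    name: str
    coefficient: float
    p_value: float
    delta_proportion: float

    def __post_init__(self):
        if not (-0.5 < self.delta_proportion < 0.5):
            raise PlatsemError("delta_proportion must lie in (-0.5, 0.5)")


def drop_incomplete_rows(values: np.ndarray,
                         covariates: Optional[np.ndarray] = None):
    """Complete-case deletion, returning filtered arrays and the drop count."""
    mask = np.all(np.isfinite(values), axis=1)
    if covariates is not None:
        mask &= np.all(np.isfinite(covariates), axis=1)
    dropped = int(values.shape[0] - mask.sum())
    if dropped:
        logger.info("dropped %d incomplete rows (complete-case)", dropped)
    return (values[mask],
            None if covariates is None else covariates[mask],
            dropped)
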
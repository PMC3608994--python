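"""Generators producing data with exactly the structure the model assumes.

Each subject carries a latent logit-scale abundance ``xi = Gamma' x + zeta``
(``zeta ~ N(0, sigma_zeta^2)``); platform ``i`` reads it out linearly as
``Y_i = lambda_i xi + eps_i`` with independent errors.  Errors are normal by
default; a scaled-t option produces the heavy-tailed readouts for which
bootstrap (rather than Wald) inference is the appropriate tool.  A binomial
count generator feeds the empirical-logit transform for end-to-end tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model_core import DegenerateInputError, ParameterEstimates, PlatformMatrix
from .estimation import implied_covariance


@dataclass
class SyntheticTruth:
    """True parameter values plus the covariate design used to generate data."""

    loadings: np.ndarray
    latent_variance: float
    error_variances: np.ndarray
    n: int
    gamma: np.ndarray = field(default_factory=lambda: np.zeros(0))
    covariate_design: Optional[np.ndarray] = None   # fixed n x k design
    platform_names: Optional[list[str]] = None
    covariate_names: list[str] = field(default_factory=list)
    error_dist: str = "normal"                      # "normal" or "t"
    t_df: float = 4.0

    def __post_init__(self):
        self.loadings = np.atleast_1d(np.asarray(self.loadings, dtype=float))
        self.error_variances = np.atleast_1d(
            np.asarray(self.error_variances, dtype=float))
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        m = self.loadings.size
        if self.error_variances.size != m:
            raise DegenerateInputError("error_variances length must match loadings")
        if np.any(self.error_variances < 0) or self.latent_variance <= 0:
            raise DegenerateInputError("variances must be nonnegative, latent > 0")
        if self.gamma.size and self.covariate_design is None:
            raise DegenerateInputError("gamma given without a covariate design")
        if self.covariate_design is not None:
            self.covariate_design = np.asarray(self.covariate_design, dtype=float)
            if self.covariate_design.shape != (self.n, self.gamma.size):
                raise DegenerateInputError("covariate design must be n x k")
        if self.platform_names is None:
            self.platform_names = [f"platform_{i + 1}" for i in range(m)]
        if self.covariate_design is not None and not self.covariate_names:
            self.covariate_names = [f"x{j + 1}" for j in range(self.gamma.size)]
        if self.error_dist not in ("normal", "t"):
            raise DegenerateInputError("error_dist must be 'normal' or 't'")
        if self.error_dist == "t" and self.t_df <= 2:
            raise DegenerateInputError("t errors need df > 2 for finite variance")

    def population_covariance(self) -> np.ndarray:
        """Sigma(theta) at the truth (cov(X) taken as the design's sample cov)."""
        covx = np.zeros((0, 0))
        if self.covariate_design is not None:
            Xc = self.covariate_design - self.covariate_design.mean(axis=0)
            covx = Xc.T @ Xc / (self.n - 1)
        est = ParameterEstimates(loadings=self.loadings,
                                 latent_variance=self.latent_variance,
                                 error_variances=self.error_variances,
                                 covariate_coefficients=self.gamma,
                                 covariate_cov=covx)
        return implied_covariance(est)

    def reliabilities(self) -> np.ndarray:
        sig = self.population_covariance()
        m = self.loadings.size
        return 1.0 - self.error_variances / np.diag(sig)[:m]


def ibd_phenotype_design(n_cd: int = 39, n_uc: int = 50, n_control: int = 53
                         ) -> tuple[np.ndarray, list[str]]:
    """Binary CD/UC indicator design emulating the IBD study's group sizes."""
    n = n_cd + n_uc + n_control
    X = np.zeros((n, 2))
    X[:n_cd, 0] = 1.0
    X[n_cd:n_cd + n_uc, 1] = 1.0
    return X, ["CD", "UC"]


def _error_draws(rng: np.random.Generator, n: int, variances: np.ndarray,
                 dist: str, t_df: float) -> np.ndarray:
    sd = np.sqrt(variances)
    if dist == "normal":
        return rng.normal(0.0, 1.0, size=(n, variances.size)) * sd
    # scaled t: unit-variance t draws times the target sd
    t = rng.standard_t(t_df, size=(n, variances.size))
    return t * np.sqrt((t_df - 2.0) / t_df) * sd


def generate(truth: SyntheticTruth, seed=None) -> PlatformMatrix:
    """Draw one dataset from the model at the given truth.

    Per subject: ``zeta ~ N(0, sigma_zeta^2)``, ``xi = Gamma' x + zeta``,
    ``Y_i = lambda_i xi + eps_i`` with independent errors of variance
    ``sigma_eps_i^2``.  The covariate design is fixed, not resampled.
    """
    rng = np.random.default_rng(seed)
    n = truth.n
    zeta = rng.normal(0.0, np.sqrt(truth.latent_variance), size=n)
    xi = zeta
    covariates = None
    if truth.covariate_design is not None:
        xi = truth.covariate_design @ truth.gamma + zeta
        covariates = truth.covariate_design.copy()
    eps = _error_draws(rng, n, truth.error_variances, truth.error_dist, truth.t_df)
    Y = np.outer(xi, truth.loadings) + eps
    return PlatformMatrix(values=Y, platform_names=list(truth.platform_names),
                          covariates=covariates,
                          covariate_names=list(truth.covariate_names))


def generate_counts(frequencies, depth, seed=None) -> np.ndarray:
    """Binomial taxon counts at given true proportions and read depths.

    ``counts[s] ~ Binomial(depth[s], frequencies[s])`` per subject; pairs with
    the empirical-logit transform for end-to-end pipeline tests.
    """
    p = np.asarray(frequencies, dtype=float)
    d = np.asarray(depth)
    if np.any((p <= 0) | (p >= 1)):
        raise DegenerateInputError("frequencies must lie strictly in (0, 1)")
    if np.any(d < 1):
        raise DegenerateInputError("depth must be at least 1")
    rng = np.random.default_rng(seed)
    return rng.binomial(np.broadcast_to(d, p.shape).astype(int), p)


def faecalibacterium_truth(n: int = 142, with_phenotypes: bool = False,
                           gamma=(-0.592, -0.164)) -> SyntheticTruth:
    """Truth calibrated to the four-platform IBD study fit.

    Fits the packaged four-platform correlation fixture and returns its point
    estimates as generating values, so simulations run at the study's own
    parameter regime.  ``with_phenotypes`` adds the CD/UC design at the
    study's group sizes (39/50/53) with the published path coefficients.
    """
    from .datasets import faecalibacterium_correlations
    from .estimation import fit_model
    from .model_core import ModelSpec

    moments = faecalibacterium_correlations()
    fit = fit_model(moments, ModelSpec(indicator_names=list(moments.names)),
                    compute_se=False)
    est = fit.estimates
    kwargs = {}
    if with_phenotypes:
        if n != 142:
            raise DegenerateInputError(
                "phenotype design is the study's 39/50/53 split (n = 142)")
        X, names = ibd_phenotype_design()
        g = np.asarray(gamma, dtype=float)
        kwargs = dict(gamma=g, covariate_design=X, covariate_names=names)
    return SyntheticTruth(loadings=est.loadings,
                          latent_variance=est.latent_variance,
                          error_variances=np.clip(est.error_variances, 0, None),
                          n=n, platform_names=list(moments.names), **kwargs)
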
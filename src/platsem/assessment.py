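"""Reliability measures, goodness-of-fit indices, and model comparison.

Reliability of a platform is the squared correlation between its readout and
the latent variable — the fraction of the readout's variance explained by the
true signal, ``R2_i = 1 - Var(eps_i)/Var(Y_i)``.  On a three-indicator
correlation matrix it reduces to ratios of pairwise correlations
(``R2_2 = r12 * r23 / r13`` and cyclic analogues), which is what makes the
measure computable by hand from a published correlation table.

Goodness of fit is summarized by the chi-square test of exact fit, RMSEA
(root mean square error of approximation) and CFI (comparative fit index
against the independence baseline).  ``compare_models`` fits the free
one-factor model alongside its two repeated-measures-ANOVA-equivalent
constrained versions and tabulates all three.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .model_core import (
    ConstraintMode,
    DegenerateInputError,
    EffectSummary,
    FitResult,
    IdentificationError,
    ModelSpec,
    MomentSummary,
    NotPositiveDefiniteError,
    PlatsemError,
    ReliabilityReport,
)
from .estimation import fit_model
from .transforms import logit_effect_to_proportion_diff


def reliability(fit: FitResult, *, use_sample_variances: bool = False,
                sample_moments: Optional[MomentSummary] = None) -> ReliabilityReport:
    """Per-platform reliability R² and latent correlation from a fitted model.

    By default the variance in the denominator is the model-implied indicator
    variance (consistent with the variance decomposition the model asserts);
    pass ``use_sample_variances=True`` with the sample moments to divide by
    the observed variances instead — the two coincide at a just-identified
    optimum.  Heywood indicators yield R² as computed, flagged, not truncated.
    """
    if not fit.converged:
        raise PlatsemError("reliability requires a converged fit")
    est = fit.estimates
    m = est.loadings.size
    if use_sample_variances:
        if sample_moments is None:
            raise DegenerateInputError(
                "use_sample_variances requires the sample moments")
        idx = [sample_moments.names.index(n) for n in fit.spec.indicator_names]
        var_y = np.diag(sample_moments.S)[idx]
    else:
        var_y = np.diag(fit.implied)[:m]
    r2 = 1.0 - est.error_variances / var_y
    std = est.standardized_loadings
    corr = np.sign(std) * np.sqrt(np.clip(r2, 0, None))
    # preserve the identity corr^2 == r2 even for Heywood r2 > 1
    with np.errstate(invalid="ignore"):
        corr = np.where(r2 >= 0, np.sign(std) * np.sqrt(r2), np.nan)
    if np.any(r2 > 1):
        import logging
        logging.getLogger("platsem").warning(
            "reliability exceeds 1 for %s (Heywood case); reported raw",
            [n for n, v in zip(fit.spec.indicator_names, r2) if v > 1])
    return ReliabilityReport(platform_names=list(fit.spec.indicator_names),
                             reliability=r2, latent_correlation=corr,
                             heywood=fit.heywood or bool(np.any(r2 > 1)))


def triple_product_reliability(r12: float, r13: float, r23: float
                               ) -> tuple[float, float, float]:
    """Closed-form reliabilities of three platforms from pairwise correlations.

    ``R2_1 = r12*r13/r23``, ``R2_2 = r12*r23/r13``, ``R2_3 = r13*r23/r12``.
    Values may exceed 1 (Heywood); they are returned raw.  All three
    correlations must be nonzero with a positive triple product.
    """
    r = np.array([r12, r13, r23], dtype=float)
    if np.any(np.isclose(r, 0.0)):
        raise IdentificationError("a zero correlation leaves the model unidentified")
    if np.prod(r) <= 0:
        raise IdentificationError(
            "inconsistent correlation signs; reflect one indicator first")
    return (r12 * r13 / r23, r12 * r23 / r13, r13 * r23 / r12)


def fit_indices(chi_sq: float, df: int, N: int,
                chi_sq_null: float, df_null: int) -> tuple[float, float]:
    """RMSEA and CFI from model and independence-baseline chi-squares.

    ``RMSEA = sqrt(max(chi2 - df, 0) / (df (N-1)))`` (0 for a saturated
    model); ``CFI = 1 - d_model / max(d_null, d_model)`` with
    ``d = max(chi2 - df, 0)``, clamped to [0, 1].
    """
    if N <= 1 or df < 0:
        raise DegenerateInputError("need N > 1 and df >= 0")
    d_model = max(chi_sq - df, 0.0)
    if df == 0:
        if chi_sq > 1e-6:
            raise PlatsemError(
                f"df = 0 with chi-square {chi_sq:g} > 0: impossible state")
        rmsea = 0.0
    else:
        rmsea = float(np.sqrt(d_model / (df * (N - 1))))
    d_null = max(chi_sq_null - df_null, 0.0)
    denom = max(d_null, d_model)
    cfi = 1.0 if denom == 0 else 1.0 - d_model / denom
    return rmsea, float(np.clip(cfi, 0.0, 1.0))


def null_model_chi_square(S: np.ndarray, n_eff: int) -> tuple[float, int]:
    """Independence-model discrepancy for an already-extracted moment matrix.

    The independence model is Sigma = diag(S); its ML discrepancy reduces to
    ``-log|R|`` with R the correlation form of S.
    """
    S = np.asarray(S, dtype=float)
    d = np.sqrt(np.diag(S))
    if np.any(d <= 0):
        raise DegenerateInputError("diagonal must be positive")
    R = S / np.outer(d, d)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise NotPositiveDefiniteError("moment matrix is not positive definite")
    p = S.shape[0]
    return float(-logdet * n_eff), p * (p - 1) // 2


def null_model_fit(moments: MomentSummary, *, n_convention: str = "n-1"
                   ) -> tuple[float, int]:
    """Chi-square and df of the independence (diagonal-covariance) baseline."""
    n_eff = moments.N - 1 if n_convention == "n-1" else moments.N
    return null_model_chi_square(moments.S, n_eff)


@dataclass
class ModelComparisonRow:
    mode: ConstraintMode
    fit: FitResult

    @property
    def label(self) -> str:
        return {
            ConstraintMode.FREE: "latent variable SEM (free loadings)",
            ConstraintMode.EQUAL_LOADINGS: "repeated measures ANOVA (multivariate)",
            ConstraintMode.EQUAL_LOADINGS_EQUAL_ERRORS: "repeated measures ANOVA (univariate)",
        }[self.mode]


@dataclass
class ModelComparison:
    """Three nested fits plus chi-square difference tests between neighbours."""

    rows: list[ModelComparisonRow]
    difference_tests: list[dict]

    @property
    def best_by_chi_square(self) -> ConstraintMode:
        return min(self.rows, key=lambda r: r.fit.chi_square).mode

    @property
    def best_by_rmsea(self) -> ConstraintMode:
        return min(self.rows, key=lambda r: r.fit.rmsea).mode

    @property
    def best_by_cfi(self) -> ConstraintMode:
        return max(self.rows, key=lambda r: r.fit.cfi).mode

    def to_records(self) -> list[dict]:
        out = []
        for row in self.rows:
            f = row.fit
            out.append({"model": row.label, "constraint": row.mode.value,
                        "chi_square": f.chi_square, "df": f.df,
                        "p_value": f.p_value, "rmsea": f.rmsea, "cfi": f.cfi})
        return out


def compare_models(moments: MomentSummary, spec: ModelSpec,
                   **fit_kwargs) -> ModelComparison:
    """Fit the free model and both ANOVA-equivalent constrained models.

    The three models are nested (free ⊃ equal loadings ⊃ equal loadings and
    errors), so F_ML is non-decreasing down the list and adjacent pairs admit
    chi-square difference tests.
    """
    modes = [ConstraintMode.FREE, ConstraintMode.EQUAL_LOADINGS,
             ConstraintMode.EQUAL_LOADINGS_EQUAL_ERRORS]
    rows = []
    for mode in modes:
        s = ModelSpec(indicator_names=list(spec.indicator_names),
                      reference=spec.reference, constraint_mode=mode,
                      covariate_names=list(spec.covariate_names))
        rows.append(ModelComparisonRow(mode, fit_model(moments, s, **fit_kwargs)))
    diffs = []
    for a, b in zip(rows, rows[1:]):
        d_chi = b.fit.chi_square - a.fit.chi_square
        d_df = b.fit.df - a.fit.df
        diffs.append({
            "restricted": b.label, "general": a.label,
            "delta_chi_square": d_chi, "delta_df": d_df,
            "p_value": float(stats.chi2.sf(max(d_chi, 0.0), d_df)),
        })
    return ModelComparison(rows=rows, difference_tests=diffs)


def covariate_effects(fit: FitResult) -> list[EffectSummary]:
    """Per-covariate effect summaries from a covariate-model fit.

    Each summary carries the path coefficient gamma, its Wald p-value (when
    standard errors are available), and the implied shift in the underlying
    proportion for that covariate set to 1 versus the zero baseline.
    """
    est = fit.estimates
    k = est.covariate_coefficients.size
    if k == 0:
        raise DegenerateInputError("fit has no covariates")
    pvals = np.full(k, np.nan)
    if fit.standard_errors and "covariate_p_values" in fit.standard_errors:
        pvals = fit.standard_errors["covariate_p_values"]
    out = []
    for j, name in enumerate(fit.spec.covariate_names):
        pattern = np.zeros(k)
        pattern[j] = 1.0
        delta = logit_effect_to_proportion_diff(est.covariate_coefficients, pattern)
        out.append(EffectSummary(name=name,
                                 coefficient=float(est.covariate_coefficients[j]),
                                 p_value=float(pvals[j]),
                                 delta_proportion=delta))
    return out
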
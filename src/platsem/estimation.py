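"""Maximum-likelihood estimation of the one-factor measurement model.

A latent variable xi (the true logit-scale relative frequency of a taxon) is
measured by m platform readouts Y_i = lambda_i * xi + eps_i, with one loading
fixed at 1 to anchor the latent scale.  Optionally xi is regressed on k
observed covariates, xi = Gamma' X + zeta, while the covariate block of the
covariance matrix is left saturated.  Estimation minimizes the ML discrepancy

    F_ML = log|Sigma(theta)| + tr(S Sigma(theta)^-1) - log|S| - p

between the sample moment matrix S and the model-implied Sigma(theta); the
three-indicator just-identified case has closed-form estimators and is solved
exactly.  chi-square = (N-1) * F_ML by default (the convention that
reproduces standard SEM software output).
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .model_core import (
    CheckedSpec,
    ConstraintMode,
    ConvergenceError,
    DegenerateInputError,
    FitResult,
    IdentificationError,
    ModelSpec,
    MomentSummary,
    NotPositiveDefiniteError,
    ParameterEstimates,
    validate_spec,
)

HEYWOOD_REL_TOL = 1e-6
_RESTART_SEED = 987654321  # deterministic jitter stream for optimizer restarts


def implied_covariance(params: ParameterEstimates,
                       spec: ModelSpec | CheckedSpec | None = None) -> np.ndarray:
    """Model-implied covariance matrix Sigma(theta).

    Without covariates: ``Lambda sigma_zeta^2 Lambda' + diag(sigma_eps^2)``.
    With covariates, the block matrix with Psi = Gamma' cov(X) Gamma +
    sigma_zeta^2 in the measurement block, cross block ``Lambda Gamma' cov(X)``
    and the saturated ``cov(X)`` block.  Symmetric by construction.
    """
    lam = params.loadings
    psi = params.total_latent_variance
    Syy = psi * np.outer(lam, lam) + np.diag(params.error_variances)
    k = params.covariate_coefficients.size
    if k == 0:
        return Syy
    covx = params.covariate_cov
    cross = np.outer(lam, params.covariate_coefficients @ covx)  # m x k
    top = np.hstack([Syy, cross])
    bottom = np.hstack([cross.T, covx])
    return np.vstack([top, bottom])


def _chol_logdet(A: np.ndarray, label: str) -> tuple[np.ndarray, float]:
    try:
        L = np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        raise NotPositiveDefiniteError(f"{label} matrix is not positive definite")
    return L, 2.0 * float(np.sum(np.log(np.diag(L))))


def ml_fit_function(sigma_theta: np.ndarray, s: np.ndarray) -> float:
    """ML discrepancy between a model-implied and a sample covariance matrix.

    Zero iff the two matrices coincide; equals ``2/(N-1)`` times the
    log-likelihood gap to the saturated model.
    """
    sigma_theta = np.asarray(sigma_theta, dtype=float)
    s = np.asarray(s, dtype=float)
    p = s.shape[0]
    if sigma_theta.shape != s.shape:
        raise DegenerateInputError("matrix dimensions differ")
    L, logdet_sigma = _chol_logdet(sigma_theta, "model-implied")
    _, logdet_s = _chol_logdet(s, "sample")
    # tr(S Sigma^-1) via triangular solves
    X = np.linalg.solve(sigma_theta, s)
    return float(logdet_sigma + np.trace(X) - logdet_s - p)


def closed_form_three_indicator(S) -> tuple[ParameterEstimates, bool]:
    """Exact ML estimators for the just-identified three-indicator model.

    With the first loading fixed at 1:
    ``lam2 = S23/S13``, ``lam3 = S23/S12``, ``sigma_zeta^2 = S12*S13/S23``,
    ``sigma_eps_i^2 = S_ii - sigma_zeta^2 * lam_i^2``.

    Returns the estimates and a Heywood flag (any negative error variance is
    returned literally and flagged, not truncated).
    """
    if isinstance(S, MomentSummary):
        S = S.S
    S = np.asarray(S, dtype=float)
    if S.shape != (3, 3):
        raise DegenerateInputError("closed form requires a 3x3 moment matrix")
    s12, s13, s23 = S[0, 1], S[0, 2], S[1, 2]
    if np.isclose(s12, 0) or np.isclose(s13, 0) or np.isclose(s23, 0):
        raise IdentificationError(
            "a zero off-diagonal moment leaves the model unidentified")
    if s12 * s13 * s23 <= 0:
        raise IdentificationError(
            "inconsistent signs among off-diagonal moments; reflect (negate) "
            "one indicator so all pairwise covariances share a sign pattern")
    lam = np.array([1.0, s23 / s13, s23 / s12])
    szeta = s12 * s13 / s23
    serr = np.diag(S) - szeta * lam ** 2
    heywood = bool(np.any(serr < 0))
    est = ParameterEstimates(loadings=lam, latent_variance=szeta,
                             error_variances=serr)
    return est, heywood


def standardize(params: ParameterEstimates, implied: np.ndarray) -> np.ndarray:
    """Standardized loadings: lambda_i * sd(xi) / sd(Y_i).

    sd(Y_i) comes from the model-implied (not sample) covariance diagonal;
    with covariates the latent sd is the total sd sqrt(Gamma' cov(X) Gamma +
    sigma_zeta^2).  The result is the indicator–latent correlation; its
    square is the platform reliability.
    """
    m = params.loadings.size
    sd_y = np.sqrt(np.diag(implied)[:m])
    if np.any(sd_y <= 0):
        raise DegenerateInputError("implied variances must be positive")
    with np.errstate(invalid="ignore"):
        lat_sd = np.sqrt(params.total_latent_variance)
    std = params.loadings * lat_sd / sd_y
    params.standardized_loadings = std
    return std


# --- optimizer machinery -----------------------------------------------------

def _tril_indices(k):
    return np.tril_indices(k)


def _pack_start(S: np.ndarray, checked: CheckedSpec) -> np.ndarray:
    m, k = checked.m, checked.k
    ref = checked.reference_index
    mode = checked.constraint_mode
    parts = []
    if mode is ConstraintMode.FREE:
        lam0 = S[:m, ref] / S[ref, ref]
        parts.append(np.delete(lam0, ref))
    parts.append([np.log(0.5 * S[ref, ref])])       # log sigma_zeta^2
    if mode is ConstraintMode.EQUAL_LOADINGS_EQUAL_ERRORS:
        parts.append([np.log(0.5 * np.mean(np.diag(S)[:m]))])
    else:
        parts.append(np.log(0.5 * np.diag(S)[:m]))
    if k:
        Sxx = S[m:, m:]
        sxy = S[m:, ref]
        parts.append(np.linalg.solve(Sxx, sxy))     # OLS start for gamma
        L = np.linalg.cholesky(Sxx)
        chol = L[_tril_indices(k)].copy()
        diag_pos = np.cumsum(np.arange(1, k + 1)) - 1
        chol[diag_pos] = np.log(np.diag(L))
        parts.append(chol)
    return np.concatenate([np.atleast_1d(np.asarray(p, dtype=float)) for p in parts])


def _unpack(x: np.ndarray, checked: CheckedSpec) -> ParameterEstimates:
    m, k = checked.m, checked.k
    ref = checked.reference_index
    mode = checked.constraint_mode
    pos = 0
    lam = np.ones(m)
    if mode is ConstraintMode.FREE:
        free = x[pos:pos + m - 1]
        pos += m - 1
        lam = np.insert(free, ref, 1.0)
    szeta = float(np.exp(x[pos])); pos += 1
    if mode is ConstraintMode.EQUAL_LOADINGS_EQUAL_ERRORS:
        serr = np.full(m, np.exp(x[pos])); pos += 1
    else:
        serr = np.exp(x[pos:pos + m]); pos += m
    gamma = np.zeros(0)
    covx = np.zeros((0, 0))
    if k:
        gamma = x[pos:pos + k]; pos += k
        chol = x[pos:pos + k * (k + 1) // 2]; pos += k * (k + 1) // 2
        L = np.zeros((k, k))
        L[_tril_indices(k)] = chol
        np.fill_diagonal(L, np.exp(np.diag(L)))
        covx = L @ L.T
    return ParameterEstimates(loadings=lam, latent_variance=szeta,
                              error_variances=serr,
                              covariate_coefficients=gamma,
                              covariate_cov=covx)


def _natural_vector(est: ParameterEstimates, checked: CheckedSpec) -> np.ndarray:
    """Natural-scale parameters for the observed information (cov(X) held fixed)."""
    mode = checked.constraint_mode
    parts = []
    if mode is ConstraintMode.FREE:
        parts.append(np.delete(est.loadings, checked.reference_index))
    parts.append([est.latent_variance])
    if mode is ConstraintMode.EQUAL_LOADINGS_EQUAL_ERRORS:
        parts.append([est.error_variances[0]])
    else:
        parts.append(est.error_variances)
    if checked.k:
        parts.append(est.covariate_coefficients)
    return np.concatenate([np.atleast_1d(np.asarray(p, dtype=float)) for p in parts])


def _from_natural(theta: np.ndarray, checked: CheckedSpec,
                  covx: np.ndarray) -> ParameterEstimates:
    m, k = checked.m, checked.k
    mode = checked.constraint_mode
    pos = 0
    lam = np.ones(m)
    if mode is ConstraintMode.FREE:
        lam = np.insert(theta[pos:pos + m - 1], checked.reference_index, 1.0)
        pos += m - 1
    szeta = float(theta[pos]); pos += 1
    if mode is ConstraintMode.EQUAL_LOADINGS_EQUAL_ERRORS:
        serr = np.full(m, theta[pos]); pos += 1
    else:
        serr = theta[pos:pos + m]; pos += m
    gamma = theta[pos:pos + k] if k else np.zeros(0)
    return ParameterEstimates(loadings=lam, latent_variance=szeta,
                              error_variances=serr,
                              covariate_coefficients=gamma,
                              covariate_cov=covx)


def _standard_errors(est: ParameterEstimates, checked: CheckedSpec,
                     S: np.ndarray, n_eff: int) -> Optional[dict]:
    """Wald SEs from the numerically inverted observed information of
    (n_eff/2) * F_ML at the optimum; None when the information is singular."""
    from statsmodels.tools.numdiff import approx_hess

    covx = est.covariate_cov
    theta0 = _natural_vector(est, checked)

    def nll(theta):
        try:
            p = _from_natural(theta, checked, covx)
            return 0.5 * n_eff * ml_fit_function(implied_covariance(p), S)
        except (NotPositiveDefiniteError, DegenerateInputError):
            return np.inf

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        H = approx_hess(theta0, nll)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    d = np.diag(cov)
    if np.any(d <= 0) or not np.all(np.isfinite(d)):
        return None
    se = np.sqrt(d)
    m, k = checked.m, checked.k
    mode = checked.constraint_mode
    pos = 0
    se_lam = np.full(m, np.nan)
    if mode is ConstraintMode.FREE:
        idx = [i for i in range(m) if i != checked.reference_index]
        se_lam[idx] = se[pos:pos + m - 1]
        pos += m - 1
    se_szeta = float(se[pos]); pos += 1
    if mode is ConstraintMode.EQUAL_LOADINGS_EQUAL_ERRORS:
        se_err = np.full(m, se[pos]); pos += 1
    else:
        se_err = se[pos:pos + m]; pos += m
    out = {"loadings": se_lam, "latent_variance": se_szeta,
           "error_variances": se_err}
    if k:
        se_g = se[pos:pos + k]
        z = est.covariate_coefficients / se_g
        out["covariate_coefficients"] = se_g
        out["covariate_p_values"] = 2.0 * stats.norm.sf(np.abs(z))
    return out


def _fit_indices_for(chi_sq: float, df: int, N: int, S: np.ndarray,
                     n_eff: int) -> tuple[float, float]:
    # local import: assessment is the public home of these operations
    from .assessment import fit_indices, null_model_chi_square

    chi_null, df_null = null_model_chi_square(S, n_eff)
    return fit_indices(chi_sq, df, N, chi_null, df_null)


def fit_model(moments: MomentSummary,
              spec: ModelSpec,
              *,
              n_convention: str = "n-1",
              compute_se: bool = True,
              use_closed_form: bool = True,
              max_restarts: int = 5,
              gtol: float = 1e-9) -> FitResult:
    """Fit the measurement model (optionally with covariates) to moments.

    Parameters
    ----------
    moments
        Moment summary containing every indicator and covariate named in the
        spec (order-free; a submatrix is extracted in spec order).
    spec
        Model specification: indicators, reference, constraint mode,
        covariates.
    n_convention
        ``"n-1"`` (default) gives ``chi2 = (N-1) F_ML``; ``"n"`` uses N.
    use_closed_form
        Solve the just-identified three-indicator FREE model exactly instead
        of iterating (falls back to the optimizer in Heywood cases so that
        variances respect the boundary).
    """
    checked = validate_spec(spec, moments)
    m, k = checked.m, checked.k
    order = checked.indicator_idx + checked.covariate_idx
    S = moments.S[np.ix_(order, order)]
    _chol_logdet(S, "sample moment")
    if n_convention not in ("n-1", "n"):
        raise DegenerateInputError("n_convention must be 'n-1' or 'n'")
    n_eff = moments.N - 1 if n_convention == "n-1" else moments.N

    est = None
    converged = True
    f = None
    if (use_closed_form and m == 3 and k == 0
            and checked.constraint_mode is ConstraintMode.FREE):
        try:
            cf_est, cf_heywood = closed_form_three_indicator(S)
        except IdentificationError:
            raise
        if not cf_heywood:
            est = cf_est
            f = ml_fit_function(implied_covariance(est), S)

    if est is None:
        x0 = _pack_start(S, checked)
        rng = np.random.default_rng(_RESTART_SEED)
        best = None
        for attempt in range(max_restarts + 1):
            x_start = x0 if attempt == 0 else x0 + rng.normal(0, 0.2, size=x0.size)

            def objective(x):
                try:
                    return ml_fit_function(implied_covariance(_unpack(x, checked)), S)
                except NotPositiveDefiniteError:
                    return 1e10

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = optimize.minimize(objective, x_start, method="BFGS",
                                        options={"gtol": gtol, "maxiter": 2000})
            gnorm = float(np.max(np.abs(res.jac)))
            ok = bool(res.success) or gnorm < 1e-6
            if best is None or res.fun < best[0].fun - 1e-12:
                best = (res, ok, gnorm)
            if ok and attempt >= 0 and res.fun <= best[0].fun + 1e-12:
                best = (res, ok, gnorm)
                break
        res, converged, gnorm = best
        if not converged:
            raise ConvergenceError(
                f"optimizer failed after {max_restarts} restarts "
                f"(best F_ML={res.fun:.6g}, |grad|={gnorm:.3g})",
                best_f=float(res.fun), grad_norm=gnorm)
        est = _unpack(res.x, checked)
        f = float(res.fun)

    implied = implied_covariance(est)
    standardize(est, implied)
    heywood = bool(np.any(
        est.error_variances < HEYWOOD_REL_TOL * np.diag(implied)[:m]))

    chi_sq = n_eff * max(f, 0.0)
    df = checked.df
    p_value = float(stats.chi2.sf(chi_sq, df)) if df > 0 else float("nan")
    rmsea, cfi = _fit_indices_for(chi_sq, df, moments.N, S, n_eff)

    se = None
    if compute_se:
        try:
            se = _standard_errors(est, checked, S, n_eff)
        except Exception:
            se = None

    return FitResult(estimates=est, f_ml=max(f, 0.0), chi_square=chi_sq,
                     df=df, p_value=p_value, rmsea=rmsea, cfi=cfi,
                     converged=converged, n_used=moments.N, spec=spec,
                     heywood=heywood, standard_errors=se, implied=implied)
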
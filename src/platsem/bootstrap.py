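"""Nonparametric bootstrap inference for the measurement model.

Subjects (rows) are resampled with replacement, preserving the
cross-platform correlation structure within a subject; covariates travel
with their rows.  Each replicate is refit and percentile intervals are read
off the replicate distribution — the route to interval estimates when the
normality behind the Wald intervals is not trusted.

Replicate ``r`` is drawn from a single seeded stream in contiguous blocks,
so it is reproducible independently of the total replicate count ``B``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model_core import (
    ConstraintMode,
    DegenerateInputError,
    FitResult,
    ModelSpec,
    MomentSummary,
    PlatsemError,
    PlatformMatrix,
    ReliabilityReport,
    moments_from_data,
)
from .estimation import fit_model
from .assessment import reliability

MAX_FAILURE_FRACTION = 0.20
MIN_CI_SAMPLES = 100


class BootstrapError(PlatsemError):
    """Raised when too many bootstrap replicates fail to fit."""


@dataclass
class BootstrapResult:
    """Replicate distributions of every estimate of interest.

    Arrays have one row per *successful* replicate; ``n_failed`` counts the
    replicates dropped for non-convergence or degenerate resamples.
    """

    spec: ModelSpec
    seed: Optional[int]
    n_requested: int
    n_failed: int
    loadings: np.ndarray                 # (B_ok, m)
    standardized_loadings: np.ndarray    # (B_ok, m)
    reliabilities: np.ndarray            # (B_ok, m)
    latent_variance: np.ndarray          # (B_ok,)
    error_variances: np.ndarray          # (B_ok, m)
    covariate_coefficients: np.ndarray = field(
        default_factory=lambda: np.zeros((0, 0)))  # (B_ok, k)

    @property
    def n_ok(self) -> int:
        return self.loadings.shape[0]


def resample_indices(n: int, B: int, seed) -> np.ndarray:
    """(B, n) row-resampling indices from one seeded stream."""
    rng = np.random.default_rng(seed)
    return rng.integers(0, n, size=(B, n))


def percentile_ci(samples, level: float = 0.95,
                  clamp_unit: bool = False) -> tuple[float, float]:
    """Percentile interval: empirical quantiles at (1-level)/2 and 1-(1-level)/2.

    Uses linear interpolation of the empirical CDF (the type-7 convention).
    ``clamp_unit`` restricts the endpoints to [0, 1]; use it for reliability
    and correlation scales only, never for loadings or covariate effects.
    """
    x = np.asarray(samples, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < MIN_CI_SAMPLES:
        raise DegenerateInputError(
            f"need at least {MIN_CI_SAMPLES} finite samples, got {x.size}")
    if not (0 < level < 1):
        raise DegenerateInputError("level must lie in (0, 1)")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(x, [alpha, 1.0 - alpha], method="linear")
    if clamp_unit:
        lo, hi = np.clip([lo, hi], 0.0, 1.0)
    return float(lo), float(hi)


def _fast_path_applies(data: PlatformMatrix, spec: ModelSpec) -> bool:
    return (data.n_platforms >= 3 and len(spec.indicator_names) == 3
            and len(spec.covariate_names) == 0
            and spec.constraint_mode is ConstraintMode.FREE)


def _closed_form_batch(Y: np.ndarray, indices: np.ndarray, ref: int):
    """Vectorized just-identified three-indicator fit over all replicates.

    Returns replicate arrays plus a validity mask; Heywood replicates (a
    negative error variance, reliability above 1) are retained as computed —
    only sign-inconsistent or degenerate resamples are invalid.
    """
    n = Y.shape[0]
    # order columns so the reference indicator is first
    order = [ref] + [i for i in range(3) if i != ref]
    Yg = Y[indices][:, :, order]                       # (B, n, 3)
    Yc = Yg - Yg.mean(axis=1, keepdims=True)
    S = np.einsum("bni,bnj->bij", Yc, Yc) / (n - 1)    # (B, 3, 3)
    s12, s13, s23 = S[:, 0, 1], S[:, 0, 2], S[:, 1, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.stack([np.ones_like(s12), s23 / s13, s23 / s12], axis=1)
        szeta = s12 * s13 / s23
        diag = np.stack([S[:, 0, 0], S[:, 1, 1], S[:, 2, 2]], axis=1)
        serr = diag - szeta[:, None] * lam ** 2
        rel = szeta[:, None] * lam ** 2 / diag
        std = lam * np.sqrt(szeta)[:, None] / np.sqrt(diag)
    valid = (s12 * s13 * s23 > 0) & np.all(np.isfinite(lam), axis=1)
    inv = np.empty(3, dtype=int)
    inv[order] = np.arange(3)                          # back to spec order
    return (lam[:, inv], std[:, inv], rel[:, inv], szeta, serr[:, inv], valid)


def bootstrap_fit(data: PlatformMatrix, spec: ModelSpec, B: int,
                  seed=None, *, indices: Optional[np.ndarray] = None,
                  **fit_kwargs) -> BootstrapResult:
    """B resampled fits of the model; rows drawn with replacement, n fixed.

    Requires raw data (a moment summary cannot be bootstrapped).  Replicates
    that fail to fit (non-convergence, sign-inconsistent moments, degenerate
    resamples) are dropped and counted; more than 20% failures is an error.
    ``indices`` overrides the resampling plan (one row of subject indices per
    replicate) for diagnostic use.
    """
    if B < 1:
        raise DegenerateInputError("B must be at least 1")
    n = data.n_samples
    if indices is None:
        indices = resample_indices(n, B, seed)
    indices = np.asarray(indices)
    if indices.shape != (B, n):
        raise DegenerateInputError(f"indices must have shape {(B, n)}")

    col = [data.platform_names.index(nm) for nm in spec.indicator_names]
    if _fast_path_applies(data, spec):
        Y = data.values[:, col]
        ref_local = spec.reference_index
        lam, std, rel, szeta, serr, valid = _closed_form_batch(Y, indices, ref_local)
        n_failed = int(B - valid.sum())
        _check_failures(n_failed, B, "sign-inconsistent or degenerate resample")
        return BootstrapResult(spec=spec, seed=seed, n_requested=B,
                               n_failed=n_failed,
                               loadings=lam[valid],
                               standardized_loadings=std[valid],
                               reliabilities=rel[valid],
                               latent_variance=szeta[valid],
                               error_variances=serr[valid])

    kcols = None
    if spec.covariate_names:
        kcols = [data.covariate_names.index(nm) for nm in spec.covariate_names]
    m, k = len(col), 0 if kcols is None else len(kcols)
    keep = {"loadings": [], "standardized_loadings": [], "reliabilities": [],
            "latent_variance": [], "error_variances": [], "gamma": []}
    failures: dict[str, int] = {}
    for r in range(B):
        idx = indices[r]
        try:
            resampled = PlatformMatrix(
                values=data.values[idx][:, col],
                platform_names=list(spec.indicator_names),
                covariates=None if kcols is None else data.covariates[idx][:, kcols],
                covariate_names=list(spec.covariate_names))
            fit = fit_model(moments_from_data(resampled), spec,
                            compute_se=False, **fit_kwargs)
            rep = reliability(fit)
        except PlatsemError as exc:
            failures[type(exc).__name__] = failures.get(type(exc).__name__, 0) + 1
            continue
        est = fit.estimates
        keep["loadings"].append(est.loadings)
        keep["standardized_loadings"].append(est.standardized_loadings)
        keep["reliabilities"].append(rep.reliability)
        keep["latent_variance"].append(est.latent_variance)
        keep["error_variances"].append(est.error_variances)
        keep["gamma"].append(est.covariate_coefficients)
    n_failed = B - len(keep["loadings"])
    _check_failures(n_failed, B, ", ".join(f"{k}: {v}" for k, v in failures.items()))
    stack = {k: (np.array(v) if v else np.zeros((0, m))) for k, v in keep.items()}
    return BootstrapResult(spec=spec, seed=seed, n_requested=B,
                           n_failed=n_failed,
                           loadings=stack["loadings"],
                           standardized_loadings=stack["standardized_loadings"],
                           reliabilities=stack["reliabilities"],
                           latent_variance=stack["latent_variance"].ravel(),
                           error_variances=stack["error_variances"],
                           covariate_coefficients=np.array(keep["gamma"])
                           if k else np.zeros((0, 0)))


def _check_failures(n_failed: int, B: int, detail: str):
    if n_failed > MAX_FAILURE_FRACTION * B:
        raise BootstrapError(
            f"{n_failed}/{B} bootstrap replicates failed ({detail})")


def reliability_with_ci(data: PlatformMatrix, spec: ModelSpec, B: int,
                        seed=None, level: float = 0.95,
                        **fit_kwargs) -> tuple[ReliabilityReport, BootstrapResult]:
    """Point reliabilities from the full-sample fit plus percentile CIs.

    CI endpoints on the reliability scale are clamped to [0, 1] (a Heywood
    replicate can push the raw upper quantile above 1, which prints as 1.000).
    """
    fit = fit_model(moments_from_data(data), spec, compute_se=False, **fit_kwargs)
    report = reliability(fit)
    boot = bootstrap_fit(data, spec, B, seed, **fit_kwargs)
    m = len(spec.indicator_names)
    lo = np.empty(m)
    hi = np.empty(m)
    for i in range(m):
        lo[i], hi[i] = percentile_ci(boot.reliabilities[:, i], level,
                                     clamp_unit=True)
    report.ci_lower = lo
    report.ci_upper = hi
    return report, boot
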
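"""Transforms putting heterogeneous platform readouts onto a common logit scale.

Sequencing platforms report taxon counts out of a total read depth; qPCR
reports a cycle-threshold difference (dCT) relative to total bacteria.  Both
are mapped to log-odds of the taxon's relative frequency so that every
platform measures the same latent quantity on the same scale.
"""

from __future__ import annotations

import numpy as np

from .model_core import DegenerateInputError

DEFAULT_SMOOTHING = 0.5  # Haldane–Anscombe constant


def empirical_logit(successes, total, smoothing: float = DEFAULT_SMOOTHING):
    """Smoothed log-odds of a sample proportion, finite at 0 and at ``total``.

    Computes ``log((k + c) / (n - k + c))`` with smoothing constant ``c``
    (default 0.5), for counts ``0 <= k <= n``, ``n > 0``.  Accepts scalars or
    arrays (broadcast).
    """
    k = np.asarray(successes, dtype=float)
    n = np.asarray(total, dtype=float)
    if smoothing <= 0:
        raise DegenerateInputError("smoothing constant must be positive")
    if np.any(n <= 0):
        raise DegenerateInputError("total count must be positive")
    if np.any(k < 0) or np.any(k > n):
        raise DegenerateInputError("need 0 <= successes <= total")
    out = np.log((k + smoothing) / (n - k + smoothing))
    return out if out.ndim else float(out)


def qpcr_to_logit(dCT):
    """Convert a qPCR cycle-threshold difference to the logit scale.

    The relative frequency implied by ``dCT`` is ``p = 2**dCT``; the result is
    ``logit(p)``.  Requires ``dCT < 0`` so that ``p`` lies in (0, 1).
    """
    d = np.asarray(dCT, dtype=float)
    if np.any(d >= 0):
        raise DegenerateInputError(
            "dCT must be negative: 2**dCT must lie strictly inside (0, 1)")
    p = np.exp2(d)
    out = np.log(p / (1.0 - p))
    return out if out.ndim else float(out)


def logit_effect_to_proportion_diff(coefficients, pattern) -> float:
    """Shift in the underlying proportion implied by covariate coefficients.

    For latent log-odds ``xi = Gamma' x`` on the centered scale, returns
    ``sigma(Gamma' x) - sigma(0)`` where ``sigma`` is the logistic function —
    the difference in estimated true relative frequency between a subject
    with covariate pattern ``x`` and the zero baseline.  Bounded in
    (−0.5, 0.5); an interpretation aid, not a marginal-effect estimator.
    """
    g = np.atleast_1d(np.asarray(coefficients, dtype=float))
    x = np.atleast_1d(np.asarray(pattern, dtype=float))
    if g.shape != x.shape:
        raise DegenerateInputError(
            f"pattern length {x.size} does not match coefficients {g.size}")
    eta = float(g @ x)
    return 1.0 / (1.0 + np.exp(-eta)) - 0.5
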
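"""Small shared statistical helpers."""

from __future__ import annotations

import numpy as np
from scipy.special import polygamma
from statsmodels.stats.multitest import multipletests

__all__ = ["fdr_bh", "trigamma_inverse", "squeeze_var"]


def fdr_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 75) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma is positive on (0, inf)")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = polygamma(1, x)
        step = tri * (1.0 - tri / y) / polygamma(2, x)
        x += step
        if abs(step) < tol * x:
            break
    return float(x)


def squeeze_var(s2, df) -> tuple[float, float, np.ndarray]:
    """Empirical-Bayes shrinkage of sample variances toward a common prior.

    Models the per-analyte residual variances ``s2`` (each on ``df`` residual
    degrees of freedom) as draws from a scaled F distribution with prior
    degrees of freedom d0 and prior variance s0^2, estimated by matching the
    first two moments of log(s2).  Returns ``(d0, s0sq, s2_post)`` where the
    posterior variance is the df-weighted blend ``(d0*s0^2 + df*s2)/(d0+df)``;
    ``d0 = inf`` collapses every variance onto s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    if np.any(s2 < 0):
        raise ValueError("negative sample variance")
    df = float(df)
    if df <= 0:
        raise ValueError("residual degrees of freedom must be positive")
    # work on strictly positive variances; exact zeros (e.g. duplicated
    # samples) are excluded from moment estimation but still shrunk
    pos = s2 > 0
    if pos.sum() < 2:
        return 0.0, float(np.median(s2)), s2.copy()
    z = np.log(s2[pos])
    e = z - polygamma(0, df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(float(evar))
        s0sq = float(np.exp(emean + polygamma(0, d0 / 2.0) - np.log(d0 / 2.0)))
        post = (d0 * s0sq + df * s2) / (d0 + df)
    else:
        d0 = np.inf
        s0sq = float(np.exp(emean))
        post = np.full_like(s2, s0sq)
    return float(d0), s0sq, post
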
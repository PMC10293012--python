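"""Small shared statistical utilities."""

from __future__ import annotations

import numpy as np
from scipy import special
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR).

    Thin wrapper over statsmodels; NaNs are propagated untouched.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x  # good starting value for the asymptotic regime
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y - dif
        if np.all(np.abs(dif) < 1e-10 * y):
            break
    return y


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of per-gene sample variances.

    Fits a scaled inverse-chi-square prior (s0^2 on d0 degrees of freedom) to
    the observed variances by the method of moments on log variances, then
    returns posterior variances ``(d0*s0^2 + df*s2) / (d0 + df)``.

    Returns (posterior variances, prior df d0, prior variance s0^2).
    d0 may be ``inf`` when the observed variances are underdispersed relative
    to chi-square sampling noise, in which case every posterior variance
    equals s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least two positive variances to fit a prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) * (1.0 - 1.0 / ok.sum())  # slight bias adjustment
    evar = evar - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = float(2.0 * _trigamma_inverse(np.array([evar]))[0])
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        post = (d0 * s02 + df * s2) / (d0 + df)
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
        post = np.full_like(s2, s02)
    # genes with zero observed variance still get the prior contribution
    post = np.where(s2 > 0, post, s02 if np.isinf(d0) else (d0 * s02) / (d0 + df))
    return post, d0, s02
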
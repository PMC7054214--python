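"""Shared statistical primitives: upper-tail tests and FDR control.

Conventions: every test here reports the upper tail P(X >= observed), so
an observed count of zero always gives p = 1.  The negative binomial is
parametrized by its mean mu and overdispersion alpha with
variance = mu + alpha * mu**2 (alpha -> 0 recovers the Poisson).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

# below this overdispersion the NB is numerically indistinguishable from
# the Poisson and the nbinom size parameter 1/alpha overflows usefully
_ALPHA_POISSON = 1e-8


def nb_sf(k, mu, alpha):
    """P(X >= k) for a Gamma-Poisson (negative binomial) count X.

    Vectorized over k and mu; alpha is a scalar >= 0.
    """
    k = np.asarray(k)
    if np.any(k < 0):
        raise ValueError("observed counts must be non-negative")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if alpha < _ALPHA_POISSON:
        return sps.poisson.sf(k - 1, mu)
    size = 1.0 / alpha
    p = size / (size + np.asarray(mu, dtype=float))
    return sps.nbinom.sf(k - 1, size, p)


def binom_sf(k, n, p):
    """P(X >= k) for X ~ Binomial(n, p)."""
    k = np.asarray(k)
    if np.any(k < 0):
        raise ValueError("observed counts must be non-negative")
    return sps.binom.sf(k - 1, n, p)


def benjamini_hochberg(p, m: int | None = None):
    """BH step-up q-values.

    ``m`` overrides the number of tests (for universes containing
    additional implicit p = 1 entries, e.g. zero-event tiles).  Ties keep
    their original order; q-values are capped at 1 and are monotone in the
    p-value ranks.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be 1-dimensional")
    if np.any(np.isnan(p)):
        raise ValueError("NaN p-values are not allowed")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if n == 0:
        return p.copy()
    if m is None:
        m = n
    if m < n:
        raise ValueError("m must be >= len(p)")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def poisson_exact_ci(k: int, conf: float = 0.95) -> tuple[float, float]:
    """Garwood exact confidence interval for a Poisson mean given count k."""
    if k < 0:
        raise ValueError("count must be non-negative")
    a = 1.0 - conf
    lo = 0.0 if k == 0 else sps.chi2.ppf(a / 2, 2 * k) / 2.0
    hi = sps.chi2.ppf(1 - a / 2, 2 * (k + 1)) / 2.0
    return float(lo), float(hi)
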
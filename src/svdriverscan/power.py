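"""Discovery-power calculations for burden and juxtaposition tests.

The burden framework asks: given a cohort of N patients, a background
mutation rate per base, an element of length L and per-position
detection sensitivity s, what is the lowest driver frequency f in the
patient population for which a binomial burden test (at a Bonferroni
per-test level alpha_global / n_tests) reaches >= 90% power?  The SRJ
analogue works over the tiles of the two-dimensional fusion map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import Element, ParameterError

NOT_POWERED = float("inf")  # sentinel: no f <= 1 reaches the power target


def _critical_count(n: int, q0: float, alpha: float) -> int:
    """Smallest k with P(Binomial(n, q0) >= k) <= alpha."""
    k = int(sps.binom.isf(alpha, n, q0))  # largest k with sf(k) > alpha
    while sps.binom.sf(k - 1, n, q0) > alpha:
        k += 1
    while k > 0 and sps.binom.sf(k - 2, n, q0) <= alpha:
        k -= 1
    return k


def binomial_power(n: int, p_alt: float, k_star: int) -> float:
    """P(Binomial(n, p_alt) >= k_star)."""
    return float(sps.binom.sf(k_star - 1, n, p_alt))


def min_detectable_frequency(n_patients: int, bg_rate: float, length: int,
                             sensitivity: float = 1.0,
                             alpha_global: float = 0.1,
                             n_tests: int = 1,
                             power_target: float = 0.9,
                             tol: float = 1e-5) -> float:
    """Minimal driver frequency with >= ``power_target`` discovery power.

    The per-patient background element mutation probability is
    q0 = 1 - (1 - bg_rate)^L; a driver at population frequency f adds an
    independent detected event with probability f * s, so the mutated
    probability is q0 + f*s*(1 - q0).  The significance threshold k* is
    the binomial critical count at the Bonferroni-adjusted level, and f*
    is found by bisection.  Returns inf ("not powered") when even f = 1
    falls short.
    """
    if min(n_patients, bg_rate, length, sensitivity, alpha_global, n_tests) <= 0:
        raise ParameterError("all power parameters must be positive")
    alpha = alpha_global / n_tests
    q0 = 1.0 - (1.0 - bg_rate) ** length
    k_star = _critical_count(n_patients, q0, alpha)

    def power(f: float) -> float:
        return binomial_power(n_patients, q0 + f * sensitivity * (1 - q0), k_star)

    if power(1.0) < power_target:
        return NOT_POWERED
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if power(mid) >= power_target:
            hi = mid
        else:
            lo = mid
    return hi


def power_grid(cohort_sizes: Sequence[int], bg_rates: Sequence[float],
               length: int, sensitivity: float = 1.0,
               alpha_global: float = 0.1, n_tests: int = 1) -> pd.DataFrame:
    """Minimal detectable frequency over a cohort-size x background grid."""
    rows = []
    for n in cohort_sizes:
        for r in bg_rates:
            f = min_detectable_frequency(n, r, length, sensitivity,
                                         alpha_global, n_tests)
            rows.append(dict(n_patients=n, bg_rate=r, length=length,
                             sensitivity=sensitivity, min_frequency=f))
    return pd.DataFrame(rows)


def srj_power(n_samples: int, median_rearr_per_sample: float,
              recurrence_rate: float, tile_count: int,
              alpha_global: float = 0.1,
              p0_map: Optional[float] = None) -> float:
    """Power to detect one recurrent juxtaposition tile.

    The per-sample per-tile background probability p0 spreads the median
    rearrangement count uniformly over the tiles (or uses a supplied
    value); a driver tile gains ``recurrence_rate`` per sample.  The
    critical count uses the tile-level Bonferroni alpha.
    """
    if recurrence_rate <= 0:
        raise ParameterError("recurrence rate must be positive")
    if min(n_samples, median_rearr_per_sample, tile_count) <= 0:
        raise ParameterError("all power parameters must be positive")
    p0 = p0_map if p0_map is not None else min(
        median_rearr_per_sample / tile_count, 1.0)
    alpha = alpha_global / tile_count
    k_star = _critical_count(n_samples, p0, alpha)
    return binomial_power(n_samples, min(p0 + recurrence_rate, 1.0), k_star)


def samples_required(median_rearr_per_sample: float, recurrence_rate: float,
                     tile_count: int, power_target: float = 0.9,
                     alpha_global: float = 0.1, n_max: int = 100_000) -> float:
    """Smallest cohort size reaching ``power_target`` SRJ power.

    Power is not monotone in N at fixed alpha (the discrete critical
    count shifts), so the search returns the first N whose power
    reaches the target.  inf when no N <= n_max suffices.
    """
    lo, hi = 1, 2
    while hi <= n_max and srj_power(hi, median_rearr_per_sample,
                                    recurrence_rate, tile_count,
                                    alpha_global) < power_target:
        lo, hi = hi, hi * 2
    if hi > n_max:
        return NOT_POWERED
    while lo < hi:
        mid = (lo + hi) // 2
        if srj_power(mid, median_rearr_per_sample, recurrence_rate,
                     tile_count, alpha_global) >= power_target:
            hi = mid
        else:
            lo = mid + 1
    return float(hi)


def detection_sensitivity_summary(sensitivity: np.ndarray,
                                  elements: Optional[Sequence[Element]] = None,
                                  positions: Optional[dict] = None
                                  ) -> pd.DataFrame:
    """Per-element summaries of a per-position sensitivity track.

    ``sensitivity`` is either a single per-base array (one element) or,
    with ``elements`` and ``positions`` given, looked up per element.
    Reports the mean sensitivity, the fraction of bases above 0.9 and
    the fraction below 0.1; the mean feeds min_detectable_frequency.
    """
    def summarize(name: str, s: np.ndarray) -> dict:
        s = np.asarray(s, dtype=float)
        if s.size == 0:
            raise ParameterError(f"element {name!r} has no bases")
        if np.any((s < 0) | (s > 1)):
            raise ParameterError("sensitivities must lie in [0, 1]")
        return dict(element=name, mean_sensitivity=float(s.mean()),
                    frac_above_0p9=float(np.mean(s > 0.9)),
                    frac_below_0p1=float(np.mean(s < 0.1)))

    if elements is None:
        return pd.DataFrame([summarize("track", sensitivity)])
    rows = []
    for el in elements:
        vals = []
        for chrom, start, end in el.intervals:
            arr = positions[chrom] if positions else sensitivity
            vals.append(arr[start:end])
        rows.append(summarize(el.id, np.concatenate(vals)))
    return pd.DataFrame(rows)


def monte_carlo_power(n: int, p_alt: float, k_star: int, n_rep: int,
                      rng: np.random.Generator) -> float:
    """Simulation estimate of binomial test power (independent oracle)."""
    draws = rng.binomial(n, p_alt, size=n_rep)
    return float(np.mean(draws >= k_star))
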
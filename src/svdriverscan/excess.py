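"""Negative-binomial-regression burden testing and excess-mutation estimation.

Background mutation rates are learned from a set of presumed-passenger
elements with a log-link negative binomial regression (covariates such
as local mutation rate, expression and copy number; offset = log element
length, optionally times cohort size), then element sets of interest are
tested for excess observed mutations.  The same machinery drives a
genome-wide scan over fixed-width windows (2 kb by default).

This is a simplified burden model: there is no trinucleotide-context
substitution model; rate heterogeneity enters only through the
covariates and the global dispersion theta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genome import Element, GenomeDef, MutationRecord, ParameterError, make_bins
from .stats import benjamini_hochberg, nb_sf, poisson_exact_ci


class FitError(RuntimeError):
    pass


@dataclass
class BurdenModel:
    """Fitted NB background: log mu = X beta + offset; var = mu + alpha mu^2."""

    coefficients: np.ndarray
    dispersion: float            # alpha (NB2); theta = 1/alpha
    covariate_names: list[str]

    def expected(self, covariates: Optional[np.ndarray], offsets: np.ndarray
                 ) -> np.ndarray:
        offsets = np.asarray(offsets, dtype=float)
        X = np.ones((len(offsets), 1))
        if covariates is not None and np.size(covariates):
            X = np.column_stack([X, np.asarray(covariates, dtype=float)])
        return np.exp(X @ self.coefficients + offsets)


def fit_nbr(counts: np.ndarray, covariates: Optional[np.ndarray],
            offsets: np.ndarray, min_elements: int = 100) -> BurdenModel:
    """Fit the passenger background regression by maximum likelihood.

    ``offsets`` are log exposures (log length, or log(length x cohort
    size)); elements with non-positive exposure must be excluded by the
    caller.  Fit SNVs and indels separately.
    """
    counts = np.asarray(counts)
    offsets = np.asarray(offsets, dtype=float)
    if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
        raise ParameterError("counts must be non-negative integers")
    if len(counts) < min_elements:
        raise ParameterError(
            f"need >= {min_elements} passenger elements, got {len(counts)}")
    X = np.ones((len(counts), 1))
    names: list[str] = []
    if covariates is not None and np.size(covariates):
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        X = np.column_stack([X, cov])
        names = [f"x{k}" for k in range(cov.shape[1])]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.NegativeBinomial(counts, X, offset=offsets,
                                      loglike_method="nb2").fit(
                disp=0, maxiter=200, method="bfgs")
        except Exception as exc:  # noqa: BLE001
            raise FitError(f"NB regression failed: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise FitError(f"NB regression did not converge: {res.mle_retvals}")
    alpha = float(res.params[-1])
    beta = np.asarray(res.params[:-1])
    if alpha < 1e-6 or not np.isfinite(alpha):
        pois = sm.GLM(counts, X, family=sm.families.Poisson(),
                      offset=offsets).fit()
        beta, alpha = np.asarray(pois.params), 0.0
    return BurdenModel(beta, alpha, names)


def burden_test(observed: np.ndarray, expected: np.ndarray, dispersion: float
                ) -> np.ndarray:
    """NB upper-tail p-value per element: P(X >= observed | mu, alpha)."""
    return nb_sf(np.asarray(observed), np.asarray(expected, dtype=float),
                 dispersion)


def count_in_elements(mutations: Sequence[MutationRecord],
                      elements: Sequence[Element],
                      var_types: Optional[set] = None) -> np.ndarray:
    """Mutation count per element (interval membership, all samples)."""
    counts = np.zeros(len(elements), dtype=int)
    muts = [m for m in mutations
            if var_types is None or m.var_type in var_types]
    for k, el in enumerate(elements):
        counts[k] = sum(el.contains(m.chrom, m.pos) for m in muts)
    return counts


def window_scan(genome: GenomeDef, mutations: Sequence[MutationRecord],
                model: BurdenModel, width: int = 2000,
                covariates: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Element-independent recurrence scan over fixed-width genome windows.

    Windows are tiled over the genome, counted, tested against the
    fitted background (offset = log window length) and BH-corrected
    within the scanned set.
    """
    bins = make_bins(genome, width)
    from .genome import BinIndex
    idx = BinIndex(bins)
    counts = np.zeros(len(bins), dtype=int)
    for m in mutations:
        j = idx.bin_of(m.chrom, m.pos)
        if j is not None:
            counts[j] += 1
    offsets = np.log([b.length for b in bins])
    mu = model.expected(covariates, offsets)
    p = burden_test(counts, mu, model.dispersion)
    q = benjamini_hochberg(p)
    return pd.DataFrame({
        "chrom": [b.chrom for b in bins],
        "start": [b.start for b in bins],
        "end": [b.end for b in bins],
        "observed": counts, "expected": mu, "p": p, "q": q,
    })


@dataclass
class ExcessReport:
    """Observed minus expected mutations over an element set, with CI."""

    observed: int
    expected: float
    excess: float
    ci_low: float
    ci_high: float
    conf: float = 0.95

    def as_dict(self) -> dict:
        return dict(observed=self.observed, expected=self.expected,
                    excess=self.excess, ci_low=self.ci_low,
                    ci_high=self.ci_high)


def excess_mutations(observed: int, expected: float, conf: float = 0.95
                     ) -> ExcessReport:
    """Excess (driver) mutations with an exact count-based interval.

    Uncertainty is attributed to the observed count only: the interval
    is the exact (Garwood) Poisson confidence interval on ``observed``,
    shifted by the fixed background expectation.
    """
    if observed < 0:
        raise ParameterError("observed must be non-negative")
    lo, hi = poisson_exact_ci(observed, conf)
    return ExcessReport(int(observed), float(expected),
                        float(observed - expected),
                        float(lo - expected), float(hi - expected), conf)


def excess_by_set(element_sets: dict[str, tuple[int, float]], conf: float = 0.95
                  ) -> pd.DataFrame:
    """Excess report per named element set from (observed, expected) pairs."""
    rows = []
    for name, (obs, exp) in element_sets.items():
        rep = excess_mutations(obs, exp, conf)
        rows.append(dict(element_set=name, **rep.as_dict()))
    return pd.DataFrame(rows)
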
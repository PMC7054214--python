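"""Multi-method p-value integration and candidate post-filtering.

Per cohort-element combination, p-values from multiple driver-discovery
methods are combined with Brown's method (Fisher's method generalized to
dependent tests via a moment-matched scaled chi-square); miscalibrated
methods are excluded first; FDR is controlled by Benjamini-Hochberg over
the concatenation of all cohorts; and surviving candidates are screened
with numeric filters against mutational-process artefacts (localized
APOBEC/AID/UV activity, palindromic DNA, unmappable regions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import MutationRecord
from .stats import benjamini_hochberg

log = logging.getLogger("svdriverscan")

P_FLOOR = 1e-300

LAMBDA_BOUNDS = (0.7, 1.5)
KS_MAX = 0.1
# rows whose leave-one-out median p falls below this are treated as
# likely signal and excluded from the calibration bulk
SIGNAL_EXCLUSION_MEDIAN = 0.05

Q_SIGNIFICANT = 0.1
Q_NEAR = 0.25

# post-filter thresholds; a candidate fails on the listed condition
FILTER_MIN_MUTATIONS = 3
FILTER_MIN_PATIENTS = 3
FILTER_MAPPABLE_MIN = 0.5      # fail if mappable fraction <= 0.5
FILTER_PALINDROME_MAX = 0.5    # fail if palindromic fraction >= 0.5
FILTER_APOBEC_MAX = 0.5        # fail if APOBEC-attributed fraction >= 0.5
FILTER_AID_MAX = 0.35          # lymphoid cohorts only
FILTER_UV_MAX = 0.5            # melanoma cohorts only

LYMPHOID_COHORTS = frozenset({"lymphoid", "lymph-bnhl", "lymph-cll", "lymph-nos"})
MELANOMA_COHORTS = frozenset({"melanoma", "skin-melanoma"})


def _chi2_median() -> float:
    return float(sps.chi2.ppf(0.5, 2))  # median of chi-square with 2 df


def calibrate_methods(matrix: pd.DataFrame,
                      lambda_bounds: tuple[float, float] = LAMBDA_BOUNDS,
                      ks_max: float = KS_MAX,
                      min_rows: int = 50) -> pd.DataFrame:
    """Per-method calibration QC against the uniform null.

    For each method column the inflation factor lambda is the median of
    -2 ln p divided by the chi-square(2 df) median, and a one-sample KS
    distance against U(0,1) is computed, over the presumed-null bulk.
    The bulk excludes rows that look like genuine signal to the OTHER
    methods (leave-one-out median p below 0.05): conditioning on the
    assessed method itself, or on a high median, would distort even a
    perfectly calibrated method.  Methods with lambda outside
    ``lambda_bounds`` or KS distance above ``ks_max`` are dropped.
    """
    methods = list(matrix.columns)
    rows = []
    for m in methods:
        p_all = matrix[m].dropna()
        others = matrix.drop(columns=m).median(axis=1, skipna=True)
        p = matrix.loc[others.isna() | (others > SIGNAL_EXCLUSION_MEDIAN),
                       m].dropna()
        low_coverage = len(p_all) < min_rows
        source = p if len(p) >= min_rows else p_all
        pv = np.clip(source.to_numpy(), P_FLOOR, 1.0)
        lam = float(np.median(-2.0 * np.log(pv)) / _chi2_median())
        ks = float(sps.kstest(pv, "uniform").statistic)
        keep = lambda_bounds[0] <= lam <= lambda_bounds[1] and ks <= ks_max
        rows.append(dict(method=m, n=len(p_all), n_null_bulk=len(p),
                         inflation_lambda=lam, ks_distance=ks,
                         low_coverage=low_coverage, keep=keep))
    report = pd.DataFrame(rows)
    if not report["keep"].any():
        raise ValueError(
            "all methods failed calibration; review lambda/KS thresholds")
    return report


def estimate_covariance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Covariance of the -2 ln p transforms across methods.

    Estimated over all rows with pairwise-complete observations; the
    matrix is projected to positive-semidefinite by clipping negative
    eigenvalues to zero.
    """
    t = -2.0 * np.log(matrix.clip(lower=P_FLOOR))
    cov = t.cov(min_periods=2)
    cov = cov.fillna(0.0)
    vals, vecs = np.linalg.eigh(cov.to_numpy())
    vals = np.clip(vals, 0.0, None)
    psd = vecs @ np.diag(vals) @ vecs.T
    psd = (psd + psd.T) / 2.0
    return pd.DataFrame(psd, index=cov.index, columns=cov.columns)


def brown_combine(pvals: pd.Series | dict, covariance: Optional[pd.DataFrame] = None
                  ) -> float:
    """Combine dependent p-values with Brown's method.

    X = sum of -2 ln p over the k observed methods has mean E = 2k and,
    allowing for dependence, variance V = 4k + 2 sum_{i<j} cov_ij.  The
    combined p-value is the upper tail of the scaled chi-square with
    scale c = V / (2E) and degrees of freedom f = 2 E^2 / V, evaluated
    at X / c.  With one method this is the identity; with zero
    covariance it reduces to Fisher's method.
    """
    s = pd.Series(pvals).dropna()
    if len(s) == 0:
        raise ValueError("no p-values to combine")
    clamped = s.clip(lower=P_FLOOR, upper=1.0)
    if (s <= 0).any():
        log.warning("brown_combine: p <= 0 clamped to %g", P_FLOOR)
    k = len(clamped)
    X = float(np.sum(-2.0 * np.log(clamped)))
    E = 2.0 * k
    V = 4.0 * k
    if covariance is not None and k > 1:
        names = list(clamped.index)
        sub = covariance.loc[names, names].to_numpy()
        V += 2.0 * float(np.triu(sub, 1).sum())
    V = max(V, 1e-12)
    c = V / (2.0 * E)
    f = 2.0 * E * E / V
    return float(sps.chi2.sf(X / c, f))


def combine_matrix(matrix: pd.DataFrame, covariance: Optional[pd.DataFrame] = None,
                   calibration: Optional[pd.DataFrame] = None) -> pd.Series:
    """Brown-combined p per row, after dropping miscalibrated methods."""
    if calibration is not None:
        keep = calibration.loc[calibration["keep"], "method"].tolist()
        matrix = matrix[keep]
        if covariance is not None:
            covariance = covariance.loc[keep, keep]
    if covariance is None:
        covariance = estimate_covariance(matrix)
    out = {}
    for idx, row in matrix.iterrows():
        r = row.dropna()
        if len(r) == 0:
            continue
        out[idx] = brown_combine(r, covariance)
    return pd.Series(out, name="p_brown")


def concat_fdr(combined: pd.Series) -> pd.DataFrame:
    """BH over the concatenated cohort-element p-values, with tiers."""
    q = benjamini_hochberg(combined.to_numpy())
    tier = np.where(q < Q_SIGNIFICANT, "significant",
                    np.where(q < Q_NEAR, "near", "ns"))
    return pd.DataFrame({"p": combined, "q": q, "tier": tier},
                        index=combined.index)


@dataclass
class FilterResult:
    flags: dict = field(default_factory=dict)    # name -> (passed|None, value)
    passed: bool = True
    not_evaluable: list[str] = field(default_factory=list)

    def reason_codes(self) -> list[str]:
        return [name for name, (ok, _) in self.flags.items() if ok is False]


def _is_lymphoid(cohort: str) -> bool:
    return cohort.lower() in LYMPHOID_COHORTS or cohort.lower().startswith("lymph")


def _is_melanoma(cohort: str) -> bool:
    return cohort.lower() in MELANOMA_COHORTS or "melanoma" in cohort.lower()


def apply_filters(mutations: Sequence[MutationRecord], cohort_type: str = ""
                  ) -> FilterResult:
    """Numeric post-filters for one candidate element.

    Fails when: fewer than 3 mutations; fewer than 3 distinct patients;
    mappable fraction <= 0.5; palindromic fraction >= 0.5; APOBEC
    fraction >= 0.5; AID fraction >= 0.35 in lymphoid cohorts; UV
    fraction >= 0.5 in melanoma cohorts.  Fractions are attributed
    mutations over total, where a mutation counts as attributed to a
    signature when that signature carries the largest share (>= 0.5 of
    its attribution mass).  Duplicating the mutation list leaves every
    fraction unchanged.
    """
    res = FilterResult()
    muts = list(mutations)
    n = len(muts)
    n_patients = len({m.sample_id for m in muts})
    res.flags["n_mutations"] = (bool(n >= FILTER_MIN_MUTATIONS), n)
    res.flags["n_patients"] = (bool(n_patients >= FILTER_MIN_PATIENTS), n_patients)
    if n == 0:
        for name in ("mappable_frac", "palindrome_frac", "apobec_frac",
                     "aid_frac", "uv_frac"):
            res.flags[name] = (None, np.nan)
            res.not_evaluable.append(name)
        res.passed = False
        return res

    mappable = np.mean([m.in_mappable for m in muts])
    palind = np.mean([m.in_palindrome for m in muts])
    res.flags["mappable_frac"] = (bool(mappable > FILTER_MAPPABLE_MIN), float(mappable))
    res.flags["palindrome_frac"] = (bool(palind < FILTER_PALINDROME_MAX), float(palind))

    def attributed_fraction(sig: str) -> float:
        return float(np.mean([m.signature_fraction(sig) >= 0.5 for m in muts]))

    has_sigs = any(m.signature_fractions for m in muts)
    if has_sigs:
        apo = attributed_fraction("APOBEC")
        res.flags["apobec_frac"] = (bool(apo < FILTER_APOBEC_MAX), apo)
    else:
        res.flags["apobec_frac"] = (None, np.nan)
        res.not_evaluable.append("apobec_frac")

    if _is_lymphoid(cohort_type):
        if has_sigs:
            aid = attributed_fraction("AID")
            res.flags["aid_frac"] = (bool(aid < FILTER_AID_MAX), aid)
        else:
            res.flags["aid_frac"] = (None, np.nan)
            res.not_evaluable.append("aid_frac")
    else:
        res.flags["aid_frac"] = (True, np.nan)

    if _is_melanoma(cohort_type):
        if has_sigs:
            uv = attributed_fraction("UV")
            res.flags["uv_frac"] = (bool(uv < FILTER_UV_MAX), uv)
        else:
            res.flags["uv_frac"] = (None, np.nan)
            res.not_evaluable.append("uv_frac")
    else:
        res.flags["uv_frac"] = (True, np.nan)

    # not-evaluable filters flag the candidate but only definite failures
    # veto it; the flag is carried into the ledger for manual review
    res.passed = all(ok is not False for ok, _ in res.flags.values())
    return res


def build_candidate_ledger(matrix: pd.DataFrame,
                           mutations_by_element: dict,
                           cohort_of_row,
                           covariance: Optional[pd.DataFrame] = None,
                           calibration: Optional[pd.DataFrame] = None
                           ) -> pd.DataFrame:
    """End-to-end candidate ledger: combine, tier, filter, re-FDR.

    ``matrix`` rows are cohort-element combinations, ``cohort_of_row``
    maps a row index to its cohort type, ``mutations_by_element`` maps a
    row index to that element's mutation list.  After filtering, the FDR
    is recalculated on the surviving candidates; final status is
    "significant" only for rows that are tiered significant, pass all
    applicable filters, and keep q < 0.1 after re-FDR.
    """
    combined = combine_matrix(matrix, covariance, calibration)
    tiers = concat_fdr(combined)
    rows = []
    for idx in tiers.index:
        muts = mutations_by_element.get(idx, [])
        cohort = cohort_of_row(idx) if callable(cohort_of_row) else cohort_of_row[idx]
        fr = apply_filters(muts, cohort)
        row = dict(row=idx, cohort=cohort, p=tiers.loc[idx, "p"],
                   q=tiers.loc[idx, "q"], tier=tiers.loc[idx, "tier"],
                   filters_pass=fr.passed,
                   filter_reasons=";".join(fr.reason_codes() + fr.not_evaluable))
        for name, (ok, val) in fr.flags.items():
            row[f"{name}_pass"] = ok
            row[f"{name}_value"] = val
        rows.append(row)
    ledger = pd.DataFrame(rows).set_index("row")
    survivors = ledger.index[ledger["filters_pass"]]
    ledger["q_refiltered"] = np.nan
    if len(survivors):
        q2 = benjamini_hochberg(combined.loc[survivors].to_numpy())
        ledger.loc[survivors, "q_refiltered"] = q2
    ledger["final_status"] = np.where(
        (ledger["tier"] == "significant") & ledger["filters_pass"]
        & (ledger["q_refiltered"] < Q_SIGNIFICANT),
        "significant", "rejected")
    return ledger
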
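"""Significantly recurrent breakpoint (SRB) detection.

Structural-variant breakpoints are binned genome-wide, counted with at
most one breakpoint per sample per bin, and tested against a
covariate-aware Gamma-Poisson (negative binomial) background whose
exposure is the number of mappable (eligible) bases per bin.  Bins
passing the FDR threshold are merged into disjoint loci, scored for
partner-breakpoint dispersion, and classified as fusion-like,
fragile-like, or copy-number driven.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genome import (BinIndex, CovariateTrack, GenomicBin, ParameterError,
                     Rearrangement)
from .stats import benjamini_hochberg, nb_sf

# bins with eligible fraction below this are excluded from fitting and
# testing: their exposure is too unstable for a rate model
MIN_ELIGIBLE_FRACTION = 0.10

FUSION_DISPERSION_THRESHOLD = 0.2
FRAGILE_TIMING_THRESHOLD = 0.5
COPY_NEUTRAL_BAND = 0.1


class FitError(RuntimeError):
    """Background regression failed; carries the optimizer trace message."""


class CollinearityError(ValueError):
    """Two covariates are (near-)perfectly correlated."""


@dataclass
class BackgroundModel:
    """Fitted Gamma-Poisson background: log mu = X beta + log(exposure)."""

    coefficients: np.ndarray      # intercept first, then one per covariate
    dispersion: float             # alpha >= 0; variance = mu + alpha mu^2
    covariate_names: list[str]
    deviance: float
    eligible_mask: np.ndarray     # bins retained for fitting/testing
    _design: np.ndarray = field(repr=False, default=None)
    _exposure: np.ndarray = field(repr=False, default=None)

    def predict_mu(self, design: Optional[np.ndarray] = None,
                   exposure: Optional[np.ndarray] = None) -> np.ndarray:
        X = self._design if design is None else design
        off = self._exposure if exposure is None else exposure
        return np.exp(X @ self.coefficients + np.log(off))

    def report(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": ["intercept"] + self.covariate_names,
            "coefficient": self.coefficients,
        })


def count_breakpoints(rearrs: Sequence[Rearrangement], bins: Sequence[GenomicBin],
                      index: Optional[BinIndex] = None) -> np.ndarray:
    """Per-bin deduplicated breakpoint counts.

    Both ends of every rearrangement are counted in their respective bins,
    but each sample contributes at most one breakpoint to any bin no
    matter how many of its breakpoints fall there.
    """
    idx = index or BinIndex(bins)
    seen: set[tuple[str, int]] = set()
    counts = np.zeros(len(bins), dtype=int)
    for r in rearrs:
        for bp in (r.bp1, r.bp2):
            j = idx.bin_of(bp.chrom, bp.pos)
            if j is None:
                continue
            key = (bp.sample_id, j)
            if key not in seen:
                seen.add(key)
                counts[j] += 1
    return counts


def _build_design(covariates: Sequence[CovariateTrack], n_bins: int) -> np.ndarray:
    X = np.ones((n_bins, 1 + len(covariates)))
    for k, cov in enumerate(covariates):
        v = np.where(cov.mask, np.nan, cov.values)
        X[:, 1 + k] = v
    return X


def _check_collinearity(X: np.ndarray, names: list[str]) -> None:
    cols = X[:, 1:]
    terms = ["intercept"] + names
    for a in range(cols.shape[1]):
        if np.std(cols[:, a]) == 0:
            raise CollinearityError(
                f"covariate {names[a]!r} is constant (collinear with intercept)")
    if cols.shape[1] >= 2:
        r = np.corrcoef(cols, rowvar=False)
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                if abs(r[a, b]) > 0.999:
                    raise CollinearityError(
                        f"covariates {names[a]!r} and {names[b]!r} are collinear "
                        f"(|r| = {abs(r[a, b]):.4f})")
    del terms


def fit_background(counts: np.ndarray, covariates: Sequence[CovariateTrack],
                   bins: Sequence[GenomicBin]) -> BackgroundModel:
    """Fit the Gamma-Poisson background regression by maximum likelihood.

    The mean is log-linear in the covariates with the log of the eligible
    base count as offset; a single global overdispersion alpha is
    estimated jointly (NB2 likelihood).  Bins with eligible exposure
    below 10% of their length are excluded.
    """
    counts = np.asarray(counts)
    if len(counts) != len(bins):
        raise ParameterError("counts and bins differ in length")
    eligible = np.array([b.eligible_bases for b in bins], dtype=float)
    lengths = np.array([b.length for b in bins], dtype=float)
    names = [c.name for c in covariates]
    X = _build_design(covariates, len(bins))
    keep = (eligible >= MIN_ELIGIBLE_FRACTION * lengths) & np.all(np.isfinite(X), axis=1)
    if keep.sum() < X.shape[1] + 1:
        raise FitError("too few eligible bins to fit the background")
    Xf, yf, ef = X[keep], counts[keep], eligible[keep]
    _check_collinearity(Xf, names)
    offset = np.log(ef)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            nb = sm.NegativeBinomial(yf, Xf, offset=offset, loglike_method="nb2")
            res = nb.fit(disp=0, maxiter=200, method="bfgs")
            alpha = float(res.params[-1])
            beta = np.asarray(res.params[:-1])
            converged = res.mle_retvals.get("converged", True)
        except Exception as exc:  # noqa: BLE001 - surfaced as FitError
            raise FitError(f"negative binomial fit failed: {exc}") from exc
    if not converged:
        raise FitError(f"background fit did not converge: {res.mle_retvals}")
    if alpha < 1e-6 or not np.isfinite(alpha):
        # boundary: overdispersion indistinguishable from Poisson
        pois = sm.GLM(yf, Xf, family=sm.families.Poisson(), offset=offset).fit()
        beta = np.asarray(pois.params)
        alpha = 0.0
        deviance = float(pois.deviance)
    else:
        mu = np.exp(Xf @ beta + offset)
        deviance = float(2 * np.sum(_nb_dev_resid(yf, mu, alpha)))
    model = BackgroundModel(beta, alpha, names, deviance, keep)
    model._design = X
    model._exposure = np.where(eligible > 0, eligible, np.nan)
    return model


def _nb_dev_resid(y, mu, alpha):
    y = np.asarray(y, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t2 = (y + 1 / alpha) * np.log((1 + alpha * y) / (1 + alpha * mu))
    return t1 - t2


def srb_pvalues(model: BackgroundModel, counts: np.ndarray,
                bins: Sequence[GenomicBin]) -> np.ndarray:
    """Upper-tail Gamma-Poisson p-value per bin; NaN for excluded bins."""
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ParameterError("observed counts must be non-negative")
    mu = model.predict_mu()
    p = np.full(len(bins), np.nan)
    ok = model.eligible_mask & np.isfinite(mu)
    p[ok] = nb_sf(counts[ok], mu[ok], model.dispersion)
    return p


@dataclass
class Locus:
    """A maximal run of adjacent significant bins."""

    chrom: str
    start: int
    end: int
    bin_indices: list[int]
    observed: int
    expected: float
    p_value: float
    q_value: float


def merge_loci(bins: Sequence[GenomicBin], counts: np.ndarray, p: np.ndarray,
               q: np.ndarray, model: BackgroundModel,
               q_threshold: float = 0.1) -> list[Locus]:
    """Merge adjacent significant bins (q < threshold) into disjoint loci.

    Locus statistics: min p over member bins, summed observed counts and
    summed (length-weighted) expected counts.
    """
    mu = model.predict_mu()
    sig = np.where(np.isfinite(q) & (q < q_threshold))[0]
    loci: list[Locus] = []
    run: list[int] = []
    for j in sig:
        if run and (j != run[-1] + 1 or bins[j].chrom != bins[run[-1]].chrom):
            loci.append(_close_run(run, bins, counts, p, q, mu))
            run = []
        run.append(j)
    if run:
        loci.append(_close_run(run, bins, counts, p, q, mu))
    return loci


def _close_run(run, bins, counts, p, q, mu) -> Locus:
    return Locus(
        chrom=bins[run[0]].chrom,
        start=bins[run[0]].start,
        end=bins[run[-1]].end,
        bin_indices=list(run),
        observed=int(counts[run].sum()),
        expected=float(np.nansum(mu[run])),
        p_value=float(np.nanmin(p[run])),
        q_value=float(np.nanmin(q[run])),
    )


def dispersion_score(locus: Locus, rearrs: Sequence[Rearrangement],
                     index: BinIndex) -> Optional[float]:
    """Normalized entropy of the partner-breakpoint bin distribution.

    For every rearrangement with a breakpoint inside the locus, the bin of
    the other-side breakpoint is collected; the score is the Shannon
    entropy of that bin frequency distribution divided by log(number of
    partner breakpoints).  0 means all partners hit one bin (fusion-like
    clustering); values near 1 mean every partner lands somewhere
    different (fragile-site scattering).  Undefined (None) with fewer
    than two partners.
    """
    partners: list[int] = []
    for r in rearrs:
        b1 = index.bin_of(r.bp1.chrom, r.bp1.pos)
        b2 = index.bin_of(r.bp2.chrom, r.bp2.pos)
        in1 = b1 in locus.bin_indices
        in2 = b2 in locus.bin_indices
        if in1 and b2 is not None:
            partners.append(b2)
        if in2 and not in1 and b1 is not None:
            partners.append(b1)
    n = len(partners)
    if n < 2:
        return None
    _, freq = np.unique(partners, return_counts=True)
    pk = freq / n
    entropy = -np.sum(pk * np.log(pk))
    return float(entropy / np.log(n))


def classify_srb(dispersion: Optional[float], mean_rep_timing: Optional[float],
                 cn_change: Optional[float] = None,
                 fusion_threshold: float = FUSION_DISPERSION_THRESHOLD,
                 fragile_threshold: float = FRAGILE_TIMING_THRESHOLD
                 ) -> tuple[str, list[str]]:
    """Classify a locus; returns (class, flags).

    Decision order: tightly clustered partners (dispersion <= threshold)
    -> fusion-like; else late replication (timing score > 0.5, with 1 =
    latest) -> fragile-like; else by sign of the mean copy-number change,
    with |change| < 0.1 copies called copy-neutral.
    """
    flags: list[str] = []
    if dispersion is not None and dispersion <= fusion_threshold:
        return "fusion-like", flags
    if dispersion is None:
        flags.append("no-dispersion-score")
    if mean_rep_timing is None:
        flags.append("unclassified-fragility")
        return "copy-neutral" if cn_change is None else _cn_class(cn_change), flags
    if mean_rep_timing > fragile_threshold:
        return "fragile-like", flags
    if cn_change is None:
        flags.append("no-copy-number")
        return "copy-neutral", flags
    return _cn_class(cn_change), flags


def _cn_class(cn_change: float) -> str:
    if abs(cn_change) < COPY_NEUTRAL_BAND:
        return "copy-neutral"
    return "amplification" if cn_change > 0 else "deletion"


def srb_scan(rearrs: Sequence[Rearrangement], bins: Sequence[GenomicBin],
             covariates: Sequence[CovariateTrack],
             rep_timing: Optional[CovariateTrack] = None,
             cn_change: Optional[dict[int, float]] = None,
             q_threshold: float = 0.1) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full SRB analysis: count, fit, test, merge, score, classify.

    Returns (per-bin table, per-locus table).
    """
    index = BinIndex(bins)
    counts = count_breakpoints(rearrs, bins, index)
    model = fit_background(counts, covariates, bins)
    p = srb_pvalues(model, counts, bins)
    ok = np.isfinite(p)
    q = np.full_like(p, np.nan)
    q[ok] = benjamini_hochberg(p[ok])
    mu = model.predict_mu()
    bin_table = pd.DataFrame({
        "chrom": [b.chrom for b in bins],
        "start": [b.start for b in bins],
        "end": [b.end for b in bins],
        "observed": counts,
        "expected": mu,
        "p": p,
        "q": q,
    })
    loci = merge_loci(bins, counts, p, q, model, q_threshold)
    rows = []
    for i, locus in enumerate(loci):
        disp = dispersion_score(locus, rearrs, index)
        timing = None
        if rep_timing is not None:
            vals = [rep_timing.values[j] for j in locus.bin_indices
                    if not rep_timing.mask[j]]
            timing = float(np.mean(vals)) if vals else None
        cn = None
        if cn_change is not None:
            cn_vals = [cn_change[j] for j in locus.bin_indices if j in cn_change]
            cn = float(np.mean(cn_vals)) if cn_vals else None
        cls, flags = classify_srb(disp, timing, cn)
        rows.append(dict(locus=f"srb_{i + 1}", chrom=locus.chrom,
                         start=locus.start, end=locus.end,
                         observed=locus.observed, expected=locus.expected,
                         p=locus.p_value, q=locus.q_value, dispersion=disp,
                         mean_rep_timing=timing, **{"class": cls},
                         flags=";".join(flags)))
    cols = ["locus", "chrom", "start", "end", "observed", "expected", "p",
            "q", "dispersion", "mean_rep_timing", "class", "flags"]
    locus_table = pd.DataFrame(rows, columns=cols)
    return bin_table, locus_table
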
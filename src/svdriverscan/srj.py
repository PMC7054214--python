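"""Significantly recurrent juxtaposition (SRJ) detection.

A juxtaposition is an unordered pair of genomic bins (a "tile" of the
two-dimensional fusion map) joined by a rearrangement.  Tiles with more
distinct samples than expected are detected with a binomial test against
a background that accounts for the break rate of each locus, the genomic
distance between them, and the relative propensity of break-invasion
versus two-break joining events, realized here as a two-component
mixture:

    score(i, j) = w * b_i * b_j  +  (1 - w) * (b_i + b_j) * g(d_ij)

with per-bin break rates b, an empirical intra-chromosomal distance
kernel g (log-spaced bins; inter-chromosomal pairs share a constant tail
mass), and mixture weight w fitted by maximum multinomial likelihood
over the observed tile assignments.  Scores are normalized so the
per-event tile probabilities p0 sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome import BinIndex, GenomicBin, ParameterError, Rearrangement
from .stats import benjamini_hochberg, binom_sf

DEFAULT_MIN_EVENT_LENGTH = 1000  # intra events shorter than this are dropped
W_GRID = np.round(np.arange(0.0, 1.0001, 0.05), 2)


@dataclass
class JuxtapositionBackground:
    """Normalized per-tile null probabilities p0 (symmetric matrix)."""

    p0: np.ndarray                # (n_bins, n_bins) symmetric, upper sum = 1
    w: float
    kernel_edges: np.ndarray      # log-spaced distance-bin edges (bp)
    kernel_values: np.ndarray     # g per distance bin
    g_inter: float

    def tile_p0(self, i: int, j: int) -> float:
        return float(self.p0[min(i, j), max(i, j)])


def filter_rearrangements(rearrs: Sequence[Rearrangement],
                          min_length: int = DEFAULT_MIN_EVENT_LENGTH
                          ) -> list[Rearrangement]:
    """Drop short intra-chromosomal events (likely artefacts)."""
    return [r for r in rearrs
            if not (r.intra and r.distance is not None and r.distance < min_length)]


def assign_tiles(rearrs: Sequence[Rearrangement], index: BinIndex
                 ) -> list[tuple[int, int, str]]:
    """(bin_i, bin_j, sample) per rearrangement, i <= j; off-genome skipped."""
    out = []
    for r in rearrs:
        b1 = index.bin_of(r.bp1.chrom, r.bp1.pos)
        b2 = index.bin_of(r.bp2.chrom, r.bp2.pos)
        if b1 is None or b2 is None:
            continue
        out.append((min(b1, b2), max(b1, b2), r.sample_id))
    return out


def count_tile_events(rearrs: Sequence[Rearrangement], index: BinIndex
                      ) -> dict[tuple[int, int], int]:
    """Distinct-sample event count per tile (one event per sample per tile)."""
    samples: dict[tuple[int, int], set[str]] = {}
    for i, j, s in assign_tiles(rearrs, index):
        samples.setdefault((i, j), set()).add(s)
    return {t: len(ss) for t, ss in samples.items()}


def _distance_matrix(bins: Sequence[GenomicBin]) -> np.ndarray:
    """Midpoint distance for intra-chromosomal bin pairs, NaN otherwise."""
    mids = np.array([b.midpoint for b in bins])
    chroms = np.array([b.chrom for b in bins])
    d = np.abs(mids[:, None] - mids[None, :])
    d[chroms[:, None] != chroms[None, :]] = np.nan
    return d


def fit_juxtaposition_background(rearrs: Sequence[Rearrangement],
                                 break_rates: np.ndarray,
                                 bins: Sequence[GenomicBin],
                                 index: Optional[BinIndex] = None,
                                 n_kernel_bins: int = 12,
                                 w_grid: np.ndarray = W_GRID
                                 ) -> JuxtapositionBackground:
    """Estimate the two-component juxtaposition background.

    ``break_rates`` are per-bin expected breakpoint rates (e.g. the SRB
    background's predicted means); bins with zero or missing rate get
    zero exposure and their tiles are removed from the testing universe.

    The mixture is parametrized with each component normalized to a
    probability distribution over tiles, so w is the fraction of events
    following the break-invasion (product-of-rates) component.  For
    each candidate w the distance kernel g is deconvolved from the
    per-distance-bin event counts by subtracting the factorized
    component's expected share, then the multinomial likelihood of the
    observed tile assignments selects w.
    """
    if len(rearrs) == 0:
        raise ParameterError("cannot estimate the background from zero rearrangements")
    b = np.asarray(break_rates, dtype=float)
    b = np.where(np.isfinite(b) & (b > 0), b, 0.0)
    if np.all(b == 0):
        raise ParameterError("all break rates are zero")
    b = b / b.sum()
    idx = index or BinIndex(bins)
    events = assign_tiles(rearrs, idx)
    if not events:
        raise ParameterError("no rearrangement maps onto the binning")
    n_ev = len(events)
    ev_idx = np.array([(i, j) for i, j, _ in events])

    dmat = _distance_matrix(bins)
    expose = (b[:, None] > 0) & (b[None, :] > 0)

    # distance bins: 0 = sub-bin-width (diagonal tiles, where short
    # intra events concentrate), 1..n_kernel = log-spaced, last = inter-
    # chromosomal.  Diagonal tiles get their own bin because the break-
    # joining propensity at near-zero distance is orders of magnitude
    # above the first log bin's average.
    tile_d = dmat[np.isfinite(dmat)]
    lo = max(tile_d[tile_d > 0].min() if np.any(tile_d > 0) else 1.0, 1.0)
    hi = max(tile_d.max(), lo * 2)
    edges = np.geomspace(lo * 0.999, hi * 1.001, n_kernel_bins + 1)
    n_bins_tot = n_kernel_bins + 2
    inter_bin = n_bins_tot - 1
    kbin = np.full(dmat.shape, inter_bin, dtype=int)
    finite = np.isfinite(dmat)
    kbin[finite] = np.clip(np.searchsorted(edges, dmat[finite], side="right"),
                           0, n_kernel_bins)

    outer = np.outer(b, b)
    outer[~expose] = 0.0
    P_f = _normalize_unordered(outer)
    A = b[:, None] + b[None, :]
    A[~expose] = 0.0

    # per-distance-bin aggregates over unordered tiles
    U_A = np.triu(A, 1) * 2.0 + np.diag(np.diag(A))
    U_Pf = np.triu(P_f, 1) * 2.0 + np.diag(np.diag(P_f))
    A_k = np.zeros(n_bins_tot)
    Pf_k = np.zeros(n_bins_tot)
    iu = np.triu_indices(len(bins), 0)
    np.add.at(A_k, kbin[iu], U_A[iu])
    np.add.at(Pf_k, kbin[iu], U_Pf[iu])
    ev_k = np.zeros(n_bins_tot)
    np.add.at(ev_k, kbin[ev_idx[:, 0], ev_idx[:, 1]], 1.0)

    best = None
    for w in w_grid:
        if w >= 1.0:
            p0 = P_f
            g_hat = np.zeros(n_bins_tot)
        else:
            # residual event mass per distance bin once the factorized
            # component's share is removed (half-count smoothing)
            resid = np.maximum((ev_k + 0.5) / (n_ev + 0.5 * n_bins_tot)
                               - w * Pf_k, 1e-12)
            with np.errstate(divide="ignore", invalid="ignore"):
                g_hat = np.where(A_k > 0, resid / A_k, 0.0)
            Pd = A * g_hat[kbin]
            Pd = _normalize_unordered(Pd)
            p0 = w * P_f + (1 - w) * Pd
        pe = p0[ev_idx[:, 0], ev_idx[:, 1]]
        if np.any(pe <= 0):
            continue
        ll = float(np.sum(np.log(pe)))
        if best is None or ll > best[0]:
            best = (ll, float(w), p0, g_hat)
    if best is None:
        raise ParameterError("background likelihood undefined for every w")
    _, w_hat, p0, g_hat = best
    return JuxtapositionBackground(p0, w_hat, edges,
                                   g_hat[1:n_kernel_bins + 1],
                                   float(g_hat[inter_bin]))


def _normalize_unordered(S: np.ndarray) -> np.ndarray:
    """Symmetric score matrix -> unordered-tile probabilities.

    An off-diagonal tile {i, j} aggregates both ordered cells (i,j) and
    (j,i), so it carries twice the score of a diagonal tile with the
    same cell value; the upper triangle (including the diagonal) then
    sums to one.
    """
    up = np.triu(S, 1) * 2.0 + np.diag(np.diag(S))
    up = up / up.sum()
    return up + np.triu(up, 1).T


def srj_test(observed: int, n_total: int, p0: float) -> float:
    """Binomial upper-tail p-value P(X >= observed | n_total, p0)."""
    if p0 <= 0:
        raise ParameterError("p0 must be positive")
    if not (0 <= observed <= n_total):
        raise ParameterError("observed must lie in [0, n_total]")
    return float(binom_sf(observed, n_total, min(p0, 1.0)))


def effect_size(observed: float, expected: float) -> float:
    """Ratio of observed to expected event counts."""
    if expected <= 0:
        raise ParameterError("expected must be positive")
    return observed / expected


def robustness_factor(observed: int, n_total: int, p0: float,
                      alpha_tile: float, rel_tol: float = 1e-3) -> Optional[float]:
    """Largest factor by which the background rate can grow while the
    tile stays significant at ``alpha_tile``.

    The binomial tail is monotone increasing in m * p0, so the supremum
    is found by bracketing and bisection.  None for non-significant
    tiles; capped at 1/p0 (the point where the inflated rate reaches 1).
    """
    if srj_test(observed, n_total, p0) > alpha_tile:
        return None
    m_cap = 1.0 / p0
    hi = 2.0
    while hi < m_cap and srj_test(observed, n_total, hi * p0) <= alpha_tile:
        hi *= 2.0
    if hi >= m_cap:
        if srj_test(observed, n_total, min(m_cap * p0, 1.0)) <= alpha_tile:
            return m_cap
        hi = m_cap
    lo = hi / 2.0
    while (hi - lo) / hi > rel_tol:
        mid = 0.5 * (lo + hi)
        if srj_test(observed, n_total, mid * p0) <= alpha_tile:
            lo = mid
        else:
            hi = mid
    return lo


def srj_scan(rearrs: Sequence[Rearrangement], bins: Sequence[GenomicBin],
             break_rates: np.ndarray, q_threshold: float = 0.1,
             min_length: int = DEFAULT_MIN_EVENT_LENGTH) -> pd.DataFrame:
    """Full SRJ analysis over all tiles with nonzero exposure.

    The multiple-testing universe is every tile whose two bins both have
    positive break rate; zero-event tiles enter with p = 1 analytically.
    """
    idx = BinIndex(bins)
    kept = filter_rearrangements(rearrs, min_length)
    if not kept:
        raise ParameterError("no rearrangements left after length filtering")
    bg = fit_juxtaposition_background(kept, break_rates, bins, idx)
    counts = count_tile_events(kept, idx)
    n_total = len(assign_tiles(kept, idx))
    upper = np.triu(bg.p0, 0)
    m_universe = int(np.sum(upper > 0))

    rows = []
    for (i, j), obs in sorted(counts.items()):
        p0 = bg.tile_p0(i, j)
        if p0 <= 0:
            continue
        exp = n_total * p0
        rows.append(dict(bin_i=i, bin_j=j, observed=obs, expected=exp,
                         p=srj_test(obs, n_total, p0), p0=p0))
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["q"] = benjamini_hochberg(table["p"].to_numpy(), m=max(m_universe, len(table)))
    table["effect_size"] = table["observed"] / table["expected"]
    sig = table["q"] < q_threshold
    # the attained BH cutoff: a significant tile stays significant while
    # its raw p remains below q_threshold * k / m (>= every significant
    # raw p by the step-up definition)
    m_eff = max(m_universe, len(table))
    alpha_tile = q_threshold * int(sig.sum()) / m_eff if sig.any() else np.nan
    table["robustness_factor"] = [
        robustness_factor(int(r.observed), n_total, r.p0, alpha_tile)
        if sig.loc[r.Index] else None
        for r in table.itertuples()
    ]
    table["chrom_i"] = [bins[i].chrom for i in table["bin_i"]]
    table["start_i"] = [bins[i].start for i in table["bin_i"]]
    table["chrom_j"] = [bins[j].chrom for j in table["bin_j"]]
    table["start_j"] = [bins[j].start for j in table["bin_j"]]
    table["intra"] = table["chrom_i"] == table["chrom_j"]
    cols = ["chrom_i", "start_i", "chrom_j", "start_j", "observed", "expected",
            "p", "q", "effect_size", "robustness_factor", "intra",
            "bin_i", "bin_j", "p0"]
    return table[cols].reset_index(drop=True)
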
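"""Synthetic-data generator with known ground truth.

Produces every input the toolkit consumes — rearrangements (BEDPE),
mutations and elements, covariate tracks, and method p-value matrices —
by inverting the generative assumptions of the corresponding tests:
per-bin Gamma-Poisson breakpoint counts over log-linear covariate
effects, the two-component juxtaposition mixture with a power-law
distance kernel, Poisson passenger mutations with planted driver
elements, and a Gaussian copula over method p-values.

The defaults describe a desk-scale study: a 30-Mb three-chromosome
genome at 100-kb bins, 200 tumour samples with ~20 rearrangements each,
moderate overdispersion (alpha = 0.1), and planted drivers hitting 3-5%
of samples — the regime in which recurrence tests must separate drivers
from fragile-site and mutational-process artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import (Breakpoint, CovariateTrack, Element, GenomeDef,
                     GenomicBin, MutationRecord, Rearrangement, make_bins)

COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class SimulationConfig:
    """All knobs of the generator; the seed is mandatory."""

    seed: int
    n_chroms: int = 3
    chrom_length: int = 10_000_000
    bin_width: int = 100_000
    # log-linear covariate effects on the breakpoint rate (per covariate)
    covariate_effects: tuple[float, ...] = (0.5, -0.3)
    baseline_log_rate: float = -11.0   # log breakpoints per eligible base
    overdispersion: float = 0.1        # alpha of the Gamma-Poisson
    n_samples: int = 200
    rearr_per_sample: float = 20.0
    mixture_w: float = 0.3
    kernel_exponent: float = 0.8       # g(d) ~ d^-exponent
    inter_fraction_scale: float = 1.0
    # spiked SRB loci: (bin index, n extra samples, regime)
    srb_spikes: tuple = ()
    # spiked SRJ pairs: (bin_i, bin_j, n recurrent samples)
    srj_spikes: tuple = ()
    # mutations
    n_elements: int = 60
    element_length: int = 1_000
    mutation_rate: float = 2e-6        # per base per sample
    driver_elements: tuple = ()        # (element index, patient frequency)
    indel_fraction: float = 0.1
    signature_regime: str = "generic"  # generic | lymphoid | melanoma | apobec
    # p-value matrix
    n_methods: int = 6
    n_rows: int = 400
    method_correlation: float = 0.3
    method_gamma: tuple[float, ...] = ()   # per-method distortion p -> p**gamma
    driver_rows: tuple = ()                # row indices given small p

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def default_genome(config: SimulationConfig) -> GenomeDef:
    names = tuple(f"chr{i + 1}" for i in range(config.n_chroms))
    return GenomeDef(names, tuple([config.chrom_length] * config.n_chroms))


def simulate_covariates(config: SimulationConfig, rng: np.random.Generator
                        ) -> tuple[list[CovariateTrack], CovariateTrack]:
    """Smooth standardized covariate tracks plus a mappability track.

    Covariates are random walks smoothed with a moving average and then
    z-scored; mappability is 1.0 for most bins with a tail of partially
    mappable bins, emulating repeat-rich regions.
    """
    genome = default_genome(config)
    n_bins = len(make_bins(genome, config.bin_width))
    tracks = []
    for k in range(len(config.covariate_effects)):
        raw = np.cumsum(rng.normal(size=n_bins))
        kernel = np.ones(9) / 9.0
        smooth = np.convolve(raw, kernel, mode="same")
        z = (smooth - smooth.mean()) / smooth.std()
        tracks.append(CovariateTrack(f"cov{k}", z))
    mapp = np.ones(n_bins)
    low = rng.random(n_bins) < 0.05
    mapp[low] = rng.uniform(0.0, 0.5, size=low.sum())
    return tracks, CovariateTrack("mappability", mapp)


def replication_timing_track(n_bins: int, rng: np.random.Generator
                             ) -> CovariateTrack:
    """Replication-timing score in [0, 1] (1 = latest replication)."""
    raw = np.cumsum(rng.normal(size=n_bins))
    smooth = np.convolve(raw, np.ones(15) / 15.0, mode="same")
    lo, hi = smooth.min(), smooth.max()
    return CovariateTrack("rep_timing", (smooth - lo) / (hi - lo + 1e-12))


def expected_rates(config: SimulationConfig, bins: Sequence[GenomicBin],
                   covariates: Sequence[CovariateTrack]) -> np.ndarray:
    """True per-bin expected breakpoint counts mu under the config."""
    eligible = np.array([b.eligible_bases for b in bins], dtype=float)
    eta = np.full(len(bins), config.baseline_log_rate)
    for beta, cov in zip(config.covariate_effects, covariates):
        eta = eta + beta * cov.values
    with np.errstate(divide="ignore"):
        return np.where(eligible > 0, np.exp(eta) * eligible, 0.0)


def simulate_nb_counts(mu: np.ndarray, alpha: float, rng: np.random.Generator
                       ) -> np.ndarray:
    """Per-bin Gamma-Poisson counts with mean mu and variance mu+alpha mu^2."""
    mu = np.asarray(mu, dtype=float)
    if alpha <= 0:
        return rng.poisson(mu)
    shape = 1.0 / alpha
    lam = mu * rng.gamma(shape, alpha, size=mu.shape)
    return rng.poisson(lam)


def _power_law_kernel(dist: np.ndarray, exponent: float) -> np.ndarray:
    return np.where(np.isfinite(dist), (np.maximum(dist, 1.0)) ** (-exponent), 0.0)


def true_tile_probabilities(config: SimulationConfig, bins: Sequence[GenomicBin],
                            rates: np.ndarray) -> np.ndarray:
    """Ground-truth symmetric p0 matrix under the mixture background."""
    b = np.where(rates > 0, rates, 0.0)
    b = b / b.sum()
    mids = np.array([x.midpoint for x in bins])
    chroms = np.array([x.chrom for x in bins])
    dist = np.abs(mids[:, None] - mids[None, :])
    dist[chroms[:, None] != chroms[None, :]] = np.nan
    G = _power_law_kernel(dist, config.kernel_exponent)
    # inter-chromosomal: flat mass comparable to the kernel tail
    tail = np.nanmin(G[G > 0]) if np.any(G > 0) else 1.0
    G[~np.isfinite(dist)] = tail * config.inter_fraction_scale
    from .srj import _normalize_unordered
    expose = (b[:, None] > 0) & (b[None, :] > 0)
    outer = np.outer(b, b)
    outer[~expose] = 0.0
    dist_comp = (b[:, None] + b[None, :]) * G
    dist_comp[~expose] = 0.0
    # each component normalized, so mixture_w is the fraction of events
    # following the product-of-rates (break-invasion) component
    return config.mixture_w * _normalize_unordered(outer) + \
        (1 - config.mixture_w) * _normalize_unordered(dist_comp)


def simulate_rearrangements(config: SimulationConfig,
                            rng: Optional[np.random.Generator] = None
                            ) -> tuple[list[Rearrangement], pd.DataFrame]:
    """Draw a cohort rearrangement set plus a truth table of planted drivers.

    Background events draw their tile from the true mixture p0 with
    per-bin gamma rate multipliers (producing the configured marginal
    overdispersion), then uniform positions within each bin.  Spiked SRB
    loci add one breakpoint per chosen sample, with the partner either
    fixed (fusion regime) or scattered; spiked SRJ pairs add one
    rearrangement per chosen sample joining the two bins.
    """
    rng = rng or config.rng()
    genome = default_genome(config)
    covs, mapp = simulate_covariates(config, rng)
    bins = make_bins(genome, config.bin_width, mapp)
    rates = expected_rates(config, bins, covs)
    if config.overdispersion > 0:
        mult = rng.gamma(1.0 / config.overdispersion, config.overdispersion,
                         size=len(bins))
        rates_eff = rates * mult
    else:
        rates_eff = rates
    p0 = true_tile_probabilities(config, bins, rates_eff)
    upper = np.triu(p0, 0)
    flat = upper.ravel()
    nz = np.flatnonzero(flat)
    probs = flat[nz] / flat[nz].sum()

    n_events = rng.poisson(config.n_samples * config.rearr_per_sample)
    choice = rng.choice(nz, size=n_events, p=probs)
    ii, jj = np.unravel_index(choice, p0.shape)
    samples = rng.integers(0, config.n_samples, size=n_events)
    sv_classes = np.array(["DEL", "DUP", "INV", "TRA"])

    rearrs: list[Rearrangement] = []

    def uniform_pos(bin_idx: int) -> int:
        b = bins[bin_idx]
        return int(rng.integers(b.start, b.end))

    def add_event(i: int, j: int, sample: str, sv: str = None):
        bi, bj = bins[i], bins[j]
        sv = sv or ("TRA" if bi.chrom != bj.chrom else str(rng.choice(sv_classes[:3])))
        bp1 = Breakpoint(bi.chrom, uniform_pos(i), sample)
        bp2 = Breakpoint(bj.chrom, uniform_pos(j), sample)
        rearrs.append(Rearrangement.canonical(bp1, bp2, sv, genome))

    for i, j, s in zip(ii, jj, samples):
        add_event(int(i), int(j), f"S{int(s):04d}")

    truth_rows = []
    for spike in config.srb_spikes:
        bin_idx, n_spike, regime = spike
        chosen = rng.choice(config.n_samples, size=n_spike, replace=False)
        fixed_partner = int(rng.integers(0, len(bins)))
        for s in chosen:
            partner = fixed_partner if regime == "fusion" else \
                int(rng.integers(0, len(bins)))
            add_event(bin_idx, partner, f"S{int(s):04d}")
        truth_rows.append(dict(
            kind="srb", bin_i=bin_idx,
            bin_j=fixed_partner if regime == "fusion" else -1,
            n_samples=n_spike, regime=regime))
    for i, j, n_rec in config.srj_spikes:
        chosen = rng.choice(config.n_samples, size=n_rec, replace=False)
        for s in chosen:
            add_event(i, j, f"S{int(s):04d}")
        truth_rows.append(dict(kind="srj", bin_i=i, bin_j=j,
                               n_samples=n_rec, regime="recurrent"))
    truth = pd.DataFrame(truth_rows,
                         columns=["kind", "bin_i", "bin_j", "n_samples", "regime"])
    return rearrs, truth


_SIG_REGIMES = {
    # per-mutation probability of being dominated by each signature
    "generic": {"APOBEC": 0.05, "AID": 0.0, "UV": 0.0},
    "apobec": {"APOBEC": 0.7, "AID": 0.0, "UV": 0.0},
    "lymphoid": {"APOBEC": 0.05, "AID": 0.5, "UV": 0.0},
    "melanoma": {"APOBEC": 0.05, "AID": 0.0, "UV": 0.7},
}

_BASES = np.array(list("ACGT"))


def _random_snv(rng) -> tuple[str, str]:
    ref = str(rng.choice(_BASES))
    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
    return ref, alt


def _draw_signatures(regime: str, rng) -> tuple:
    probs = _SIG_REGIMES[regime]
    fracs = {}
    for name, pr in probs.items():
        if pr > 0 and rng.random() < pr:
            fracs[name] = float(rng.uniform(0.6, 1.0))
    rest = 1.0 - sum(fracs.values())
    if rest > 0:
        fracs["other"] = rest
    return tuple(sorted(fracs.items()))


def simulate_elements(config: SimulationConfig, rng: np.random.Generator
                      ) -> list[Element]:
    """Non-overlapping fixed-length elements spread across the genome."""
    genome = default_genome(config)
    spacing = genome.total_length // (config.n_elements + 1)
    elements = []
    for k in range(config.n_elements):
        gpos = (k + 1) * spacing
        acc = 0
        for chrom, length in zip(genome.chrom_names, genome.chrom_lengths):
            if gpos < acc + length - config.element_length:
                start = gpos - acc
                elements.append(Element(
                    f"e{k:03d}", [(chrom, start, start + config.element_length)]))
                break
            acc += length
    return elements


def simulate_mutations(config: SimulationConfig,
                       rng: Optional[np.random.Generator] = None
                       ) -> tuple[list[MutationRecord], list[Element], pd.DataFrame]:
    """Passenger mutations per element plus planted driver elements.

    Passenger counts are Poisson(rate x length) per element per sample;
    each driver element listed in ``driver_elements`` receives one extra
    mutation in the stated fraction of patients.  Signature attribution
    follows the cohort regime so the integration filters are exercised.
    """
    rng = rng or config.rng()
    elements = simulate_elements(config, rng)
    muts: list[MutationRecord] = []

    def add_mut(el: Element, sample: str):
        chrom, start, end = el.intervals[0]
        pos = int(rng.integers(start, end))
        if rng.random() < config.indel_fraction:
            size = int(rng.integers(1, 9))
            ins = rng.random() < 0.5
            ref, alt = ("A", "A" + "".join(rng.choice(_BASES, size))) if ins \
                else ("A" + "".join(rng.choice(_BASES, size)), "A")
        else:
            ref, alt = _random_snv(rng)
        vt, ilen = MutationRecord.classify_alleles(ref, alt)
        muts.append(MutationRecord(
            chrom, pos, ref, alt, sample, vt, ilen,
            _draw_signatures(config.signature_regime, rng),
            in_mappable=bool(rng.random() > 0.02),
            in_palindrome=bool(rng.random() < 0.02)))

    lam = config.mutation_rate * config.element_length
    for el in elements:
        n_bg = rng.poisson(lam * config.n_samples)
        for _ in range(n_bg):
            add_mut(el, f"S{int(rng.integers(0, config.n_samples)):04d}")

    truth_rows = []
    for el_idx, freq in config.driver_elements:
        el = elements[el_idx]
        n_carriers = max(1, int(round(freq * config.n_samples)))
        carriers = rng.choice(config.n_samples, size=n_carriers, replace=False)
        for s in carriers:
            add_mut(el, f"S{int(s):04d}")
        truth_rows.append(dict(element=el.id, frequency=freq,
                               n_carriers=n_carriers))
    truth = pd.DataFrame(truth_rows, columns=["element", "frequency", "n_carriers"])
    return muts, elements, truth


def simulate_pvalue_matrix(config: SimulationConfig,
                           rng: Optional[np.random.Generator] = None
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlated method p-values via a Gaussian copula, with distortions.

    Null rows draw a multivariate normal with constant inter-method
    correlation and map each margin to U(0,1); per-method calibration
    distortion applies p -> p**gamma (gamma < 1 deflates significance,
    gamma > 1 inflates it).  Driver rows replace their uniforms with
    strongly small values.
    """
    rng = rng or config.rng()
    k = config.n_methods
    rho = config.method_correlation
    R = np.full((k, k), rho)
    np.fill_diagonal(R, 1.0)
    L = np.linalg.cholesky(R)
    z = rng.standard_normal((config.n_rows, k)) @ L.T
    u = sps.norm.cdf(z)
    gammas = config.method_gamma or tuple([1.0] * k)
    p = u ** np.asarray(gammas)
    for row in config.driver_rows:
        p[row] = (rng.uniform(0, 1, size=k)) ** 12
    cols = [f"m{j}" for j in range(k)]
    matrix = pd.DataFrame(p, columns=cols)
    matrix.index = [f"cohortA::el{i:04d}" for i in range(config.n_rows)]
    truth = pd.DataFrame(dict(row=list(config.driver_rows)))
    return matrix, truth


def random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_BASES, size=n))


def palindrome_mask(seq: str, arm: int = 6, max_loop: int = 8) -> np.ndarray:
    """Positions lying inside a DNA palindrome (hairpin-forming) arm.

    Slides every window of ``arm`` bases and checks whether its reverse
    complement occurs downstream within ``max_loop`` bases; matched arm
    positions on both sides are flagged.  Brute force, intended for
    small fixture sequences.
    """
    n = len(seq)
    mask = np.zeros(n, dtype=bool)
    for i in range(n - 2 * arm + 1):
        left_rc = _revcomp(seq[i:i + arm])
        for loop in range(0, max_loop + 1):
            j = i + arm + loop
            if j + arm > n:
                break
            if seq[j:j + arm] == left_rc:
                mask[i:i + arm] = True
                mask[j:j + arm] = True
    return mask


def _revcomp(s: str) -> str:
    return s.translate(COMPLEMENT)[::-1]
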
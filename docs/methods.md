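# Methods

This note records the models behind svdriverscan, the defaults and why
they were chosen, what the simulator does and does not emulate, and
the numerical choices a maintainer would otherwise have to reverse-
engineer from the code.

## Coordinates and units

All coordinates are 0-based half-open (BED/BEDPE native). MAF-like
mutation tables may be declared 1-based with an explicit flag; the
conversion is never guessed from the data. Bin widths, element lengths
and distances are in bp; mutation rates are per base per patient;
replication-timing scores are rescaled to [0, 1] with 1 = latest
replication.

## SRB: Gamma–Poisson breakpoint background

Breakpoint ends are binned (default width 100 kb, configurable — only
the SRJ tile size is canonical, so the SRB width is an explicit knob)
and counted with at most one breakpoint per sample per bin; both ends
of every rearrangement count in their respective bins. The background
is a negative binomial (NB2) regression

    log mu_b = beta0 + sum_k beta_k x_bk + log(eligible_b),
    Var(X_b) = mu_b + alpha * mu_b^2

fitted by maximum likelihood (statsmodels), with the mappable-base
count per bin as exposure. Covariates are pluggable rather than a
fixed set; the simulator's defaults are smooth z-scored tracks
standing in for replication timing, gene density and GC content. A
single global alpha absorbs unmodelled rate heterogeneity; per-bin
random effects are deliberately not modelled. Bins with eligible
exposure below 10% of their width are excluded from fitting and
testing — their rate estimates are dominated by the exposure
denominator. Collinear covariates (|r| > 0.999, or any constant
column) abort the fit with the offending pair named, and a fitted
alpha below 1e-6 falls back to the Poisson GLM.

Per-bin p-values are the exact NB upper tail P(X >= observed); BH
q-values are computed over eligible bins and adjacent significant bins
(Q < 0.1) merge into loci scored by min p, summed observed and summed
expected counts.

**Dispersion score and classification.** The score is the Shannon
entropy of the partner-breakpoint bin distribution divided by log of
the number of partners (undefined below 2 partners). The decision
tree runs: dispersion <= 0.2 -> fusion-like; else mean
replication-timing score > 0.5 -> fragile-like; else the sign of the
mean copy-number change, with |change| < 0.1 copies called
copy-neutral. The 0.2 fusion threshold and the entropy normalization
are package choices — the underlying concept (clustered partners
separate fusions from fragile scattering, late replication marks
fragility) fixes only the ordering of the tests. Missing inputs
produce an explicit `unclassified-fragility` / `no-copy-number` flag
rather than a silent default.

## SRJ: juxtaposition background

Events are assigned to unordered bin pairs ("tiles"); intra events
shorter than 1 kb are dropped as likely artefacts (configurable).
Counting is per sample per tile, mirroring the SRB dedup rule. The
null tile distribution is a two-component mixture

    p0 = w * Pf + (1 - w) * Pd,
    Pf ∝ b_i * b_j          (break followed by invasion),
    Pd ∝ (b_i + b_j) * g(d) (two breaks joined, distance-dependent),

with each component normalized to a probability distribution over
tiles, so w is directly the fraction of events following the
factorized component. Off-diagonal unordered tiles carry twice the
cell score of diagonal tiles (they aggregate two ordered cells). The
kernel g lives on log-spaced distance bins with two special bins:
sub-bin-width distances (diagonal tiles — near-zero-distance joining
is orders of magnitude more likely than the first log bin's average,
and lumping them together badly underestimates diagonal p0) and
inter-chromosomal pairs (one constant mass). For each w on a grid
(step 0.05) the kernel is deconvolved from the per-distance-bin event
counts by subtracting the factorized component's expected share
(half-count smoothing, floor 1e-12), and the multinomial likelihood of
the observed tile assignments selects w. A naive empirical kernel —
events per tile per distance bin — absorbs the factorized component's
own distance profile and drives the fitted w to zero, which is why the
deconvolution exists.

The test is the exact binomial upper tail with N = total events and
the tile's p0; observed counts are deduplicated per sample, which is
slightly conservative when one sample hits a tile repeatedly. The
multiple-testing universe is all tiles with nonzero exposure;
zero-event tiles contribute p = 1 analytically through the BH `m`
parameter. The robustness factor is found by bisection (1e-3 relative
tolerance) on the monotone map m -> P(Bin(N, m*p0) >= obs), against
the attained BH cutoff q_threshold * k / m_universe; it is capped at
1/p0, where the inflated background saturates.

## Brown's combination and post-filters

Methods are first screened on a presumed-null bulk — rows whose
leave-one-out median p (over the other methods) exceeds 0.05; rows
below that look like genuine signal to the other methods and are
excluded. Conditioning instead on a high all-method median distorts
even a perfectly calibrated method, which is why the bulk is defined
by exclusion of signal only. A method is dropped when its inflation
factor lambda = median(-2 ln p) / chi2_2-median leaves [0.7, 1.5] or
its KS distance to U(0,1) exceeds 0.1 (both configurable). Methods
with fewer than 50 rows are assessed on whatever is available and
flagged low-coverage.

Brown's method combines a row's k observed p-values as X = sum(-2 ln
p), E = 2k, V = 4k + 2 * sum_{i<j} cov(-2 ln p_i, -2 ln p_j), with the
covariance estimated pairwise-complete across all rows and projected
to positive semidefinite (negative eigenvalues clipped). The combined
p is the upper tail of the scaled chi-square with scale V/(2E) and
2E^2/V degrees of freedom at X; k = 1 reduces to the identity and
zero covariance to Fisher's method. p-values at or below zero are
clamped to 1e-300 with a warning. FDR is controlled by BH over the
concatenation of all cohorts; Q < 0.1 is significant and 0.1 <= Q <
0.25 near-significant.

Post-filters fail a candidate on: < 3 mutations, < 3 distinct
patients, mappable fraction <= 0.5, palindromic fraction >= 0.5,
APOBEC-attributed fraction >= 0.5, AID fraction >= 0.35 (lymphoid
cohorts), UV fraction >= 0.5 (melanoma cohorts). A mutation counts as
attributed to a signature when that signature carries >= 0.5 of its
attribution mass; fractions are invariant to duplicating the mutation
list. Filters whose annotations are missing are reported
not-evaluable and flag the candidate without vetoing it — the flag is
meant for manual review. After filtering, BH is recomputed on the
survivors and final significance requires the tier, the filters and
the re-FDR simultaneously.

## Burden, excess and power

The burden background is an NB2 regression of passenger-element
counts on covariates with log length (optionally times cohort size)
as offset — deliberately simplified: there is no trinucleotide-context
substitution model, so context-driven rate variation must be captured
by covariates and the global dispersion. This is a fidelity limit
relative to full context-aware burden callers. The genome-wide scan
tiles 2-kb windows, tests each against the fitted background and
BH-corrects within the scanned set.

Excess mutations are observed minus expected with the uncertainty
attributed to the observed count only: the exact Garwood Poisson
interval on the observed count, shifted by the (fixed) expectation.

Power: the per-patient background element probability is q0 = 1 -
(1 - rate)^L; a driver of population frequency f with detection
sensitivity s mutates an additional f*s*(1-q0) (union of independent
events, not simple addition). The critical count k* is the smallest k
with P(Bin(N, q0) >= k) <= alpha_global / n_tests (default global
budget 0.1), and the minimal detectable frequency is found by
bisection to 1e-5. SRJ power works the same way over the fusion-map
tiles with p0 = median rearrangements per sample spread uniformly over
tiles (or a supplied map). `samples_required` inverts by search; note
power is not monotone in N at fixed alpha because k* shifts
discretely, so the search returns the first N reaching the target.
For the same reason the minimal-frequency surface is locally sawtooth:
at a fixed k*, a slightly higher background rate itself contributes
events and *lowers* f*; monotonicity in the background is a
coarse-scale property between well-separated rates.

## The simulator

`svdriverscan.simulate` inverts each test's generative null and plants
configurable truth. Defaults describe a desk-scale study: 3
chromosomes of 10 Mb at 100-kb bins, 200 samples, ~20 rearrangements
per sample, overdispersion alpha = 0.1, mutation rate 2e-6 per base
per patient over 60 elements of 1 kb, six methods with correlation
0.3. Rearrangements draw their tile from the true mixture (power-law
kernel d^-0.8) with per-bin gamma rate multipliers producing the
configured marginal overdispersion; spiked SRB loci add one breakpoint
in each of n chosen samples with clustered ("fusion") or scattered
partners, and spiked SRJ pairs join two bins in n samples. Mutations
are Poisson passengers plus planted drivers in a fixed fraction of
patients, with signature attributions drawn by cohort regime
(generic / APOBEC-heavy / lymphoid AID-heavy / melanoma UV-heavy).
Method p-value matrices come from a Gaussian copula with per-method
distortion p -> p^gamma. A brute-force DNA palindrome annotator (arm
>= 6 bp, loop <= 8 bp) is included for building filter fixtures.

What the simulator does **not** emulate — and what passing tests
therefore do not establish about real cohorts: real covariate
structure (its tracks are smooth noise), sequence context and
signature composition beyond coarse attribution fractions, clustered
events from single catastrophic processes (chromothripsis,
chromoplexy), caller-specific artefacts, and inter-sample rate
heterogeneity beyond the gamma multipliers. One consequence shows up
in its own tests: because both ends of each event are counted and
partners cluster, the fitted SRB dispersion (~0.2) exceeds the
generated per-bin alpha (0.1) — the background model absorbs the
dependence, as intended, but parameter-recovery checks are therefore
run on directly simulated counts.

## Numerical and testing conventions

Count tails are computed exactly through scipy's nbinom/binom/poisson
survival functions (alpha < 1e-8 switches NB to Poisson); brute-force
pmf summation serves as the oracle in tests at 1e-10 relative
tolerance. BH ties keep input order; q is capped at 1. Discrete
upper-tail tests are conservative: the attained level at p < 0.01 is
roughly 0.008–0.009 when expected counts are 25–100 and drops to
~0.005 near expected count 1, so calibration checks run in the
large-expected-count regime where the nominal band is attainable, and
small-count conservatism (never anti-conservatism) is the expected
behaviour elsewhere. Stochastic tests fix their seeds; tolerances are
stated as ±3 SE of the quantity measured.

## Known limitations

- Breakpoint ends are treated as exchangeable; orientation is carried
  through I/O but unused by the statistics.
- The SRJ binomial treats events as independent draws; per-sample
  event-count variation makes hot tiles slightly overdispersed
  relative to the model.
- The covariance of -2 ln p is estimated from the same matrix being
  combined; with few rows this under-disperses Brown's null slightly.
- No SCNA segmentation, liftover, annotation against gene models, or
  reference-FASTA dependence; copy-number change per locus and
  signature attributions are consumed as inputs.
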
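"""Recurrent-breakpoint detection: counting, background fit, testing,
locus merging, dispersion scoring and classification."""

import numpy as np
import pytest

from svdriverscan.genome import (BinIndex, Breakpoint, CovariateTrack,
                                 GenomeDef, Rearrangement, make_bins)
from svdriverscan import srb
from svdriverscan.simulate import simulate_nb_counts
from svdriverscan.stats import benjamini_hochberg


def rearr(c1, p1, c2, p2, sample, sv="DEL"):
    return Rearrangement.canonical(Breakpoint(c1, p1, sample),
                                   Breakpoint(c2, p2, sample), sv)


class TestCounting:
    def test_one_sample_many_breakpoints_counts_once(self, small_bins):
        rs = [rearr("chr1", 10, "chr1", 20, "s1"),
              rearr("chr1", 30, "chr1", 40, "s1")]
        counts = srb.count_breakpoints(rs, small_bins)
        assert counts[0] == 1

    def test_three_samples_count_three(self, small_bins):
        rs = [rearr("chr1", 10, "chr2", 500_000, f"s{i}") for i in range(3)]
        counts = srb.count_breakpoints(rs, small_bins)
        assert counts[0] == 3

    def test_del_with_both_ends_in_one_bin(self, small_bins):
        rs = [rearr("chr1", 10, "chr1", 500, "s1")]
        counts = srb.count_breakpoints(rs, small_bins)
        assert counts[0] == 1

    def test_both_ends_counted_in_their_bins(self, small_bins):
        rs = [rearr("chr1", 10, "chr1", 150_000, "s1")]
        counts = srb.count_breakpoints(rs, small_bins)
        assert counts[0] == 1 and counts[1] == 1

    def test_doubling_rearrangements_leaves_counts_unchanged(self, small_bins,
                                                             sim_config):
        from svdriverscan.simulate import simulate_rearrangements
        rs, _ = simulate_rearrangements(sim_config)
        g = GenomeDef(("chr1", "chr2"), (5_000_000, 5_000_000))
        bins = make_bins(g, 100_000)
        once = srb.count_breakpoints(rs, bins)
        twice = srb.count_breakpoints(rs + rs, bins)
        assert np.array_equal(once, twice)


def _bins_with_tracks(n_bins, rng, width=10_000):
    g = GenomeDef(("chr1",), (n_bins * width,))
    bins = make_bins(g, width)
    x = rng.normal(size=n_bins)
    return g, bins, CovariateTrack("x", x)


class TestBackgroundFit:
    def test_poisson_truth_recovered(self, rng):
        # counts ~ Poisson(exp(b0 + b1 x) * exposure)
        g, bins, cov = _bins_with_tracks(10_000, rng)
        eta = -8.0 + 0.5 * cov.values + np.log([b.eligible_bases for b in bins])
        counts = rng.poisson(np.exp(eta))
        model = srb.fit_background(counts, [cov], bins)
        assert model.coefficients[0] == pytest.approx(-8.0, abs=0.05)
        assert model.coefficients[1] == pytest.approx(0.5, abs=0.05)
        assert model.dispersion < 0.02

    def test_overdispersion_recovered(self, rng):
        g, bins, cov = _bins_with_tracks(10_000, rng)
        mu = np.exp(-8.5 + 0.4 * cov.values) * \
            np.array([b.eligible_bases for b in bins])
        counts = simulate_nb_counts(mu, 0.5, rng)
        model = srb.fit_background(counts, [cov], bins)
        assert 0.4 <= model.dispersion <= 0.6

    def test_constant_covariate_collinear_with_intercept(self, rng):
        g, bins, _ = _bins_with_tracks(100, rng)
        const = CovariateTrack("c", np.ones(100))
        with pytest.raises(srb.CollinearityError):
            srb.fit_background(np.ones(100, dtype=int), [const], bins)

    def test_duplicated_covariates_detected(self, rng):
        g, bins, cov = _bins_with_tracks(200, rng)
        twin = CovariateTrack("twin", cov.values.copy())
        with pytest.raises(srb.CollinearityError, match="twin"):
            srb.fit_background(rng.poisson(1.0, 200), [cov, twin], bins)

    def test_low_exposure_bins_excluded(self, rng):
        g, bins, cov = _bins_with_tracks(500, rng)
        frac = np.ones(500)
        frac[:50] = 0.05  # below the 10% exposure floor
        mapp = CovariateTrack("m", frac)
        bins2 = make_bins(g, 10_000, mapp)
        counts = rng.poisson(2.0, 500)
        model = srb.fit_background(counts, [cov], bins2)
        assert model.eligible_mask.sum() == 450
        p = srb.srb_pvalues(model, counts, bins2)
        assert np.isnan(p[:50]).all()


class TestPValues:
    def test_zero_observed_gives_one(self, rng):
        g, bins, cov = _bins_with_tracks(500, rng)
        counts = rng.poisson(2.0, 500)
        counts[0] = 0
        model = srb.fit_background(counts, [cov], bins)
        p = srb.srb_pvalues(model, counts, bins)
        assert p[0] == 1.0

    def test_matches_nb_tail_of_fitted_model(self, rng):
        from scipy import stats as sps
        g, bins, cov = _bins_with_tracks(2000, rng)
        counts = simulate_nb_counts(np.full(2000, 5.0), 0.3, rng)
        model = srb.fit_background(counts, [cov], bins)
        p = srb.srb_pvalues(model, counts, bins)
        mu = model.predict_mu()
        size = 1.0 / model.dispersion
        want = sps.nbinom.sf(counts - 1, size, size / (size + mu))
        assert np.allclose(p, want, rtol=1e-10)


class TestMergeLoci:
    def _setup(self, qvals, rng):
        n = len(qvals)
        g, bins, cov = _bins_with_tracks(n, rng)
        counts = np.ones(n, dtype=int)
        model = srb.fit_background(counts * 0 + np.arange(n) % 3, [cov], bins)
        p = np.asarray(qvals)
        return bins, counts, p, np.asarray(qvals), model

    def test_adjacent_bins_merge(self, rng):
        q = np.array([0.01, 0.02, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5] * 10)
        bins, counts, p, q, model = self._setup(q, rng)
        loci = srb.merge_loci(bins, counts, p, q, model)
        assert len(loci) == 10
        assert loci[0].start == 0 and loci[0].end == 20_000

    def test_gap_splits_loci(self, rng):
        q = np.full(100, 0.9)
        q[[10, 12]] = 0.01  # separated by a non-significant bin
        bins, counts, p, q, model = self._setup(q, rng)
        loci = srb.merge_loci(bins, counts, p, q, model)
        assert len(loci) == 2

    def test_scattered_bins_stay_separate(self, rng):
        q = np.full(100, 0.9)
        q[[5, 20, 40, 60, 80]] = 0.01
        bins, counts, p, q, model = self._setup(q, rng)
        assert len(srb.merge_loci(bins, counts, p, q, model)) == 5


class TestDispersionScore:
    def _locus(self, bins):
        return srb.Locus("chr1", 0, 100_000, [0], 8, 1.0, 1e-5, 1e-4)

    def test_all_partners_one_bin_scores_zero(self, small_bins):
        rs = [rearr("chr1", 10 + i, "chr1", 500_000 + i, f"s{i}")
              for i in range(8)]
        idx = BinIndex(small_bins)
        score = srb.dispersion_score(self._locus(small_bins), rs, idx)
        assert score == pytest.approx(0.0)

    def test_all_partners_distinct_scores_one(self, small_bins):
        rs = [rearr("chr1", 10 + i, "chr1" if i < 4 else "chr2",
                    (100_000 * (i + 1) + 5) if i < 4 else (100_000 * (i - 4) + 5),
                    f"s{i}") for i in range(8)]
        idx = BinIndex(small_bins)
        score = srb.dispersion_score(self._locus(small_bins), rs, idx)
        assert score == pytest.approx(1.0)

    def test_two_partner_bins_entropy(self, small_bins):
        # 4 partners in one bin, 4 in another: log(2)/log(8) = 1/3
        rs = [rearr("chr1", 10 + i, "chr1", (500_000 if i < 4 else 700_000) + i,
                    f"s{i}") for i in range(8)]
        idx = BinIndex(small_bins)
        score = srb.dispersion_score(self._locus(small_bins), rs, idx)
        assert score == pytest.approx(np.log(2) / np.log(8))

    def test_fewer_than_two_partners_undefined(self, small_bins):
        rs = [rearr("chr1", 10, "chr1", 500_000, "s1")]
        idx = BinIndex(small_bins)
        assert srb.dispersion_score(self._locus(small_bins), rs, idx) is None


class TestClassification:
    def test_low_dispersion_is_fusion_like_regardless_of_timing(self):
        assert srb.classify_srb(0.1, 0.9)[0] == "fusion-like"

    def test_high_dispersion_late_timing_is_fragile(self):
        assert srb.classify_srb(0.8, 0.6)[0] == "fragile-like"

    def test_copy_number_branch(self):
        assert srb.classify_srb(0.8, 0.3, +1.4)[0] == "amplification"
        assert srb.classify_srb(0.8, 0.3, -0.8)[0] == "deletion"
        assert srb.classify_srb(0.8, 0.3, +0.05)[0] == "copy-neutral"

    def test_missing_timing_flagged(self):
        cls, flags = srb.classify_srb(0.8, None, +1.0)
        assert "unclassified-fragility" in flags


class TestTypeIError:
    def test_null_counts_are_calibrated_at_one_percent(self, rng):
        """Counts simulated from the fitted background give p < 0.01 at
        a rate consistent with nominal (discreteness makes the test
        conservative, never anti-conservative)."""
        g, bins, cov = _bins_with_tracks(10_000, rng)
        mu_true = np.exp(-7.5 + 0.3 * cov.values) * 10_000
        counts = simulate_nb_counts(mu_true, 0.2, rng)
        model = srb.fit_background(counts, [cov], bins)
        null = simulate_nb_counts(model.predict_mu(), model.dispersion, rng)
        p = srb.srb_pvalues(model, null, bins)
        frac = np.mean(p < 0.01)
        se = np.sqrt(0.01 * 0.99 / len(p))
        assert frac <= 0.01 + 3 * se
        assert frac >= 0.003  # not wildly conservative either
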
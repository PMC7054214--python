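"""Method calibration, Brown's combination, concatenated FDR and the
post-filter ledger."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from svdriverscan.genome import MutationRecord
from svdriverscan import integration as integ
from svdriverscan.simulate import SimulationConfig, simulate_pvalue_matrix


def make_mut(sample="s1", mappable=True, palindrome=False, sigs=()):
    return MutationRecord("chr1", 100, "A", "G", sample,
                          signature_fractions=sigs, in_mappable=mappable,
                          in_palindrome=palindrome)


class TestCalibration:
    def test_uniform_null_kept(self, rng):
        p = pd.DataFrame(rng.uniform(0, 1, (1000, 3)), columns=list("abc"))
        rep = integ.calibrate_methods(p)
        assert rep["keep"].all()
        assert np.allclose(rep["inflation_lambda"], 1.0, atol=0.25)

    def test_inflated_method_dropped(self, rng):
        u = rng.uniform(0, 1, (1000, 2))
        p = pd.DataFrame({"good": u[:, 0], "bad": u[:, 1] ** 2})
        rep = integ.calibrate_methods(p).set_index("method")
        # for p = U^2, E[-2 ln p] doubles: lambda ~ 2 > 1.5
        assert rep.loc["good", "keep"]
        assert not rep.loc["bad", "keep"]
        assert rep.loc["bad", "inflation_lambda"] > 1.5

    def test_sparse_method_flagged_low_coverage(self, rng):
        p = pd.DataFrame(rng.uniform(0, 1, (1000, 2)), columns=["a", "b"])
        p.loc[p.index[:960], "b"] = np.nan
        rep = integ.calibrate_methods(p).set_index("method")
        assert rep.loc["b", "low_coverage"]

    def test_all_dropped_raises(self, rng):
        u = rng.uniform(0, 1, 500)
        p = pd.DataFrame({"a": u ** 3, "b": u ** 4})
        with pytest.raises(ValueError, match="calibration"):
            integ.calibrate_methods(p)


class TestBrown:
    def test_single_method_identity(self):
        assert integ.brown_combine({"m": 0.03}) == pytest.approx(0.03, rel=1e-12)

    def test_fisher_worked_value(self):
        # two independent p = 0.05: X = -2 ln(0.0025), chi2 with 4 df
        got = integ.brown_combine({"a": 0.05, "b": 0.05})
        want = float(sps.chi2.sf(-2 * np.log(0.0025), 4))
        assert got == pytest.approx(want, rel=1e-12)
        assert got == pytest.approx(0.01747, abs=5e-5)

    def test_reduces_to_fisher_with_zero_covariance(self, rng):
        cov = pd.DataFrame(np.zeros((3, 3)), index=list("abc"),
                           columns=list("abc"))
        p = dict(zip("abc", rng.uniform(0, 1, 3)))
        got = integ.brown_combine(p, cov)
        fisher = float(sps.chi2.sf(-2 * np.sum(np.log(list(p.values()))), 6))
        assert got == pytest.approx(fisher, rel=1e-10)

    def test_perfectly_duplicated_methods_collapse(self):
        # duplicated columns have cov(-2 ln p) = 4: combining two copies
        # must reproduce the single-method p
        cov = pd.DataFrame(4.0 * np.ones((2, 2)), index=["a", "b"],
                           columns=["a", "b"])
        for p in (0.5, 0.05, 1e-4):
            got = integ.brown_combine({"a": p, "b": p}, cov)
            assert got == pytest.approx(p, rel=1e-6)

    def test_nonpositive_p_clamped(self):
        out = integ.brown_combine({"a": 0.0, "b": 0.5})
        assert 0 < out < 1e-100

    def test_combined_uniform_under_correlated_null(self):
        """Brown-combined p stays uniform for strongly dependent methods."""
        for seed, rho in [(1, 0.0), (2, 0.5), (3, 0.9)]:
            cfg = SimulationConfig(seed=seed, n_methods=5, n_rows=800,
                                   method_correlation=rho)
            matrix, _ = simulate_pvalue_matrix(cfg)
            cov = integ.estimate_covariance(matrix)
            combined = integ.combine_matrix(matrix, cov)
            ks = sps.kstest(combined.to_numpy(), "uniform")
            assert ks.pvalue > 0.01, f"rho={rho}: KS p={ks.pvalue}"


class TestCovariance:
    def test_psd_projection(self, rng):
        cfg = SimulationConfig(seed=5, n_methods=4, n_rows=300,
                               method_correlation=0.6)
        matrix, _ = simulate_pvalue_matrix(cfg)
        matrix.iloc[::7, 2] = np.nan  # force pairwise-complete estimation
        cov = integ.estimate_covariance(matrix)
        vals = np.linalg.eigvalsh(cov.to_numpy())
        assert np.all(vals >= -1e-10)
        # diagonal near var(-2 ln U) = 4
        assert np.allclose(np.diag(cov), 4.0, atol=1.5)


class TestConcatFdr:
    def test_tiers(self):
        s = pd.Series({"r1": 1e-5, "r2": 0.0005, "r3": 0.9})
        out = integ.concat_fdr(s)
        assert out.loc["r1", "tier"] == "significant"
        assert set(out["tier"]) <= {"significant", "near", "ns"}

    def test_tier_boundaries(self):
        # build q values directly around the 0.1 / 0.25 boundaries
        q = np.array([0.09, 0.17, 0.3])
        tier = np.where(q < integ.Q_SIGNIFICANT, "significant",
                        np.where(q < integ.Q_NEAR, "near", "ns"))
        assert list(tier) == ["significant", "near", "ns"]

    def test_concatenation_changes_m(self, rng):
        a = pd.Series(rng.uniform(0, 0.1, 20), index=[f"a{i}" for i in range(20)])
        b = pd.Series(rng.uniform(0.5, 1, 20), index=[f"b{i}" for i in range(20)])
        qa = integ.concat_fdr(a)["q"]
        qab = integ.concat_fdr(pd.concat([a, b]))["q"]
        assert not np.allclose(qa.to_numpy(), qab[a.index].to_numpy())


class TestFilters:
    def test_too_few_mutations(self):
        res = integ.apply_filters([make_mut("s1"), make_mut("s2")])
        assert not res.passed
        assert "n_mutations" in res.reason_codes()

    def test_too_few_patients(self):
        res = integ.apply_filters([make_mut("s1")] * 4)
        assert "n_patients" in res.reason_codes()

    def test_palindrome_fraction(self):
        muts = [make_mut(f"s{i}", palindrome=(i < 3)) for i in range(5)]
        res = integ.apply_filters(muts)  # 60% palindromic
        assert "palindrome_frac" in res.reason_codes()

    def test_apobec_fraction(self):
        muts = [make_mut(f"s{i}", sigs=(("APOBEC", 0.9),)) for i in range(3)] + \
               [make_mut("s3", sigs=(("other", 1.0),))]
        res = integ.apply_filters(muts)  # 75% APOBEC-attributed
        assert "apobec_frac" in res.reason_codes()

    def test_aid_only_in_lymphoid(self):
        muts = [make_mut(f"s{i}", sigs=(("AID", 0.9),) if i < 2 else
                         (("other", 1.0),)) for i in range(5)]
        # AID fraction 0.40: fails lymphoid threshold 0.35, passes elsewhere
        assert "aid_frac" in integ.apply_filters(muts, "Lymph-BNHL").reason_codes()
        assert integ.apply_filters(muts, "Liver-HCC").passed

    def test_duplication_invariance(self):
        muts = [make_mut(f"s{i}", mappable=(i % 2 == 0)) for i in range(6)]
        r1 = integ.apply_filters(muts)
        r2 = integ.apply_filters(muts + muts)
        for name in ("mappable_frac", "palindrome_frac"):
            assert r1.flags[name][1] == pytest.approx(r2.flags[name][1])

    def test_missing_annotations_flagged_not_evaluable(self):
        muts = [MutationRecord("chr1", i, "A", "G", f"s{i}") for i in range(4)]
        res = integ.apply_filters(muts)
        assert "apobec_frac" in res.not_evaluable


class TestLedger:
    def _inputs(self, rng):
        cfg = SimulationConfig(seed=9, n_methods=4, n_rows=120,
                               method_correlation=0.2,
                               driver_rows=(0, 1, 2))
        matrix, _ = simulate_pvalue_matrix(cfg)
        muts = {idx: [make_mut(f"s{i}", sigs=(("other", 1.0),))
                      for i in range(5)] for idx in matrix.index}
        return matrix, muts

    def test_refdr_equals_bh_on_survivors(self, rng):
        from svdriverscan.stats import benjamini_hochberg
        matrix, muts = self._inputs(rng)
        ledger = integ.build_candidate_ledger(matrix, muts, lambda idx: "")
        surv = ledger.index[ledger["filters_pass"]]
        combined = integ.combine_matrix(matrix)
        q2 = benjamini_hochberg(combined.loc[surv].to_numpy())
        assert np.allclose(ledger.loc[surv, "q_refiltered"].to_numpy(), q2)

    def test_final_status_requires_everything(self, rng):
        matrix, muts = self._inputs(rng)
        # knock out the filter for one driver row: single patient
        first = matrix.index[0]
        muts[first] = [make_mut("s1", sigs=(("other", 1.0),))] * 5
        ledger = integ.build_candidate_ledger(matrix, muts, lambda idx: "")
        assert ledger.loc[first, "final_status"] == "rejected"
        sig = ledger[ledger["final_status"] == "significant"]
        assert (sig["tier"] == "significant").all()
        assert sig["filters_pass"].all()
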
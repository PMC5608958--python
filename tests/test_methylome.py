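import numpy as np
import pandas as pd
import pytest

from conftest import make_table
from cpgdm import methylome
from cpgdm.methylome import (
    ConcordanceResult,
    call_dm,
    collapse_and_filter,
    concordance_r2,
)
from cpgdm.methylome import test_dm as dm_test  # alias: keep pytest from collecting it
from oracles import fisher_oracle


class TestCollapse:
    def test_additive_collapse_of_dyad(self):
        table = make_table(
            [("chr1", 100, "+", [3], [1]), ("chr1", 101, "-", [2], [2])],
            ["s1"], {"s1": "uncut"},
        )
        out = collapse_and_filter(table, min_cov=0)
        assert out.n_sites == 1
        assert out.sites.loc[0, "pos"] == 100
        assert out.meth[0, 0] == 5 and out.unmeth[0, 0] == 3
        assert not out.sites.loc[0, "one_sided"]

    def test_unpartnered_minus_keeps_own_position(self):
        table = make_table(
            [("chr1", 101, "-", [2], [2])], ["s1"], {"s1": "uncut"}
        )
        out = collapse_and_filter(table, min_cov=0)
        assert out.sites.loc[0, "pos"] == 101
        assert bool(out.sites.loc[0, "one_sided"])

    def test_every_sample_threshold_inclusive_at_five(self):
        samples = [f"s{i}" for i in range(6)]
        conditions = {s: ("uncut" if i < 3 else "cut") for i, s in enumerate(samples)}
        kept = make_table(
            [("chr1", 10, "+", [5, 7, 9, 6, 5, 8], [0, 0, 0, 0, 0, 0])],
            samples, conditions,
        )
        dropped = make_table(
            [("chr1", 10, "+", [4, 7, 9, 6, 5, 8], [0, 0, 0, 0, 0, 0])],
            samples, conditions,
        )
        assert collapse_and_filter(kept, min_cov=5).n_sites == 1
        assert collapse_and_filter(dropped, min_cov=5).n_sites == 0

    def test_pooled_scope_sums_samples(self):
        table = make_table(
            [("chr1", 10, "+", [2, 2], [0, 2])], ["a", "b"],
            {"a": "uncut", "b": "cut"},
        )
        assert collapse_and_filter(table, min_cov=5, scope="pooled").n_sites == 1
        assert collapse_and_filter(table, min_cov=5).n_sites == 0

    def test_absent_counts_fail_every_sample_filter(self):
        table = make_table(
            [("chr1", 10, "+", [6, np.nan], [2, np.nan])], ["a", "b"],
            {"a": "uncut", "b": "cut"},
        )
        assert collapse_and_filter(table, min_cov=5).n_sites == 0
        # pooled scope ignores the absent sample
        assert collapse_and_filter(table, min_cov=5, scope="pooled").n_sites == 1

    def test_empty_table(self):
        table = make_table([], ["s1"], {"s1": "uncut"})
        assert collapse_and_filter(table).n_sites == 0

    def test_unknown_scope_rejected(self, toy_table):
        with pytest.raises(ValueError):
            collapse_and_filter(toy_table, scope="sometimes")


class TestTestDM:
    def _single_site(self, mu, uu, mc, uc):
        return make_table(
            [("chr1", 50, "+", [mu, mc], [uu, uc])], ["u1", "c1"],
            {"u1": "uncut", "c1": "cut"},
        )

    def test_quoted_example_delta_and_p(self):
        res = dm_test(self._single_site(18, 2, 4, 16))
        assert res.loc[0, "delta_pp"] == pytest.approx(-70.0)
        assert res.loc[0, "p"] == pytest.approx(fisher_oracle(18, 2, 4, 16), abs=1e-12)

    def test_exchangeable_table(self):
        res = dm_test(self._single_site(7, 3, 7, 3))
        assert res.loc[0, "delta_pp"] == 0.0
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_small_table_exact_value(self):
        res = dm_test(self._single_site(3, 1, 1, 3))
        assert res.loc[0, "p"] == pytest.approx(34 / 70, abs=1e-12)

    def test_zero_coverage_condition_excluded(self):
        res = dm_test(self._single_site(0, 0, 5, 5))
        assert np.isnan(res.loc[0, "p"])
        assert res.loc[0, "reason"] == "zero_coverage"

    def test_replicates_are_pooled(self):
        table = make_table(
            [("chr1", 5, "+", [9, 9, 2, 2], [1, 1, 8, 8])],
            ["u1", "u2", "c1", "c2"],
            {"u1": "uncut", "u2": "uncut", "c1": "cut", "c2": "cut"},
        )
        res = dm_test(table)
        assert res.loc[0, "delta_pp"] == pytest.approx(-70.0)
        assert res.loc[0, "p"] == pytest.approx(fisher_oracle(18, 2, 4, 16), abs=1e-12)

    def test_logistic_lrt_branch(self):
        strong = dm_test(self._single_site(18, 2, 4, 16), method="logistic-lrt")
        null = dm_test(self._single_site(5, 5, 5, 5), method="logistic-lrt")
        assert 0 < strong.loc[0, "p"] < 1e-4
        assert null.loc[0, "p"] == pytest.approx(1.0)

    def test_unknown_method_rejected(self, toy_table):
        with pytest.raises(ValueError):
            dm_test(toy_table, method="magic")


class TestCallDM:
    @staticmethod
    def _frame(p, delta):
        return pd.DataFrame(
            {"chrom": ["chr1"], "pos": [1], "delta_pp": [delta], "p": [p],
             "reason": [""]}
        )

    def test_dm_hyper(self):
        out, summary = call_dm(self._frame(0.03, 25.0))
        assert bool(out.loc[0, "is_dm"])
        assert summary == {"n_tested": 1, "n_dm": 1, "n_hyper": 1, "n_hypo": 0}

    def test_fails_delta_threshold(self):
        out, _ = call_dm(self._frame(0.001, 15.0))
        assert not bool(out.loc[0, "is_dm"])

    def test_fails_q_threshold(self):
        out, _ = call_dm(self._frame(0.06, -70.0))
        assert not bool(out.loc[0, "is_dm"])

    def test_delta_threshold_strict(self):
        out, _ = call_dm(self._frame(0.001, 20.0))
        assert not bool(out.loc[0, "is_dm"])  # requires strictly greater

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            call_dm(self._frame(0.5, 0.0), q_threshold=1.5)
        with pytest.raises(ValueError):
            call_dm(self._frame(0.5, 0.0), delta_threshold=150)

    def test_q_is_bh_over_tested_sites(self):
        frame = pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "pos": [1, 2, 3],
                "delta_pp": [30.0, 30.0, 30.0],
                "p": [0.005, 0.02, 0.9],
                "reason": [""] * 3,
            }
        )
        out, _ = call_dm(frame)
        np.testing.assert_allclose(out["q"], [0.015, 0.03, 0.9])


class TestConcordance:
    def test_identical_vectors(self):
        a = {"s1": 0.0, "s2": 50.0, "s3": 100.0}
        res = concordance_r2(a, dict(a))
        assert res == ConcordanceResult(r2=pytest.approx(1.0), n=3)

    def test_quoted_value(self):
        a = {1: 0.0, 2: 50.0, 3: 100.0}
        b = {1: 10.0, 2: 60.0, 3: 90.0}
        assert concordance_r2(a, b).r2 == pytest.approx(0.9796, abs=2e-4)

    def test_disjoint_sites_error(self):
        with pytest.raises(ValueError, match="shared"):
            concordance_r2({1: 0.0}, {2: 0.0})

    def test_zero_variance_error(self):
        with pytest.raises(ValueError, match="variance"):
            concordance_r2({1: 5.0, 2: 5.0, 3: 5.0}, {1: 1.0, 2: 2.0, 3: 3.0})


def test_table_validation():
    with pytest.raises(ValueError, match="condition"):
        make_table([("chr1", 1, "+", [1], [1])], ["s1"], {})
    with pytest.raises(ValueError, match="negative"):
        make_table([("chr1", 1, "+", [-1], [1])], ["s1"], {"s1": "cut"})
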
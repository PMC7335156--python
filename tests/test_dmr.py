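import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from seedmeth import dmr
from seedmeth.dmr import (aggregate_windows, filter_and_merge,
                          gtest_pvalues, slim_qvalues, tile_windows,
                          window_starts, window_test)


def sample_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context",
                                       "n_meth", "n_unmeth"])


class TestTiling:
    def test_published_geometry(self):
        w = tile_windows({"c": 250})
        assert list(zip(w["start"], w["end"])) == [
            (0, 100), (50, 150), (100, 200), (150, 250), (200, 250)]

    def test_short_chromosome_single_window(self):
        w = tile_windows({"c": 80})
        assert list(zip(w["start"], w["end"])) == [(0, 80)]

    @given(length=st.integers(1, 5000))
    @settings(max_examples=100, deadline=None)
    def test_union_covers_chromosome(self, length):
        starts = window_starts(length, 100, 50)
        ends = np.minimum(starts + 100, length)
        covered = np.zeros(length, dtype=bool)
        for s, e in zip(starts, ends):
            covered[s:e] = True
        assert covered.all()

    def test_size_step_contract(self):
        with pytest.raises(ValueError):
            window_starts(100, 50, 100)


class TestAggregation:
    def test_depth_rule_and_pooling(self):
        a = [sample_frame([("c", 10, "+", "CG", 5, 0),
                           ("c", 20, "+", "CG", 4, 6),
                           ("c", 30, "+", "CG", 3, 2)])]
        b = [sample_frame([("c", 10, "+", "CG", 0, 5),
                           ("c", 20, "+", "CG", 0, 10),
                           ("c", 30, "+", "CG", 0, 5)])]
        win = aggregate_windows(a, b, "CG", {"c": 100})
        assert len(win) == 1
        assert win["n_cytosines"].iloc[0] == 3
        assert win["M_A"].iloc[0] == 12 and win["N_A"].iloc[0] == 20

    def test_low_depth_site_excluded_in_either_group(self):
        a = [sample_frame([("c", 10, "+", "CG", 5, 0),
                           ("c", 20, "+", "CG", 4, 0)])]  # cov 4 < 5
        b = [sample_frame([("c", 10, "+", "CG", 0, 5),
                           ("c", 20, "+", "CG", 0, 9)])]
        win = aggregate_windows(a, b, "CG", {"c": 100})
        assert win["n_cytosines"].iloc[0] == 1

    def test_pooled_level_not_mean_of_site_levels(self):
        a = [sample_frame([("c", 10, "+", "CG", 10, 0),
                           ("c", 20, "+", "CG", 0, 10)])]
        b = [sample_frame([("c", 10, "+", "CG", 5, 5),
                           ("c", 20, "+", "CG", 5, 5)])]
        win = aggregate_windows(a, b, "CG", {"c": 100})
        assert win["level_A"].iloc[0] == pytest.approx(50.0)

    def test_replicates_pool_within_group(self):
        a = [sample_frame([("c", 10, "+", "CG", 3, 0)]),
             sample_frame([("c", 10, "+", "CG", 2, 1)])]
        b = [sample_frame([("c", 10, "+", "CG", 1, 2)]),
             sample_frame([("c", 10, "+", "CG", 0, 3)])]
        win = aggregate_windows(a, b, "CG", {"c": 100})
        # each group pools to coverage 6 >= 5, so the site qualifies
        assert win["n_cytosines"].iloc[0] == 1
        assert win["N_A"].iloc[0] == 6

    def test_empty_context_yields_no_windows(self):
        a = [sample_frame([("c", 10, "+", "CG", 5, 0)])]
        b = [sample_frame([("c", 10, "+", "CG", 5, 0)])]
        win = aggregate_windows(a, b, "CHH", {"c": 100})
        assert win.empty


class TestWindowTest:
    def test_identical_counts_give_p_one(self):
        assert window_test([(30, 60)], [(30, 60)]) == 1.0

    def test_degenerate_all_unmethylated(self):
        assert window_test([(0, 50)], [(0, 40)]) == 1.0

    def test_single_replicate_equals_g_test(self):
        p = window_test([(90, 100)], [(10, 100)])
        oracle = stats.chi2_contingency([[90, 10], [10, 90]],
                                        correction=False,
                                        lambda_="log-likelihood").pvalue
        assert p == pytest.approx(oracle, abs=1e-12)

    def test_random_tables_match_g_test_oracle(self, rng):
        for _ in range(200):
            na, nb = rng.integers(5, 200, size=2)
            ma, mb = rng.integers(0, na + 1), rng.integers(0, nb + 1)
            p = window_test([(ma, na)], [(mb, nb)])
            tab = [[ma, na - ma], [mb, nb - mb]]
            if min(sum(r) for r in tab) == 0 or \
               min(sum(c) for c in zip(*tab)) == 0:
                assert p == 1.0
                continue
            oracle = stats.chi2_contingency(
                tab, correction=False, lambda_="log-likelihood").pvalue
            assert p == pytest.approx(oracle, abs=1e-9)

    def test_group_label_symmetry(self):
        assert window_test([(70, 100)], [(20, 80)]) == pytest.approx(
            window_test([(20, 80)], [(70, 100)]), abs=1e-15)

    def test_replicates_match_glm_likelihood_ratio(self):
        """Replicate-level binomial GLM (statsmodels) gives the same LR
        p-value as the pooled closed form."""
        import statsmodels.api as sm
        cases = [
            ([(30, 100), (25, 90)], [(50, 100), (60, 110)]),
            ([(5, 40), (9, 60)], [(12, 35), (20, 70)]),
            ([(0, 20), (3, 30)], [(8, 25), (2, 15)]),
        ]
        for counts_a, counts_b in cases:
            endog, exog = [], []
            for g, counts in ((0, counts_a), (1, counts_b)):
                for m, n in counts:
                    endog.append([m, n - m])
                    exog.append([1.0, g])
            full = sm.GLM(np.array(endog), np.array(exog),
                          family=sm.families.Binomial()).fit()
            null = sm.GLM(np.array(endog), np.array(exog)[:, :1],
                          family=sm.families.Binomial()).fit()
            lr = 2 * (full.llf - null.llf)
            oracle = stats.chi2.sf(lr, 1)
            assert window_test(counts_a, counts_b) == pytest.approx(
                oracle, abs=1e-8)

    def test_zero_coverage_group_rejected(self):
        with pytest.raises(ValueError):
            window_test([(0, 0)], [(5, 10)])

    def test_vectorised_nan_for_empty_group(self):
        p = gtest_pvalues([5, 5], [10, 10], [0, 5], [0, 10])
        assert np.isnan(p[0]) and not np.isnan(p[1])


class TestQvalues:
    def test_bh_hand_example(self):
        q = slim_qvalues(np.array([0.01, 0.02, 0.03]), pi0=1.0)
        assert q == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert slim_qvalues(np.ones(5)).tolist() == [1.0] * 5

    def test_pi0_one_equals_bh_exactly(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 200))
            p = rng.uniform(0, 1, size=n)
            q = slim_qvalues(p, pi0=1.0)
            bh = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(q, bh, rtol=0, atol=0)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_order_preserving(self, ps):
        p = np.array(ps)
        q = slim_qvalues(p)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_null_pi0_near_one(self, rng):
        p = rng.uniform(0, 1, size=5000)
        assert dmr.estimate_pi0(p) > 0.9

    def test_empty_input(self):
        assert slim_qvalues(np.array([])).size == 0


def window_row(chrom, start, end, diff, q, n_cyt=5, context="CG",
               n=200):
    return {"chrom": chrom, "start": start, "end": end, "context": context,
            "n_cytosines": n_cyt, "diff": diff, "q_value": q,
            "N_A": n, "N_B": n, "M_A": 0, "M_B": 0,
            "level_A": 0.0, "level_B": 0.0, "p_value": q}


class TestFilterAndMerge:
    def test_overlapping_bins_merge(self):
        w = pd.DataFrame([window_row("c", 0, 100, 40, 1e-5),
                          window_row("c", 50, 150, 30, 1e-4)])
        d = filter_and_merge(w)
        assert len(d) == 1
        assert (d["start"].iloc[0], d["end"].iloc[0]) == (0, 150)
        assert d["n_bins"].iloc[0] == 2

    def test_boundary_gap_merges(self):
        w = pd.DataFrame([window_row("c", 0, 100, 40, 1e-5),
                          window_row("c", 150, 250, 30, 1e-4)])
        d = filter_and_merge(w)
        assert len(d) == 1 and d["end"].iloc[0] == 250

    def test_gap_beyond_limit_splits(self):
        w = pd.DataFrame([window_row("c", 0, 100, 40, 1e-5),
                          window_row("c", 151, 251, 30, 1e-4)])
        assert len(filter_and_merge(w)) == 2

    def test_opposite_directions_never_merge(self):
        w = pd.DataFrame([window_row("c", 0, 100, 40, 1e-5),
                          window_row("c", 50, 150, -30, 1e-4)])
        d = filter_and_merge(w)
        assert len(d) == 2
        assert set(d["direction"]) == {"hyper", "hypo"}

    def test_filters_applied(self):
        w = pd.DataFrame([
            window_row("c", 0, 100, 40, 1e-5, n_cyt=2),   # too few Cs
            window_row("c", 200, 300, 20, 1e-5),          # diff < 25
            window_row("c", 400, 500, 40, 0.02),          # q > 0.01
            window_row("c", 600, 700, 40, 1e-5),          # passes
        ])
        d = filter_and_merge(w)
        assert len(d) == 1 and d["start"].iloc[0] == 600

    def test_weighted_mean_diff(self):
        w = pd.DataFrame([window_row("c", 0, 100, 40, 1e-5, n=300),
                          window_row("c", 50, 150, 28, 1e-4, n=100)])
        d = filter_and_merge(w)
        assert d["mean_diff"].iloc[0] == pytest.approx(
            (40 * 600 + 28 * 200) / 800)

    def test_merging_idempotent(self):
        w = pd.DataFrame([window_row("c", 0, 100, 40, 1e-5),
                          window_row("c", 50, 150, 42, 1e-6),
                          window_row("c", 300, 400, -30, 1e-3)])
        once = filter_and_merge(w)
        # re-present the DMRs as bins; merging must not change intervals
        again = filter_and_merge(pd.DataFrame([
            window_row(r["chrom"], r["start"], r["end"], r["mean_diff"],
                       r["min_q"]) for _, r in once.iterrows()]))
        assert list(again["start"]) == list(once["start"])
        assert list(again["end"]) == list(once["end"])

    def test_unsorted_input_rejected(self):
        w = pd.DataFrame([window_row("c", 100, 200, 40, 1e-5),
                          window_row("c", 0, 100, 40, 1e-5)])
        with pytest.raises(ValueError, match="sorted"):
            filter_and_merge(w)

    def test_diff_distribution_conserves_counts(self):
        w = pd.DataFrame([window_row("c", 0, 100, 40, 1e-5),
                          window_row("c", 300, 400, -30, 1e-3)])
        d = filter_and_merge(w)
        hist = dmr.diff_distribution(d)
        assert hist["n_dmrs"].sum() == len(d)
        hyper_only = d[d["direction"] == "hyper"]
        hist2 = dmr.diff_distribution(hyper_only)
        assert hist2.loc[hist2["diff_high"] <= 0, "n_dmrs"].sum() == 0
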
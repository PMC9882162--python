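"""Rank/Fisher tests, permutation machinery, tail enrichment, BH."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from nlrdivers.stats import (StatsError, balancing_selection_candidates,
                             bh_adjust, fisher_2x2, matched_perm_test,
                             perm_diff_test, rank_set_score, rank_sum_test,
                             tail_count_test)


class TestRankSum:
    def test_small_sample_exact_p(self):
        _, p = rank_sum_test([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_identical_multisets(self):
        _, p = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_shift_invariance(self):
        x, y = [1.0, 4.0, 2.5], [3.0, 6.0, 5.5, 7.0]
        s1, p1 = rank_sum_test(x, y)
        s2, p2 = rank_sum_test([v + 100 for v in x], [v + 100 for v in y])
        assert (s1, p1) == (s2, p2)

    def test_empty_group_errors(self):
        with pytest.raises(StatsError):
            rank_sum_test([], [1, 2])


class TestFisher:
    def test_balanced_table(self):
        odds, p = fisher_2x2([[5, 5], [5, 5]])
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        table = [[1, 9], [11, 3]]
        _, p = fisher_2x2(table)
        # enumerate all tables with the observed margins
        a_obs = 1
        row1, row2 = 10, 14
        col1 = 12
        N = row1 + row2
        probs = {a: hypergeom.pmf(a, N, row1, col1)
                 for a in range(max(0, col1 - row2), min(row1, col1) + 1)}
        p_exp = sum(v for v in probs.values()
                    if v <= probs[a_obs] * (1 + 1e-12))
        assert p == pytest.approx(p_exp, rel=1e-9)

    def test_transpose_invariance(self):
        t = [[2, 8], [9, 4]]
        assert fisher_2x2(t)[1] == pytest.approx(
            fisher_2x2(np.transpose(t))[1])

    def test_degenerate_margin_errors(self):
        with pytest.raises(StatsError):
            fisher_2x2([[0, 0], [3, 4]])


def exhaustive_diff_p(values, labels, stat, tail="two-sided"):
    """Test-local enumeration over all label assignments."""
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    uniq = sorted(set(labels.tolist()))
    n_a = int(np.sum(labels == uniq[0]))
    fn = np.mean if stat == "mean" else np.median
    obs = fn(values[labels == uniq[0]]) - fn(values[labels != uniq[0]])
    null = []
    for combo in itertools.combinations(range(len(values)), n_a):
        sel = np.zeros(len(values), bool)
        sel[list(combo)] = True
        null.append(fn(values[sel]) - fn(values[~sel]))
    null = np.array(null)
    if tail == "two-sided":
        return np.mean(np.abs(null) >= abs(obs) - 1e-12)
    return np.mean(null >= obs - 1e-12)


class TestPermDiff:
    def test_identical_values_give_p_one(self):
        res = perm_diff_test([3.0] * 8, ["a"] * 4 + ["b"] * 4, seed=1)
        assert res.observed == 0.0
        assert res.p_value == 1.0

    def test_exhaustive_agrees_with_enumeration_oracle(self, rng):
        for stat in ("mean", "median"):
            for _ in range(5):
                vals = rng.normal(size=6)
                labels = np.array(["a"] * 3 + ["b"] * 3)
                res = perm_diff_test(vals, labels, stat=stat, seed=7)
                assert res.exhaustive
                assert res.n_replicates == 20
                assert res.p_value == pytest.approx(
                    exhaustive_diff_p(vals, labels, stat), abs=1e-12)

    def test_exhaustive_switch_threshold(self, rng):
        # C(12, 6) = 924 <= 10,000 -> exhaustive even if fewer requested
        vals = rng.normal(size=12)
        labels = ["a"] * 6 + ["b"] * 6
        res = perm_diff_test(vals, labels, n_replicates=50, seed=3)
        assert res.exhaustive and res.n_replicates == 924
        # C(30, 15) >> 10,000 -> Monte Carlo
        vals = rng.normal(size=30)
        labels = ["a"] * 15 + ["b"] * 15
        res = perm_diff_test(vals, labels, n_replicates=200, seed=3)
        assert not res.exhaustive and res.n_replicates == 200

    def test_seeded_reproducibility(self, rng):
        vals = rng.normal(size=40)
        labels = ["a"] * 10 + ["b"] * 30
        r1 = perm_diff_test(vals, labels, n_replicates=500, seed=42)
        r2 = perm_diff_test(vals, labels, n_replicates=500, seed=42)
        assert r1.p_value == r2.p_value

    def test_add_one_variant_never_zero(self, rng):
        vals = np.concatenate([np.zeros(12), np.full(12, 50.0)])
        labels = ["a"] * 12 + ["b"] * 12
        res = perm_diff_test(vals, labels, n_replicates=99, seed=0,
                             add_one=True)
        assert res.p_value >= 1 / (res.n_replicates + 1)

    def test_power_with_one_sd_effect(self, rng):
        """Group effect of 1 SD at sizes 15 vs 150 is detected at
        alpha=0.05 in the large majority of datasets (sanity floor)."""
        n_datasets, hits = 500, 0
        for _ in range(n_datasets):
            a = rng.normal(1.0, 1.0, size=15)
            b = rng.normal(0.0, 1.0, size=150)
            res = perm_diff_test(
                np.concatenate([a, b]), ["a"] * 15 + ["b"] * 150,
                n_replicates=300, seed=int(rng.integers(2**31)))
            hits += res.p_value < 0.05
        assert hits / n_datasets > 0.80


class TestMatchedPerm:
    def _table(self, rng, n_pool=300, n_target=12, confounded=True):
        cov = rng.uniform(0, 100, size=n_pool + n_target)
        resp = 0.5 * cov * confounded + rng.normal(0, 5.0,
                                                   size=n_pool + n_target)
        ids = [f"g{i}" for i in range(n_pool + n_target)]
        return pd.DataFrame({"gene_id": ids, "resp": resp, "cov": cov}), \
            ids[:n_target]

    def test_target_at_pool_minimum_gives_p_zero(self, rng):
        table, targets = self._table(rng, confounded=False)
        table.loc[table["gene_id"].isin(targets), "resp"] = -1e9
        res = matched_perm_test(table, targets, "resp", "cov",
                                n_replicates=200, seed=5, tail="less")
        assert res.p_value == 0.0

    def test_seeded_reproducibility(self, rng):
        table, targets = self._table(rng)
        kw = dict(n_replicates=300, seed=11, tail="two-sided")
        assert matched_perm_test(table, targets, "resp", "cov", **kw).p_value \
            == matched_perm_test(table, targets, "resp", "cov", **kw).p_value

    def test_matching_corrects_covariate_confounding(self, rng):
        """Targets sampled from the high-covariate region (but inside the
        pool's support) inherit high responses through the covariate; the
        matched null absorbs that bias, the naive permutation does not."""
        n_rej_matched = n_rej_naive = 0
        n_sets = 60
        for _ in range(n_sets):
            cov = rng.uniform(0, 100, size=312)
            resp = 0.5 * cov + rng.normal(0, 2.0, size=312)
            order = np.argsort(cov)
            ids = np.array([f"g{i}" for i in range(312)])
            table = pd.DataFrame({"gene_id": ids, "resp": resp, "cov": cov})
            # random 12 from the top covariate third
            targets = rng.choice(ids[order[-100:]], size=12, replace=False)
            m = matched_perm_test(table, targets, "resp", "cov",
                                  n_replicates=300,
                                  seed=int(rng.integers(2**31)),
                                  tail="greater")
            labels = np.isin(ids, targets)
            naive = perm_diff_test(resp, np.where(labels, "t", "p"),
                                   n_replicates=300,
                                   seed=int(rng.integers(2**31)),
                                   tail="greater",
                                   group_order=("t", "p"))
            n_rej_matched += m.p_value < 0.05
            n_rej_naive += naive.p_value < 0.05
        assert n_rej_naive == n_sets            # confounding alone rejects
        assert n_rej_matched < 0.3 * n_sets     # matching absorbs it


class TestTailCount:
    def test_exact_top_subset(self, rng):
        vals = pd.Series(rng.normal(size=200),
                         index=[f"g{i}" for i in range(200)])
        top = vals.nlargest(10).index.tolist()
        res = tail_count_test(vals, top, percentile=0.05, direction="top",
                              n_replicates=500, seed=2)
        assert res.observed_in_tail == 10
        assert res.p_value == 0.0

    def test_expected_count(self, rng):
        vals = pd.Series(rng.normal(size=400),
                         index=[f"g{i}" for i in range(400)])
        res = tail_count_test(vals, vals.index[:20].tolist(),
                              percentile=0.05, n_replicates=100, seed=3)
        assert res.expected_in_tail == pytest.approx(1.0)

    def test_random_subsets_center_on_expected(self, rng):
        vals = pd.Series(rng.normal(size=500),
                         index=[f"g{i}" for i in range(500)])
        observed = []
        for _ in range(1000):
            subset = rng.choice(vals.index, size=20, replace=False)
            res = tail_count_test(vals, subset.tolist(), percentile=0.05,
                                  n_replicates=10, seed=1)
            observed.append(res.observed_in_tail)
        mean = np.mean(observed)
        se = np.std(observed, ddof=1) / math.sqrt(len(observed))
        assert abs(mean - 1.0) < 3 * se + 0.05

    def test_bottom_direction(self, rng):
        vals = pd.Series(np.arange(100.0),
                         index=[f"g{i}" for i in range(100)])
        res = tail_count_test(vals, ["g0", "g1", "g2"], percentile=0.05,
                              direction="bottom", n_replicates=300, seed=4)
        assert res.observed_in_tail == 3
        assert res.p_value == 0.0


class TestBalancingSelection:
    def test_requires_both_tails(self, rng):
        idx = [f"g{i}" for i in range(100)]
        pi = pd.Series(np.arange(100.0), index=idx)
        d = pd.Series(rng.permutation(100.0 * np.arange(100) / 99),
                      index=idx)
        hits = balancing_selection_candidates(pi, d, percentile=0.95)
        top_pi = set(idx[95:])
        top_d = set(d.nlargest(5).index)
        assert set(hits) == top_pi & top_d
        # top in pi but median in d is never a candidate
        mid_d = d.rank().sub(50).abs().idxmin()
        if mid_d in top_pi:
            assert mid_d not in hits

    def test_empty_intersection(self):
        idx = list("abcdefghij")
        pi = pd.Series(np.arange(10.0), index=idx)
        d = pd.Series(np.arange(10.0)[::-1], index=idx)
        assert balancing_selection_candidates(pi, d, 0.95) == []


class TestRankSetScore:
    def test_extreme_sets(self, rng):
        vals = pd.Series(rng.normal(size=50),
                         index=[f"g{i}" for i in range(50)])
        top = vals.nlargest(5).index.tolist()
        bottom = vals.nsmallest(5).index.tolist()
        assert rank_set_score(vals, top, n_replicates=50,
                              seed=1).observed == pytest.approx(1.0)
        assert rank_set_score(vals, bottom, n_replicates=50,
                              seed=1).observed == pytest.approx(0.0)

    def test_random_sets_center_on_half(self, rng):
        vals = pd.Series(rng.normal(size=200),
                         index=[f"g{i}" for i in range(200)])
        scores = [
            rank_set_score(vals,
                           rng.choice(vals.index, 10, replace=False).tolist(),
                           n_replicates=10, seed=1).observed
            for _ in range(1000)
        ]
        se = np.std(scores, ddof=1) / math.sqrt(len(scores))
        assert abs(np.mean(scores) - 0.5) < 3 * se + 0.01


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_hand_computed_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(size=25)
        assert np.all(bh_adjust(p) >= p - 1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(StatsError):
            bh_adjust([0.5, 1.2])
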
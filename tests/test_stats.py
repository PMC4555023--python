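"""Nonparametric tests against brute-force enumeration oracles."""

from itertools import combinations, product

import numpy as np
import pytest
from scipy.stats import rankdata

from h2sync import (
    linear_r2,
    load_index_table,
    mann_whitney_u,
    group_stats_report,
    spearman_corr,
    wilcoxon_signed_rank,
)
from h2sync.stats import DegenerateTestError


def exact_wilcoxon_p(diffs):
    """Enumerate all 2^n sign assignments of the ranked |differences|."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    dist = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in product([0, 1], repeat=len(d))
    ]
    dist = np.asarray(dist)
    p = 2 * min(np.mean(dist <= w_obs), np.mean(dist >= w_obs))
    return min(p, 1.0)


def exact_mannwhitney_p(a, b):
    """Enumerate all C(n+m, n) group assignments of the pooled sample."""
    pooled = np.concatenate([a, b])
    n = len(a)
    ranks = rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    us = []
    for idx in combinations(range(len(pooled)), n):
        us.append(ranks[list(idx)].sum() - n * (n + 1) / 2)
    us = np.asarray(us)
    p = 2 * min(np.mean(us <= u_obs), np.mean(us >= u_obs))
    return min(p, 1.0)


class TestWilcoxon:
    def test_five_positive_pairs_exact_p(self):
        a = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        b = np.array([1.0, 1.5, 2.0, 2.5, 3.0])
        res = wilcoxon_signed_rank(a, b)
        assert res.pvalue == pytest.approx(0.0625)  # 2 / 2^5
        assert res.method == "exact"

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_path_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.3, 1.0, 8)
        b = np.zeros(8)
        res = wilcoxon_signed_rank(a, b)
        assert res.pvalue == pytest.approx(exact_wilcoxon_p(a - b), abs=1e-12)

    def test_two_sidedness_under_swap(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 12)
        assert wilcoxon_signed_rank(a, b).pvalue == pytest.approx(
            wilcoxon_signed_rank(b, a).pvalue
        )

    def test_monotone_transform_invariance(self):
        # the signed-rank statistic depends on differences, so invariance
        # holds for transforms preserving difference ranks, e.g. scaling
        rng = np.random.default_rng(4)
        a, b = rng.normal(1, 1, 10), rng.normal(0, 1, 10)
        assert wilcoxon_signed_rank(3 * a, 3 * b).pvalue == pytest.approx(
            wilcoxon_signed_rank(a, b).pvalue
        )

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(DegenerateTestError):
            wilcoxon_signed_rank(np.ones(6), np.ones(6))

    def test_zero_differences_dropped_and_counted(self):
        a = np.array([1.0, 2, 3, 4, 5, 6, 7.0])
        b = np.array([1.0, 1, 1, 1, 1, 1, 7.0])
        res = wilcoxon_signed_rank(a, b)
        assert res.extra["n_zero_dropped"] == 2
        assert res.n == 5


class TestMannWhitney:
    def test_separated_groups_exact_p(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6], method="exact")
        assert res.statistic == 0.0
        assert res.pvalue == pytest.approx(0.1)  # 2 / C(6,3)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_path_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0.8, 1, 5), rng.normal(0, 1, 7)
        res = mann_whitney_u(a, b, method="exact")
        assert res.pvalue == pytest.approx(exact_mannwhitney_p(a, b), abs=1e-12)

    def test_exact_and_asymptotic_agree_for_small_tie_free_samples(self):
        # the normal approximation tracks the exact enumeration closely in
        # the decision-relevant tail and qualitatively elsewhere
        rng = np.random.default_rng(9)
        for _ in range(50):
            a, b = rng.normal(1.0, 1, 6), rng.normal(0, 1, 8)
            pe = mann_whitney_u(a, b, method="exact").pvalue
            pa = mann_whitney_u(a, b, method="asymptotic").pvalue
            assert abs(pe - pa) <= 0.06
            if pe < 0.05:
                assert abs(pe - pa) <= 0.01

    def test_identical_groups_give_p_one(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.pvalue == pytest.approx(1.0, abs=1e-9)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(1, 1, 9), rng.normal(0, 1, 11)
        assert mann_whitney_u(np.exp(a), np.exp(b)).pvalue == pytest.approx(
            mann_whitney_u(a, b).pvalue
        )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestSpearmanAndOls:
    def test_monotone_series_have_unit_rho(self):
        x = np.arange(10.0)
        assert spearman_corr(x, np.exp(x)).statistic == pytest.approx(1.0)
        assert spearman_corr(x, -np.exp(x)).statistic == pytest.approx(-1.0)

    def test_rho_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
        r1 = spearman_corr(x, y).statistic
        r2 = spearman_corr(np.exp(x), y**3).statistic
        assert r1 == pytest.approx(r2)

    def test_constant_input_degenerate(self):
        with pytest.raises(DegenerateTestError):
            spearman_corr(np.ones(10), np.arange(10.0))

    def test_perfect_line_r2_one(self):
        x = np.arange(10.0)
        res = linear_r2(x, 2 * x + 1)
        assert res.statistic == pytest.approx(1.0)
        assert res.extra["slope"] == pytest.approx(2.0)

    def test_independent_noise_r2_near_zero(self):
        rng = np.random.default_rng(7)
        res = linear_r2(rng.normal(0, 1, 500), rng.normal(0, 1, 500))
        assert res.statistic < 0.05


class TestStatsReport:
    def test_packaged_table_report_structure(self):
        report = group_stats_report(load_index_table())
        assert report.n_seizures == 22
        assert report.n_pattern == {"A": 6, "B": 16}
        assert report.n_tests == 17
        frame = report.to_frame()
        assert len(frame) == 17
        assert set(frame["family"]) == {
            "es_vs_so",
            "es_index_vs_duration",
            "es_index_vs_duration_ols",
            "pattern_a_vs_b_index",
            "pattern_a_vs_b_degree",
        }
        assert "Group statistics" in report.summary()

    def test_single_pattern_table_flags_contrast(self):
        records = [r for r in load_index_table() if r.pattern == "B"]
        report = group_stats_report(records)
        assert all(v is None for v in report.pattern_indices.values())
        assert report.flags

    def test_per_patient_aggregation_reduces_n(self):
        report = group_stats_report(load_index_table(), per_patient=True)
        # 10 patients, two of which show both patterns -> 12 observations
        assert report.n_seizures == 12
        assert report.per_patient
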
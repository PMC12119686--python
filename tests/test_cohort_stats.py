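"""Nonparametric battery vs brute-force enumeration oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import hypergeom, rankdata

from crpmap.cohort_stats import (
    DataError,
    SpecificationError,
    build_association_table,
    compare_groups_continuous,
    correlate,
    exact_2x2,
    multi_paired_compare,
    paired_compare,
)


# ---------------------------------------------------------------------------
# enumeration oracles (independent of scipy's test implementations)


def mannwhitney_exact_oracle(x, y):
    """Two-sided exact p by enumerating all group assignments (no ties)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        gx = pooled[list(combo)]
        gy = np.delete(pooled, list(combo))
        us.append(sum(1 for xi in gx for yj in gy if xi > yj))
    us = np.asarray(us)
    p_low = np.mean(us <= u_obs)
    p_high = np.mean(us >= u_obs)
    return u_obs, min(1.0, 2 * min(p_low, p_high))


def fisher_point_prob_oracle(table):
    """Two-sided p: sum of all tables (fixed margins) no more probable."""
    a, b, c, d = np.asarray(table).ravel()
    n, r1, c1 = a + b + c + d, a + b, a + c
    p_obs = hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for aa in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        p = hypergeom.pmf(aa, n, r1, c1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


def wilcoxon_sign_flip_oracle(before, after):
    """Two-sided exact p by enumerating all 2^n sign assignments."""
    d = np.asarray(after, float) - np.asarray(before, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    t_obs = ranks[d > 0].sum()
    ts = []
    for signs in itertools.product([0, 1], repeat=len(d)):
        ts.append(sum(r for r, s in zip(ranks, signs) if s))
    ts = np.asarray(ts)
    p = min(1.0, 2 * min(np.mean(ts <= t_obs), np.mean(ts >= t_obs)))
    return min(t_obs, ranks.sum() - t_obs), p


# ---------------------------------------------------------------------------


class TestMannWhitney:
    def test_identical_groups_symmetric(self):
        r = compare_groups_continuous([1, 2, 3, 1, 2, 3], [False] * 3 + [True] * 3)
        assert r.statistic == pytest.approx(4.5)
        assert r.p_value == pytest.approx(1.0)

    def test_fully_separated_small_groups_exact(self):
        r = compare_groups_continuous(
            [1, 2, 3, 10, 20, 30], [False] * 3 + [True] * 3
        )
        assert r.statistic == 0
        assert r.p_value == pytest.approx(0.1)
        assert "exact" in r.test

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(15):
            n1, n2 = rng.integers(2, 6), rng.integers(2, 6)
            pooled = rng.permutation(rng.normal(size=n1 + n2))  # distinct values
            x, y = pooled[:n1], pooled[n1:]
            r = compare_groups_continuous(
                np.concatenate([x, y]), [False] * n1 + [True] * n2
            )
            u, p = mannwhitney_exact_oracle(x, y)
            assert r.statistic == pytest.approx(u, abs=1e-9)
            assert r.p_value == pytest.approx(p, abs=1e-9)

    def test_summaries_report_group_medians(self):
        r = compare_groups_continuous(
            [1, 2, 3, 10, 20, 30], [False] * 3 + [True] * 3,
            group_labels=("lo", "hi"),
        )
        assert r.summaries["lo"][0] == 2
        assert r.summaries["hi"][0] == 20

    def test_empty_group_rejected(self):
        with pytest.raises(DataError):
            compare_groups_continuous([1, 2, 3], [False, False, False])

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(29)
        vals = rng.normal(size=40)
        flags = rng.random(40) < 0.5
        flags[:2] = [True, False]
        perm = rng.permutation(40)
        a = compare_groups_continuous(vals, flags)
        b = compare_groups_continuous(vals[perm], flags[perm])
        assert a.p_value == pytest.approx(b.p_value)
        assert a.statistic == pytest.approx(b.statistic)


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1, 2, 3, 4, 5]
        assert correlate(x, [10, 20, 30, 40, 50])[0] == pytest.approx(1.0)
        assert correlate(x, [50, 40, 30, 20, 10])[0] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(31)
        x = rng.normal(size=42)
        y = 0.5 * x + rng.normal(size=42)
        rho, _ = correlate(x, y)
        rx, ry = rankdata(x), rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-9)

    def test_tied_values_use_average_ranks(self):
        x = [1, 1, 2, 3, 3]
        y = [2, 2, 4, 6, 6]
        rho, _ = correlate(x, y)
        assert rho == pytest.approx(1.0)


class TestFisher:
    def test_balanced_table_null(self):
        odds, p = exact_2x2([[5, 5], [5, 5]])
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_perfect_separation_matches_hypergeometric(self):
        _, p = exact_2x2([[10, 0], [0, 10]])
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)
        assert p == pytest.approx(1.0824e-5, rel=1e-3)

    def test_matches_point_probability_oracle(self):
        rng = np.random.default_rng(37)
        for _ in range(20):
            t = rng.integers(0, 10, size=(2, 2))
            if t.sum() == 0 or t.sum(0).min() == 0 or t.sum(1).min() == 0:
                continue
            _, p = exact_2x2(t)
            assert p == pytest.approx(fisher_point_prob_oracle(t), abs=1e-12)

    def test_row_and_column_swap_invariance(self):
        t = [[7, 2], [3, 9]]
        _, p = exact_2x2(t)
        assert exact_2x2([t[1], t[0]])[1] == pytest.approx(p)
        assert exact_2x2(np.array(t).T)[1] == pytest.approx(p)

    def test_zero_cell_odds_ratio_uses_continuity_correction(self):
        odds, _ = exact_2x2([[4, 0], [2, 6]])
        assert odds == pytest.approx((4.5 * 6.5) / (0.5 * 2.5))

    def test_non_integer_table_rejected(self):
        with pytest.raises(DataError):
            exact_2x2([[1.5, 2], [3, 4]])


class TestWilcoxon:
    def test_identical_vectors_convention(self):
        with pytest.warns(UserWarning, match="zero"):
            r = paired_compare([1, 2, 3], [1, 2, 3])
        assert r.p_value == 1.0

    def test_single_nonzero_pair_powerless(self):
        with pytest.warns(UserWarning):
            r = paired_compare([1, 1, 1], [1, 1, 2])
        assert r.p_value == pytest.approx(1.0)

    def test_matches_sign_flip_oracle(self):
        rng = np.random.default_rng(41)
        for _ in range(10):
            n = int(rng.integers(6, 11))
            before = rng.normal(size=n)
            after = before + rng.normal(0.5, 1.0, size=n)
            if np.unique(np.abs(after - before)).size < n:
                continue
            with np.errstate(all="ignore"):
                r = paired_compare(before, after)
            t, p = wilcoxon_sign_flip_oracle(before, after)
            assert r.statistic == pytest.approx(t, abs=1e-9)
            assert r.p_value == pytest.approx(p, abs=1e-9)


class TestFriedman:
    def test_identical_conditions_null(self):
        data = np.tile(np.arange(6, dtype=float)[:, None], (1, 3))
        with pytest.warns(UserWarning, match="identical"):
            omnibus, dunn = multi_paired_compare(data)
        assert omnibus.p_value == 1.0
        assert (dunn["p_adjusted"] == 1.0).all()

    def test_two_conditions_agree_in_direction_with_signed_rank(self):
        rng = np.random.default_rng(43)
        a = rng.normal(size=12)
        b = a + rng.normal(1.0, 0.3, size=12)
        omnibus, dunn = multi_paired_compare(np.column_stack([a, b]))
        r = paired_compare(a, b)
        # both must see b > a
        assert dunn["z"].iloc[0] > 0
        med_a, med_b = r.summaries["before"][0], r.summaries["after"][0]
        assert med_b > med_a
        assert omnibus.p_value < 0.05 and r.p_value < 0.05

    def test_matches_scipy_reference_for_three_plus_conditions(self):
        from scipy.stats import friedmanchisquare

        rng = np.random.default_rng(49)
        for k in (3, 4, 5):
            data = rng.normal(size=(12, k))
            omnibus, _ = multi_paired_compare(data)
            chi2, p = friedmanchisquare(*[data[:, j] for j in range(k)])
            assert omnibus.statistic == pytest.approx(chi2, abs=1e-9)
            assert omnibus.p_value == pytest.approx(p, abs=1e-9)

    def test_subject_row_permutation_invariance(self):
        rng = np.random.default_rng(47)
        data = rng.normal(size=(10, 4))
        omnibus1, dunn1 = multi_paired_compare(data)
        omnibus2, dunn2 = multi_paired_compare(data[rng.permutation(10)])
        assert omnibus1.p_value == pytest.approx(omnibus2.p_value)
        assert np.allclose(dunn1["z"], dunn2["z"])


class TestAssociationTable:
    def test_fixture_seroprevalence_contingency(self, fixture_pipeline):
        table = build_association_table(
            fixture_pipeline["matrix"],
            fixture_pipeline["records"],
            [("any_epitope_positive", "group", "auto")],
        )
        row = table.rows.iloc[0]
        assert row["test"] == "fisher"
        # 24 of 42 SLE and 4 of 11 HBD are epitope-positive
        assert row["statistic"] == 24
        assert row["p_value"] > 0.05  # 57% vs 36% is not significant at n=53

    def test_constant_variable_emits_na_row(self, fixture_pipeline):
        records = fixture_pipeline["records"]
        for r in records:
            r.apl_positive = False
        with pytest.warns(UserWarning, match="degenerate"):
            table = build_association_table(
                fixture_pipeline["matrix"], records,
                [("apl_positive", "n_epitopes", "auto")],
            )
        assert np.isnan(table.rows.iloc[0]["p_value"])
        assert "degenerate" in table.rows.iloc[0]["note"]

    def test_symmetric_test_invariant_to_lhs_rhs_swap(self, fixture_pipeline):
        args = (fixture_pipeline["matrix"], fixture_pipeline["records"])
        t1 = build_association_table(*args, [("anti_crp_au", "n_epitopes", "auto")])
        t2 = build_association_table(*args, [("n_epitopes", "anti_crp_au", "auto")])
        assert t1.rows.iloc[0]["p_value"] == pytest.approx(t2.rows.iloc[0]["p_value"])

    def test_unknown_variable_rejected(self, fixture_pipeline):
        with pytest.raises(SpecificationError):
            build_association_table(
                fixture_pipeline["matrix"], fixture_pipeline["records"],
                [("no_such_column", "group", "auto")],
            )

    def test_benjamini_hochberg_switch_monotone(self, fixture_pipeline):
        spec = [
            ("any_epitope_positive", "group", "auto"),
            ("n_epitopes", "anti_crp_au", "auto"),
            ("SEIL^80-83", "complement_classical_pct", "auto"),
        ]
        raw = build_association_table(
            fixture_pipeline["matrix"], fixture_pipeline["records"], spec
        )
        adj = build_association_table(
            fixture_pipeline["matrix"], fixture_pipeline["records"], spec,
            bh_correction=True,
        )
        assert (adj.rows["p_adjusted"] >= raw.rows["p_value"] - 1e-12).all()
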
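"""Weir-Cockerham Fst, Tajima's D, and the gene scans."""

import numpy as np
import pandas as pd
import pytest

from popscan import selection
from popscan.model import MISSING, GeneModel
from popscan.selection import (
    candidate_fst_scan,
    fst_aggregate,
    gene_stats,
    high_diversity_scan,
    tajima_constants,
    tajima_d,
    tajima_d_from_counts,
    wc_fst_site,
)

from conftest import build_table, wc_theta_oracle


def two_group_table(dosages_g1, dosages_g2, **kw):
    """Stack two groups of dosage rows; group1 = first rows."""
    from test_diversity import gt_from_dosage

    d = np.vstack([dosages_g1, dosages_g2])
    t = build_table(gt_from_dosage(d), **kw)
    g1 = np.arange(len(dosages_g1))
    g2 = np.arange(len(dosages_g1), len(d))
    return t, g1, g2


class TestWcFstSite:
    def test_fixed_difference_is_one(self):
        t, g1, g2 = two_group_table([[0]] * 5, [[2]] * 5)
        comp = wc_fst_site(t, g1, g2)
        assert comp.theta[0] == pytest.approx(1.0, abs=1e-12)

    def test_fixed_difference_unequal_sizes(self):
        for n1, n2 in [(2, 7), (5, 3), (1, 9)]:
            t, g1, g2 = two_group_table([[0]] * n1, [[2]] * n2)
            comp = wc_fst_site(t, g1, g2)
            assert comp.theta[0] == pytest.approx(1.0, abs=1e-12), (n1, n2)

    def test_no_differentiation(self):
        # identical frequencies and het rates, equal n
        rows = [[0], [1], [1], [2]]
        t, g1, g2 = two_group_table(rows, rows)
        comp = wc_fst_site(t, g1, g2)
        # realized a is near (not exactly) zero at finite n; theta not positive
        assert abs(comp.a[0]) < 0.05
        assert comp.theta[0] <= 0 + 1e-12

    def test_monomorphic_site_nan(self):
        t, g1, g2 = two_group_table([[0]] * 3, [[0]] * 3)
        comp = wc_fst_site(t, g1, g2)
        assert np.isnan(comp.theta[0]) and comp.a[0] == 0

    def test_overlapping_groups_rejected(self):
        t, g1, g2 = two_group_table([[0]] * 3, [[2]] * 3)
        with pytest.raises(ValueError):
            wc_fst_site(t, g1, np.array([0, 3]))

    def test_matches_algebra_oracle(self):
        rng = np.random.default_rng(99)
        from test_diversity import gt_from_dosage

        d = rng.integers(0, 3, size=(12, 300))
        miss = rng.random(d.shape) < 0.1
        d[miss] = -1
        t = build_table(gt_from_dosage(d))
        g1, g2 = np.arange(6), np.arange(6, 12)
        comp = wc_fst_site(t, g1, g2)
        for j in range(300):
            stats = []
            for grp in (g1, g2):
                dg = d[grp, j]
                called = dg >= 0
                n = called.sum()
                if n == 0:
                    break
                p = dg[called].sum() / (2 * n)
                h = (dg[called] == 1).sum() / n
                stats.append((n, p, h))
            if len(stats) < 2 or (stats[0][0] + stats[1][0]) / 2 <= 1:
                continue
            a, b, c = wc_theta_oracle(*stats[0], *stats[1])
            if a == b == c == 0:
                continue
            assert comp.a[j] == pytest.approx(a, abs=1e-12)
            assert comp.b[j] == pytest.approx(b, abs=1e-12)
            assert comp.c[j] == pytest.approx(c, abs=1e-12)


class TestFstAggregate:
    def _intervals(self, *spans):
        return pd.DataFrame(
            [("chr1", s, e, f"iv{k}") for k, (s, e) in enumerate(spans)],
            columns=["chrom", "start", "end", "id"],
        )

    def test_single_site_equals_site_theta(self):
        t, g1, g2 = two_group_table([[0], [1]], [[2], [1]])
        comp = wc_fst_site(t, g1, g2)
        agg = fst_aggregate(comp, self._intervals((0, 100)))
        assert agg.theta[0] == pytest.approx(comp.theta[0], abs=1e-12)

    def test_all_fixed_differences(self):
        t, g1, g2 = two_group_table([[0, 0, 0]] * 4, [[2, 2, 2]] * 4)
        comp = wc_fst_site(t, g1, g2)
        agg = fst_aggregate(comp, self._intervals((0, 100)))
        assert agg.theta[0] == pytest.approx(1.0, abs=1e-12) and bool(agg.is_one[0])

    def test_ratio_of_sums_not_mean_of_ratios(self):
        # site 1: strong differentiation; site 2: weak -- construct and compare
        t, g1, g2 = two_group_table([[0, 1], [0, 1]], [[2, 1], [2, 0]])
        comp = wc_fst_site(t, g1, g2)
        agg = fst_aggregate(comp, self._intervals((0, 100)))
        thetas = comp.theta.to_numpy()
        ros = comp.a.sum() / (comp.a + comp.b + comp.c).sum()
        assert agg.theta[0] == pytest.approx(ros, abs=1e-12)
        assert abs(agg.theta[0] - np.nanmean(thetas)) > 1e-6

    def test_empty_interval_nan(self):
        t, g1, g2 = two_group_table([[0]], [[2]])
        comp = wc_fst_site(t, g1, g2)
        agg = fst_aggregate(comp, self._intervals((1000, 2000)))
        assert np.isnan(agg.theta[0]) and not bool(agg.is_one[0])


class TestTajima:
    @pytest.mark.parametrize(
        "n,a1",
        [(2, 1.0), (4, 1 + 1 / 2 + 1 / 3), (10, sum(1 / i for i in range(1, 10)))],
    )
    def test_constants_closed_forms(self, n, a1):
        k = tajima_constants(n)
        assert k["a1"] == pytest.approx(a1, rel=1e-12)
        assert k["a2"] == pytest.approx(sum(1 / i**2 for i in range(1, n)), rel=1e-12)
        assert k["b1"] == pytest.approx((n + 1) / (3 * (n - 1)), rel=1e-12)

    def test_no_segregating_sites_nan(self):
        res = tajima_d_from_counts(10, np.array([0, 10, 0]))
        assert res.S == 0 and np.isnan(res.D)

    def test_zero_numerator_case(self):
        # n=4: 8 singletons + 3 doubletons give pi_sum = S/a1 exactly
        counts = np.array([1] * 8 + [2] * 3)
        res = tajima_d_from_counts(4, counts)
        assert res.pi_sum == pytest.approx(res.S / res.a1, abs=1e-12)
        assert res.D == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_transcription(self):
        rng = np.random.default_rng(5)
        n = 10
        counts = rng.integers(1, n, size=16)
        res = tajima_d_from_counts(n, counts)
        # independent scalar transcription of the formula
        a1 = sum(1 / i for i in range(1, n))
        a2 = sum(1 / i**2 for i in range(1, n))
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1, e2 = c1 / a1, c2 / (a1**2 + a2)
        S = len(counts)
        pi = sum(2 * c * (n - c) / (n * (n - 1)) for c in counts)
        D = (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))
        assert res.D == pytest.approx(D, rel=1e-12)

    def test_complete_case_sites_only(self):
        from test_diversity import gt_from_dosage

        d = np.array([[1, 1], [0, 1], [1, 0], [2, -1]])  # site 2 has a missing call
        t = build_table(gt_from_dosage(d))
        res = tajima_d(t, np.arange(4))
        assert res.S == 1  # only the complete site segregates for the group

    def test_small_group_nan(self):
        from test_diversity import gt_from_dosage

        t = build_table(gt_from_dosage([[1]]))
        with pytest.warns(UserWarning):
            res = tajima_d(t, np.array([0]))
        assert np.isnan(res.D)


class TestGeneScans:
    def _gene(self, gid, start, end):
        return GeneModel(
            gene_id=gid, chrom="chr1", strand="+", start=start, end=end,
            exons=[(start, end)], cds=[],
        )

    def test_gene_with_no_variants(self):
        t, g1, g2 = two_group_table([[1]] * 3, [[1]] * 3, positions=[5000])
        groups = {"pepo": g1, "ovifera": g2}
        stats = gene_stats(t, [self._gene("empty", 0, 900)], groups)
        row = stats.iloc[0]
        assert row.pi_pepo == 0 and np.isnan(row.tajima_d_pepo) and np.isnan(row.fst)

    def test_gene_pi_matches_window_kernel(self):
        from popscan import diversity
        from test_diversity import gt_from_dosage

        rng = np.random.default_rng(8)
        d = rng.integers(0, 3, size=(6, 10))
        t = build_table(gt_from_dosage(d), positions=list(range(0, 1000, 100)))
        g1, g2 = np.arange(3), np.arange(3, 6)
        stats = gene_stats(t, [self._gene("g", 0, 1000)], {"a": g1, "b": g2})
        win = diversity.window_pi(t, {"chr1": 1000}, group=g1, window=1000)
        assert stats.pi_a[0] == pytest.approx(win.value[0], abs=1e-15)

    def test_fst_scan_strict_threshold_and_equality_class(self):
        stats = pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g3", "g4"],
                "fst": [0.80, 0.81, 1.0 - 1e-15, np.nan],
                "fst_is_one": [False, False, True, False],
            }
        )
        rep = candidate_fst_scan(stats)
        assert rep["genes_above"] == ["g2", "g3"]  # 0.80 exactly is excluded
        assert rep["genes_fixed"] == ["g3"]  # tolerance-based equality flag
        assert rep["pct_above"] == pytest.approx(50.0)

    def test_high_diversity_no_flags_when_equal(self):
        stats = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(20)],
             "pi_a": [0.1] * 20, "pi_b": [0.2] * 20}
        )
        rep = high_diversity_scan(stats)
        assert rep["flagged"]["a"] == [] and rep["flagged"]["b"] == []

    def test_flagged_in_both_excluded_from_exclusives(self):
        pi_a = [0.0] * 99 + [9.0]
        pi_b = [0.0] * 99 + [9.0]
        stats = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(100)], "pi_a": pi_a, "pi_b": pi_b}
        )
        rep = high_diversity_scan(stats)
        assert rep["flagged"]["a"] == ["g99"] and rep["shared"] == ["g99"]
        assert rep["exclusive"]["a"] == [] and rep["exclusive"]["b"] == []
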
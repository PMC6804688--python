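"""Nucleotide diversity, composite r², LD decay, and background LD."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popscan import diversity
from popscan.model import MISSING

from conftest import build_table, pi_bruteforce, random_table


def gt_from_dosage(dosages):
    """Rows of 0/1/2 dosages (-1 for missing) -> genotype pair array."""
    d = np.asarray(dosages)
    gt = np.stack([np.where(d == 2, 1, 0), np.where(d >= 1, 1, 0)], axis=2).astype(np.int8)
    gt[d < 0] = MISSING
    return gt


class TestSitePi:
    def test_four_haplotypes_two_alt(self):
        # 2 diploids, dosages (1,1): n=4 alleles, c=2 -> 2*2*2/(4*3)
        t = build_table(gt_from_dosage([[1], [1]]))
        assert diversity.site_pi(t)[0] == pytest.approx(2 / 3, abs=1e-12)

    def test_pooled_all_het_pattern(self):
        # 8 diploids all het: n=16, c=8 -> 2*8*8/(16*15)
        t = build_table(gt_from_dosage([[1]] * 8))
        assert diversity.site_pi(t)[0] == pytest.approx(2 * 8 * 8 / (16 * 15), abs=1e-12)

    def test_monomorphic_is_zero(self):
        t = build_table(gt_from_dosage([[0], [0], [0]]))
        assert diversity.site_pi(t)[0] == 0.0

    def test_small_n_is_nan(self):
        t = build_table(gt_from_dosage([[1], [-1], [-1]]))
        assert np.isnan(diversity.site_pi(t)[0])

    def test_empty_group_rejected(self):
        t = build_table(gt_from_dosage([[1]]))
        with pytest.raises(ValueError):
            diversity.site_pi(t, group=np.array([], dtype=int))

    def test_matches_bruteforce_on_random_sites(self):
        rng = np.random.default_rng(42)
        t = random_table(rng, n_samples=10, n_sites=200, missing_rate=0.15)
        pi = diversity.site_pi(t)
        for j in range(t.n_sites):
            alleles = [
                a for i in range(t.n_samples) for a in t.gt[i, j] if a != MISSING
            ]
            expected = pi_bruteforce(alleles) if len(alleles) >= 4 else float("nan")
            if np.isnan(expected):
                assert np.isnan(pi[j])
            else:
                assert pi[j] == pytest.approx(expected, abs=1e-12)


class TestWindowPi:
    def test_single_site_window(self):
        t = build_table(gt_from_dosage([[1], [0], [1], [0]]), positions=[500])
        tr = diversity.window_pi(t, {"chr1": 1000}, window=1000)
        site = diversity.site_pi(t)[0]
        assert tr.value[0] == pytest.approx(site / 1000, abs=1e-15)

    def test_no_variants_zero(self):
        t = build_table(gt_from_dosage([[0], [0], [0]]), positions=[5])
        tr = diversity.window_pi(t, {"chrX": 2000}, window=1000)
        assert (tr.value == 0).all()

    def test_denominator_scaling(self):
        t = build_table(gt_from_dosage([[1], [0], [1], [0]]), positions=[100])
        small = diversity.window_pi(t, {"chr1": 1000}, window=1000).value[0]
        big = diversity.window_pi(t, {"chr1": 2000}, window=2000).value[0]
        assert big == pytest.approx(small / 2, rel=1e-12)


class TestPairwiseR2:
    def test_identical_columns(self):
        t = build_table(gt_from_dosage([[0, 0], [1, 1], [2, 2], [1, 1]]))
        pairs = diversity.pairwise_r2(t)
        assert len(pairs) == 1 and pairs.r2[0] == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_dosages(self):
        t = build_table(gt_from_dosage([[0, 0], [0, 2], [2, 0], [2, 2]]))
        pairs = diversity.pairwise_r2(t)
        assert pairs.r2[0] == pytest.approx(0.0, abs=1e-12)

    def test_max_dist_cutoff(self):
        t = build_table(
            gt_from_dosage([[0, 0], [1, 1], [2, 2], [1, 0]]), positions=[0, 600_000]
        )
        assert len(diversity.pairwise_r2(t, max_dist=500_000)) == 0

    def test_monomorphic_pairs_skipped(self):
        t = build_table(gt_from_dosage([[0, 1], [0, 0], [0, 2], [0, 1]]))
        assert len(diversity.pairwise_r2(t)) == 0

    def test_banded_equals_direct_correlation(self):
        rng = np.random.default_rng(3)
        t = random_table(rng, n_samples=12, n_sites=40, missing_rate=0.1, n_chrom=1)
        pairs = diversity.pairwise_r2(t, min_samples=3)
        d = t.dosage()
        for row in pairs.sample(min(len(pairs), 40), random_state=1).itertuples():
            x, y = d[:, row.site_a], d[:, row.site_b]
            ok = ~np.isnan(x) & ~np.isnan(y)
            r = np.corrcoef(x[ok], y[ok])[0, 1]
            assert row.r2 == pytest.approx(r * r, abs=1e-9)


class TestWindowLd:
    def test_empty_and_single(self):
        pairs = pd.DataFrame(
            {"chrom": ["chr1"], "midpoint": [25_000.0], "distance": [100], "r2": [0.7]}
        )
        tr = diversity.window_ld(pairs, {"chr1": 100_000}, window=50_000)
        assert tr.value[0] == pytest.approx(0.7)
        assert np.isnan(tr.value[1])

    def test_mean_matches(self):
        pairs = pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "midpoint": [10_000.0, 20_000.0, 30_000.0],
                "distance": [1, 2, 3],
                "r2": [0.2, 0.4, 0.9],
            }
        )
        tr = diversity.window_ld(pairs, {"chr1": 50_000}, window=50_000)
        assert tr.value[0] == pytest.approx(np.mean([0.2, 0.4, 0.9]))


class TestLdDecayFit:
    def test_constant_data(self):
        rng = np.random.default_rng(0)
        pairs = pd.DataFrame(
            {"distance": rng.integers(0, 400_000, 500), "r2": np.full(500, 0.5)}
        )
        fit = diversity.ld_decay_fit(pairs)
        assert np.allclose(fit.fitted, 0.5, atol=1e-9)
        assert fit.crossings[0.4] is None and fit.crossings[0.6] == 0.0

    def test_fit_within_local_data_range(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 300_000, 5000)
        r2 = np.clip(1.0 / (1.0 + d / 50_000) + rng.normal(0, 0.005, len(d)), 0, 1)
        pairs = pd.DataFrame({"distance": d, "r2": r2})
        fit = diversity.ld_decay_fit(pairs)
        lo, hi = r2.min(), r2.max()
        assert (fit.fitted >= lo - 0.02).all() and (fit.fitted <= hi + 0.02).all()

    def test_insufficient_pairs(self):
        pairs = pd.DataFrame({"distance": [1, 2], "r2": [0.1, 0.2]})
        with pytest.raises(ValueError):
            diversity.ld_decay_fit(pairs)


class TestBackgroundLd:
    def test_single_chromosome_rejected(self):
        t = build_table(gt_from_dosage(np.random.default_rng(0).integers(0, 3, (6, 10))))
        with pytest.raises(ValueError, match="chromosome"):
            diversity.background_ld(t, n_reps=5, n_snps=5, seed=0)

    def test_exhaustion_warns(self):
        rng = np.random.default_rng(5)
        t = random_table(rng, n_samples=6, n_sites=20, missing_rate=0)
        with pytest.warns(UserWarning, match="available"):
            res = diversity.background_ld(t, n_reps=10, n_snps=100, seed=1)
        assert res.n_snps_per_rep == 20

    def test_chromosome_relabeling_invariance_and_determinism(self):
        rng = np.random.default_rng(6)
        t = random_table(rng, n_samples=8, n_sites=60, missing_rate=0.05)
        a = diversity.background_ld(t, n_reps=20, n_snps=30, seed=9)
        relabeled = t.copy()
        relabeled.sites["chrom"] = relabeled.sites.chrom.map(
            {"chr1": "chrB", "chr2": "chrA"}
        )
        b = diversity.background_ld(relabeled, n_reps=20, n_snps=30, seed=9)
        c = diversity.background_ld(t, n_reps=20, n_snps=30, seed=9)
        assert np.array_equal(a.replicate_means, b.replicate_means)
        assert np.array_equal(a.replicate_means, c.replicate_means)

    def test_independent_loci_replicate_mean_near_1_over_n(self):
        rng = np.random.default_rng(7)
        n = 60
        dos = rng.binomial(2, 0.5, size=(n, 300))
        t = build_table(
            gt_from_dosage(dos),
            chroms=["chr1"] * 150 + ["chr2"] * 150,
            positions=list(range(150)) + list(range(150)),
        )
        res = diversity.background_ld(t, n_reps=30, n_snps=200, seed=3)
        assert np.nanmean(res.replicate_means) == pytest.approx(1.0 / n, rel=0.2)


class TestObservedHeterozygosity:
    def test_pure_windows(self):
        t = build_table([[(0, 1), (1, 1)], [(0, 1), (1, 1)]], positions=[10, 150_000])
        tr = diversity.observed_heterozygosity(t, {"chr1": 200_000}, window=100_000)
        w0 = tr[(tr.start == 0)].set_index("stat").value
        w1 = tr[(tr.start == 100_000)].set_index("stat").value
        assert w0["het_freq"] == 1.0 and w0["homalt_freq"] == 0.0
        assert w1["het_freq"] == 0.0 and w1["homalt_freq"] == 1.0


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_r2_and_pi_bounds_property(seed):
    """Invariants: r2 in [0,1]; site pi within the biallelic upper bound."""
    rng = np.random.default_rng(seed)
    t = random_table(rng, n_samples=6, n_sites=30, missing_rate=0.2)
    pairs = diversity.pairwise_r2(t)
    assert ((pairs.r2 >= 0) & (pairs.r2 <= 1 + 1e-12)).all()
    pi = diversity.site_pi(t)
    called = 2 * (~t.is_missing).sum(axis=0)
    ok = ~np.isnan(pi)
    bound = 0.5 * called[ok] / np.maximum(called[ok] - 1, 1)
    assert (pi[ok] <= bound + 1e-12).all() and (pi[ok] >= 0).all()
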
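"""ROH calling, sROH~nROH residuals, LD decay, folded SFS, Ho and Fis."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from popmosaic import diversity as div
from popmosaic.genotypes import MISSING

from conftest import make_genotypes


def naive_roh(pos, dosage, params=None):
    """Direct re-statement of the two-pass window rules, O(S*W)."""
    p = params or div.ROHParams()
    s = len(pos)
    win_hom = []
    for start in range(s):
        w = dosage[start : min(start + p.win_snp, s)]
        win_hom.append(
            np.count_nonzero(w == 1) <= p.win_het
            and np.count_nonzero(w == MISSING) <= p.win_missing
        )
    eligible = []
    for i in range(s):
        over = [k for k in range(max(0, i - p.win_snp + 1), i + 1)]
        frac = sum(win_hom[k] for k in over) / len(over)
        eligible.append(frac >= p.win_threshold)
    segs = []
    i = 0
    while i < s:
        if not eligible[i]:
            i += 1
            continue
        j = i
        while j + 1 < s and eligible[j + 1] and pos[j + 1] - pos[j] <= p.gap_kb * 1000:
            j += 1
        n_snps = j - i + 1
        length = pos[j] - pos[i] + 1
        if (
            n_snps >= p.min_snp
            and length >= p.min_kb * 1000
            and length / n_snps <= p.density_kb * 1000
        ):
            segs.append((int(pos[i]), int(pos[j]), n_snps))
        i = j + 1
    return segs


class TestROH:
    def test_fully_heterozygous_no_segments(self):
        g = make_genotypes(
            np.ones((1, 300), dtype=np.int8), pos=np.arange(300) * 5000 + 1
        )
        assert div.call_roh(g) == []

    def test_long_homozygous_run_called(self):
        # 150 homozygous SNPs spaced 5 kb inside heterozygous flanks
        dosage = np.concatenate(
            [np.ones(60), np.zeros(150), np.ones(60)]
        ).astype(np.int8)[None, :]
        pos = np.arange(270) * 5000 + 1
        g = make_genotypes(dosage, pos=pos)
        segs = div.call_roh(g)
        assert len(segs) == 1
        seg = segs[0]
        assert seg.length_kb >= 500
        assert 100 <= seg.n_snps <= 150
        oracle = naive_roh(pos, dosage[0])
        assert [(s.start, s.end, s.n_snps) for s in segs] == oracle

    def test_gap_splits_run(self):
        dosage = np.concatenate(
            [np.ones(30), np.zeros(150), np.ones(30)]
        ).astype(np.int8)[None, :]
        pos = np.arange(210) * 5000 + 1
        pos[105:] += 600_000  # 600 kb gap inside the run
        g = make_genotypes(dosage, pos=pos)
        assert div.call_roh(g) == []  # split pieces fail min_snp/min_kb
        assert naive_roh(pos, dosage[0]) == []

    def test_matches_naive_oracle_on_random_data(self):
        rng = np.random.default_rng(11)
        for trial in range(3):
            s = 700
            pos = np.sort(rng.choice(np.arange(1, s * 7000), s, replace=False))
            dosage = rng.binomial(2, rng.uniform(0.1, 0.9, s)).astype(np.int8)
            # plant a run to make segments likely
            a, b = 100, 450
            dosage[a:b] = np.where(dosage[a:b] == 1, 0, dosage[a:b])
            g = make_genotypes(dosage[None, :], pos=pos)
            segs = [(x.start, x.end, x.n_snps) for x in div.call_roh(g)]
            assert segs == naive_roh(pos, dosage)

    def test_coordinate_shift_invariance(self):
        rng = np.random.default_rng(12)
        s = 400
        pos = np.sort(rng.choice(np.arange(1, s * 6000), s, replace=False))
        dosage = (2 * rng.binomial(1, 0.5, s)).astype(np.int8)[None, :]
        g1 = make_genotypes(dosage, pos=pos)
        g2 = make_genotypes(dosage, pos=pos + 1_000_000)
        s1 = div.call_roh(g1)
        s2 = div.call_roh(g2)
        assert [(x.start + 1_000_000, x.end + 1_000_000) for x in s1] == [
            (x.start, x.end) for x in s2
        ]

    def test_segments_never_overlap(self):
        rng = np.random.default_rng(13)
        s = 1500
        pos = np.sort(rng.choice(np.arange(1, s * 6000), s, replace=False))
        dosage = rng.binomial(2, 0.95, s).astype(np.int8)[None, :]
        g = make_genotypes(dosage, pos=pos)
        segs = sorted(div.call_roh(g), key=lambda x: x.start)
        for a, b in zip(segs, segs[1:]):
            assert a.end < b.start

    def test_unsorted_rejected(self):
        # unsorted coordinates are rejected at container construction
        with pytest.raises(ValueError):
            make_genotypes(np.zeros((1, 3), dtype=np.int8), pos=[10, 5, 20])


class TestROHRegression:
    def test_exact_line_zero_residuals(self):
        df = pd.DataFrame(
            {"nROH": [1.0, 2, 3, 4], "sROH_kb": [100.0, 200, 300, 400]},
            index=list("abcd"),
        )
        res = div.roh_regression_residual(df, list("abcd"))
        np.testing.assert_allclose(res.to_numpy(), 0.0, atol=1e-9)

    def test_baseline_residuals_sum_to_zero_and_inbred_positive(self):
        rng = np.random.default_rng(14)
        n = rng.integers(3, 12, size=10).astype(float)
        s = 600 * n + rng.normal(0, 40, size=10)
        df = pd.DataFrame(
            {"nROH": np.append(n, 5.0), "sROH_kb": np.append(s, 600 * 5 * 2)},
            index=[f"b{i}" for i in range(10)] + ["inbred"],
        )
        res = div.roh_regression_residual(df, [f"b{i}" for i in range(10)])
        assert abs(res.iloc[:10].sum()) < 1e-6
        assert res["inbred"] > 0  # doubled IBD segment lengths

    def test_constant_baseline_rejected(self):
        df = pd.DataFrame(
            {"nROH": [2.0, 2, 2], "sROH_kb": [1.0, 2, 3]}, index=list("abc")
        )
        with pytest.raises(ValueError):
            div.roh_regression_residual(df, list("abc"))


class TestLDDecay:
    def test_duplicated_snps_full_r2(self):
        rng = np.random.default_rng(15)
        col = rng.binomial(2, 0.5, size=(6, 1)).astype(np.int8)
        dosage = np.concatenate([col, col], axis=1)
        g = make_genotypes(dosage, pos=[1000, 2000], pops=["P"] * 6)
        ld = div.ld_decay(g, "P", reps=2, seed=1)
        assert ld.loc[0, "mean_r2"] == pytest.approx(1.0)

    def test_independent_snps_flat_null(self):
        # null mean of genotype r^2 with n individuals is ~1/(n-1)
        rng = np.random.default_rng(16)
        n_sites = 600
        pos = np.sort(rng.choice(np.arange(1, 1_200_000), n_sites, replace=False))
        p = rng.uniform(0.2, 0.8, n_sites)
        dosage = rng.binomial(2, p, size=(10, n_sites)).astype(np.int8)
        g = make_genotypes(dosage, pos=pos, pops=["P"] * 10)
        ld = div.ld_decay(g, "P", downsample_to=5, reps=10, seed=2)
        vals = ld["mean_r2"].dropna()
        assert np.all(np.abs(vals - 0.25) < 0.08)
        assert vals.max() - vals.min() < 0.1  # flat across distance bins

    def test_bottleneck_raises_ld(self):
        # founder-limited population (4 haplotypes recombined) vs a large
        # outbred one: LD strictly larger in every bin >= 5 kb
        rng = np.random.default_rng(17)
        n_sites = 800
        pos = np.sort(rng.choice(np.arange(1, 900_000), n_sites, replace=False))
        p = rng.uniform(0.2, 0.8, n_sites)
        founders = (rng.random((4, n_sites)) < p).astype(np.int8)
        small = np.stack(
            [
                founders[rng.integers(0, 4)] + founders[rng.integers(0, 4)]
                for _ in range(8)
            ]
        ).astype(np.int8)
        big = rng.binomial(2, p, size=(8, n_sites)).astype(np.int8)
        g = make_genotypes(
            np.vstack([small, big]), pos=pos, pops=["S"] * 8 + ["B"] * 8
        )
        ld_s = div.ld_decay(g, "S", reps=5, seed=3)["mean_r2"]
        ld_b = div.ld_decay(g, "B", reps=5, seed=3)["mean_r2"]
        for k in range(2, len(ld_s)):
            assert ld_s[k] > ld_b[k]

    def test_optional_full_bins(self):
        assert (40_000, 45_000) in div.LD_BINS_FULL
        assert (40_000, 45_000) not in div.LD_BINS


class TestFoldedSFS:
    def test_all_singletons(self):
        # each site: exactly one heterozygote among the 5 individuals
        dosage = np.zeros((5, 20), dtype=np.int8)
        for s in range(20):
            dosage[s % 5, s] = 1
        g = make_genotypes(dosage, pops=["P"] * 5)
        sfs = div.folded_sfs(g, "P", downsample_to=5, reps=1, seed=1)
        np.testing.assert_allclose(sfs, [1, 0, 0, 0, 0])

    def test_watterson_expectation(self):
        # frequency-draw oracle: allele count among 10 haplotypes drawn
        # with P(i) proportional to 1/i, folded spectrum ~ (1/i + 1/(2n-i))
        rng = np.random.default_rng(18)
        n_hap, n_sites = 10, 40_000
        w = 1 / np.arange(1, n_hap)
        counts = rng.choice(np.arange(1, n_hap), p=w / w.sum(), size=n_sites)
        dosage = np.zeros((5, n_sites), dtype=np.int8)
        for s in range(n_sites):
            carriers = rng.choice(n_hap, size=counts[s], replace=False)
            for c in carriers:
                dosage[c // 2, s] += 1
        g = make_genotypes(dosage, pops=["P"] * 5)
        sfs = div.folded_sfs(g, "P", downsample_to=5, reps=1, seed=2)
        folded = np.array(
            [1 / i + (1 / (n_hap - i) if i != n_hap - i else 0) for i in range(1, 6)]
        )
        folded[-1] = 1 / 5  # i = n-i class counted once
        expected = folded / folded.sum()
        se = np.sqrt(expected * (1 - expected) / n_sites)
        assert np.all(np.abs(sfs - expected) <= 4 * se + 0.01)

    def test_founder_limited_population_fewer_singletons(self):
        rng = np.random.default_rng(19)
        n_sites = 30_000
        p = rng.uniform(0.05, 0.95, n_sites)
        founders = (rng.random((4, n_sites)) < p).astype(np.int8)
        small = np.stack(
            [
                founders[rng.integers(0, 4)] + founders[rng.integers(0, 4)]
                for _ in range(5)
            ]
        ).astype(np.int8)
        big = np.stack(
            [
                (rng.random(n_sites) < p).astype(np.int8)
                + (rng.random(n_sites) < p).astype(np.int8)
                for _ in range(5)
            ]
        ).astype(np.int8)
        g = make_genotypes(
            np.vstack([small, big]), pops=["S"] * 5 + ["B"] * 5
        )
        sfs_s = div.folded_sfs(g, "S", reps=3, seed=4)
        sfs_b = div.folded_sfs(g, "B", reps=3, seed=4)
        assert sfs_s[0] < sfs_b[0]

    def test_too_few_individuals_rejected(self):
        g = make_genotypes(np.ones((3, 10), dtype=np.int8), pops=["P"] * 3)
        with pytest.raises(ValueError):
            div.folded_sfs(g, "P", downsample_to=5)


class TestHetStats:
    def test_ho_hand_count(self):
        dosage = np.zeros((2, 10), dtype=np.int8)
        dosage[0, :3] = 1
        dosage[1, :] = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 0])
        stats = div.het_stats(make_genotypes(dosage))
        assert stats.loc["S0", "Ho"] == pytest.approx(0.3)

    def test_fully_homozygous_fis_one(self):
        rng = np.random.default_rng(20)
        dosage = rng.binomial(2, 0.5, size=(20, 2000)).astype(np.int8)
        dosage[0] = np.where(dosage[0] == 1, 2, dosage[0])
        stats = div.het_stats(make_genotypes(dosage))
        assert stats.loc["S0", "Fis"] == pytest.approx(1.0)

    def test_hwe_individual_fis_near_zero(self):
        rng = np.random.default_rng(21)
        p = rng.uniform(0.05, 0.95, 100_000)
        dosage = rng.binomial(2, p, size=(30, 100_000)).astype(np.int8)
        stats = div.het_stats(make_genotypes(dosage))
        assert abs(stats["Fis"].iloc[0]) < 0.05

    def test_ho_fis_anticorrelated_with_planted_autozygosity(self):
        rng = np.random.default_rng(22)
        n_sites = 20_000
        p = rng.uniform(0.1, 0.9, n_sites)
        rows = []
        for f_auto in np.linspace(0, 0.8, 12):
            a1 = (rng.random(n_sites) < p).astype(np.int8)
            a2 = (rng.random(n_sites) < p).astype(np.int8)
            auto = rng.random(n_sites) < f_auto
            a2 = np.where(auto, a1, a2)
            rows.append(a1 + a2)
        stats = div.het_stats(make_genotypes(np.stack(rows).astype(np.int8)))
        rho = spearmanr(stats["Ho"], stats["Fis"]).statistic
        assert rho <= -0.9

    def test_fully_missing_individual_flagged(self):
        dosage = np.ones((3, 5), dtype=np.int8)
        dosage[0] = MISSING
        stats = div.het_stats(make_genotypes(dosage))
        assert np.isnan(stats.loc["S0", "Fis"])
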
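"""Diversity statistics against independent brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from salsel.io import MISSING
from salsel.popgen import (
    allelic_richness,
    heterozygosity,
    pca,
    per_locus_fst,
    site_pi,
    wc_components,
    wc_fst,
    windowed_pi,
)
from tests.conftest import make_gm

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def wc_theta_oracle(geno_a: list[int], geno_b: list[int]) -> tuple[float, float, float]:
    """Scalar Weir & Cockerham (1984) variance components for one locus.

    Written directly from the published estimator with r=2 populations,
    using genotype lists (alternate-allele dosage, missing excluded before
    the call).  Returns (a, b, c).
    """
    r = 2
    n = [len(geno_a), len(geno_b)]
    p = [sum(g) / (2 * len(g)) for g in (geno_a, geno_b)]
    h = [sum(1 for x in g if x == 1) / len(g) for g in (geno_a, geno_b)]
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni**2 for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def pi_oracle(dosages: np.ndarray) -> float:
    """Mean pairwise haplotype difference at one site from called genotypes.

    Expands genotypes into allele lists and averages |a_i - a_j| over all
    haplotype pairs (phase does not matter for a per-site difference).
    """
    alleles = []
    for g in dosages:
        if g != MISSING:
            alleles += [1] * g + [0] * (2 - g)
    if len(alleles) < 2:
        return np.nan
    diffs = [abs(a - b) for a, b in itertools.combinations(alleles, 2)]
    return float(np.mean(diffs))


def ar_oracle(allele_counts: list[int], g: int) -> float:
    """Rarefied allele count by exhaustive subsample enumeration."""
    pool = []
    for i, c in enumerate(allele_counts):
        pool += [i] * c
    vals = [len(set(sub)) for sub in itertools.combinations(pool, g)]
    return float(np.mean(vals))


def ranksum_p_oracle(x, y) -> float:
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    n = len(x)
    obs = ranks[:n].sum()
    mu = n * (len(pooled) + 1) / 2
    stats = [
        sum(ranks[list(idx)])
        for idx in itertools.combinations(range(len(pooled)), n)
    ]
    extreme = sum(1 for s in stats if abs(s - mu) >= abs(obs - mu) - 1e-9)
    return extreme / len(stats)


# ---------------------------------------------------------------------------
# heterozygosity
# ---------------------------------------------------------------------------


class TestHeterozygosity:
    def test_forced_single_locus(self):
        gm = make_gm([[1, 1]])
        records, _ = heterozygosity(gm, "A", [])
        assert (records["Ho"] == 1.0).all()
        assert records["He"].tolist() == pytest.approx([0.5, 0.5])

    def test_all_homozygous_reference(self):
        gm = make_gm(np.zeros((5, 4), dtype=np.int8))
        records, _ = heterozygosity(gm, "A", [])
        assert (records["Ho"] == 0).all() and (records["He"] == 0).all()

    def test_wilcoxon_matches_exact_enumeration(self):
        # find a draw where Ho/He values are tie-free so the exact rank-sum
        # distribution applies (ties would switch the test to midranks)
        for seed in range(3, 50):
            rng = np.random.default_rng(seed)
            dosage = rng.binomial(2, 0.4, size=(137, 12)).astype(np.int8)
            dosage[rng.random(dosage.shape) < 0.1] = MISSING
            groups = ["CR"] * 6 + ["HC1"] * 6
            gm = make_gm(dosage, groups=groups)
            records, tests = heterozygosity(gm, "CR", ["HC1"])
            if records["Ho"].nunique() == 12 and records["He"].nunique() == 12:
                break
        else:
            pytest.fail("no tie-free draw found")
        for stat in ("Ho", "He"):
            x = records.loc[records["group"] == "HC1", stat].to_numpy()
            y = records.loc[records["group"] == "CR", stat].to_numpy()
            expected = ranksum_p_oracle(x, y)
            got = tests.loc[tests["statistic"] == stat, "p"].iloc[0]
            assert got == pytest.approx(expected, rel=1e-9)

    def test_zero_call_sample_flagged(self):
        dosage = np.array([[1, MISSING], [0, MISSING]], dtype=np.int8)
        records, _ = heterozygosity(make_gm(dosage), "A", [])
        assert np.isnan(records["Ho"].iloc[1])


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------


class TestWindowedPi:
    def test_single_site_example(self):
        # 10 diploids, 5 alt alleles of 20: site pi = 15*5/C(20,2)
        dosage = np.array([[1, 1, 1, 1, 1, 0, 0, 0, 0, 0]], dtype=np.int8)
        gm = make_gm(dosage, pos=[42])
        pi = site_pi(gm)
        assert pi[0] == pytest.approx(75 / 190)
        win = windowed_pi(gm, window_bp=5000)
        assert win["pi"].iloc[0] == pytest.approx(75 / 190 / 5000)
        assert pi[0] == pytest.approx(pi_oracle(dosage[0]))

    def test_matches_pair_enumeration_with_missingness(self):
        rng = np.random.default_rng(7)
        dosage = rng.binomial(2, 0.3, size=(30, 6)).astype(np.int8)  # <= 12 haplotypes
        dosage[rng.random(dosage.shape) < 0.15] = MISSING
        gm = make_gm(dosage, pos=rng.choice(20_000, 30, replace=False) + 1)
        pi = site_pi(gm)
        for i in range(30):
            expected = pi_oracle(dosage[i])
            if np.isnan(expected):
                assert np.isnan(pi[i])
            else:
                assert pi[i] == pytest.approx(expected)
        win = windowed_pi(gm, window_bp=5000)
        manual = {}
        for i in range(30):
            key = (gm.pos[i] - 1) // 5000 * 5000
            if not np.isnan(pi[i]):
                manual[key] = manual.get(key, 0.0) + pi[i]
        for _, row in win.iterrows():
            assert row["pi"] == pytest.approx(manual.get(row["start"], 0.0) / 5000)

    def test_window_scaling(self):
        rng = np.random.default_rng(8)
        gm = make_gm(rng.binomial(2, 0.5, size=(10, 8)).astype(np.int8), pos=np.arange(10) + 1)
        a = windowed_pi(gm, window_bp=5000)["pi"].iloc[0]
        b = windowed_pi(gm, window_bp=10_000)["pi"].iloc[0]
        assert b == pytest.approx(a / 2)

    def test_empty_window_omitted(self):
        gm = make_gm(np.array([[1, 0]], dtype=np.int8), pos=[12_001])
        win = windowed_pi(gm, window_bp=5000)
        assert win["start"].tolist() == [10_000]

    def test_invalid_window_rejected(self):
        gm = make_gm(np.array([[1, 0]], dtype=np.int8))
        with pytest.raises(ValueError):
            windowed_pi(gm, window_bp=0)


# ---------------------------------------------------------------------------
# allelic richness
# ---------------------------------------------------------------------------


class TestAllelicRichness:
    def test_fixed_locus(self):
        gm = make_gm(np.zeros((1, 6), dtype=np.int8), groups=["A"] * 3 + ["B"] * 3)
        ar = allelic_richness(gm, ["A", "B"])
        assert ar["Ar"].tolist() == pytest.approx([1.0, 1.0])

    def test_combinatorial_example(self):
        # one group with allele counts (7, 3) out of N=10; other group g=4
        dosage = np.array([[2, 2, 2, 1, 0, 1, 1, MISSING, MISSING, MISSING]], dtype=np.int8)
        groups = ["A"] * 5 + ["B"] * 5
        gm = make_gm(dosage)
        gm.groups = dict(zip(gm.samples, groups))
        # group A: dosages 2,2,2,1,0 -> 7 alt, 3 ref of 10; B: 1,1 -> 2 of 4 alleles
        ar = allelic_richness(gm, ["A", "B"])
        a_val = ar.loc[ar["group"] == "A", "Ar"].iloc[0]
        expected = (1 - comb(3, 4) / comb(10, 4)) + (1 - comb(7, 4) / comb(10, 4))
        assert a_val == pytest.approx(expected) == pytest.approx(11 / 6)
        assert a_val == pytest.approx(ar_oracle([7, 3], 4))

    def test_no_rarefaction_limit(self):
        # equal allele counts in both groups: g equals N, Ar = observed alleles
        dosage = np.array([[2, 1, 0, 1, 1, 0]], dtype=np.int8)
        gm = make_gm(dosage, groups=["A"] * 3 + ["B"] * 3)
        ar = allelic_richness(gm, ["A", "B"])
        assert ar["Ar"].tolist() == pytest.approx([2.0, 2.0])

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        dosage = rng.binomial(2, rng.uniform(0.2, 0.8, 8)[:, None], size=(8, 6)).astype(np.int8)
        dosage[rng.random(dosage.shape) < 0.2] = MISSING
        gm = make_gm(dosage, groups=["A"] * 3 + ["B"] * 3)
        counts = {grp: gm.allele_counts(grp) for grp in ("A", "B")}
        g_depth = np.minimum(counts["A"][1], counts["B"][1])
        usable = g_depth >= 2
        if not usable.any():
            pytest.skip("degenerate draw")
        ar = allelic_richness(gm, ["A", "B"])
        for grp in ("A", "B"):
            alt, total = counts[grp]
            vals = [
                ar_oracle([int(alt[i]), int(total[i] - alt[i])], int(g_depth[i]))
                for i in range(8)
                if usable[i]
            ]
            got = ar.loc[ar["group"] == grp, "Ar"].iloc[0]
            assert got == pytest.approx(np.mean(vals))


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


class TestPca:
    def test_duplicated_sample_identical_coordinates(self):
        rng = np.random.default_rng(4)
        dosage = rng.binomial(2, 0.5, size=(50, 5)).astype(np.int8)
        dosage = np.hstack([dosage, dosage[:, [0]]])
        coords, _ = pca(make_gm(dosage))
        first = coords.filter(like="PC").iloc[0].to_numpy()
        dup = coords.filter(like="PC").iloc[-1].to_numpy()
        assert np.allclose(first, dup, atol=1e-6)  # null-space PCs are noise

    def test_explained_variance_spectral_properties(self, tiny_sim):
        _, explained = pca(tiny_sim.sequenced)
        assert explained.sum() <= 1 + 1e-9
        assert (np.diff(explained) <= 1e-12).all()

    def test_two_demes_separate_on_pc1(self):
        rng = np.random.default_rng(9)
        n_var, n_per = 400, 15
        p1 = rng.uniform(0.2, 0.8, n_var)
        shift = rng.choice([-0.25, 0.25], n_var)
        p2 = np.clip(p1 + shift, 0.05, 0.95)
        a = rng.binomial(2, p1[:, None], size=(n_var, n_per))
        b = rng.binomial(2, p2[:, None], size=(n_var, n_per))
        gm = make_gm(np.hstack([a, b]).astype(np.int8), groups=["A"] * n_per + ["B"] * n_per)
        coords, _ = pca(gm)
        deme = (coords["group"] == "B").to_numpy(float)
        r = np.corrcoef(coords["PC1"], deme)[0, 1]
        assert abs(r) > 0.8


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------


class TestWcFst:
    def test_all_heterozygote_groups_give_zero(self):
        """With every individual heterozygous the a-component vanishes exactly."""
        gm = make_gm(np.ones((4, 8), dtype=np.int8), groups=["A"] * 4 + ["B"] * 4)
        res = wc_fst(gm, "A", "B", n_boot=10, rng=np.random.default_rng(0))
        assert abs(res.fst) < 1e-12

    def test_fixed_difference_gives_one(self):
        dosage = np.array([[0, 0, 0, 0, 2, 2, 2, 2]] * 3, dtype=np.int8)
        gm = make_gm(dosage, groups=["A"] * 4 + ["B"] * 4)
        res = wc_fst(gm, "A", "B", n_boot=10, rng=np.random.default_rng(0))
        assert res.fst == pytest.approx(1.0)

    def test_matches_scalar_oracle_on_constructed_case(self):
        dosage = np.array(
            [
                [0, 1, 2, 1, 0, 0, 1, 2],
                [2, 2, 1, 1, 0, 1, 0, 0],
            ],
            dtype=np.int8,
        )
        gm = make_gm(dosage, groups=["A"] * 4 + ["B"] * 4)
        a, b, c = wc_components(gm, "A", "B")
        num = den = 0.0
        for i in range(2):
            ai, bi, ci = wc_theta_oracle(list(dosage[i, :4]), list(dosage[i, 4:]))
            assert a[i] == pytest.approx(ai)
            assert b[i] == pytest.approx(bi)
            assert c[i] == pytest.approx(ci)
            num += ai
            den += ai + bi + ci
        res = wc_fst(gm, "A", "B", n_boot=10, rng=np.random.default_rng(0))
        assert res.fst == pytest.approx(num / den)

    def test_symmetry(self, tiny_sim):
        gm = tiny_sim.sequenced
        r1 = wc_fst(gm, "CR", "HC1", n_boot=10, rng=np.random.default_rng(1))
        r2 = wc_fst(gm, "HC1", "CR", n_boot=10, rng=np.random.default_rng(1))
        assert r1.fst == pytest.approx(r2.fst)

    def test_small_group_rejected(self):
        gm = make_gm(np.zeros((2, 3), dtype=np.int8), groups=["A", "A", "B"])
        with pytest.raises(ValueError):
            wc_fst(gm, "A", "B")

    def test_random_split_centered_at_zero(self):
        rng = np.random.default_rng(11)
        dosage = rng.binomial(2, rng.uniform(0.1, 0.9, 300)[:, None], size=(300, 20)).astype(np.int8)
        thetas = []
        for _ in range(200):
            perm = rng.permutation(20)
            groups = np.empty(20, dtype=object)
            groups[perm[:10]] = "A"
            groups[perm[10:]] = "B"
            gm = make_gm(dosage, groups=list(groups))
            a, b, c = wc_components(gm, "A", "B")
            thetas.append(np.nansum(a) / np.nansum(a + b + c))
        thetas = np.array(thetas)
        se = thetas.std(ddof=1) / np.sqrt(len(thetas))
        assert abs(thetas.mean()) < 2 * se + 1e-4

    def test_negative_theta_not_clamped(self):
        rng = np.random.default_rng(12)
        dosage = rng.binomial(2, 0.5, size=(40, 10)).astype(np.int8)
        gm = make_gm(dosage, groups=["A"] * 5 + ["B"] * 5)
        fst = per_locus_fst(gm, "A", "B")
        assert np.nanmin(fst) < 0  # sampling noise must produce negatives
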
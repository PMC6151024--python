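"""QC filters, LD pruning, frequency and f-statistic estimators."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from uralpop import allele_stats as al
from uralpop.formats import MISSING

from conftest import make_freq_table, make_genotypes, make_samples


# ---------------------------------------------------------------------------
# filter_snps
# ---------------------------------------------------------------------------

def test_filter_snps_strict_thresholds():
    # SNP 0: MAF 0.0005 (1 alt allele in 1000) -> removed at maf_min 0.001
    n = 500
    calls = np.zeros((3, n), dtype=np.int8)
    calls[0, 0] = 1
    calls[1, : n // 2] = 1          # MAF 0.25, kept
    calls[2, :] = MISSING           # all missing -> removed
    g = make_genotypes(calls)
    kept = al.filter_snps(g, maf_min=0.001, call_rate_min=0.0)
    assert list(kept.snp_ids) == ["rs1"]


def test_filter_snps_call_rate_boundary():
    # call rate exactly 0.97 fails the strict inequality
    calls = np.ones((2, 100), dtype=np.int8)
    calls[0, :3] = MISSING   # rate 0.97 -> removed
    calls[1, :2] = MISSING   # rate 0.98 -> kept
    g = make_genotypes(calls)
    kept = al.filter_snps(g, maf_min=0.0, call_rate_min=0.97)
    assert list(kept.snp_ids) == ["rs1"]


# ---------------------------------------------------------------------------
# ld_prune
# ---------------------------------------------------------------------------

def _brute_force_ok(g, window, r2_max):
    """No surviving within-window pair may exceed r2_max."""
    for start in range(0, g.n_snps, 1):
        idx = np.arange(start, min(start + window, g.n_snps))
        for i in idx:
            for j in idx:
                if i >= j or g.chrom[i] != g.chrom[j]:
                    continue
                xi, xj = g.calls[i].astype(float), g.calls[j].astype(float)
                ok = (g.calls[i] != MISSING) & (g.calls[j] != MISSING)
                if ok.sum() < 2 or xi[ok].std() == 0 or xj[ok].std() == 0:
                    continue
                r = np.corrcoef(xi[ok], xj[ok])[0, 1]
                if r * r > r2_max:
                    return False
    return True


def test_ld_prune_duplicate_columns_keep_one():
    rng = np.random.default_rng(3)
    base = rng.integers(0, 3, size=20)
    calls = np.vstack([base, base, rng.integers(0, 3, size=20)]).astype(np.int8)
    g = make_genotypes(calls)
    pruned = al.ld_prune(g, window=3, step=1, r2_max=0.4)
    assert "rs0" in pruned.snp_ids or "rs1" in pruned.snp_ids
    assert not ("rs0" in pruned.snp_ids and "rs1" in pruned.snp_ids)


def test_ld_prune_matches_brute_force_check(rng):
    # 10-SNP toy panel with planted correlated pairs
    n = 40
    base = rng.integers(0, 3, size=(10, n)).astype(np.int8)
    base[3] = base[2]
    flip = rng.random(n) < 0.1
    base[3, flip] = (2 - base[3, flip])
    base[7] = base[6]
    g = make_genotypes(base)
    pruned = al.ld_prune(g, window=6, step=2, r2_max=0.4)
    assert _brute_force_ok(pruned, window=6, r2_max=0.4)
    # determinism
    pruned2 = al.ld_prune(g, window=6, step=2, r2_max=0.4)
    assert list(pruned.snp_ids) == list(pruned2.snp_ids)


def test_ld_prune_ignores_monomorphic():
    calls = np.zeros((3, 10), dtype=np.int8)
    calls[1] = np.arange(10) % 3
    calls[2] = calls[1]
    g = make_genotypes(calls)
    pruned = al.ld_prune(g, window=3, step=1, r2_max=0.4)
    assert "rs0" in pruned.snp_ids  # monomorphic never dropped


# ---------------------------------------------------------------------------
# allele_frequencies
# ---------------------------------------------------------------------------

def test_allele_frequencies_autosomal():
    g = make_genotypes([[0, 1, 2]], samples=["A_0", "A_1", "A_2"])
    samples = make_samples({"A": 3})
    ft = al.allele_frequencies(g, samples, ["A"])
    assert ft.freq[0, 0] == pytest.approx(0.5)
    assert ft.n_alleles[0, 0] == 6
    assert ft.het_count[0, 0] == 1


def test_allele_frequencies_male_chrx_single_allele():
    g = make_genotypes([[0, 2]], chrom=["X"], samples=["A_0", "A_1"])
    samples = make_samples({"A": 2}, sexes={"A": "male"})
    ft = al.allele_frequencies(g, samples, ["A"])
    assert ft.freq[0, 0] == pytest.approx(0.5)
    assert ft.n_alleles[0, 0] == 2


def test_allele_frequencies_all_missing_flagged():
    g = make_genotypes([[MISSING, MISSING]], samples=["A_0", "A_1"])
    samples = make_samples({"A": 2})
    ft = al.allele_frequencies(g, samples, ["A"])
    assert np.isnan(ft.freq[0, 0])
    assert ft.n_alleles[0, 0] == 0


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

def test_wc_fst_single_locus_oracle():
    # p1=0.2, p2=0.8, n=50 diploids each, Hardy-Weinberg heterozygosity;
    # frozen value from a direct evaluation of the 1984 components
    ft = make_freq_table([[0.2, 0.8]], n_alleles=[[100, 100]],
                         het=[[16, 16]])
    assert al.wc_fst(ft, "P0", "P1") == pytest.approx(0.524609843937575,
                                                      abs=1e-12)


def test_wc_fst_fixed_difference_is_one():
    ft = make_freq_table([[0.0, 1.0]], n_alleles=[[100, 100]], het=[[0, 0]])
    assert al.wc_fst(ft, "P0", "P1") == pytest.approx(1.0)


def test_wc_fst_panmictic_near_zero(rng):
    # two samples from one panmictic population: theta within +-0.005 of 0
    n_snps, n = 5000, 100
    p = rng.uniform(0.05, 0.95, n_snps)
    g = make_genotypes(rng.binomial(2, p[:, None], size=(n_snps, 2 * n)),
                       samples=[f"A_{i}" for i in range(n)]
                               + [f"B_{i}" for i in range(n)])
    samples = pd.concat([make_samples({"A": n}), make_samples({"B": n})],
                        ignore_index=True)
    ft = al.allele_frequencies(g, samples, ["A", "B"])
    assert abs(al.wc_fst(ft, "A", "B")) < 0.005


def test_wc_fst_identical_columns_small():
    rng = np.random.default_rng(5)
    p = rng.uniform(0.1, 0.9, 1000)
    calls = rng.binomial(2, p[:, None], size=(1000, 20)).astype(np.int8)
    g = make_genotypes(np.hstack([calls, calls]),
                       samples=[f"A_{i}" for i in range(20)]
                               + [f"B_{i}" for i in range(20)])
    samples = pd.concat([make_samples({"A": 20}), make_samples({"B": 20})],
                        ignore_index=True)
    ft = al.allele_frequencies(g, samples, ["A", "B"])
    assert al.wc_fst(ft, "A", "B") <= 0.01


# ---------------------------------------------------------------------------
# Blocks and jackknife
# ---------------------------------------------------------------------------

def test_make_blocks_counts_and_boundaries():
    chrom = np.array(["1"] * 1200)
    b = al.make_blocks(chrom, 500)
    assert b.m == 3
    assert list(b.snps_per_block) == [500, 500, 200]
    chrom2 = np.array(["1"] * 600 + ["2"] * 10)
    b2 = al.make_blocks(chrom2, 500)
    assert b2.m == 3
    assert b2.block_index[599] != b2.block_index[600]
    b3 = al.make_blocks(np.array(["1"]), 500)
    assert b3.m == 1


def test_block_jackknife_closed_form():
    # leave-one-out ratios 0.1 and 0.3 -> SE = sqrt(0.5*(0.01+0.01)) = 0.1
    blocks = al.BlockSpec(block_index=np.array([0, 1]), m=2,
                          snps_per_block=np.array([1, 1]))
    est, se = al.block_jackknife(np.array([3.0, 1.0]),
                                 np.array([10.0, 10.0]), blocks)
    assert est == pytest.approx(0.2)
    assert se == pytest.approx(0.1, abs=1e-12)


def test_block_jackknife_identical_blocks_zero_se():
    blocks = al.make_blocks(np.array(["1"] * 10), 2)
    num = np.ones(10)
    den = np.full(10, 2.0)
    est, se = al.block_jackknife(num, den, blocks)
    assert est == pytest.approx(0.5)
    assert se == pytest.approx(0.0, abs=1e-15)


def test_block_jackknife_single_block_errors():
    blocks = al.BlockSpec(block_index=np.zeros(5, dtype=int), m=1,
                          snps_per_block=np.array([5]))
    with pytest.raises(ValueError, match="2 usable blocks"):
        al.block_jackknife(np.ones(5), np.ones(5), blocks)


# ---------------------------------------------------------------------------
# f3 and D
# ---------------------------------------------------------------------------

def _toy_blocks(n, size=1):
    return al.make_blocks(np.array(["1"] * n), max(size, 2))


def test_outgroup_f3_hand_computed_mean():
    o = np.array([0.1, 0.5, 0.9, 0.3, 0.6])
    x = np.array([0.2, 0.4, 0.5, 0.3, 0.9])
    y = np.array([0.0, 0.6, 0.8, 0.5, 0.7])
    expected = np.mean((o - x) * (o - y))
    ft = make_freq_table(np.column_stack([o, x, y]))
    res = al.outgroup_f3(ft, "P0", "P1", "P2", _toy_blocks(5, 2))
    assert res.estimate == pytest.approx(expected, abs=1e-12)
    assert res.n_snps == 5


def test_outgroup_f3_symmetric_in_x_y(rng):
    freq = rng.uniform(0.05, 0.95, size=(50, 3))
    ft = make_freq_table(freq)
    b = _toy_blocks(50, 10)
    r1 = al.outgroup_f3(ft, "P0", "P1", "P2", b)
    r2 = al.outgroup_f3(ft, "P0", "P2", "P1", b)
    assert r1.estimate == r2.estimate
    assert r1.std_error == r2.std_error


def test_outgroup_f3_same_population_square():
    freq = np.column_stack([np.array([0.1, 0.9, 0.4, 0.6]),
                            np.array([0.7, 0.2, 0.5, 0.3]),
                            np.array([0.7, 0.2, 0.5, 0.3])])
    ft = make_freq_table(freq)
    res = al.outgroup_f3(ft, "P0", "P1", "P2", _toy_blocks(4, 2))
    assert res.estimate >= 0


def test_d_statistic_hand_computed_ratio():
    a = np.array([0.1, 0.2, 0.9, 0.4])
    b = np.array([0.3, 0.7, 0.5, 0.2])
    c = np.array([0.6, 0.1, 0.8, 0.9])
    d = np.array([0.2, 0.5, 0.3, 0.6])
    num = ((a - b) * (c - d)).sum()
    den = ((a + b - 2 * a * b) * (c + d - 2 * c * d)).sum()
    ft = make_freq_table(np.column_stack([a, b, c, d]))
    res = al.d_statistic(ft, "P0", "P1", "P2", "P3", _toy_blocks(4, 2))
    assert res.estimate == pytest.approx(num / den, abs=1e-12)


def test_d_statistic_symmetries(rng):
    freq = rng.uniform(0.05, 0.95, size=(60, 4))
    freq[:, 3] = freq[:, 2]
    ft = make_freq_table(freq)
    b = _toy_blocks(60, 10)
    res = al.d_statistic(ft, "P0", "P1", "P2", "P3", b)
    assert res.estimate == 0.0  # identical C and D

    freq2 = rng.uniform(0.05, 0.95, size=(60, 4))
    ft2 = make_freq_table(freq2)
    r_cd = al.d_statistic(ft2, "P0", "P1", "P2", "P3", b)
    r_dc = al.d_statistic(ft2, "P0", "P1", "P3", "P2", b)
    assert r_cd.estimate == pytest.approx(-r_dc.estimate, abs=1e-12)
    assert abs(r_cd.z_score) == pytest.approx(abs(r_dc.z_score), abs=1e-9)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_d_statistic_invariant_under_allele_relabeling(seed):
    """Flipping p -> 1-p at a site simultaneously for all four populations
    leaves D unchanged."""
    rng = np.random.default_rng(seed)
    freq = rng.uniform(0.05, 0.95, size=(40, 4))
    flip = rng.random(40) < 0.5
    flipped = freq.copy()
    flipped[flip] = 1.0 - flipped[flip]
    b = _toy_blocks(40, 10)
    r1 = al.d_statistic(make_freq_table(freq), "P0", "P1", "P2", "P3", b)
    r2 = al.d_statistic(make_freq_table(flipped), "P0", "P1", "P2", "P3", b)
    assert r1.estimate == pytest.approx(r2.estimate, abs=1e-12)
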
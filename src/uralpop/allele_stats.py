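"""SNP QC, LD pruning, allele frequencies and allele-frequency statistics.

Implements the Weir & Cockerham (1984) two-population F_ST estimator, the
outgroup f3-statistic and the Patterson D-statistic, each as a
ratio-of-averages over SNPs with standard errors from a delete-one-block
jackknife over contiguous genomic blocks.

Sign convention for D(A, B; C, D) with A the outgroup and B the test
population: excess allele sharing (shared drift) between B and C drives D
negative; sharing between B and D drives it positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import MISSING, GenotypeDataset, ValidationError


@dataclass
class FreqTable:
    """Per-population alt-allele frequencies with allele-count bookkeeping.

    ``freq`` is NaN where a population has zero genotyped alleles at a SNP
    (the "unavailable" flag).  ``n_alleles`` counts 2 per genotyped diploid
    call, except male chrX calls which contribute 1.  ``het_count`` counts
    observed heterozygotes (calls equal to 1).
    """

    pops: list[str]
    freq: np.ndarray        # (n_snps, n_pops), NaN = unavailable
    n_alleles: np.ndarray   # (n_snps, n_pops) int
    het_count: np.ndarray   # (n_snps, n_pops) int
    n_diploid: np.ndarray   # (n_snps, n_pops) int, genotyped diploid calls
    chrom: np.ndarray
    pos_bp: np.ndarray

    @property
    def n_snps(self) -> int:
        return self.freq.shape[0]

    def col(self, pop: str) -> int:
        try:
            return self.pops.index(pop)
        except ValueError:
            raise KeyError(f"population {pop!r} not in frequency table") from None


@dataclass
class BlockSpec:
    """Assignment of SNPs to contiguous genomic blocks for the jackknife."""

    block_index: np.ndarray  # per-SNP block id, contiguous in (chrom, pos)
    m: int
    snps_per_block: np.ndarray

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValidationError("block count must be >= 1")


@dataclass
class FStatResult:
    kind: str               # "f3_outgroup" or "D"
    estimate: float
    std_error: float
    z_score: float
    n_snps: int
    n_blocks: int

    @property
    def significant(self) -> bool:
        """|Z| > 3, the conventional threshold for D-statistics."""
        return abs(self.z_score) > 3


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def filter_snps(g: GenotypeDataset, maf_min: float = 0.001,
                call_rate_min: float = 0.97) -> GenotypeDataset:
    """Keep SNPs with overall MAF > maf_min and call rate > call_rate_min.

    Both inequalities are strict: a SNP at exactly the threshold is removed.
    MAF is computed on the pooled sample.
    """
    if not (0 <= maf_min <= 1 and 0 <= call_rate_min <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    called = g.calls != MISSING
    n_called = called.sum(axis=1)
    call_rate = n_called / g.n_samples
    alt = np.where(called, g.calls, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0, alt / (2.0 * n_called), 0.0)
    maf = np.minimum(freq, 1.0 - freq)
    keep = (maf > maf_min) & (call_rate > call_rate_min)
    if not keep.any():
        warnings.warn("filter_snps removed every SNP")
    return g.subset_snps(keep)


def _pairwise_r2(calls: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between SNP dosage rows.

    Missing calls are excluded pairwise.  Pairs with zero variance in either
    member (over the complete observations) get r^2 = 0 so monomorphic SNPs
    never trigger drops.
    """
    x = calls.astype(float)
    mask = (calls != MISSING).astype(float)
    x = np.where(calls == MISSING, 0.0, x)
    n = mask @ mask.T
    sx = x @ mask.T
    sy = mask @ x.T
    sxy = x @ x.T
    sxx = (x * x) @ mask.T
    syy = mask @ (x * x).T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        r2 = cov * cov / (vx * vy)
    r2[~np.isfinite(r2)] = 0.0
    np.fill_diagonal(r2, 0.0)
    return r2


def ld_prune(g: GenotypeDataset, window: int = 200, step: int = 25,
             r2_max: float = 0.4) -> GenotypeDataset:
    """Greedy sliding-window LD pruning of genotype dosage correlations.

    Within each window of ``window`` SNPs (advanced by ``step``), any retained
    pair with r^2 > r2_max loses its lower-MAF member (tie: the later SNP is
    dropped).  Deterministic for fixed input.
    """
    if not window > step > 0:
        raise ValueError("require window > step > 0")
    called = g.calls != MISSING
    n_called = called.sum(axis=1)
    alt = np.where(called, g.calls, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0, alt / (2.0 * n_called), 0.0)
    maf = np.minimum(freq, 1.0 - freq)

    keep = np.ones(g.n_snps, dtype=bool)
    for c in pd.unique(g.chrom):
        idx = np.flatnonzero(g.chrom == c)
        for start in range(0, len(idx), step):
            widx = idx[start:start + window]
            if len(widx) < 2:
                continue
            r2 = _pairwise_r2(g.calls[widx])
            for jj in range(1, len(widx)):
                if not keep[widx[jj]]:
                    continue
                for ii in range(jj):
                    if not (keep[widx[ii]] and keep[widx[jj]]):
                        continue
                    if r2[ii, jj] > r2_max:
                        a, b = widx[ii], widx[jj]
                        # drop lower MAF; tie -> larger index
                        drop = b if maf[b] <= maf[a] else a
                        keep[drop] = False
                        if drop == widx[jj]:
                            break
            if len(widx) < window:
                break
    return g.subset_snps(keep)


# ---------------------------------------------------------------------------
# Frequencies
# ---------------------------------------------------------------------------

def allele_frequencies(g: GenotypeDataset, samples: pd.DataFrame,
                       populations: list[str] | None = None) -> FreqTable:
    """Alt-allele frequency per population per SNP.

    Missing calls are excluded from numerator and denominator.  On chrX,
    male calls (0/2 hemizygotes) contribute a single allele: the allele
    count is 2 per genotyped female plus 1 per genotyped male, and the alt
    count adds call/2 per male.
    """
    if populations is None:
        populations = list(pd.unique(samples["population"]))
    sex = dict(zip(samples["sample_id"], samples["sex"]))
    pop_of = dict(zip(samples["sample_id"], samples["population"]))
    is_x = g.chrom == "X"

    n_snps = g.n_snps
    n_pops = len(populations)
    freq = np.full((n_snps, n_pops), np.nan)
    n_alleles = np.zeros((n_snps, n_pops), dtype=np.int64)
    het = np.zeros((n_snps, n_pops), dtype=np.int64)
    n_dip = np.zeros((n_snps, n_pops), dtype=np.int64)

    for k, pop in enumerate(populations):
        members = [s for s in g.samples if pop_of.get(s) == pop]
        if not members:
            raise ValueError(f"population {pop!r} has no genotyped samples")
        cols = g.sample_index(members)
        male = np.array([sex.get(s) == "male" for s in members])
        calls = g.calls[:, cols]
        called = calls != MISSING
        alt_sum = np.where(called, calls, 0).sum(axis=1).astype(float)
        n2 = 2 * called.sum(axis=1)
        n_dip[:, k] = called.sum(axis=1)
        het[:, k] = (calls == 1).sum(axis=1)
        # chrX males: one allele each, dosage/2 alt alleles
        if is_x.any() and male.any():
            mcalls = calls[:, male]
            mcalled = mcalls != MISSING
            m_n = mcalled.sum(axis=1)
            m_alt = np.where(mcalled, mcalls, 0).sum(axis=1) / 2.0
            alt_sum = np.where(is_x, alt_sum - 2 * m_alt + m_alt, alt_sum)
            n2 = np.where(is_x, n2 - m_n, n2)
        n_alleles[:, k] = n2
        with np.errstate(invalid="ignore", divide="ignore"):
            f = alt_sum / n2
        freq[:, k] = np.where(n2 > 0, f, np.nan)

    return FreqTable(pops=list(populations), freq=freq, n_alleles=n_alleles,
                     het_count=het, n_diploid=n_dip,
                     chrom=g.chrom.copy(), pos_bp=g.pos_bp.copy())


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

def wc_fst_components(freqs: FreqTable, popA: str, popB: str
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP Weir & Cockerham (1984) variance components (a, b, c).

    Two-population case (r = 2) with sample sizes in diploid equivalents
    (n_alleles / 2) and observed heterozygote frequencies.  SNPs lacking
    data in either population, or with fewer than two diploid equivalents
    on average, are masked NaN.
    """
    ia, ib = freqs.col(popA), freqs.col(popB)
    p1, p2 = freqs.freq[:, ia], freqs.freq[:, ib]
    n1 = freqs.n_alleles[:, ia] / 2.0
    n2 = freqs.n_alleles[:, ib] / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        h1 = np.where(n1 > 0, freqs.het_count[:, ia] / n1, np.nan)
        h2 = np.where(n2 > 0, freqs.het_count[:, ib] / n2, np.nan)

        r = 2.0
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)

        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2
                                 - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2
                                     - ((2 * nbar - 1) / (4 * nbar)) * hbar)
        c = hbar / 2.0

    usable = (np.isfinite(p1) & np.isfinite(p2) & (n1 > 0) & (n2 > 0)
              & (nbar > 1) & (nc > 0))
    a = np.where(usable, a, np.nan)
    b = np.where(usable, b, np.nan)
    c = np.where(usable, c, np.nan)
    return a, b, c


def wc_fst(freqs: FreqTable, popA: str, popB: str) -> float:
    """Weir & Cockerham theta-hat as a ratio of averages: sum a / sum(a+b+c)."""
    a, b, c = wc_fst_components(freqs, popA, popB)
    usable = np.isfinite(a)
    if not usable.any():
        raise ValueError(f"no SNPs shared between {popA!r} and {popB!r}")
    num = np.nansum(a[usable])
    den = np.nansum((a + b + c)[usable])
    if den == 0:
        raise ValueError("zero total variance; F_ST undefined")
    return float(num / den)


# ---------------------------------------------------------------------------
# Blocks and jackknife
# ---------------------------------------------------------------------------

def make_blocks(chrom: np.ndarray, block_size_snps: int = 500) -> BlockSpec:
    """Contiguous blocks of at most ``block_size_snps``, never spanning
    chromosome boundaries."""
    if block_size_snps < 2:
        raise ValueError("block size must be >= 2")
    chrom = np.asarray(chrom)
    block_index = np.empty(len(chrom), dtype=np.int64)
    next_block = 0
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        within = np.arange(len(idx)) // block_size_snps
        block_index[idx] = next_block + within
        next_block += int(within[-1]) + 1 if len(idx) else 0
    counts = np.bincount(block_index, minlength=next_block)
    return BlockSpec(block_index=block_index, m=next_block,
                     snps_per_block=counts)


def block_jackknife(numerators: np.ndarray, denominators: np.ndarray,
                    blocks: BlockSpec) -> tuple[float, float]:
    """Delete-one-block jackknife for a ratio statistic.

    Returns (estimate, std_error): the estimate is the full-data ratio
    sum(num)/sum(den); SE^2 = ((m-1)/m) * sum_j (theta_(j) - theta_bar)^2
    with theta_(j) the leave-one-out ratios and theta_bar their mean
    (equal-weight form; blocks are built with near-equal SNP counts).
    Blocks whose removal zeroes the denominator are merged into the
    preceding block (or following, for the first) with a warning.
    """
    numerators = np.asarray(numerators, dtype=float)
    denominators = np.asarray(denominators, dtype=float)
    usable = np.isfinite(numerators) & np.isfinite(denominators)
    num_b = np.bincount(blocks.block_index[usable],
                        weights=numerators[usable], minlength=blocks.m)
    den_b = np.bincount(blocks.block_index[usable],
                        weights=denominators[usable], minlength=blocks.m)
    # drop blocks with no usable SNPs at all; merge blocks that would leave
    # a zero denominator when deleted
    has_data = np.bincount(blocks.block_index[usable],
                           minlength=blocks.m) > 0
    num_b, den_b = num_b[has_data], den_b[has_data]
    tot_num, tot_den = num_b.sum(), den_b.sum()
    if tot_den == 0:
        raise ValueError("zero denominator over all SNPs; statistic undefined")

    loo_den = tot_den - den_b
    while (loo_den == 0).any() and len(num_b) > 1:
        j = int(np.flatnonzero(loo_den == 0)[0])
        k = j - 1 if j > 0 else j + 1
        warnings.warn(f"merging jackknife block {j} into its neighbour "
                      "(zero leave-one-out denominator)")
        num_b[k] += num_b[j]
        den_b[k] += den_b[j]
        num_b = np.delete(num_b, j)
        den_b = np.delete(den_b, j)
        loo_den = den_b.sum() - den_b

    m = len(num_b)
    if m < 2:
        raise ValueError("block jackknife requires at least 2 usable blocks")
    estimate = tot_num / tot_den
    theta_j = (tot_num - num_b) / loo_den
    theta_bar = theta_j.mean()
    se = np.sqrt((m - 1) / m * ((theta_j - theta_bar) ** 2).sum())
    return float(estimate), float(se)


# ---------------------------------------------------------------------------
# f3 and D
# ---------------------------------------------------------------------------

def _freq_cols(freqs: FreqTable, pops: list[str]) -> list[np.ndarray]:
    return [freqs.freq[:, freqs.col(p)] for p in pops]


def outgroup_f3(freqs: FreqTable, outgroup: str, X: str, Y: str,
                blocks: BlockSpec) -> FStatResult:
    """Outgroup f3(outgroup; X, Y) = mean over SNPs of (o - x)(o - y).

    Proportional to the drift shared by X and Y relative to the outgroup.
    No finite-sample bias correction or heterozygosity normalization is
    applied.  SE and Z come from the delete-one-block jackknife.
    """
    if len({outgroup, X, Y}) != 3:
        raise ValueError("outgroup, X and Y must be three distinct populations")
    o, x, y = _freq_cols(freqs, [outgroup, X, Y])
    usable = np.isfinite(o) & np.isfinite(x) & np.isfinite(y)
    num = np.where(usable, (o - x) * (o - y), np.nan)
    den = np.where(usable, 1.0, np.nan)
    est, se = block_jackknife(num, den, blocks)
    z = est / se if se > 0 else np.inf * np.sign(est) if est else 0.0
    n_blocks = len(np.unique(blocks.block_index[usable]))
    return FStatResult("f3_outgroup", est, se, float(z),
                       int(usable.sum()), n_blocks)


def d_statistic(freqs: FreqTable, A: str, B: str, C: str, D: str,
                blocks: BlockSpec) -> FStatResult:
    """Patterson D for (A, B; C, D) with A the outgroup and B the test pop.

    D = sum (a-b)(c-d) / sum (a+b-2ab)(c+d-2cd); shared drift between the
    test population B and C drives D negative.  Z from the block jackknife;
    |Z| > 3 is the conventional significance threshold (see
    FStatResult.significant).
    """
    if len({A, B, C, D}) != 4:
        raise ValueError("D-statistic requires four distinct populations")
    a, b, c, d = _freq_cols(freqs, [A, B, C, D])
    usable = (np.isfinite(a) & np.isfinite(b) & np.isfinite(c) & np.isfinite(d))
    num = np.where(usable, (a - b) * (c - d), np.nan)
    den = np.where(usable, (a + b - 2 * a * b) * (c + d - 2 * c * d), np.nan)
    est, se = block_jackknife(num, den, blocks)
    z = est / se if se > 0 else 0.0
    n_blocks = len(np.unique(blocks.block_index[usable]))
    return FStatResult("D", est, se, float(z), int(usable.sum()), n_blocks)
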
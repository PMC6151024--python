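import numpy as np
import pandas as pd
import pytest

from uralpop.allele_stats import FreqTable
from uralpop.formats import GenotypeDataset


def make_genotypes(calls, chrom=None, samples=None, pos_bp=None,
                   pos_cm=None) -> GenotypeDataset:
    """Small genotype dataset from a (n_snps, n_samples) call array."""
    calls = np.asarray(calls, dtype=np.int8)
    n_snps, n_samples = calls.shape
    if chrom is None:
        chrom = ["1"] * n_snps
    if samples is None:
        samples = [f"s{j}" for j in range(n_samples)]
    if pos_bp is None:
        pos_bp = np.arange(1, n_snps + 1) * 1000
    if pos_cm is None:
        pos_cm = np.asarray(pos_bp) / 1e6
    return GenotypeDataset(
        snp_ids=np.array([f"rs{i}" for i in range(n_snps)]),
        chrom=np.asarray(chrom), pos_bp=np.asarray(pos_bp, dtype=np.int64),
        pos_cm=np.asarray(pos_cm, dtype=float),
        ref=np.array(["A"] * n_snps), alt=np.array(["G"] * n_snps),
        samples=list(samples), calls=calls,
    )


def make_samples(pops: dict[str, int], sexes=None, region="r1",
                 language="Uralic:Finnic", coords=None) -> pd.DataFrame:
    """Sample table with ``pops`` mapping population -> n_samples."""
    rows = []
    for pop, n in pops.items():
        lat, lon = (coords or {}).get(pop, (60.0, 25.0))
        for k in range(n):
            rows.append({
                "sample_id": f"{pop}_{k}", "population": pop,
                "sex": (sexes or {}).get(pop, "female"),
                "language_group": language, "region": region,
                "lat": lat, "lon": lon,
            })
    return pd.DataFrame(rows)


def make_freq_table(freq, n_alleles=None, het=None, chrom=None) -> FreqTable:
    """FreqTable from a (n_snps, n_pops) frequency array."""
    freq = np.asarray(freq, dtype=float)
    n_snps, n_pops = freq.shape
    if n_alleles is None:
        n_alleles = np.full_like(freq, 100, dtype=np.int64)
    if het is None:
        het = np.zeros_like(freq, dtype=np.int64)
    if chrom is None:
        chrom = ["1"] * n_snps
    return FreqTable(
        pops=[f"P{k}" for k in range(n_pops)], freq=freq,
        n_alleles=np.asarray(n_alleles, dtype=np.int64),
        het_count=np.asarray(het, dtype=np.int64),
        n_diploid=np.asarray(n_alleles, dtype=np.int64) // 2,
        chrom=np.asarray(chrom),
        pos_bp=np.arange(1, n_snps + 1, dtype=np.int64),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
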
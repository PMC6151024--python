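"""Replicated calibration and power studies over synthetic scenarios.

Each function here runs one self-contained Monte-Carlo study against the
generator's planted truth: type-I calibration of the IBD permutation test,
the Mantel/partial-Mantel tests, the sex-bias ANOVA and the D-statistic
|Z| > 3 rule under null scenarios, and detection power for the planted
IBD excess, gene-language correlation and male-biased admixture under
study-like scenarios.  The replicate counts and problem sizes are scaled
so a full suite runs in minutes on one CPU; sizes are stated per function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ibd as ibd_mod
from .allele_stats import (FreqTable, allele_frequencies, d_statistic,
                           make_blocks, wc_fst)
from .correlation import mantel, partial_mantel
from .distances import (DistanceMatrix, build_distance_matrix,
                        geographic_distance_matrix, patristic_distances,
                        tvd_groups)
from .formats import is_uralic
from .sexbias import classify_pairs, paired_f3_table, sexbias_anova
from .simulate import (PopulationSpec, ScenarioConfig, child_seeds,
                       make_scenario, null_world, simulate_ibd_tracts,
                       uralic_world)


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _seed_stream(seed: int, n: int, tag: str) -> list[int]:
    return list(child_seeds(seed, [f"{tag}{i}" for i in range(n)]).values())


def freq_table_from_draws(freq: np.ndarray, n_diploid: int) -> FreqTable:
    """FreqTable around directly drawn sample frequencies (one chromosome).

    Used by replicated studies that need population frequency estimates
    without materialising genotype matrices; the binomial draw of allele
    counts matches the distribution of mean genotype dosages.
    """
    n_snps, n_pops = freq.shape
    return FreqTable(
        pops=[f"P{k}" for k in range(n_pops)],
        freq=freq,
        n_alleles=np.full((n_snps, n_pops), 2 * n_diploid, dtype=np.int64),
        het_count=np.zeros((n_snps, n_pops), dtype=np.int64),
        n_diploid=np.full((n_snps, n_pops), n_diploid, dtype=np.int64),
        chrom=np.array(["1"] * n_snps),
        pos_bp=np.arange(1, n_snps + 1, dtype=np.int64),
    )


def fst_distance_matrix(freqs: FreqTable, pops: list[str]) -> DistanceMatrix:
    """Pairwise Weir-Cockerham F_ST matrix, negative estimates floored at 0
    so the result is a valid distance matrix."""
    return build_distance_matrix(
        lambda a, b: max(0.0, wc_fst(freqs, a, b)), pops)


def tvd_distance_matrix(chunkcounts, samples: pd.DataFrame,
                        pops: list[str]) -> DistanceMatrix:
    members = {p: list(samples.loc[samples["population"] == p, "sample_id"])
               for p in pops}

    def fn(a: str, b: str) -> float:
        return tvd_groups(chunkcounts, members[a], members[b])

    return build_distance_matrix(fn, pops)


# ---------------------------------------------------------------------------
# D-statistic null calibration
# ---------------------------------------------------------------------------

def dstat_null_calibration(seed: int, n_rep: int = 200, n_snps: int = 10000,
                           n_diploid: int = 25, f_drift: float = 0.1,
                           block_size: int = 500) -> dict:
    """Fraction of |Z| > 3 calls for D under a star phylogeny.

    Four populations drift independently (Balding-Nichols F) from a shared
    ancestral frequency, so no pair shares drift and D has expectation 0;
    the |Z| > 3 call rate should stay below 2%.
    """
    seeds = _seed_stream(seed, n_rep, "dnull")
    blocks = make_blocks(np.array(["1"] * n_snps), block_size)
    n_sig = 0
    for s in seeds:
        rng = np.random.default_rng(s)
        p_anc = rng.uniform(0.05, 0.95, n_snps)
        scale = (1 - f_drift) / f_drift
        pop = rng.beta(p_anc[:, None] * scale,
                       (1 - p_anc)[:, None] * scale, size=(n_snps, 4))
        freq = rng.binomial(2 * n_diploid, pop) / (2.0 * n_diploid)
        ft = freq_table_from_draws(freq, n_diploid)
        res = d_statistic(ft, "P0", "P1", "P2", "P3", blocks)
        n_sig += int(abs(res.z_score) > 3)
    return {"rate": n_sig / n_rep, "n_rep": n_rep}


# ---------------------------------------------------------------------------
# IBD permutation test: calibration and power
# ---------------------------------------------------------------------------

_IBD_POPS = ["Finns", "Udmurts", "Swedes", "Latvians", "Estonians"]
_IBD_TARGET, _IBD_PARTNER = "Finns", "Udmurts"
_IBD_CONTROLS = ["Swedes", "Latvians"]


def _ibd_trial(cfg: ScenarioConfig, pops: list[str], n_perm: int,
               seed: int) -> float:
    """One tract simulation + full post-processing + permutation test;
    returns the p-value for the 1-2 cM bin."""
    specs = {p.name: p for p in cfg.populations if p.name in pops}
    rows = []
    for p in specs.values():
        for k in range(p.n_samples):
            rows.append({"sample_id": f"{p.name}_{k:03d}", "population": p.name,
                         "sex": "male" if k % 2 else "female",
                         "language_group": p.language_group, "region": p.region,
                         "lat": p.lat, "lon": p.lon})
    samples = pd.DataFrame(rows)
    s1, s2 = _seed_stream(seed, 2, "ibdtrial")
    tracts = simulate_ibd_tracts(samples, specs, cfg.ibd_base_rate,
                                 cfg.ibd_length_mean_cm,
                                 cfg.geo_decay_scale_km,
                                 cfg.uralic_excess_multiplier, s1)
    tracts = ibd_mod.consensus_filter(tracts)
    tracts = ibd_mod.merge_gaps(tracts)
    binned = ibd_mod.bin_by_length(tracts)
    res = ibd_mod.control_permutation_test(
        binned["1-2"], samples, _IBD_TARGET, _IBD_PARTNER, _IBD_CONTROLS,
        bin_label="1-2", n_perm=n_perm, seed=s2)
    return res.p_value


def ibd_null_calibration(seed: int, n_rep: int = 200, n_perm: int = 299,
                         n_samples: int = 15) -> dict:
    """Type-I rate of the control permutation test under an exchangeable
    null (no Uralic excess, flat geography)."""
    cfg = null_world(seed=0, n_samples=n_samples)
    seeds = _seed_stream(seed, n_rep, "ibdnull")
    n_rej = 0
    for s in seeds:
        p = _ibd_trial(cfg, _IBD_POPS, n_perm, s)
        n_rej += int(p < 0.05)
    return {"rate": n_rej / n_rep, "n_rep": n_rep}


def ibd_excess_power(seed: int, n_rep: int = 100, n_perm: int = 299,
                     n_samples: int = 15) -> dict:
    """Detection rate (p < 0.05) for the planted three-fold cross-regional
    Uralic IBD excess under study-like geography."""
    cfg = uralic_world(seed=0, n_samples=n_samples)
    seeds = _seed_stream(seed, n_rep, "ibdpow")
    n_rej = 0
    for s in seeds:
        p = _ibd_trial(cfg, _IBD_POPS, n_perm, s)
        n_rej += int(p < 0.05)
    return {"rate": n_rej / n_rep, "n_rep": n_rep}


# ---------------------------------------------------------------------------
# Mantel framework: calibration and power
# ---------------------------------------------------------------------------

def _euclid_matrix(rng: np.random.Generator, n: int) -> DistanceMatrix:
    pts = rng.normal(size=(n, 2))
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=-1))
    return DistanceMatrix([f"L{i}" for i in range(n)], d)


def mantel_independent_calibration(seed: int, n_rep: int = 200, n: int = 30,
                                   n_perm: int = 199) -> dict:
    """Rejection rate of the Mantel test on independent random geometries."""
    seeds = _seed_stream(seed, n_rep, "mnull")
    n_rej = 0
    for s in seeds:
        rng = np.random.default_rng(s)
        d1 = _euclid_matrix(rng, n)
        d2 = _euclid_matrix(rng, n)
        res = mantel(d1, d2, n_perm=n_perm, seed=s & 0x7FFFFFFF)
        n_rej += int(res.p_value < 0.05)
    return {"rate": n_rej / n_rep, "n_rep": n_rep}


def _reduced_uralic_cfg(base_cfg_fn, seed: int, n_samples: int,
                        n_snps_auto: int, n_snps_x: int) -> ScenarioConfig:
    base = base_cfg_fn(seed=seed)
    pops = [p for p in base.populations if is_uralic(p.language_group)]
    for p in pops:
        p.n_samples = n_samples
    return ScenarioConfig(
        populations=pops, outgroup=None, n_snps_auto=n_snps_auto,
        n_snps_x=n_snps_x, f_shared=base.f_shared,
        f_siberian=base.f_siberian,
        uralic_excess_multiplier=base.uralic_excess_multiplier,
        geo_decay_scale_km=base.geo_decay_scale_km,
        lexical_genetic_correlation=base.lexical_genetic_correlation,
        seed=seed)


def gene_language_trial(cfg: ScenarioConfig, n_perm: int, seed: int) -> float:
    """Partial Mantel p for lexical vs autosomal F_ST keeping geography."""
    bundle = make_scenario(cfg)
    uralic = [p.name for p in cfg.populations if is_uralic(p.language_group)]
    g_auto = bundle.genotypes.subset_snps(bundle.genotypes.chrom != "X")
    freqs = allele_frequencies(g_auto, bundle.samples, uralic)
    gen = fst_distance_matrix(freqs, uralic)
    lex = patristic_distances(bundle.lexical_tree).submatrix(uralic)
    geo = geographic_distance_matrix(bundle.samples, uralic)
    return partial_mantel(lex, gen, geo, n_perm=n_perm, seed=seed).p_value


def gene_language_calibration(seed: int, n_rep: int = 200, n_perm: int = 199,
                              n_samples: int = 10, n_snps_auto: int = 3000
                              ) -> dict:
    """Rejection rate of the partial Mantel (lexical vs F_ST | geography)
    when the generator plants no gene-language coupling (rho = 0)."""
    seeds = _seed_stream(seed, n_rep, "glnull")
    n_rej = 0
    for s in seeds:
        cfg = _reduced_uralic_cfg(null_world, s & 0x7FFFFFFF, n_samples,
                                  n_snps_auto, 100)
        p = gene_language_trial(cfg, n_perm, s & 0x7FFFFFFF)
        n_rej += int(p < 0.05)
    return {"rate": n_rej / n_rep, "n_rep": n_rep}


def uralic_panel(n_pops: int = 15, rho: float = 0.6, seed: int = 0,
                 n_samples: int = 12, n_snps_auto: int = 3000,
                 n_snps_x: int = 100) -> ScenarioConfig:
    """A wider all-Uralic panel for the gene-language power study.

    Population attributes are fixed (no randomness): a west-east Siberian
    ancestry cline with population-specific deviations, drift levels cycling
    over realistic magnitudes, and coordinates spanning the study area.
    """
    f_cycle = [0.01, 0.03, 0.06, 0.02, 0.08]
    dev_cycle = [0.15, -0.10, 0.0, 0.05, -0.15]
    regions = ["Baltic-Scandinavian", "Eastern European-Volga", "Siberian"]
    pops = []
    for i in range(n_pops):
        lon = 20 + 70 * i / (n_pops - 1)
        lat = 58 + 8 * math.sin(2.3 * i)
        alpha = min(0.95, max(0.0, 0.8 * (lon - 20) / 70 + dev_cycle[i % 5]))
        pops.append(PopulationSpec(
            name=f"U{i:02d}", region=regions[(3 * i) // n_pops],
            language_group="Uralic:Synthetic", n_samples=n_samples,
            lat=lat, lon=lon, f_drift=f_cycle[i % 5],
            alpha_m=alpha, alpha_f=alpha, n3_freq=0.4))
    return ScenarioConfig(populations=pops, outgroup=None,
                          n_snps_auto=n_snps_auto, n_snps_x=n_snps_x,
                          lexical_genetic_correlation=rho, seed=seed)


def gene_language_power(seed: int, n_rep: int = 100, n_perm: int = 999,
                        n_pops: int = 15, rho: float = 0.6) -> dict:
    """Detection rate of the planted gene-language correlation (rho = 0.6,
    15 Uralic populations) by the partial Mantel test keeping geography."""
    seeds = _seed_stream(seed, n_rep, "glpow")
    n_rej = 0
    for s in seeds:
        cfg = uralic_panel(n_pops=n_pops, rho=rho, seed=s & 0x7FFFFFFF)
        p = gene_language_trial(cfg, n_perm, s & 0x7FFFFFFF)
        n_rej += int(p < 0.05)
    return {"rate": n_rej / n_rep, "n_rep": n_rep}


# ---------------------------------------------------------------------------
# Sex-bias ANOVA: calibration and power
# ---------------------------------------------------------------------------

def sexbias_panel(n_pairs: int = 8, alpha_m_high: float = 0.3,
                  alpha_f_high: float = 0.0, calibration: bool = False,
                  n_samples: int = 12, n_snps_auto: int = 25000,
                  n_snps_x: int = 10000, seed: int = 0
                  ) -> tuple[ScenarioConfig, list[tuple[str, str]]]:
    """Disjoint-pair scenario for the autosome-vs-chrX affinity contrast.

    ``n_pairs`` (test, comparison) pairs per group.  Test populations all
    carry autosomal Siberian ancestry 0.15; in the power design the
    high-group tests receive it male-biased (alpha_m, alpha_f as given,
    default 0.3/0.0 so only the chrX fraction differs), while in the
    calibration design every test population is sex-symmetric and the
    high/low labels come from the N3-M178 frequencies alone - the two
    groups are then genetically identical processes.  Comparison
    populations are Siberian-ancestry populations whose admixture fraction
    ladders over [0.6, 1.0] in both groups, giving the within-group
    affinity spread the regression needs.  Pairs are disjoint so the ANOVA
    rows are independent.
    """
    if calibration:
        am_h, af_h = 0.15, 0.15
    else:
        am_h, af_h = alpha_m_high, alpha_f_high
    pops: list[PopulationSpec] = []
    pairs: list[tuple[str, str]] = []
    for i in range(n_pairs):
        a_comp = 0.6 + 0.4 * i / max(n_pairs - 1, 1)
        lon = 60.0 + i
        pops.append(PopulationSpec(
            name=f"HT{i:02d}", region="Siberian", language_group="Uralic:Synthetic",
            n_samples=n_samples, lat=60.0, lon=lon, f_drift=0.02,
            alpha_m=am_h, alpha_f=af_h, n3_freq=0.75))
        pops.append(PopulationSpec(
            name=f"HC{i:02d}", region="Siberian", language_group="Turkic:Synthetic",
            n_samples=n_samples, lat=65.0, lon=lon, f_drift=0.02,
            alpha_m=a_comp, alpha_f=a_comp, n3_freq=0.75))
        pops.append(PopulationSpec(
            name=f"LT{i:02d}", region="Siberian", language_group="Uralic:Synthetic",
            n_samples=n_samples, lat=55.0, lon=lon, f_drift=0.02,
            alpha_m=0.15, alpha_f=0.15, n3_freq=0.02))
        pops.append(PopulationSpec(
            name=f"LC{i:02d}", region="Siberian", language_group="Turkic:Synthetic",
            n_samples=n_samples, lat=50.0, lon=lon, f_drift=0.02,
            alpha_m=a_comp, alpha_f=a_comp, n3_freq=0.02))
        pairs.append((f"HT{i:02d}", f"HC{i:02d}"))
        pairs.append((f"LT{i:02d}", f"LC{i:02d}"))
    outgroup = PopulationSpec(name="Outgroup", region="Africa",
                              language_group="NigerCongo:Defoid",
                              n_samples=20, lat=7.4, lon=3.9, f_drift=0.0)
    cfg = ScenarioConfig(populations=pops, outgroup=outgroup,
                         n_snps_auto=n_snps_auto, n_snps_x=n_snps_x,
                         f_siberian=0.25, f_outgroup=0.1,
                         ibd_base_rate=0.0, chunk_total=100,
                         hg_sample_size=50, seed=seed)
    return cfg, pairs


def sexbias_trial(cfg: ScenarioConfig, pairs: list[tuple[str, str]]) -> float:
    """One generated panel through the full sex-bias pipeline; returns the
    ANOVA group-term p-value."""
    bundle = make_scenario(cfg)
    g = bundle.genotypes
    g_auto = g.subset_snps(g.chrom != "X")
    g_x = g.subset_snps(g.chrom == "X")
    pops = [p.name for p in cfg.populations] + [cfg.outgroup.name]
    freqs_auto = allele_frequencies(g_auto, bundle.samples, pops)
    freqs_x = allele_frequencies(g_x, bundle.samples, pops)
    blocks_auto = make_blocks(g_auto.chrom, 500)
    blocks_x = make_blocks(g_x.chrom, 500)
    n3 = dict(zip(bundle.summaries["population"],
                  bundle.summaries["n3_m178_freq"]))
    table = paired_f3_table(freqs_auto, freqs_x, cfg.outgroup.name,
                            [a for a, _ in pairs], [b for _, b in pairs],
                            blocks_auto, blocks_x, n3, pairs=pairs)
    table = classify_pairs(table)
    return sexbias_anova(table).p_group


def sexbias_calibration(seed: int, n_rep: int = 200, n_pairs: int = 6,
                        n_samples: int = 10, n_snps_auto: int = 6000,
                        n_snps_x: int = 2500) -> dict:
    """Type-I rate of the ANOVA group term with no planted sex bias."""
    seeds = _seed_stream(seed, n_rep, "sbnull")
    n_rej = 0
    for s in seeds:
        cfg, pairs = sexbias_panel(n_pairs=n_pairs, calibration=True,
                                   n_samples=n_samples,
                                   n_snps_auto=n_snps_auto,
                                   n_snps_x=n_snps_x, seed=s & 0x7FFFFFFF)
        n_rej += int(sexbias_trial(cfg, pairs) < 0.05)
    return {"rate": n_rej / n_rep, "n_rep": n_rep}


def sexbias_power(seed: int, n_rep: int = 100, n_pairs: int = 8,
                  alpha_m: float = 0.3, alpha_f: float = 0.0) -> dict:
    """Detection rate of planted male-biased admixture (alpha_m = 0.3,
    alpha_f = 0 in the high-co-ancestry donors) by the ANOVA group term."""
    seeds = _seed_stream(seed, n_rep, "sbpow")
    n_rej = 0
    for s in seeds:
        cfg, pairs = sexbias_panel(n_pairs=n_pairs, alpha_m_high=alpha_m,
                                   alpha_f_high=alpha_f, calibration=False,
                                   seed=s & 0x7FFFFFFF)
        n_rej += int(sexbias_trial(cfg, pairs) < 0.05)
    return {"rate": n_rej / n_rep, "n_rep": n_rep}


# ---------------------------------------------------------------------------
# F_ST recovery
# ---------------------------------------------------------------------------

def fst_recovery(seed: int, n_snps: int = 5000, F: float = 0.1,
                 n_diploid: int = 50) -> dict:
    """Estimate Weir-Cockerham F_ST between two independently drifted
    Balding-Nichols populations through the full genotype pipeline."""
    from .simulate import bn_frequencies, simulate_genotypes
    s1, s2, s3 = _seed_stream(seed, 3, "fstrec")
    rng = np.random.default_rng(s1)
    p_anc = rng.uniform(0.05, 0.95, n_snps)
    rng2 = np.random.default_rng(s2)
    freqs = {"A": bn_frequencies(p_anc, F, rng2),
             "B": bn_frequencies(p_anc, F, rng2)}
    samples = pd.DataFrame({
        "sample_id": [f"A_{i}" for i in range(n_diploid)]
                     + [f"B_{i}" for i in range(n_diploid)],
        "population": ["A"] * n_diploid + ["B"] * n_diploid,
        "sex": ["female"] * (2 * n_diploid),
        "language_group": "Uralic:Synthetic", "region": "r1",
        "lat": 60.0, "lon": 25.0,
    })
    g = simulate_genotypes(freqs, {"A": np.empty(0), "B": np.empty(0)},
                           samples, s3)
    ft = allele_frequencies(g, samples, ["A", "B"])
    theta = wc_fst(ft, "A", "B")
    return {"theta_hat": theta, "F": F, "error": abs(theta - F),
            "n_snps": n_snps}
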
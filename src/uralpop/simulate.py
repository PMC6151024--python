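"""Synthetic data generator for the full analysis pipeline.

The generator produces every input the analyses consume - genotypes,
sample metadata, IBD tracts, haplogroup counts, chunkcount matrices,
geographic coordinates and a lexical tree - from one seeded scenario
configuration, with enough planted structure that each analysis stage has
a known truth to recover:

* Allele frequencies follow a hierarchical Balding-Nichols model: an
  ancestral frequency, a shared non-African drift layer, an independently
  drifted "Siberian" source, per-population drift, and admixture of the
  Siberian source into each population with separate male and female
  fractions (``alpha_m``, ``alpha_f``).  Autosomes receive the fraction
  ``(alpha_m + alpha_f) / 2`` and chrX ``(alpha_m + 2 alpha_f) / 3``, the
  standard single-pulse sex-linked admixture arithmetic.
* IBD tract counts per sample pair are Poisson with rate
  ``base * exp(-geo_km / decay) * (beta if both populations are Uralic)``;
  lengths are exponential truncated to [1, 5) cM.
* chrY haplogroup counts are multinomial; chunkcount rows are
  Dirichlet-multinomial around population copying profiles shaped by the
  realized genetic distances.
* The lexical tree is built by average-linkage agglomeration of a blend
  ``rho * genetic-structure + (1 - rho) * independent latent`` over the
  Uralic-labelled populations, so the gene-language correlation is tunable
  and vanishes (given geography) at ``rho = 0``.

A splitmix64 scheme derives independent child seeds for each component
from the single master seed, so every artifact is reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .distances import haversine_km, upgma
from .formats import (ChunkcountMatrix, DistanceMatrix, GenotypeDataset,
                      HaplogroupTable, is_uralic)

# approximate genetic lengths of the 22 human autosomes (cM)
CHROM_LENGTHS_CM = np.array([286, 269, 223, 214, 204, 192, 187, 168, 166,
                             181, 158, 175, 126, 119, 141, 134, 128, 117,
                             107, 108, 62, 74], dtype=float)

_MASK64 = (1 << 64) - 1


def _splitmix64(state: int) -> tuple[int, int]:
    state = (state + 0x9E3779B97F4A7C15) & _MASK64
    z = state
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    return (z ^ (z >> 31)) & _MASK64, state


def child_seeds(master_seed: int, names: Sequence[str]) -> dict[str, int]:
    """Derive one independent child seed per named component (splitmix64).

    The mapping depends only on the master seed and the name order, so each
    component is individually reproducible.
    """
    state = master_seed & _MASK64
    out = {}
    for name in names:
        value, state = _splitmix64(state)
        out[name] = value
    return out


# ---------------------------------------------------------------------------
# Scenario configuration
# ---------------------------------------------------------------------------

@dataclass
class PopulationSpec:
    name: str
    region: str
    language_group: str
    n_samples: int
    lat: float
    lon: float
    f_drift: float            # Balding-Nichols F of the population's own drift
    alpha_m: float = 0.0      # male admixture fraction from the Siberian source
    alpha_f: float = 0.0      # female admixture fraction
    n3_freq: float = 0.05     # chrY hg N3-M178 frequency

    @property
    def alpha_auto(self) -> float:
        return (self.alpha_m + self.alpha_f) / 2.0

    @property
    def alpha_x(self) -> float:
        return (self.alpha_m + 2.0 * self.alpha_f) / 3.0


@dataclass
class ScenarioConfig:
    populations: list[PopulationSpec]
    outgroup: PopulationSpec | None = None
    n_snps_auto: int = 20000
    n_snps_x: int = 2000
    f_shared: float = 0.05      # drift shared by all non-outgroup populations
    f_siberian: float = 0.2     # drift of the admixing Siberian source
    f_outgroup: float = 0.1
    ibd_base_rate: float = 1.0  # expected tracts per cross-population pair
    ibd_length_mean_cm: float = 1.5
    geo_decay_scale_km: float = 3000.0
    uralic_excess_multiplier: float = 1.0   # beta; >= 1
    hg_sample_size: int = 50
    chunk_total: int = 1000
    chunk_concentration: float = 100.0
    lexical_genetic_correlation: float = 0.0   # rho
    geo_jitter_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("duplicate population names")
        for p in self.populations:
            if p.n_samples < 2:
                raise ValueError(f"population {p.name!r} needs >= 2 samples")
            for frac in (p.alpha_m, p.alpha_f, p.f_drift, p.n3_freq):
                if not 0 <= frac <= 1:
                    raise ValueError(f"fraction out of [0,1] in {p.name!r}")
        if self.uralic_excess_multiplier < 1:
            raise ValueError("uralic_excess_multiplier must be >= 1")
        if not 0 <= self.lexical_genetic_correlation <= 1:
            raise ValueError("lexical_genetic_correlation must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        d = dict(d)
        d["populations"] = [PopulationSpec(**p) for p in d["populations"]]
        if d.get("outgroup") is not None:
            d["outgroup"] = PopulationSpec(**d["outgroup"])
        return cls(**d)


@dataclass
class ScenarioBundle:
    config: ScenarioConfig
    genotypes: GenotypeDataset
    samples: pd.DataFrame
    tracts: pd.DataFrame
    haplogroups: HaplogroupTable
    chunkcounts: ChunkcountMatrix
    lexical_tree: dendropy.Tree
    summaries: pd.DataFrame   # population, k9_frequency, n3_m178_freq, ...
    truth: dict


# ---------------------------------------------------------------------------
# Frequency machinery
# ---------------------------------------------------------------------------

def bn_frequencies(p_anc: np.ndarray, F: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols draw: Beta(p(1-F)/F, (1-p)(1-F)/F) per SNP.

    F = 0 returns the ancestral frequencies unchanged; F = 1 is an error.
    """
    p_anc = np.asarray(p_anc, dtype=float)
    if not 0 <= F < 1:
        raise ValueError("require 0 <= F < 1")
    if F == 0:
        return p_anc.copy()
    scale = (1.0 - F) / F
    return rng.beta(p_anc * scale, (1.0 - p_anc) * scale)


def admix_frequencies(f_base: np.ndarray, f_siberian: np.ndarray,
                      alpha: float) -> np.ndarray:
    """Single-pulse admixture: f = alpha * f_siberian + (1 - alpha) * f_base."""
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    return alpha * np.asarray(f_siberian) + (1 - alpha) * np.asarray(f_base)


def sex_adjusted_alphas(alpha_m: float, alpha_f: float) -> tuple[float, float]:
    """(alpha_auto, alpha_X) for a single admixture pulse with the given
    male and female fractions: (m+f)/2 and (m+2f)/3."""
    return (alpha_m + alpha_f) / 2.0, (alpha_m + 2.0 * alpha_f) / 3.0


def _autosome_map(n_snps: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assign SNPs to chromosomes 1..22 proportionally to genetic length,
    uniformly spaced at 1 cM/Mb."""
    weights = CHROM_LENGTHS_CM / CHROM_LENGTHS_CM.sum()
    counts = np.floor(weights * n_snps).astype(int)
    counts[: n_snps - counts.sum()] += 1
    chroms, pos_bp, pos_cm = [], [], []
    for c, (k, length_cm) in enumerate(zip(counts, CHROM_LENGTHS_CM), start=1):
        if k == 0:
            continue
        cm = np.linspace(0, length_cm, k, endpoint=False) + length_cm / (2 * k)
        chroms.extend([str(c)] * k)
        pos_cm.extend(cm)
        pos_bp.extend(np.round(cm * 1e6).astype(int) + 1)
    return (np.array(chroms), np.array(pos_bp, dtype=np.int64),
            np.array(pos_cm, dtype=float))


def simulate_genotypes(freqs_auto: Mapping[str, np.ndarray],
                       freqs_x: Mapping[str, np.ndarray],
                       samples: pd.DataFrame,
                       seed: int) -> GenotypeDataset:
    """Draw genotype calls from per-population frequencies.

    Autosomal calls are Binomial(2, f); female chrX calls Binomial(2, f_X);
    male chrX calls are 2 * Bernoulli(f_X) (hemizygotes coded 0/2).
    """
    rng = np.random.default_rng(seed)
    pops = list(freqs_auto)
    n_auto = len(next(iter(freqs_auto.values())))
    n_x = len(next(iter(freqs_x.values()))) if freqs_x else 0

    chrom_a, bp_a, cm_a = _autosome_map(n_auto)
    x_cm = np.linspace(0, 180.0, n_x, endpoint=False) + 90.0 / max(n_x, 1)
    snp_ids = np.array([f"rsA{i:06d}" for i in range(n_auto)]
                       + [f"rsX{i:05d}" for i in range(n_x)])
    chrom = np.concatenate([chrom_a, np.array(["X"] * n_x)])
    pos_bp = np.concatenate([bp_a, np.round(x_cm * 1e6).astype(np.int64) + 1])
    pos_cm = np.concatenate([cm_a, x_cm])

    sample_ids = list(samples["sample_id"])
    calls = np.empty((n_auto + n_x, len(sample_ids)), dtype=np.int8)
    col = 0
    for _, row in samples.iterrows():
        pop = row["population"]
        fa = freqs_auto[pop]
        calls[:n_auto, col] = rng.binomial(2, fa)
        if n_x:
            fx = freqs_x[pop]
            if row["sex"] == "male":
                calls[n_auto:, col] = 2 * rng.binomial(1, fx)
            else:
                calls[n_auto:, col] = rng.binomial(2, fx)
        col += 1

    return GenotypeDataset(
        snp_ids=snp_ids, chrom=chrom, pos_bp=pos_bp, pos_cm=pos_cm,
        ref=np.array(["A"] * (n_auto + n_x)),
        alt=np.array(["G"] * (n_auto + n_x)),
        samples=sample_ids, calls=calls,
    )


# ---------------------------------------------------------------------------
# IBD tracts
# ---------------------------------------------------------------------------

def _truncated_exp(rng: np.random.Generator, mean: float, lo: float,
                   hi: float, size: int) -> np.ndarray:
    """Exponential(mean) conditioned on [lo, hi) by inverse CDF."""
    a = np.exp(-lo / mean)
    b = np.exp(-hi / mean)
    u = rng.uniform(size=size)
    return -mean * np.log(a - u * (a - b))


def pair_rate(popA: PopulationSpec, popB: PopulationSpec, base: float,
              decay_km: float, beta: float) -> float:
    """Expected tract count for one sample pair across two populations."""
    d = haversine_km((popA.lat, popA.lon), (popB.lat, popB.lon))
    lam = base * (np.exp(-d / decay_km) if np.isfinite(decay_km) else 1.0)
    if is_uralic(popA.language_group) and is_uralic(popB.language_group):
        lam *= beta
    return float(lam)


def simulate_ibd_tracts(samples: pd.DataFrame,
                        pop_specs: Mapping[str, PopulationSpec],
                        base_rate: float, length_mean_cm: float,
                        decay_km: float, beta: float,
                        seed: int) -> pd.DataFrame:
    """Plant IBD tracts pair by pair: Poisson counts, truncated-exponential
    lengths in [1, 5) cM, positions uniform on the autosomal map."""
    rng = np.random.default_rng(seed)
    ids = list(samples["sample_id"])
    pops = list(samples["population"])
    n = len(ids)
    rate_cache: dict[tuple[str, str], float] = {}
    rows_a, rows_b, lams = [], [], []
    for i in range(n):
        for j in range(i + 1, n):
            key = tuple(sorted((pops[i], pops[j])))
            if key not in rate_cache:
                rate_cache[key] = pair_rate(pop_specs[key[0]], pop_specs[key[1]],
                                            base_rate, decay_km, beta)
            a, b = sorted((ids[i], ids[j]))
            rows_a.append(a)
            rows_b.append(b)
            lams.append(rate_cache[key])
    counts = rng.poisson(np.array(lams))
    total = int(counts.sum())
    lengths = _truncated_exp(rng, length_mean_cm, 1.0, 5.0, total)
    chrom_p = CHROM_LENGTHS_CM / CHROM_LENGTHS_CM.sum()
    chrom_idx = rng.choice(len(CHROM_LENGTHS_CM), size=total, p=chrom_p)
    starts = rng.uniform(0, CHROM_LENGTHS_CM[chrom_idx] - lengths)
    rec_a = np.repeat(rows_a, counts)
    rec_b = np.repeat(rows_b, counts)
    return pd.DataFrame({
        "sample_a": rec_a, "sample_b": rec_b,
        "chrom": (chrom_idx + 1).astype(str),
        "start_cm": starts, "end_cm": starts + lengths,
        "score": np.full(total, 1e-12), "run_id": np.ones(total, dtype=int),
    })


# ---------------------------------------------------------------------------
# Haplogroups and chunkcounts
# ---------------------------------------------------------------------------

def haplogroup_frequency_vectors(pops: Sequence[PopulationSpec]
                                 ) -> pd.DataFrame:
    """Per-population chrY haplogroup frequency vectors.

    N3-M178 comes from the spec; a small N2-P43 fraction scales with the
    Siberian ancestry fraction, and the remainder splits over common
    West-Eurasian lineages in fixed proportions.
    """
    hgs = ["N3-M178", "N2-P43", "R1a", "I1", "other"]
    rows = []
    for p in pops:
        n2 = min(0.1 * p.alpha_auto, 1.0 - p.n3_freq)
        rest = 1.0 - p.n3_freq - n2
        rows.append([p.n3_freq, n2, 0.4 * rest, 0.2 * rest, 0.4 * rest])
    return pd.DataFrame(rows, index=[p.name for p in pops], columns=hgs)


def simulate_haplogroup_counts(freq_vectors: pd.DataFrame,
                               n_per_pop: int | Mapping[str, int],
                               seed: int, locus: str = "chrY"
                               ) -> HaplogroupTable:
    """Multinomial haplogroup counts per population."""
    rng = np.random.default_rng(seed)
    rows = {}
    for pop, probs in freq_vectors.iterrows():
        p = probs.to_numpy(dtype=float)
        if not np.isclose(p.sum(), 1.0):
            raise ValueError(f"frequency vector for {pop!r} does not sum to 1")
        n = n_per_pop[pop] if isinstance(n_per_pop, Mapping) else n_per_pop
        rows[pop] = rng.multinomial(n, p / p.sum())
    counts = pd.DataFrame.from_dict(rows, orient="index",
                                    columns=freq_vectors.columns)
    return HaplogroupTable(locus=locus, counts=counts)


def simulate_chunkcounts(group_profiles: pd.DataFrame,
                         recipients: Sequence[tuple[str, str]],
                         concentration: float, total: int,
                         seed: int) -> ChunkcountMatrix:
    """Dirichlet-multinomial copying rows around each recipient's group
    profile.  ``recipients`` is a list of (recipient_id, group) pairs."""
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    donors = list(group_profiles.columns)
    rows = {}
    for rid, group in recipients:
        prof = group_profiles.loc[group].to_numpy(dtype=float)
        prof = prof / prof.sum()
        alpha = np.where(prof > 0, concentration * prof, 1e-9)
        w = rng.dirichlet(alpha)
        rows[rid] = rng.multinomial(total, w)
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=donors)
    return ChunkcountMatrix(counts=counts.astype(float))


# ---------------------------------------------------------------------------
# Lexical tree and geography
# ---------------------------------------------------------------------------

def _standardize_offdiag(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    v = values[iu]
    z = (v - v.mean()) / v.std()
    out = np.zeros_like(values)
    out[iu] = z
    return out + out.T


def simulate_lexical_and_geo(populations: Sequence[PopulationSpec],
                             genetic_structure: DistanceMatrix,
                             rho: float, seed: int,
                             geo_jitter_deg: float = 0.0
                             ) -> tuple[dendropy.Tree, pd.DataFrame]:
    """Lexical tree over the Uralic-labelled populations plus coordinates.

    An independent 2-D latent space provides language-internal divergence;
    its pairwise distances are blended with the (standardized) genetic
    drift structure at weight ``rho`` and agglomerated into an ultrametric
    tree.  At rho = 0 the lexical distances are independent of the genetic
    structure; the sampling coordinates are the configured locations plus
    optional jitter.
    """
    if not 0 <= rho <= 1:
        raise ValueError("rho must lie in [0, 1]")
    uralic = [p for p in populations if is_uralic(p.language_group)]
    if len(uralic) < 3:
        raise ValueError("need at least 3 Uralic-labelled populations")
    rng = np.random.default_rng(seed)
    names = [p.name for p in uralic]
    latent = rng.normal(size=(len(names), 2))
    diff = latent[:, None, :] - latent[None, :, :]
    e_dist = np.sqrt((diff ** 2).sum(axis=-1))
    e_star = _standardize_offdiag(e_dist)
    g = genetic_structure.submatrix(names).values
    g_star = _standardize_offdiag(g)
    blend = rho * g_star + (1 - rho) * e_star
    iu = np.triu_indices(len(names), k=1)
    lo, hi = blend[iu].min(), blend[iu].max()
    span = hi - lo if hi > lo else 1.0
    vals = np.zeros_like(blend)
    vals[iu] = (blend[iu] - lo) / span + 0.2   # positive, zero diagonal
    vals = vals + vals.T
    tree = upgma(DistanceMatrix(names, vals))

    coords = pd.DataFrame({
        "population": [p.name for p in populations],
        "lat": [p.lat + rng.normal(0, geo_jitter_deg) if geo_jitter_deg else p.lat
                for p in populations],
        "lon": [p.lon + rng.normal(0, geo_jitter_deg) if geo_jitter_deg else p.lon
                for p in populations],
    })
    return tree, coords


# ---------------------------------------------------------------------------
# Scenario orchestration
# ---------------------------------------------------------------------------

def _sample_table(cfg: ScenarioConfig, coords: pd.DataFrame) -> pd.DataFrame:
    rows = []
    coord = coords.set_index("population")
    pops = list(cfg.populations) + ([cfg.outgroup] if cfg.outgroup else [])
    for p in pops:
        for k in range(p.n_samples):
            rows.append({
                "sample_id": f"{p.name}_{k:03d}",
                "population": p.name,
                "sex": "male" if k % 2 == 0 else "female",
                "language_group": p.language_group,
                "region": p.region,
                "lat": float(coord.loc[p.name, "lat"]),
                "lon": float(coord.loc[p.name, "lon"]),
            })
    return pd.DataFrame(rows)


def true_genetic_distances(freqs: Mapping[str, np.ndarray],
                           populations: Sequence[str]) -> DistanceMatrix:
    """Mean squared frequency difference between population frequency
    vectors - the drift structure the genotypes realize, free of sampling
    noise."""
    pops = list(populations)
    n = len(pops)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = float(((freqs[pops[i]] - freqs[pops[j]]) ** 2).mean())
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(pops, vals)


def _copying_profiles(d_true: DistanceMatrix) -> pd.DataFrame:
    """Population copying profiles over population donors.

    Weight decays with the realized genetic distance; the own-population
    donor weight (zero distance) is therefore maximal, as in real
    chromosome-painting output where individuals copy most from their own
    population.  Genetically close populations then have similar profiles
    and small TVD.
    """
    pops = d_true.labels
    tau = 0.5 * np.mean(d_true.condensed())
    prof = np.exp(-d_true.values / max(tau, 1e-12))
    prof = prof / prof.sum(axis=1, keepdims=True)
    return pd.DataFrame(prof, index=pops, columns=pops)


def make_scenario(cfg: ScenarioConfig) -> ScenarioBundle:
    """Generate a complete, mutually consistent dataset from one config.

    All randomness flows from the master seed through named child seeds;
    the same config therefore yields a bit-identical bundle.
    """
    seeds = child_seeds(cfg.seed, [
        "ancestral", "shared", "siberian", "pop_drift", "genotypes",
        "ibd", "haplogroups", "chunkcounts", "lexical",
    ])
    rng_anc = np.random.default_rng(seeds["ancestral"])
    p_anc_a = rng_anc.uniform(0.05, 0.95, cfg.n_snps_auto)
    p_anc_x = rng_anc.uniform(0.05, 0.95, cfg.n_snps_x)

    rng_sh = np.random.default_rng(seeds["shared"])
    p_eur_a = bn_frequencies(p_anc_a, cfg.f_shared, rng_sh)
    p_eur_x = bn_frequencies(p_anc_x, cfg.f_shared, rng_sh)
    rng_sib = np.random.default_rng(seeds["siberian"])
    p_sib_a = bn_frequencies(p_eur_a, cfg.f_siberian, rng_sib)
    p_sib_x = bn_frequencies(p_eur_x, cfg.f_siberian, rng_sib)

    rng_pop = np.random.default_rng(seeds["pop_drift"])
    freqs_auto: dict[str, np.ndarray] = {}
    freqs_x: dict[str, np.ndarray] = {}
    for p in cfg.populations:
        base_a = bn_frequencies(p_eur_a, p.f_drift, rng_pop)
        base_x = bn_frequencies(p_eur_x, p.f_drift, rng_pop)
        freqs_auto[p.name] = admix_frequencies(base_a, p_sib_a, p.alpha_auto)
        freqs_x[p.name] = admix_frequencies(base_x, p_sib_x, p.alpha_x)
    if cfg.outgroup is not None:
        og = cfg.outgroup
        freqs_auto[og.name] = bn_frequencies(p_anc_a, cfg.f_outgroup, rng_pop)
        freqs_x[og.name] = bn_frequencies(p_anc_x, cfg.f_outgroup, rng_pop)

    pop_names = [p.name for p in cfg.populations]
    d_true = true_genetic_distances(freqs_auto, pop_names)

    lexical_tree, coords = simulate_lexical_and_geo(
        cfg.populations, d_true, cfg.lexical_genetic_correlation,
        seeds["lexical"], cfg.geo_jitter_deg)
    if cfg.outgroup is not None:
        coords = pd.concat([coords, pd.DataFrame([{
            "population": cfg.outgroup.name, "lat": cfg.outgroup.lat,
            "lon": cfg.outgroup.lon}])], ignore_index=True)

    samples = _sample_table(cfg, coords)
    genotypes = simulate_genotypes(freqs_auto, freqs_x, samples,
                                   seeds["genotypes"])

    study_samples = samples[samples["population"].isin(pop_names)]
    pop_specs = {p.name: p for p in cfg.populations}
    tracts = simulate_ibd_tracts(study_samples, pop_specs, cfg.ibd_base_rate,
                                 cfg.ibd_length_mean_cm,
                                 cfg.geo_decay_scale_km,
                                 cfg.uralic_excess_multiplier, seeds["ibd"])

    hg_freqs = haplogroup_frequency_vectors(cfg.populations)
    haplogroups = simulate_haplogroup_counts(hg_freqs, cfg.hg_sample_size,
                                             seeds["haplogroups"])

    profiles = _copying_profiles(d_true)
    recipients = [(sid, pop) for sid, pop in
                  zip(study_samples["sample_id"], study_samples["population"])]
    chunkcounts = simulate_chunkcounts(profiles, recipients,
                                       cfg.chunk_concentration,
                                       cfg.chunk_total, seeds["chunkcounts"])

    realized_n3 = haplogroups.frequencies()["N3-M178"]
    summaries = pd.DataFrame({
        "population": pop_names,
        "k9_frequency": [p.alpha_auto for p in cfg.populations],
        "n3_m178_freq": [float(realized_n3[p]) for p in pop_names],
        "n2_p43_freq": [float(haplogroups.frequencies().loc[p, "N2-P43"])
                        for p in pop_names],
    })

    truth = {
        "config": cfg.to_dict(),
        "seeds": seeds,
        "alpha_auto": {p.name: p.alpha_auto for p in cfg.populations},
        "alpha_x": {p.name: p.alpha_x for p in cfg.populations},
        "n3_freq": {p.name: p.n3_freq for p in cfg.populations},
        "true_genetic_distances": d_true,
        "copying_profiles": profiles,
        "pop_freqs_auto": freqs_auto,
        "pop_freqs_x": freqs_x,
    }
    return ScenarioBundle(config=cfg, genotypes=genotypes, samples=samples,
                          tracts=tracts, haplogroups=haplogroups,
                          chunkcounts=chunkcounts, lexical_tree=lexical_tree,
                          summaries=summaries, truth=truth)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

REGION_BALTIC = "Baltic-Scandinavian"
REGION_VOLGA = "Eastern European-Volga"
REGION_SIBERIA = "Siberian"

# 12 study populations in three regions; Siberian (k9-like) ancestry averages
# ~0.4 for Volga-Uralic Finno-Ugric speakers and ~0.2 for their Turkic
# neighbours, with a west-to-east cline and a mild male bias.
_URALIC_WORLD_POPS = [
    # name, region, language_group, n, lat, lon, F, a_m, a_f, n3
    ("Finns", REGION_BALTIC, "Uralic:Finnic", 15, 61.0, 25.0, 0.020, 0.08, 0.04, 0.60),
    ("Estonians", REGION_BALTIC, "Uralic:Finnic", 15, 58.7, 25.5, 0.010, 0.05, 0.03, 0.33),
    ("Saami", REGION_BALTIC, "Uralic:Saami", 15, 67.5, 20.0, 0.060, 0.08, 0.04, 0.40),
    ("Swedes", REGION_BALTIC, "IndoEuropean:Germanic", 15, 59.5, 16.0, 0.010, 0.02, 0.01, 0.08),
    ("Latvians", REGION_BALTIC, "IndoEuropean:Baltic", 15, 56.9, 24.5, 0.010, 0.03, 0.02, 0.15),
    ("Udmurts", REGION_VOLGA, "Uralic:Permic", 15, 57.0, 53.0, 0.020, 0.50, 0.30, 0.55),
    ("Maris", REGION_VOLGA, "Uralic:Volgaic", 15, 56.5, 48.0, 0.020, 0.45, 0.30, 0.45),
    ("Mordovians", REGION_VOLGA, "Uralic:Volgaic", 15, 54.2, 45.2, 0.015, 0.25, 0.15, 0.20),
    ("Russians", REGION_VOLGA, "IndoEuropean:Slavic", 15, 56.0, 44.0, 0.010, 0.12, 0.08, 0.12),
    ("Tatars", REGION_VOLGA, "Turkic:Kipchak", 15, 55.8, 49.1, 0.010, 0.25, 0.15, 0.10),
    ("Khanty", REGION_SIBERIA, "Uralic:Ugric", 15, 61.0, 69.0, 0.040, 0.75, 0.65, 0.60),
    ("Nganasans", REGION_SIBERIA, "Uralic:Samoyedic", 15, 70.0, 90.0, 0.080, 0.95, 0.90, 0.90),
]

_OUTGROUP = ("Yoruba-like", "Africa", "NigerCongo:Defoid", 20, 7.4, 3.9,
             0.0, 0.0, 0.0, 0.0)


def _mk_pop(t: tuple) -> PopulationSpec:
    name, region, lang, n, lat, lon, f, am, af, n3 = t
    return PopulationSpec(name=name, region=region, language_group=lang,
                          n_samples=n, lat=lat, lon=lon, f_drift=f,
                          alpha_m=am, alpha_f=af, n3_freq=n3)


def uralic_world(seed: int = 0, n_samples: int | None = None,
                 **overrides) -> ScenarioConfig:
    """Default study-like scenario: 12 populations, 3 regions, a planted
    three-fold cross-regional Uralic IBD excess, gene-correlated lexical
    distances (rho = 0.6), and mildly male-biased Siberian ancestry."""
    pops = [_mk_pop(t) for t in _URALIC_WORLD_POPS]
    if n_samples is not None:
        for p in pops:
            p.n_samples = n_samples
    defaults = dict(
        populations=pops, outgroup=_mk_pop(_OUTGROUP),
        n_snps_auto=20000, n_snps_x=2000,
        uralic_excess_multiplier=3.0,
        lexical_genetic_correlation=0.6,
        seed=seed,
    )
    defaults.update(overrides)
    return ScenarioConfig(**defaults)


def null_world(seed: int = 0, n_samples: int | None = None,
               **overrides) -> ScenarioConfig:
    """Calibration scenario: no Uralic IBD excess (beta = 1, flat geography),
    no gene-language coupling (rho = 0) and sex-symmetric admixture
    (alpha_m = alpha_f per population)."""
    pops = [_mk_pop(t) for t in _URALIC_WORLD_POPS]
    for p in pops:
        a = p.alpha_auto
        p.alpha_m = a
        p.alpha_f = a
    if n_samples is not None:
        for p in pops:
            p.n_samples = n_samples
    defaults = dict(
        populations=pops, outgroup=_mk_pop(_OUTGROUP),
        n_snps_auto=20000, n_snps_x=2000,
        uralic_excess_multiplier=1.0,
        geo_decay_scale_km=float("inf"),
        lexical_genetic_correlation=0.0,
        seed=seed,
    )
    defaults.update(overrides)
    return ScenarioConfig(**defaults)
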
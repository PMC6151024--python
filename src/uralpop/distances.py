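"""Distance matrices for the gene-language correlation suite.

Six kinds of population distances feed the Mantel framework: Weir-Cockerham
F_ST on autosomal SNPs (see allele_stats), haplogroup-frequency F_ST and
Slatkin-linearized Phi_ST for mtDNA/chrY, total variation distance between
chromosome-painting copying profiles, great-circle geography, and patristic
distances on the lexical tree.  A deterministic UPGMA builds the
population-clustering tree from any distance matrix.
"""

from __future__ import annotations

import math
import warnings
from typing import Callable, Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .formats import ChunkcountMatrix, DistanceMatrix, HaplogroupTable

EARTH_RADIUS_KM = 6371.0088


def conventional_fst_haplogroups(h: HaplogroupTable, popA: str, popB: str
                                 ) -> float:
    """Multi-allelic frequency F_ST (Nei's G_ST) between two populations.

    F = (H_T - H_S) / H_T with H_S the unweighted mean within-population
    expected heterozygosity 1 - sum p^2 and H_T computed from the mean of
    the two frequency vectors.  NaN when both populations are fixed for the
    same haplogroup (H_T = 0).
    """
    f = h.frequencies()
    p1 = f.loc[popA].to_numpy()
    p2 = f.loc[popB].to_numpy()
    hs = ((1 - (p1 ** 2).sum()) + (1 - (p2 ** 2).sum())) / 2.0
    pbar = (p1 + p2) / 2.0
    ht = 1 - (pbar ** 2).sum()
    if ht == 0:
        warnings.warn(f"H_T = 0 for {popA!r} vs {popB!r}; F_ST undefined")
        return float("nan")
    return float((ht - hs) / ht)


def phi_st(h: HaplogroupTable, popA: str, popB: str) -> float:
    """Two-population AMOVA Phi_ST with unit distance between haplogroups.

    With no molecular distances available, inter-haplotype distance is 1
    between distinct haplogroups and 0 otherwise, which reduces the AMOVA
    sums of squares to functions of haplogroup counts.
    """
    c1 = h.counts.loc[popA].to_numpy(dtype=float)
    c2 = h.counts.loc[popB].to_numpy(dtype=float)
    n1, n2 = c1.sum(), c2.sum()
    if n1 <= 0 or n2 <= 0:
        raise ValueError("both populations need positive haplotype totals")
    N = n1 + n2
    pooled = c1 + c2
    # sum of delta over ordered pairs = N^2 - sum_k count_k^2
    ssd_total = (N ** 2 - (pooled ** 2).sum()) / (2.0 * N)
    ssd_within = ((n1 ** 2 - (c1 ** 2).sum()) / (2.0 * n1)
                  + (n2 ** 2 - (c2 ** 2).sum()) / (2.0 * n2))
    ssd_among = ssd_total - ssd_within
    msd_among = ssd_among / 1.0
    msd_within = ssd_within / (N - 2.0)
    n_c = N - (n1 ** 2 + n2 ** 2) / N
    sigma_w = msd_within
    sigma_a = (msd_among - msd_within) / n_c
    denom = sigma_a + sigma_w
    if denom == 0:
        return 0.0
    return float(sigma_a / denom)


def phi_st_linearized(h: HaplogroupTable, popA: str, popB: str) -> float:
    """Slatkin's linearization Phi / (1 - Phi), floored at 0.

    Phi_ST = 1 (fixed different haplogroups) makes the linearization
    infinite; the cell is flagged missing (NaN) with a warning so the
    correlation suite can drop it complete-case.
    """
    phi = phi_st(h, popA, popB)
    if phi >= 1.0:
        warnings.warn(f"Phi_ST = 1 for {popA!r} vs {popB!r}; linearized value "
                      "infinite, cell flagged missing")
        return float("nan")
    if phi < 0:
        phi = 0.0
    return float(phi / (1.0 - phi))


def tvd_groups(c: ChunkcountMatrix, groupA: Iterable[str],
               groupB: Iterable[str],
               exclude_donors: Iterable[str] = ()) -> float:
    """Total variation distance between mean copying profiles of two groups.

    Each group's profile is the mean of its recipients' donor rows with
    self-copy cells and excluded donor columns removed, renormalized to sum
    one; TVD = 0.5 * L1 distance, in [0, 1].
    """
    groupA, groupB = list(groupA), list(groupB)
    if set(groupA) & set(groupB):
        raise ValueError("recipient groups must be disjoint")
    if not groupA or not groupB:
        raise ValueError("recipient groups must be non-empty")
    exclude = set(exclude_donors)

    def profile(group: list[str]) -> np.ndarray:
        rows = c.counts.loc[group].copy()
        for r in group:
            if r in rows.columns:
                rows.loc[r, r] = 0.0  # self-copy ignored
        keep = [d for d in rows.columns if d not in exclude]
        prof = rows[keep].to_numpy(dtype=float).mean(axis=0)
        total = prof.sum()
        if total <= 0:
            raise ValueError("zero-sum copying profile after exclusions")
        return prof / total

    fa, fb = profile(groupA), profile(groupB)
    return float(0.5 * np.abs(fa - fb).sum())


def haversine_km(p1: tuple[float, float], p2: tuple[float, float],
                 radius_km: float = EARTH_RADIUS_KM) -> float:
    """Great-circle distance in km between (lat, lon) points in degrees."""
    lat1, lon1 = p1
    lat2, lon2 = p2
    for lat in (lat1, lat2):
        if not -90 <= lat <= 90:
            raise ValueError(f"latitude {lat} outside [-90, 90]")
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    h = (math.sin(dphi / 2) ** 2
         + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2)
    return float(2 * radius_km * math.asin(min(1.0, math.sqrt(h))))


def patristic_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Tip-to-tip path-length (patristic) distance matrix, labels sorted."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(labels, vals)


def upgma(d: DistanceMatrix) -> dendropy.Tree:
    """Average-linkage agglomeration producing an ultrametric dendropy tree.

    Ties in the minimum pairwise distance break deterministically by the
    lexicographically smallest (label, label) pair, where a cluster is named
    by its smallest member label.
    """
    if d.n < 2:
        raise ValueError("UPGMA needs at least two taxa")
    if np.isnan(d.values).any():
        raise ValueError("distance matrix contains NaN")

    taxa = dendropy.TaxonNamespace(d.labels)
    nodes: dict[str, dendropy.Node] = {}
    sizes: dict[str, int] = {}
    heights: dict[str, float] = {}
    for lab in d.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes[lab] = node
        sizes[lab] = 1
        heights[lab] = 0.0
    dist: dict[frozenset, float] = {}
    labels = list(d.labels)
    for i in range(d.n):
        for j in range(i + 1, d.n):
            dist[frozenset((labels[i], labels[j]))] = d.values[i, j]

    active = sorted(labels)
    while len(active) > 1:
        best = None
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                a, b = active[i], active[j]
                dd = dist[frozenset((a, b))]
                key = (dd, min(a, b), max(a, b))
                if best is None or key < best:
                    best = key
        dd, a, b = best
        height = dd / 2.0
        parent = dendropy.Node()
        for child in (a, b):
            nodes[child].edge.length = height - heights[child]
            parent.add_child(nodes[child])
        new = min(a, b)  # cluster named by smallest member label
        other = max(a, b)
        na, nb = sizes[a], sizes[b]
        for x in active:
            if x in (a, b):
                continue
            dxa = dist[frozenset((x, a))]
            dxb = dist[frozenset((x, b))]
            dist[frozenset((x, new))] = (na * dxa + nb * dxb) / (na + nb)
        nodes[new] = parent
        sizes[new] = na + nb
        heights[new] = height
        active.remove(other)

    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = nodes[active[0]]
    tree.is_rooted = True
    return tree


def build_distance_matrix(pairwise_fn: Callable[[str, str], float],
                          populations: Sequence[str]) -> DistanceMatrix:
    """Fill a symmetric labelled matrix from a pairwise function.

    NaN returns are recorded as missing cells (see
    DistanceMatrix.missing_pairs) and excluded complete-case downstream.
    """
    pops = list(populations)
    n = len(pops)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = pairwise_fn(pops[i], pops[j])
            vals[i, j] = vals[j, i] = v
    return DistanceMatrix(pops, vals)


def geographic_distance_matrix(samples: pd.DataFrame,
                               populations: Sequence[str] | None = None
                               ) -> DistanceMatrix:
    """Haversine distances between population sampling locations (km)."""
    coords = (samples.groupby("population")[["lat", "lon"]].first())
    pops = list(populations) if populations is not None else list(coords.index)

    def fn(a: str, b: str) -> float:
        return haversine_km(tuple(coords.loc[a]), tuple(coords.loc[b]))

    return build_distance_matrix(fn, pops)
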
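#!/usr/bin/env python
"""Build every distance matrix and run the gene-language Mantel suite.

Six distance matrices over the Uralic-speaking populations - autosomal
Weir-Cockerham F_ST, chunkcount TVD, chrY haplogroup G_ST and linearized
Phi_ST, lexical patristic distances and haversine geography - then Mantel
and partial Mantel tests (1000 permutations, one-sided positive) of each
genetic matrix against the lexical distances, with and without keeping
geography constant.
"""

import argparse
from pathlib import Path

import pandas as pd

from uralpop.allele_stats import allele_frequencies, wc_fst
from uralpop.correlation import mantel, partial_mantel
from uralpop.distances import (build_distance_matrix,
                               conventional_fst_haplogroups,
                               geographic_distance_matrix,
                               patristic_distances, phi_st_linearized,
                               tvd_groups)
from uralpop.formats import (is_uralic, read_counts_table, read_genotypes,
                             read_newick, read_samples, write_square_matrix)
from uralpop.simulate import child_seeds

ap = argparse.ArgumentParser()
ap.add_argument("--world", type=Path, default=Path("results/world"))
ap.add_argument("--out", type=Path, default=Path("results/mantel"))
ap.add_argument("--seed", type=int, default=1)
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

samples = read_samples(args.world / "samples.tsv")
g = read_genotypes(args.world / "genotypes.tsv", samples=samples)
hg = read_counts_table(args.world / "haplogroups_chrY.csv",
                       kind="haplogroup", locus="chrY")
cc = read_counts_table(args.world / "chunkcounts.csv", kind="chunkcount")
tree = read_newick(args.world / "lexical_tree.nwk")

lang = dict(zip(samples["population"], samples["language_group"]))
uralic = sorted(p for p in samples["population"].unique() if is_uralic(lang[p]))
members = {p: list(samples.loc[samples["population"] == p, "sample_id"])
           for p in uralic}

g_auto = g.subset_snps(g.chrom != "X")
freqs = allele_frequencies(g_auto, samples, uralic)
matrices = {
    "autosomal_fst": build_distance_matrix(
        lambda a, b: max(0.0, wc_fst(freqs, a, b)), uralic),
    "chunkcount_tvd": build_distance_matrix(
        lambda a, b: tvd_groups(cc, members[a], members[b]), uralic),
    "chrY_gst": build_distance_matrix(
        lambda a, b: conventional_fst_haplogroups(hg, a, b), uralic),
    "chrY_phist_linearized": build_distance_matrix(
        lambda a, b: phi_st_linearized(hg, a, b), uralic),
}
lex = patristic_distances(tree).submatrix(uralic)
geo = geographic_distance_matrix(samples, uralic)
for name, m in {**matrices, "lexical": lex, "geography": geo}.items():
    write_square_matrix(m, args.out / f"{name}.csv")

seeds = list(child_seeds(args.seed, [f"s{i}" for i in range(20)]).values())
rows = []
k = 0
for name, m in matrices.items():
    r_plain = mantel(lex, m, n_perm=1000, seed=seeds[k] & 0x7FFFFFFF)
    r_part = partial_mantel(lex, m, geo, n_perm=1000,
                            seed=seeds[k + 1] & 0x7FFFFFFF)
    k += 2
    rows.append((f"lexical vs {name}", r_plain.r, r_plain.p_value,
                 r_part.r, r_part.p_value, r_plain.n_labels))
r_geo = mantel(lex, geo, n_perm=1000, seed=seeds[k] & 0x7FFFFFFF)
rows.append(("lexical vs geography", r_geo.r, r_geo.p_value,
             float("nan"), float("nan"), r_geo.n_labels))

table = pd.DataFrame(rows, columns=["comparison", "mantel_r", "mantel_p",
                                    "partial_r_given_geo", "partial_p",
                                    "n_pops"])
table.to_csv(args.out / "mantel_tests.csv", index=False)
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
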
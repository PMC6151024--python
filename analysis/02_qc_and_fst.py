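#!/usr/bin/env python
"""QC the simulated genotypes and compute the autosomal F_ST structure.

Reads the artifacts of 01_simulate_world.py, applies the SNP filters
(MAF > 0.1%, call rate > 97%) and sliding-window LD pruning
(r^2 > 0.4 in 200-SNP windows, step 25), then computes pairwise
Weir-Cockerham F_ST between all study populations and the UPGMA tree
that summarizes the clustering.
"""

import argparse
from pathlib import Path

from uralpop.allele_stats import (allele_frequencies, filter_snps, ld_prune,
                                  wc_fst)
from uralpop.distances import build_distance_matrix, upgma
from uralpop.formats import (read_genotypes, read_samples,
                             write_newick, write_square_matrix)

ap = argparse.ArgumentParser()
ap.add_argument("--world", type=Path, default=Path("results/world"))
ap.add_argument("--out", type=Path, default=Path("results/fst"))
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

samples = read_samples(args.world / "samples.tsv")
g = read_genotypes(args.world / "genotypes.tsv", samples=samples)
g_auto = g.subset_snps(g.chrom != "X")

qc = filter_snps(g_auto, maf_min=0.001, call_rate_min=0.97)
pruned = ld_prune(qc, window=200, step=25, r2_max=0.4)
print(f"QC: {g_auto.n_snps} -> {qc.n_snps} after filters, "
      f"{pruned.n_snps} after LD pruning")

pops = sorted(p for p in samples["population"].unique()
              if samples.loc[samples["population"] == p, "region"].iloc[0]
              != "Africa")
freqs = allele_frequencies(pruned, samples, pops)
fst = build_distance_matrix(lambda a, b: max(0.0, wc_fst(freqs, a, b)), pops)
write_square_matrix(fst, args.out / "wc_fst_matrix.csv")
tree = upgma(fst)
write_newick(tree, args.out / "upgma_fst.nwk")

print(f"F_ST matrix over {len(pops)} populations -> {args.out}/wc_fst_matrix.csv")
print("UPGMA tree:", tree.as_string(schema="newick").strip())
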
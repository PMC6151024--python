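#!/usr/bin/env python
"""Outgroup f3 and D statistics on the simulated world.

f3(outgroup; X, Y) ranks the shared drift of every Uralic population with
every other study population; D(outgroup, test; Uralic, non-Uralic)
contrasts allele sharing of each test population with a fixed
(Uralic, non-Uralic) pair - negative D means excess sharing with the
Uralic member.  Standard errors come from a 500-SNP block jackknife and
|Z| > 3 is flagged significant.
"""

import argparse
from pathlib import Path

import pandas as pd

from uralpop.allele_stats import (allele_frequencies, d_statistic,
                                  make_blocks, outgroup_f3)
from uralpop.formats import is_uralic, read_genotypes, read_samples

ap = argparse.ArgumentParser()
ap.add_argument("--world", type=Path, default=Path("results/world"))
ap.add_argument("--out", type=Path, default=Path("results/fstats"))
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

samples = read_samples(args.world / "samples.tsv")
g = read_genotypes(args.world / "genotypes.tsv", samples=samples)
g_auto = g.subset_snps(g.chrom != "X")

outgroup = samples.loc[samples["region"] == "Africa", "population"].iloc[0]
pops = sorted(samples["population"].unique())
lang = dict(zip(samples["population"], samples["language_group"]))
study = [p for p in pops if p != outgroup]
uralic = [p for p in study if is_uralic(lang[p])]

freqs = allele_frequencies(g_auto, samples, pops)
blocks = make_blocks(g_auto.chrom, 500)

rows = []
for x in uralic:
    for y in study:
        if x == y:
            continue
        r = outgroup_f3(freqs, outgroup, x, y, blocks)
        rows.append((x, y, r.estimate, r.std_error, r.z_score, r.n_snps))
f3 = pd.DataFrame(rows, columns=["X", "Y", "f3", "se", "z", "n_snps"])
f3.to_csv(args.out / "outgroup_f3.csv", index=False)
top = f3.sort_values("f3", ascending=False).head(3)
print("highest shared drift (f3):")
print(top.to_string(index=False))

# D(outgroup, test; Uralic C, non-Uralic D) for a fixed western pair
C, D = "Estonians", "Latvians"
rows = []
for test in study:
    if test in (C, D):
        continue
    r = d_statistic(freqs, outgroup, test, C, D, blocks)
    rows.append((test, C, D, r.estimate, r.std_error, r.z_score,
                 r.significant))
dd = pd.DataFrame(rows, columns=["test", "C", "D", "D_stat", "se", "z",
                                 "significant"])
dd.to_csv(args.out / "d_statistics.csv", index=False)
print(f"\nD(outgroup, test; {C}, {D}): {int(dd['significant'].sum())} of "
      f"{len(dd)} tests beyond |Z| > 3")
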
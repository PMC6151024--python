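#!/usr/bin/env python
"""IBD post-processing, cross-regional sharing and the permutation test.

Consensus-filters and gap-merges the raw tracts, bins them by length
(1-2, 2-3, 3-4, 4-5 cM), tabulates mean pairwise sharing per population
pair and bin, and runs the geographic-control permutation test for each
Uralic population against Uralic partners from other regions.  The
significance matrix colours each (target, partner) cell by whether excess
sharing is with a Uralic or non-Uralic partner.
"""

import argparse
from pathlib import Path

import pandas as pd

from uralpop import ibd
from uralpop.formats import is_uralic, read_ibd_tracts, read_samples
from uralpop.simulate import child_seeds

ap = argparse.ArgumentParser()
ap.add_argument("--world", type=Path, default=Path("results/world"))
ap.add_argument("--out", type=Path, default=Path("results/ibd"))
ap.add_argument("--n-perm", type=int, default=2000)
ap.add_argument("--seed", type=int, default=1)
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

samples = read_samples(args.world / "samples.tsv")
samples = samples[samples["region"] != "Africa"]
tracts = read_ibd_tracts(args.world / "ibd_tracts.tsv")
tracts = ibd.merge_gaps(ibd.consensus_filter(tracts))
binned = ibd.bin_by_length(tracts)

pops = sorted(samples["population"].unique())
table = ibd.sharing_table(binned, samples, pops)
table.to_csv(args.out / "sharing_table.csv", index=False)

region = dict(zip(samples["population"], samples["region"]))
lang = dict(zip(samples["population"], samples["language_group"]))
uralic = [p for p in pops if is_uralic(lang[p])]

# geographic controls: the non-Uralic populations of the target's region
controls = {p: [q for q in pops if region[q] == region[p]
                and not is_uralic(lang[q])] for p in uralic}

results = []
seeds = child_seeds(args.seed, [f"perm{i}" for i in range(1000)])
k = 0
for target in uralic:
    if not controls[target]:
        continue  # no geographic control group for this target
    for partner in uralic:
        if region[partner] == region[target]:
            continue
        for bin_label in ("1-2", "2-3"):
            res = ibd.control_permutation_test(
                binned[bin_label], samples, target, partner,
                controls[target], bin_label=bin_label, n_perm=args.n_perm,
                seed=list(seeds.values())[k] & 0x7FFFFFFF)
            results.append(res)
            k += 1

pd.DataFrame([{
    "target": r.target, "partner": r.partner, "bin": r.bin,
    "observed_cm_per_pair": r.observed, "p_value": r.p_value,
    "controls": "+".join(r.control_pops),
} for r in results]).to_csv(args.out / "permutation_tests.csv", index=False)

sig = ibd.significance_matrix(
    [r for r in results if r.bin == "1-2"], samples)
sig.cells.to_csv(args.out / "significance_matrix_1-2cM.csv")
n_sig = (sig.cells != "none").to_numpy().sum()
print(f"{len(results)} permutation tests; {n_sig} significant cells in the "
      f"1-2 cM bin (alpha = 0.05)")
print(sig.cells.to_string())
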
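"""IBD tract post-processing and the geographic-control permutation test.

Tracts arrive as per-pair, per-chromosome cM intervals from multiple
detector runs.  The pipeline is: consensus filtering (score threshold +
union across runs), gap merging with a minimum-length cutoff, binning by
length, mean pairwise sharing between populations, and a permutation test
that compares a target population's sharing with a distant partner against
sharing computed from random subsamples of a pooled geographic control
group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import IBD_COLUMNS, is_uralic


@dataclass
class PermutationResult:
    target: str
    partner: str
    bin: str
    observed: float          # cM per pair
    n_perm: int
    n_exceed: int            # null draws >= observed
    p_value: float
    control_pops: list[str]
    seed: int

    def __post_init__(self) -> None:
        expected = (self.n_exceed + 1) / (self.n_perm + 1)
        assert abs(self.p_value - expected) < 1e-12


@dataclass
class SignificanceMatrix:
    """Fig-4-style matrix: rows = tested populations, columns = partners.

    Cells are "none", "uralic_excess" (excess sharing with a Uralic-speaking
    partner) or "nonuralic_excess"; the control listing per row records the
    pooled geographic control populations used for that target.
    """

    cells: pd.DataFrame
    controls: dict[str, list[str]] = field(default_factory=dict)


def _lengths(t: pd.DataFrame) -> np.ndarray:
    return (t["end_cm"] - t["start_cm"]).to_numpy()


def _union_intervals(starts: np.ndarray, ends: np.ndarray,
                     gap_max: float = 0.0) -> list[tuple[float, float]]:
    """Union of half-open intervals, additionally bridging gaps < gap_max."""
    order = np.argsort(starts, kind="stable")
    out: list[tuple[float, float]] = []
    for s, e in zip(starts[order], ends[order]):
        if out and s - out[-1][1] < gap_max or out and s <= out[-1][1]:
            prev_s, prev_e = out[-1]
            out[-1] = (prev_s, max(prev_e, e))
        else:
            out.append((float(s), float(e)))
    return out


def consensus_filter(t: pd.DataFrame, score_max: float = 1e-10,
                     runs: int = 10) -> pd.DataFrame:
    """Keep tracts with score <= score_max and union them across runs.

    For each pair and chromosome, overlapping or abutting intervals from
    any of the ``runs`` detector runs coalesce into one tract; run ids are
    erased (set to 0) and the minimum contributing score is retained.
    """
    if len(t) and ((t["run_id"] < 1) | (t["run_id"] > runs)).any():
        raise ValueError(f"run_id outside [1, {runs}]")
    kept = t[t["score"] <= score_max]
    rows = []
    for (a, b, chrom), grp in kept.groupby(["sample_a", "sample_b", "chrom"],
                                           sort=True):
        merged = _union_intervals(grp["start_cm"].to_numpy(),
                                  grp["end_cm"].to_numpy())
        score = float(grp["score"].min())
        for s, e in merged:
            rows.append((a, b, chrom, s, e, score, 0))
    return pd.DataFrame(rows, columns=IBD_COLUMNS)


def merge_gaps(t: pd.DataFrame, gap_max_cm: float = 0.5,
               min_length_cm: float = 1.0) -> pd.DataFrame:
    """Bridge spurious gaps shorter than ``gap_max_cm`` and drop short tracts.

    Emulates the standard post-processing of detector output in which low
    marker density and phasing switch errors break long IBD blocks: per pair
    and chromosome, tracts separated by a gap < gap_max_cm merge; merged
    tracts shorter than ``min_length_cm`` are then discarded.  Idempotent.
    """
    rows = []
    for (a, b, chrom), grp in t.groupby(["sample_a", "sample_b", "chrom"],
                                        sort=True):
        merged = _union_intervals(grp["start_cm"].to_numpy(),
                                  grp["end_cm"].to_numpy(), gap_max=gap_max_cm)
        score = float(grp["score"].min())
        for s, e in merged:
            if e - s >= min_length_cm:
                rows.append((a, b, chrom, s, e, score, 0))
    return pd.DataFrame(rows, columns=IBD_COLUMNS)


def bin_by_length(t: pd.DataFrame,
                  edges: list[float] = [1.0, 2.0, 3.0, 4.0, 5.0]
                  ) -> dict[str, pd.DataFrame]:
    """Sort tracts into half-open length bins [e_i, e_{i+1}).

    A tract of length exactly 2.0 cM goes to the "2-3" bin; tracts at or
    beyond the last edge (and below the first) are excluded.
    """
    if (np.diff(edges) <= 0).any():
        raise ValueError("bin edges must be strictly increasing")
    lengths = _lengths(t)
    out: dict[str, pd.DataFrame] = {}
    for lo, hi in zip(edges[:-1], edges[1:]):
        label = f"{lo:g}-{hi:g}"
        out[label] = t[(lengths >= lo) & (lengths < hi)].reset_index(drop=True)
    return out


def _pop_members(samples: pd.DataFrame, pop: str) -> list[str]:
    return list(samples.loc[samples["population"] == pop, "sample_id"])


def n_pairs(n_a: int, n_b: int, same_pop: bool) -> int:
    return n_a * (n_a - 1) // 2 if same_pop else n_a * n_b


def pair_sharing_matrix(t: pd.DataFrame, rows: list[str],
                        cols: list[str]) -> np.ndarray:
    """Total tract length (cM) per (row-sample, col-sample) pair."""
    ridx = {s: i for i, s in enumerate(rows)}
    cidx = {s: j for j, s in enumerate(cols)}
    out = np.zeros((len(rows), len(cols)))
    lengths = _lengths(t)
    a = t["sample_a"].to_numpy()
    b = t["sample_b"].to_numpy()
    for x, y, ln in zip(a, b, lengths):
        if x in ridx and y in cidx:
            out[ridx[x], cidx[y]] += ln
        if y in ridx and x in cidx:
            out[ridx[y], cidx[x]] += ln
    return out


def mean_pairwise_sharing(t: pd.DataFrame, samples: pd.DataFrame,
                          popA: str, popB: str) -> float:
    """Sum of tract lengths between the populations divided by pair count.

    The denominator is n_A * n_B for distinct populations and n(n-1)/2
    within one; pairs without any tract contribute zero length but still
    count as pairs.  ``t`` is typically one length bin.
    """
    mem_a = _pop_members(samples, popA)
    mem_b = _pop_members(samples, popB)
    same = popA == popB
    pairs = n_pairs(len(mem_a), len(mem_b), same)
    if pairs == 0:
        raise ValueError(f"no pairs between {popA!r} and {popB!r}")
    mat = pair_sharing_matrix(t, mem_a, mem_b)
    if same:
        total = float(np.triu(mat, k=1).sum())
    else:
        total = float(mat.sum())
    return total / pairs


def control_permutation_test(t: pd.DataFrame, samples: pd.DataFrame,
                             target: str, partner: str,
                             control_pops: list[str], bin_label: str = "",
                             n_perm: int = 10000, seed: int = 0,
                             include_target_in_pool: bool = True
                             ) -> PermutationResult:
    """Permutation test of excess IBD sharing against a geographic control.

    The observed statistic is the target population's mean pairwise sharing
    with the partner.  The null distribution resamples, ``n_perm`` times,
    a subset of the pooled *individuals* of the target's sample size
    (without replacement) and computes their sharing with the partner.
    p = (#{null >= observed} + 1) / (n_perm + 1), one-sided upper.

    By default the pool is the target's individuals together with the
    control individuals, which makes the randomization exact: under the
    null hypothesis that the target shares like its geographic controls,
    the observed subset is one draw from the resampling orbit and p is
    uniform.  ``include_target_in_pool=False`` restricts the pool to the
    controls alone; that variant's null is under-dispersed (every draw
    reuses the same control individuals) and is kept only for comparison.
    """
    if target in control_pops or partner in control_pops:
        raise ValueError("target and partner must not be control populations")
    region = dict(zip(samples["population"], samples["region"]))
    if region.get(target) == region.get(partner):
        warnings.warn(f"target {target!r} and partner {partner!r} share a "
                      "region; the geographic control logic assumes they do not")
    mem_t = _pop_members(samples, target)
    mem_p = _pop_members(samples, partner)
    pool: list[str] = []
    for cp in control_pops:
        pool.extend(_pop_members(samples, cp))
    n_t = len(mem_t)
    if len(pool) < n_t:
        raise ValueError(f"pooled control ({len(pool)}) smaller than target "
                         f"sample ({n_t})")
    if include_target_in_pool:
        pool = mem_t + pool
    observed = mean_pairwise_sharing(t, samples, target, partner)

    mat = pair_sharing_matrix(t, pool, mem_p)
    row_totals = mat.sum(axis=1)
    rng = np.random.default_rng(seed)
    denom = n_t * len(mem_p)
    null = np.empty(n_perm)
    for i in range(n_perm):
        pick = rng.choice(len(pool), size=n_t, replace=False)
        null[i] = row_totals[pick].sum() / denom
    n_exceed = int((null >= observed).sum())
    p = (n_exceed + 1) / (n_perm + 1)
    return PermutationResult(target=target, partner=partner, bin=bin_label,
                             observed=observed, n_perm=n_perm,
                             n_exceed=n_exceed, p_value=p,
                             control_pops=list(control_pops), seed=seed)


def significance_matrix(results: list[PermutationResult],
                        samples: pd.DataFrame,
                        alpha: float = 0.05) -> SignificanceMatrix:
    """Colour the (target, partner) grid by permutation significance.

    A cell is "uralic_excess" when p < alpha and the partner speaks a
    Uralic language, "nonuralic_excess" when p < alpha and it does not,
    else "none".  Duplicate (target, partner, bin) cells are an error.
    """
    seen = set()
    lang = dict(zip(samples["population"], samples["language_group"]))
    targets = list(dict.fromkeys(r.target for r in results))
    partners = list(dict.fromkeys(r.partner for r in results))
    cells = pd.DataFrame("none", index=targets, columns=partners)
    controls: dict[str, list[str]] = {}
    for r in results:
        key = (r.target, r.partner, r.bin)
        if key in seen:
            raise ValueError(f"duplicate cell {key}")
        seen.add(key)
        controls[r.target] = r.control_pops
        if r.p_value < alpha:
            kind = ("uralic_excess" if is_uralic(lang.get(r.partner, ""))
                    else "nonuralic_excess")
            cells.loc[r.target, r.partner] = kind
    return SignificanceMatrix(cells=cells, controls=controls)


def sharing_table(t_binned: dict[str, pd.DataFrame], samples: pd.DataFrame,
                  populations: list[str] | None = None) -> pd.DataFrame:
    """Mean pairwise sharing (cM/pair) for every population pair and bin."""
    if populations is None:
        populations = list(pd.unique(samples["population"]))
    rows = []
    for bin_label, tb in t_binned.items():
        for i, a in enumerate(populations):
            for b in populations[i:]:
                mem_a = _pop_members(samples, a)
                mem_b = _pop_members(samples, b)
                pairs = n_pairs(len(mem_a), len(mem_b), a == b)
                if pairs == 0:
                    continue
                mean = mean_pairwise_sharing(tb, samples, a, b)
                rows.append((bin_label, a, b, pairs, mean * pairs, mean))
    return pd.DataFrame(rows, columns=["bin", "pop_a", "pop_b", "pair_count",
                                       "total_cm", "mean_cm_per_pair"])
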
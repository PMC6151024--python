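"""IBD post-processing, sharing statistics and the permutation test."""

import numpy as np
import pandas as pd
import pytest

from uralpop import ibd
from uralpop.formats import IBD_COLUMNS
from uralpop.simulate import child_seeds

from conftest import make_samples


def tracts(rows):
    return pd.DataFrame(rows, columns=IBD_COLUMNS)


# ---------------------------------------------------------------------------
# consensus_filter
# ---------------------------------------------------------------------------

def test_consensus_score_threshold_and_union():
    t = tracts([
        ("a", "b", "1", 1.0, 2.0, 1e-12, 1),
        ("a", "b", "1", 1.5, 3.0, 1e-11, 4),
        ("a", "b", "1", 5.0, 6.0, 1e-9, 2),    # score too high -> dropped
        ("a", "b", "2", 1.0, 2.0, 1e-12, 1),
        ("a", "b", "2", 3.0, 4.0, 1e-12, 2),   # disjoint -> stays separate
    ])
    out = ibd.consensus_filter(t)
    chr1 = out[out["chrom"] == "1"]
    assert len(chr1) == 1
    assert (chr1.iloc[0]["start_cm"], chr1.iloc[0]["end_cm"]) == (1.0, 3.0)
    assert len(out[out["chrom"] == "2"]) == 2
    assert (out["run_id"] == 0).all()


def test_consensus_coalesces_abutting():
    t = tracts([("a", "b", "1", 1.0, 2.0, 1e-12, 1),
                ("a", "b", "1", 2.0, 3.0, 1e-12, 2)])
    out = ibd.consensus_filter(t)
    assert len(out) == 1 and out.iloc[0]["end_cm"] == 3.0


# ---------------------------------------------------------------------------
# merge_gaps
# ---------------------------------------------------------------------------

def test_merge_gaps_rules():
    t = tracts([
        ("a", "b", "1", 1.0, 2.2, 1e-12, 0),
        ("a", "b", "1", 2.5, 4.0, 1e-12, 0),   # gap 0.3 < 0.5 -> merged
        ("a", "b", "2", 1.0, 2.0, 1e-12, 0),
        ("a", "b", "2", 3.0, 4.0, 1e-12, 0),   # gap 1.0 -> kept apart
        ("a", "c", "1", 0.2, 0.9, 1e-12, 0),   # 0.7 cM -> discarded
    ])
    out = ibd.merge_gaps(t)
    ab1 = out[(out["sample_b"] == "b") & (out["chrom"] == "1")]
    assert len(ab1) == 1
    assert (ab1.iloc[0]["start_cm"], ab1.iloc[0]["end_cm"]) == (1.0, 4.0)
    assert len(out[(out["sample_b"] == "b") & (out["chrom"] == "2")]) == 2
    assert (out["sample_b"] != "c").all()


def test_merge_gaps_idempotent():
    rng = np.random.default_rng(11)
    rows = []
    for k in range(60):
        s = rng.uniform(0, 50)
        rows.append(("a", f"b{k % 5}", str(k % 3 + 1), s,
                     s + rng.uniform(0.2, 4.0), 1e-12, 0))
    t = tracts(rows)
    once = ibd.merge_gaps(t)
    twice = ibd.merge_gaps(once)
    pd.testing.assert_frame_equal(once, twice)


# ---------------------------------------------------------------------------
# bin_by_length
# ---------------------------------------------------------------------------

def test_bin_by_length_half_open_and_exclusions():
    t = tracts([
        ("a", "b", "1", 0.0, 1.5, 1e-12, 0),   # 1.5 -> "1-2"
        ("a", "b", "1", 0.0, 2.0, 1e-12, 0),   # exactly 2.0 -> "2-3"
        ("a", "b", "1", 0.0, 6.0, 1e-12, 0),   # >= 5 -> excluded
    ])
    bins = ibd.bin_by_length(t)
    assert len(bins["1-2"]) == 1 and bins["1-2"].iloc[0]["end_cm"] == 1.5
    assert len(bins["2-3"]) == 1 and bins["2-3"].iloc[0]["end_cm"] == 2.0
    assert sum(len(b) for b in bins.values()) == 2


def test_bin_by_length_conserves_total_length(rng):
    rows = []
    for k in range(200):
        s = rng.uniform(0, 50)
        rows.append(("a", "b", "1", s, s + rng.uniform(0.1, 7.0), 1e-12, 0))
    t = tracts(rows)
    bins = ibd.bin_by_length(t)
    total_in = (t["end_cm"] - t["start_cm"]).sum()
    lengths = t["end_cm"] - t["start_cm"]
    discarded = lengths[(lengths < 1.0) | (lengths >= 5.0)].sum()
    binned = sum((b["end_cm"] - b["start_cm"]).sum() for b in bins.values())
    assert binned + discarded == pytest.approx(total_in, rel=1e-12)


# ---------------------------------------------------------------------------
# mean_pairwise_sharing
# ---------------------------------------------------------------------------

def test_mean_pairwise_sharing_hand_count():
    samples = pd.concat([make_samples({"A": 2}), make_samples({"B": 3})],
                        ignore_index=True)
    t = tracts([("A_0", "B_1", "1", 1.0, 2.2, 1e-12, 0),
                ("A_1", "B_2", "1", 1.0, 2.8, 1e-12, 0)])
    # total 3.0 cM over 2*3 = 6 pairs
    assert ibd.mean_pairwise_sharing(t, samples, "A", "B") == pytest.approx(0.5)
    assert ibd.mean_pairwise_sharing(tracts([]), samples, "A", "B") == 0.0


def test_mean_pairwise_sharing_within_population():
    samples = make_samples({"A": 2})
    t = tracts([("A_0", "A_1", "1", 1.0, 2.5, 1e-12, 0)])
    assert ibd.mean_pairwise_sharing(t, samples, "A", "A") == pytest.approx(1.5)


# ---------------------------------------------------------------------------
# control_permutation_test
# ---------------------------------------------------------------------------

def _three_pop_samples(n=6):
    rows = []
    for pop, region in [("T", "r1"), ("P", "r2"), ("C", "r1")]:
        for k in range(n):
            rows.append({"sample_id": f"{pop}_{k}", "population": pop,
                         "sex": "female", "language_group": "Uralic:Finnic",
                         "region": region, "lat": 60.0, "lon": 25.0})
    return pd.DataFrame(rows)


def test_permutation_p_floor_when_observed_tops_all():
    samples = _three_pop_samples()
    rows = [("P_%d" % j, "T_%d" % i, "1", 1.0, 2.5, 1e-12, 0)
            for i in range(6) for j in range(6)]
    from uralpop.formats import canonicalize_tracts
    t = canonicalize_tracts(tracts(rows))
    res = ibd.control_permutation_test(t, samples, "T", "P", ["C"],
                                       n_perm=100, seed=7)
    assert res.p_value == pytest.approx(1 / 101)
    assert res.n_exceed == 0


def test_permutation_reproducible_and_p_mean_half_under_null():
    """Exchangeable sharing: p is uniform, so its mean over replicates
    approaches 1/2."""
    samples = _three_pop_samples(n=6)
    seeds = child_seeds(123, [f"r{i}" for i in range(200)])
    ps = []
    for s in seeds.values():
        rng = np.random.default_rng(s)
        rows = []
        for pop in ("T", "C"):
            for i in range(6):
                for j in range(6):
                    for _ in range(rng.poisson(1.0)):
                        st = rng.uniform(0, 40)
                        rows.append((f"{pop}_{i}", f"P_{j}", "1", st,
                                     st + rng.uniform(1.0, 2.0), 1e-12, 0))
        from uralpop.formats import canonicalize_tracts
        t = canonicalize_tracts(tracts(rows))
        res = ibd.control_permutation_test(t, samples, "T", "P", ["C"],
                                           n_perm=99, seed=int(s) & 0x7FFFFFFF)
        ps.append(res.p_value)
    assert abs(np.mean(ps) - 0.5) < 0.05

    res1 = ibd.control_permutation_test(t, samples, "T", "P", ["C"],
                                        n_perm=99, seed=42)
    res2 = ibd.control_permutation_test(t, samples, "T", "P", ["C"],
                                        n_perm=99, seed=42)
    assert res1.p_value == res2.p_value
    assert res1.n_exceed == res2.n_exceed


def test_permutation_precondition_errors():
    samples = _three_pop_samples()
    t = tracts([])
    with pytest.raises(ValueError, match="control"):
        ibd.control_permutation_test(t, samples, "T", "P", ["T"])
    big = pd.concat([samples,
                     make_samples({"T2": 20}, region="r1")], ignore_index=True)
    with pytest.raises(ValueError, match="smaller than target"):
        ibd.control_permutation_test(t, big, "T2", "P", ["C"])


# ---------------------------------------------------------------------------
# significance_matrix
# ---------------------------------------------------------------------------

def _result(target, partner, p, bin_label="1-2"):
    n_exceed = round(p * 1001) - 1
    return ibd.PermutationResult(target=target, partner=partner,
                                 bin=bin_label, observed=1.0, n_perm=1000,
                                 n_exceed=n_exceed,
                                 p_value=(n_exceed + 1) / 1001,
                                 control_pops=["C"], seed=0)


def test_significance_matrix_colouring():
    samples = pd.concat([
        make_samples({"T": 2}, language="Uralic:Finnic"),
        make_samples({"U": 2}, language="Uralic:Permic"),
        make_samples({"N": 2}, language="IndoEuropean:Slavic"),
    ], ignore_index=True)
    results = [_result("T", "U", 0.003), _result("T", "N", 0.01)]
    m = ibd.significance_matrix(results, samples, alpha=0.05)
    assert m.cells.loc["T", "U"] == "uralic_excess"
    assert m.cells.loc["T", "N"] == "nonuralic_excess"
    results2 = [_result("T", "U", 0.2)]
    m2 = ibd.significance_matrix(results2, samples)
    assert m2.cells.loc["T", "U"] == "none"
    with pytest.raises(ValueError, match="duplicate"):
        ibd.significance_matrix([_result("T", "U", 0.1)] * 2, samples)
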
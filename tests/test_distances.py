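"""Haplogroup F_ST / Phi_ST, TVD, haversine, patristic distances and UPGMA."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from uralpop import distances as di
from uralpop.formats import ChunkcountMatrix, DistanceMatrix, HaplogroupTable


def hg_table(c1, c2, hgs=None):
    hgs = hgs or [f"h{i}" for i in range(len(c1))]
    return HaplogroupTable("chrY", pd.DataFrame([c1, c2], index=["p1", "p2"],
                                                columns=hgs))


# ---------------------------------------------------------------------------
# Haplogroup F_ST (G_ST) and Phi_ST
# ---------------------------------------------------------------------------

def test_gst_identity_fixed_and_oracle():
    assert di.conventional_fst_haplogroups(hg_table([8, 2], [8, 2]),
                                           "p1", "p2") == pytest.approx(0.0)
    assert di.conventional_fst_haplogroups(hg_table([10, 0], [0, 10]),
                                           "p1", "p2") == pytest.approx(1.0)
    # H_S = 0.32, H_T = 0.5 -> (0.5 - 0.32)/0.5 = 0.36
    assert di.conventional_fst_haplogroups(hg_table([8, 2], [2, 8]),
                                           "p1", "p2") == pytest.approx(
        0.36, abs=1e-12)


def test_gst_undefined_when_both_fixed_same():
    with pytest.warns(UserWarning, match="undefined"):
        v = di.conventional_fst_haplogroups(hg_table([10, 0], [10, 0]),
                                            "p1", "p2")
    assert np.isnan(v)


def test_phi_st_amova_oracle():
    # counts (8,2) vs (2,8): exact fractions Phi = 73/153, linearized 73/80
    h = hg_table([8, 2], [2, 8])
    assert di.phi_st(h, "p1", "p2") == pytest.approx(73 / 153, abs=1e-12)
    assert di.phi_st_linearized(h, "p1", "p2") == pytest.approx(73 / 80,
                                                                abs=1e-12)


def test_phi_st_degenerate_cases():
    assert di.phi_st_linearized(hg_table([5, 5], [5, 5]), "p1", "p2") == 0.0
    with pytest.warns(UserWarning, match="infinite"):
        v = di.phi_st_linearized(hg_table([10, 0], [0, 10]), "p1", "p2")
    assert np.isnan(v)


def test_phi_st_linearization_monotone():
    lins, phis = [], []
    for k in [1, 2, 3, 4]:
        h = hg_table([10 - k, k], [k, 10 - k])
        phis.append(di.phi_st(h, "p1", "p2"))
        lins.append(di.phi_st_linearized(h, "p1", "p2"))
    order = np.argsort(phis)
    assert all(np.diff(np.array(lins)[order]) >= 0)


def test_gst_and_phi_agree_under_weak_differentiation(rng):
    """G_ST and the AMOVA Phi_ST agree within 0.02 for two haplogroups at
    n = 500 per population when differentiation is weak.

    The two statistics are not identical - their ratio approaches 2 as
    divergence shrinks - so agreement on the absolute scale holds only
    where both are small, the regime of the uniparental comparisons here.
    """
    n = 500
    c1 = rng.multinomial(n, [0.45, 0.55])
    c2 = rng.multinomial(n, [0.55, 0.45])
    h = hg_table(list(c1), list(c2))
    gst = di.conventional_fst_haplogroups(h, "p1", "p2")
    phi = di.phi_st(h, "p1", "p2")
    assert abs(gst - phi) < 0.02


# ---------------------------------------------------------------------------
# TVD
# ---------------------------------------------------------------------------

def _chunk(rows, donors, recipients):
    return ChunkcountMatrix(pd.DataFrame(rows, index=recipients,
                                         columns=donors))


def test_tvd_identity_maximal_and_oracle():
    donors = ["d1", "d2", "d3"]
    c = _chunk([[5, 5, 0], [5, 5, 0]], donors, ["r1", "r2"])
    assert di.tvd_groups(c, ["r1"], ["r2"]) == pytest.approx(0.0)
    c2 = _chunk([[10, 0, 0], [0, 0, 10]], donors, ["r1", "r2"])
    assert di.tvd_groups(c2, ["r1"], ["r2"]) == pytest.approx(1.0)
    # (0.5, 0.5, 0) vs (0.25, 0.25, 0.5) -> 0.5 * (0.25 + 0.25 + 0.5) = 0.5
    c3 = _chunk([[2, 2, 0], [1, 1, 2]], donors, ["r1", "r2"])
    assert di.tvd_groups(c3, ["r1"], ["r2"]) == pytest.approx(0.5, abs=1e-12)


def test_tvd_ignores_self_copy_and_validates():
    c = _chunk([[3.0, 1, 1], [0.0, 2, 2]], ["r1", "d2", "d3"], ["r1", "r2"])
    # r1's self-copy cell (3.0) must not enter its profile
    assert di.tvd_groups(c, ["r1"], ["r2"]) == pytest.approx(0.0)
    with pytest.raises(ValueError, match="disjoint"):
        di.tvd_groups(c, ["r1"], ["r1"])
    with pytest.raises(ValueError, match="zero-sum"):
        di.tvd_groups(c, ["r1"], ["r2"], exclude_donors={"d2", "d3"})


# ---------------------------------------------------------------------------
# Haversine
# ---------------------------------------------------------------------------

def test_haversine_closed_forms():
    assert di.haversine_km((60, 25), (60, 25)) == 0.0
    # antipodal -> pi * R
    assert di.haversine_km((0, 0), (0, 180)) == pytest.approx(
        np.pi * di.EARTH_RADIUS_KM, rel=1e-9)
    # one equatorial degree -> 2 pi R / 360
    assert di.haversine_km((0, 0), (0, 1)) == pytest.approx(
        2 * np.pi * di.EARTH_RADIUS_KM / 360, rel=1e-9)
    with pytest.raises(ValueError, match="latitude"):
        di.haversine_km((91, 0), (0, 0))


def test_haversine_triangle_inequality(rng):
    for _ in range(50):
        pts = [(float(rng.uniform(-90, 90)), float(rng.uniform(-180, 180)))
               for _ in range(3)]
        d01 = di.haversine_km(pts[0], pts[1])
        d12 = di.haversine_km(pts[1], pts[2])
        d02 = di.haversine_km(pts[0], pts[2])
        assert d02 <= d01 + d12 + 1e-6


# ---------------------------------------------------------------------------
# Patristic distances
# ---------------------------------------------------------------------------

def test_patristic_brute_force_oracle():
    tree = dendropy.Tree.get(data="((A:1,B:2):0.5,(C:3,D:4):1.5);",
                             schema="newick")
    m = di.patristic_distances(tree)
    expected = {("A", "B"): 3.0, ("A", "C"): 6.0, ("A", "D"): 7.0,
                ("B", "C"): 7.0, ("B", "D"): 8.0, ("C", "D"): 7.0}
    for (a, b), d in expected.items():
        i, j = m.labels.index(a), m.labels.index(b)
        assert m.values[i, j] == pytest.approx(d, abs=1e-12)
    assert np.allclose(np.diag(m.values), 0.0)


def test_patristic_cherry():
    tree = dendropy.Tree.get(data="(A:1,B:2);", schema="newick")
    m = di.patristic_distances(tree)
    assert m.values[0, 1] == pytest.approx(3.0)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def test_upgma_two_taxa_splits_distance():
    m = DistanceMatrix(["A", "B"], np.array([[0.0, 4.0], [4.0, 0.0]]))
    tree = di.upgma(m)
    lengths = sorted(l.edge.length for l in tree.leaf_node_iter())
    assert lengths == pytest.approx([2.0, 2.0])


def test_upgma_three_taxon_hand_case():
    m = DistanceMatrix(["A", "B", "C"],
                       np.array([[0.0, 2.0, 6.0],
                                 [2.0, 0.0, 6.0],
                                 [6.0, 6.0, 0.0]]))
    tree = di.upgma(m)
    pat = di.patristic_distances(tree)
    i, j, k = (pat.labels.index(x) for x in "ABC")
    assert pat.values[i, j] == pytest.approx(2.0)   # heights 1 and 3
    assert pat.values[i, k] == pytest.approx(6.0)
    assert pat.values[j, k] == pytest.approx(6.0)
    c_leaf = [l for l in tree.leaf_node_iter() if l.taxon.label == "C"][0]
    assert c_leaf.edge.length == pytest.approx(3.0)


def test_upgma_tie_break_deterministic():
    m = DistanceMatrix(list("DCBA"), np.ones((4, 4)) - np.eye(4))
    s1 = di.upgma(m).as_string(schema="newick")
    s2 = di.upgma(m).as_string(schema="newick")
    assert s1 == s2
    with pytest.raises(ValueError, match="NaN"):
        vals = np.ones((4, 4)) - np.eye(4)
        vals[0, 1] = vals[1, 0] = np.nan
        di.upgma(DistanceMatrix(list("ABCD"), vals))


# ---------------------------------------------------------------------------
# build_distance_matrix
# ---------------------------------------------------------------------------

def test_build_distance_matrix_missing_cells():
    def fn(a, b):
        return np.nan if {a, b} == {"p1", "p3"} else 1.0

    m = di.build_distance_matrix(fn, ["p1", "p2", "p3"])
    assert m.missing_pairs() == [("p1", "p3")]
    assert m.values[0, 1] == 1.0


def test_geographic_distance_matrix():
    samples = pd.DataFrame([
        {"sample_id": "a", "population": "A", "sex": "female",
         "language_group": "x", "region": "r", "lat": 0.0, "lon": 0.0},
        {"sample_id": "b", "population": "B", "sex": "female",
         "language_group": "x", "region": "r", "lat": 0.0, "lon": 1.0},
    ])
    m = di.geographic_distance_matrix(samples)
    assert m.values[0, 1] == pytest.approx(111.19, abs=0.01)
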